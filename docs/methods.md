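# Methods

## The inference problem

Two sister species diverged from a common ancestral population at some
time T_split. The data are multilocus alignments of haploid sequences
(n_A and n_B per locus) at unlinked coding loci, with a single outgroup
sequence per locus that (i) polarizes alleles into ancestral/derived and
(ii) calibrates mutation rates through its divergence. The inference
compares twelve divergence models — four migration scenarios crossed
with three population-size modes — and estimates the parameters of the
best one, using ABC: the likelihood is replaced by closeness of
simulated to observed summary statistics.

## Summary statistics

All statistics are computed on *usable* masked sites: synonymous
positions where no ingroup sequence is missing (N/-) and the pooled
ingroup sample carries at most two alleles. Complete-case filtering
matches direct-sequencing data, where a missing base is a failed read,
not a genotype. Denominators are counts of usable sites.

Per locus: π (unbiased mean pairwise difference per site, per species),
Watterson's θ_W = S/a₁/L with a₁ = Σ_{i<n} 1/i, Tajima's D with the 1989
variance normalization (undefined at S = 0, propagated as NaN and never
as 0), F_ST = 1 − π_s/π_T with π_s the *unweighted* mean of the two
within-species π (the definition names the average within-population
diversity, not a per-chromosome average), K_AB (mean pairwise
between-species difference per site), K_out (mean ingroup–outgroup
difference per outgroup-callable usable site) and the Nei net divergence
net_K_out = K_out − (π_A + π_B)/2. No multiple-hit correction is applied
anywhere: the simulator is infinite-sites, and consistency between
observed and simulated statistics matters more than mutational realism
at these divergence levels (K_syn ≲ 0.1).

Polarized sites are classified by the derived frequency in each species
(f ∈ (0,1) vs {0,1}) into Sx_A, Sx_B, Sf_A, Sf_B, Ss, Sx_Af_B, Sx_Bf_A.
Sites fixed derived in *both* species are excluded: they are neither
polymorphic nor between-ingroup fixed differences (equivalently, the
(0,0) and (n_A,n_B) corners of the joint SFS are structurally empty).
Sites that cannot be polarized (missing or third-state outgroup,
>2 ingroup alleles) are tallied in a skip report.

The dataset-level vector has 22 entries: mean and SD across loci of
{π_A, π_B, θW_A, θW_B, D_A, D_B, K_AB, F_ST} (16), means of
{Ss, Sf = Sf_A+Sf_B, Sx_A, Sx_B} (4), and SDs of {Ss, Sf} (2). Loci with
an undefined statistic are excluded from that statistic's moments only,
with exclusion counts recorded; a column with no contributing locus
yields 0 (this occurs only for near-zero-diversity parameter draws
inside reference tables). SDs use ddof = 0 so a single-locus dataset has
well-defined (zero) spread.

## Coalescent simulator

A Hudson-style ancestral recombination graph over two demes. Scaling:
time in units of 4·N_ref generations with N_ref = the drawn N_hal (ms
convention of scaling by a focal deme); a lineage pair in a deme of
relative size x coalesces at rate 2/x; per-lineage migration rate M =
4·N_ref·m where m is the backward per-generation migrant fraction;
mutation rate θ = 4·N_ref·μ·L per unit of carried ancestral length;
recombination rate ρ per unit of carried breadth, with ρ = θ by default
(the observed ρ/θ ≈ 1 in outcrossing *Arabidopsis*-like panels).

Each lineage carries a linked list of genomic segments tagged with the
bitset of descendant samples. Coalescence merges two segment lists,
unioning bitsets on overlaps; a segment whose bitset reaches the full
sample has found its marginal MRCA, is recorded as an (interval, time)
triple and dropped. Recombination splits a lineage at a uniform
breakpoint within its breadth. Mutations are competing events at rate
θ·(carried length), placed uniformly on the carrying segment; because
the ancestral state is known, polarization of simulated data is exact
and no outgroup lineage is simulated. The simulation ends when no
ancestral material remains. Time-varying sizes use exact inversion of
the exponential-rate integral per epoch; epochs encode the growth onset,
bottleneck time, migration windows (CM: (0, T_split); AM:
(T_iso, T_split); SC: (0, T_SC)) and the merge of both demes into the
ancestor at T_split. A hard event-count guard (4×10⁶) catches runaway
recombination. The kernel is numba-compiled; one study-scale locus
(62+96 samples, θ ≈ ρ ≈ 3) simulates in ~0.3 ms.

Shape parameters the scenario grid leaves implicit are declared
defaults, configurable: E-mode growth starts (forwards) at T_split/2
from a founding size N_anc/2 per daughter; B-mode reduces species A to a
fraction f_b ~ U(0.01, 0.5) of N_hal at T_b ~ U(0, T_split) with
exponential regrowth to the present, constant N_hal before T_b, species
B constant.

Validation: E[S] = θ·a₁ and E[π·L] = θ in the single-deme reduction
(within 5% at 5000 replicates); grand-TMRCA means against coalescent
theory; and two-sample KS agreement with msprime for S, π and Tajima's D
on matched SIC/CMC/AMC/SCC/SIE/SIB scenarios (the msprime comparison is
a test-suite oracle only; the simulator shares no code with it).

## Priors

N_hal, N_lyr ~ U(0, 300 000); N_anc ~ U(0, 1 000 000); M (each
direction) ~ U(0, 20) in 4Nm units; T_split ~ U(0, 3 200 000) years;
T_iso, T_SC (and T_b) ~ U(0, T_split) conditional on the drawn T_split;
f_b ~ U(0.01, 0.5). Generation time 2 years. Sizes drawn at the lower
bound are floored at one individual.

## ABC procedures

Distances standardize every statistic by its median absolute deviation
over the pooled reference table (robust to the heavy-tailed statistic
distributions produced by diffuse priors; zero-MAD columns fall back to
the SD, then to 1). Rejection keeps the nearest fraction (0.1% at the
full 5×10⁶-per-model scale; desk presets keep an absolute floor of ≥100
rows) weighted by the Epanechnikov kernel w = 1 − (δ/δ_max)².

Model choice regresses the model indicator on the statistics within the
accepted set. Two backends: weighted multinomial logistic regression
(default — deterministic, converged, fast at desk scale) and an
ensemble of single-hidden-layer neural classifiers (50 × 10 hidden units
at full scale) with the Epanechnikov weights realized as weighted
bootstrap resampling per member, probabilities averaged and
renormalized. The rejection-only weighted-frequency posterior is always
reported alongside. The hierarchical procedure first compares, within
each scenario class, constant size pairwise against growth and against
bottleneck; each class's best model advances to a four-way final.

Parameter estimation keeps the 2000 nearest simulations (500 at desk
scale), maps parameters to ℝ by the log-tangent transform
y = log tan(π/2 · (x−a)/(b−a)) of each prior interval (round-trips to
10⁻¹⁰ of the interval width; boundary values are ε-clamped), adjusts the
accepted draws by the ensemble-averaged conditional-mean shift
y* = y + m̂(s_obs) − m̂(s) fitted by neural-net regressions (100 × 15
hidden units at full scale), back-transforms (automatically inside the
prior box; nested times re-clipped below T_split), and summarizes with
weighted Gaussian-KDE modes and smallest-width HPD intervals on a
512-point grid. A zero-spread accepted set downgrades to rejection-only
with a warning.

## Calibration and goodness of fit

PODs are drawn per candidate model from its own reference table (a
table row *is* a prior-predictive dataset), with the POD's own row
removed from its table before inference; fresh-simulation PODs are
available behind a flag. Recovery is the fraction of PODs whose true
model gets posterior > 0.5. The correctness probability given an
observed posterior value p* is the density ratio
d_winner(p*) / Σ_m d_m(p*) under equal model priors, with each density a
boundary-reflected Gaussian KDE on [0, 1].

Goodness of fit draws parameter vectors from the weighted posterior,
re-simulates datasets, and compares held-out statistics — the
proportions of the six aggregated site classes, which enter the
inference only as count means/SDs, never as composition — with
two-sided (r+1)/(n+1)-corrected posterior-predictive p-values.

## Synthetic studies

The generator emulates the target data shape: 29 unlinked coding loci of
402–1398 sites (every third codon position four-fold degenerate, so the
synonymous mask is honest), 62 + 96 haplotypes, per-locus mutation rates
log-normally scattered (σ = 0.2) around 7×10⁻⁹ per site per generation,
and a default strict-isolation truth (N_hal = 82k, N_lyr = 79.2k,
N_anc = 532.9k, T_split = 337.4 ka) representative of a recently
diverged outcrossing plant pair. Simulated segregating records are
relabeled onto distinct synonymous columns (harmless under infinite
sites) and a derived base planted on the carriers. The outgroup is one
sequence carrying Poisson mutations for the calibrated branch — (2·T_out
− t_root) generations at the locus rate *plus* an
ancestral-polymorphism component equal to the panel's mean within-
species π, which is exactly the quantity the Nei net-divergence
correction later removes; the planted net outgroup divergence is thereby
consistent with the 5 MY calibration by construction, and the clock
round trip μ̂ = net_K/(2·T_out/g) recovers the planted rates to ~10%
(locus-averaged).

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: within-species population structure
(the two-population models see each species as panmictic), indels and
alignment error, codon-usage bias, finite-sites homoplasy, outgroup
polymorphism, and missing individuals. Truth records (model, parameters,
per-locus μ and seeds) make every generated study bit-reproducible.

## Problem sizes in the shipped experiments

Reference tables of 2500 (test suite) / 4000 (acceptance script) rows
per model with 60/80 PODs per true model for the four-way calibration;
5000-row tables with 50/30 repeats for the estimation-coverage
experiment; 5000 replicates for closed forms; 1000 random alignments for
the brute-force equivalence. These sizes keep a full run on one
workstation CPU in minutes; the full-scale settings (5×10⁶ simulations
per model, 0.1% acceptance, 2000 accepted for estimation, 50/100-member
ensembles) are expressed by the `paper` preset in `divabc.config` and
scale linearly.

## Known limitations

* **The scenario classes are nested**, and with diffuse hierarchical
  priors large parts of their prior-predictive distributions coincide:
  SC with T_SC ≈ T_split is CM; AM with T_iso ≈ 0 is CM; AM with
  T_iso ≈ T_split is SI. Measured on full 10⁴-row reference tables under
  the study conditions, cross-validated classifiers separate CMC from
  SCC with only ~0.59 accuracy and SIC from AMC with ~0.73 — an
  information ceiling of the 22-statistic vector that no ABC backend can
  beat. Four-way POD recovery under prior-drawn truths consequently
  plateaus around 0.5–0.8 depending on the class, and the correctness
  probability at a moderately high observed posterior stays below ~0.9.
  Calibration against PODs at *fitted* (posterior-representative)
  parameter values, or richer statistics (haplotype- or LD-based), would
  be required for sharper discrimination of the migration-timing
  scenarios; both are outside the current statistic set.
* The 22-statistic composition is a declared default, overridable in
  configuration.
* Regression adjustment uses the conditional-mean shift only (no
  heteroscedastic variance correction).
* Adjusted draws of nested times are clipped to the adjusted T_split
  rather than re-drawn, which can create small point masses at the
  constraint boundary.
* The simulator is strictly two demes plus ancestor: no within-species
  substructure, selection, gene conversion or finite-sites mutation.
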