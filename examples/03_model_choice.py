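"""ABC model choice between divergence scenarios.

Builds small reference tables for the strict-isolation and
constant-migration models, simulates an observed dataset under strict
isolation, and reports the posterior model probabilities: the
rejection-only (weighted-frequency) estimate and the regression-adjusted
one.
"""

import numpy as np

from divabc import (ABCSettings, LocusSpec, ParameterVector, PriorSet,
                    build_reference_table, model_choice)
from divabc.coalescent import Workspace, simulate_dataset
from divabc.popgen import summarize_matrix

loci = [LocusSpec(f"l{j}", 20, 24, 300, 7e-9) for j in range(12)]
priors = PriorSet()
ws = Workspace(64)

print("building reference tables (1500 simulations per model) ...")
tables = {m: build_reference_table(m, priors, loci, 1500, seed=i,
                                   workspace=ws)
          for i, m in enumerate(("SIC", "CMC"))}

truth = ParameterVector("SIC", N_hal=90_000, N_lyr=70_000, N_anc=400_000,
                        T_split=1_200_000)
per_locus, _ = simulate_dataset(truth, loci, seed=99, workspace=ws)
obs, _ = summarize_matrix(per_locus[:, :12])

settings = ABCSettings(acceptance_rate=0.05, min_accept=100, seed=1)
posterior = model_choice(obs, tables, settings)

print(f"\nobservation simulated under SIC "
      f"(T_split = {truth.T_split:,.0f} years)")
for m in sorted(posterior.probs):
    print(f"  P({m}) = {posterior.probs[m]:.3f}   "
          f"(rejection-only: {posterior.rejection_probs[m]:.3f})")
print(f"best model: {posterior.best}")
print("\nProbabilities close to 1 for SIC mean the summary statistics "
      "of the observation sit inside the strict-isolation cloud.")
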