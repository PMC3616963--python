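#!/usr/bin/env python
"""Relative-dS ternary spread for each clade trio, clonal vs recombining.

The spread (median distance of per-gene relative-dS triples from their
mean) sits near 0.1 for clonal genes and in the 0.3-0.45 band when
within-clade histories are decoupled by free recombination.
"""

from pathlib import Path

from cohesim.experiments import GROUP_A, GROUP_B, spread_experiment

N_GENES = 150
SEED = 7

results = Path("results")
results.mkdir(exist_ok=True)

with open(results / "spread.tsv", "w") as fh:
    fh.write("trio\tmode\tspread\tn_genes\n")
    for name, trio in (("A", GROUP_A), ("B", GROUP_B)):
        for mode in ("clonal", "randomized"):
            s = spread_experiment(n_genes=N_GENES, mode=mode,
                                  seed=SEED, trio=trio)
            fh.write(f"{name}\t{mode}\t{s:.4f}\t{N_GENES}\n")
            print(f"trio {name} ({'+'.join(trio)}), {mode}: "
                  f"spread = {s:.3f}")
print(f"spread table -> {results/'spread.tsv'}")
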