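"""A miniature run of the tree-recovery experiment.

Simulates short alignments on the 'three-domain-like' fixture (where
the two long branches are truly joined, so recovery is easy) and on a
trimmed schedule, then prints the recovery summary.  The full desk-
scale protocol (two-domain fixture, 2,000 sites, 10 replicates,
profile counts 1/4/16) is the package default and takes considerably
longer; see the reproduction section of the README.
"""

from hetphylo.experiments import (
    RecoveryConfig,
    run_recovery_experiment,
    summarize_recovery,
)

cfg = RecoveryConfig(
    tree_kinds=("three_domain_like",),
    n_replicates=2,
    n_sites=500,
    cells=((1, False), (1, True)),
)
table = run_recovery_experiment(cfg, seed=7)
summary, monotonic = summarize_recovery(table)
print(summary.to_string(index=False))
print("\neach row: recovery fraction of the long-stem clan, mean "
      "symmetric (RF) and branch-score distances to the generating tree.")
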