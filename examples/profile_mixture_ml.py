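"""Maximum likelihood under a fixed-profile mixture model.

Simulates amino-acid data whose sites draw their compositions from the
packaged synthetic profile bank, then fits a single-composition model
and a 16-profile mixture (weights and gamma shape estimated) on the
true tree and compares the fits.
"""

import numpy as np

from hetphylo import (
    GammaASRV,
    MixtureComposition,
    SubstitutionModel,
    fixture_trees,
    hogenom_like_bank,
    optimize,
    simulate_alignment,
)
from hetphylo.experiments import profile_centroids
from hetphylo.models import SingleComposition, uniform_exchangeabilities

bank = hogenom_like_bank(64)
tree = fixture_trees("thermus_like")
sim_model = SubstitutionModel(
    "AA", uniform_exchangeabilities(20),
    MixtureComposition(bank, np.full(bank.K, 1 / bank.K)),
    GammaASRV(0.935, 4))
aln, _ = simulate_alignment(tree, sim_model, 1000, seed=5)
print(f"simulated {aln.n_taxa} taxa x {aln.n_sites} amino-acid sites "
      "with per-site compositions from a 64-profile bank\n")

single = SubstitutionModel("AA", uniform_exchangeabilities(20),
                           SingleComposition(np.full(20, 0.05)),
                           GammaASRV(1.0, 4))
res1 = optimize(tree, aln, single, free=("branch_lengths", "alpha"),
                tol=1e-3, max_sweeps=6)
print(f"single composition + G : lnL {res1.lnl:10.1f}  "
      f"(alpha-hat {res1.model.asrv.shape:.2f})")

mix = SubstitutionModel(
    "AA", uniform_exchangeabilities(20),
    MixtureComposition(profile_centroids(bank, 16), np.full(16, 1 / 16)),
    GammaASRV(1.0, 4))
res16 = optimize(tree, aln, mix, free=("branch_lengths", "alpha", "weights"),
                 tol=1e-3, max_sweeps=6)
print(f"16-profile mixture + G : lnL {res16.lnl:10.1f}  "
      f"(alpha-hat {res16.model.asrv.shape:.2f})")
print(f"\nmixture advantage: {res16.lnl - res1.lnl:+.1f} log units — "
      "site-compositional heterogeneity carries a large share of the "
      "signal in such data.")
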