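"""Compositional attraction and its distance-based rescue.

On data in which two non-sister taxa (A and C) converge in GC content,
a stationary-model distance groups them together, while the paralinear
(LogDet-family) distance with partial constant-site removal recovers
the generating topology.
"""

from hetphylo import distance_matrix, is_clan, make_case_study, neighbor_joining

aln, tree, _ = make_case_study("composition_attraction", seed=3,
                               n_sites=10_000)
print("generating tree:", tree.to_newick())
print("true sister pairs: (A,B) and (C,D); A and C share a convergent "
      "composition\n")

nj_jc = neighbor_joining(distance_matrix(aln, "jc"))
print("stationary (Jukes-Cantor) distances ->", nj_jc.to_newick())
print("  groups the convergent pair (A,C):", is_clan(nj_jc, {"A", "C"}))

for p in (0.0, 0.5):
    dm = distance_matrix(aln, "paralinear", constant_removal_p=p)
    nj = neighbor_joining(dm)
    ok = is_clan(nj, {"A", "B"}) and is_clan(nj, {"C", "D"})
    print(f"paralinear, {int(p*100)}% constant sites removed -> "
          f"recovers the generating topology: {ok}")
print("\nremoving constant sites acts as a partial rate correction: "
      "the paralinear distance assumes equal site rates, and the "
      "surplus of never-changing sites otherwise compresses it.")
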