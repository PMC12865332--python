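"""Cross-species conservation and multi-evidence gene convergence.

Compares drug-response DE tables of two species over a strict 1:1 ortholog
map (hypergeometric overlap per direction, Pearson correlation of log2FC),
then intersects three upregulated evidence streams to find the convergent
gene present in all of them.
"""

import numpy as np

from screpurpose import (
    SimConfig,
    conserved_response,
    gen_ortholog_study,
    intersect_upregulated,
    lfc_to_fold,
    share_of_set,
)

de_a, de_b, orth_map, truth = gen_ortholog_study(SimConfig(seed=0))
res = conserved_response(de_a, de_b, orth_map)
print(f"background: {res.n_background} 1:1 orthologs tested in both species")
print(f"significant: {res.n_sig_a} (A) / {res.n_sig_b} (B); "
      f"conserved same-direction: {res.n_conserved} "
      f"({res.n_conserved_up} up, {res.n_conserved_down} down)")
print(f"overlap p (up-direction): {res.p_hyper_up:.3g}; "
      f"r over conserved pairs: {res.r_conserved:.3f}")
print(f"conserved-up share of A's up genes: "
      f"{share_of_set(res.n_conserved_up, res._n_up_a)}%")

fold, pct = lfc_to_fold(1.16)
print(f"\nfold arithmetic: log2FC 1.16 -> {fold:.2f}-fold ({pct:.1f}% up); "
      f"threshold log2(1.5) = {np.log2(1.5):.2f}")

rng = np.random.default_rng(0)
pool = [f"g{i}" for i in range(90)]
streams = {
    name: set(rng.choice(pool[i * 30:(i + 1) * 30], 10, replace=False))
    | {"gCONVERGENT"}
    for i, name in enumerate(("drug_response", "microglia", "hazard_strata"))
}
venn = intersect_upregulated(streams, min_sets=3)
print(f"\ntriple intersection of evidence streams: {venn.full_intersection}")
# the single shared gene across all three streams is the convergent
# therapeutic target the intersection analysis is designed to surface
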