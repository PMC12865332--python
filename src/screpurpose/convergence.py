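"""Multi-evidence gene convergence and cross-species conservation.

Upregulated signatures from independent evidence streams are intersected
Venn-style (genes shared by at least two streams, with the full-overlap list
reported explicitly); drug responses measured in two species are compared
over a strictly 1:1 ortholog map, with conservation defined as significant
same-direction differential expression in both species, tested per direction
by an upper-tail hypergeometric draw against the jointly tested background.
Fold-change arithmetic helpers convert log2 fold changes to folds and
percent changes with half-up rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .de import SignedGeneSet

__all__ = [
    "ConvergenceResult",
    "ConservationResult",
    "intersect_upregulated",
    "conserved_response",
    "lfc_to_fold",
    "share_of_set",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimal places."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConvergenceResult:
    """Venn-style overlap structure of named upregulated gene sets."""

    stream_sizes: dict[str, int]
    exclusive_counts: dict[frozenset, int]
    exclusive_genes: dict[frozenset, list[str]]
    genes_in_at_least: dict[int, list[str]]
    min_sets: int

    @property
    def full_intersection(self) -> list[str]:
        key = frozenset(self.stream_sizes)
        return self.exclusive_genes.get(key, [])

    @property
    def convergent_genes(self) -> list[str]:
        return self.genes_in_at_least[self.min_sets]

    def consistency_ok(self) -> bool:
        """Exclusive-region counts must add up to each stream's size."""
        for name, size in self.stream_sizes.items():
            total = sum(
                c for key, c in self.exclusive_counts.items() if name in key
            )
            if total != size:
                return False
        return True


def intersect_upregulated(
    streams: dict[str, SignedGeneSet | set | list],
    min_sets: int = 2,
    require_up_provenance: bool = True,
) -> ConvergenceResult:
    """Intersect the Up genes of named evidence streams.

    Accepts :class:`SignedGeneSet` streams (their Up genes are used; when
    ``require_up_provenance`` their provenance must record the thresholds
    used) or plain gene collections. Reports counts and gene lists for every
    exclusive Venn region plus, for each overlap level k, the genes present
    in at least k streams; the full intersection is reported explicitly.
    Order of the stream mapping does not affect the result.
    """
    if len(streams) < 1:
        raise ValueError("at least one stream required")
    if not 1 <= min_sets <= len(streams):
        raise ValueError("min_sets must lie in [1, number of streams]")
    up: dict[str, set[str]] = {}
    for name, stream in streams.items():
        if isinstance(stream, SignedGeneSet):
            if require_up_provenance and "lfc_cut" not in stream.provenance:
                raise ValueError(
                    f"stream {name!r} carries no threshold provenance; pass "
                    "require_up_provenance=False to intersect anyway"
                )
            up[name] = stream.up_genes
        else:
            up[name] = set(stream)

    names = sorted(up)
    membership: dict[str, frozenset] = {}
    for gene in set.union(*(up[n] for n in names)):
        membership[gene] = frozenset(n for n in names if gene in up[n])
    exclusive_counts: dict[frozenset, int] = {}
    exclusive_genes: dict[frozenset, list[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            key = frozenset(combo)
            genes = sorted(g for g, m in membership.items() if m == key)
            exclusive_counts[key] = len(genes)
            exclusive_genes[key] = genes
    genes_in_at_least = {
        k: sorted(g for g, m in membership.items() if len(m) >= k)
        for k in range(1, len(names) + 1)
    }
    return ConvergenceResult(
        stream_sizes={n: len(up[n]) for n in names},
        exclusive_counts=exclusive_counts,
        exclusive_genes=exclusive_genes,
        genes_in_at_least=genes_in_at_least,
        min_sets=min_sets,
    )


@dataclass
class ConservationResult:
    """Cross-species conservation summary over a 1:1 ortholog background."""

    n_background: int
    n_sig_a: int
    n_sig_b: int
    n_conserved: int
    n_conserved_up: int
    n_conserved_down: int
    p_hyper_up: float
    p_hyper_down: float
    r_all: float
    r_conserved: float
    conserved_genes: dict[str, int] = field(default_factory=dict)

    @property
    def p_hyper(self) -> float:
        """Primary overlap p-value (Up-direction test)."""
        return self.p_hyper_up

    @property
    def share_a_pct(self) -> float:
        """Conserved-Up share of species A's upregulated genes (percent)."""
        return share_of_set(self.n_conserved_up, self._n_up_a)

    @property
    def share_b_pct(self) -> float:
        return share_of_set(self.n_conserved_up, self._n_up_b)

    # populated by conserved_response
    _n_up_a: int = 0
    _n_up_b: int = 0


def _check_one_to_one(orth_map: pd.DataFrame) -> pd.DataFrame:
    if orth_map.shape[1] < 2:
        raise ValueError("ortholog map needs two columns")
    a, b = orth_map.columns[:2]
    if orth_map[a].duplicated().any() or orth_map[b].duplicated().any():
        raise ValueError("ortholog map is not strictly 1:1 (duplicated ids)")
    return orth_map.rename(columns={a: "gene_a", b: "gene_b"})


def conserved_response(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    orth_map: pd.DataFrame,
    p_cut: float = 0.05,
    lfc_cut: float = 0.58,
    use_fdr: bool = False,
) -> ConservationResult:
    """Assess conservation of a transcriptional response across two species.

    The background is the set of 1:1 ortholog pairs tested in both DE
    tables. Significance per species uses strict dual cuts (raw p or FDR,
    and |log2FC|); a pair is conserved when significant in both species with
    matching sign. Overlap significance is an upper-tail hypergeometric test
    per direction, conditioning on species A's Up (resp. Down) set as the
    successes and species B's same-direction set as the draws. Pearson
    correlations of log2FC are reported over the full background (``r_all``)
    and the conserved pairs (``r_conserved``).
    """
    orth = _check_one_to_one(orth_map)
    col = "fdr" if use_fdr else "p_value"
    a = de_a.set_index("gene")
    b = de_b.set_index("gene")
    pairs = orth[orth["gene_a"].isin(a.index) & orth["gene_b"].isin(b.index)]
    n_bg = len(pairs)
    if n_bg < 2:
        raise ValueError("fewer than two ortholog pairs tested in both tables")

    lfc_a = a.loc[pairs["gene_a"], "log2FC"].to_numpy()
    lfc_b = b.loc[pairs["gene_b"], "log2FC"].to_numpy()
    sig_a = (a.loc[pairs["gene_a"], col].to_numpy() < p_cut) & (
        np.abs(lfc_a) > lfc_cut
    )
    sig_b = (b.loc[pairs["gene_b"], col].to_numpy() < p_cut) & (
        np.abs(lfc_b) > lfc_cut
    )
    up_a, up_b = sig_a & (lfc_a > 0), sig_b & (lfc_b > 0)
    down_a, down_b = sig_a & (lfc_a < 0), sig_b & (lfc_b < 0)
    cons_up = up_a & up_b
    cons_down = down_a & down_b

    def _tail(k: int, K: int, n: int) -> float:
        return float(stats.hypergeom.sf(k - 1, n_bg, K, n))

    def _pearson(x: np.ndarray, y: np.ndarray) -> float:
        if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
            return np.nan
        return float(stats.pearsonr(x, y)[0])

    r_all = _pearson(lfc_a, lfc_b)
    conserved_mask = cons_up | cons_down
    r_cons = _pearson(lfc_a[conserved_mask], lfc_b[conserved_mask])

    result = ConservationResult(
        n_background=n_bg,
        n_sig_a=int(sig_a.sum()),
        n_sig_b=int(sig_b.sum()),
        n_conserved=int(conserved_mask.sum()),
        n_conserved_up=int(cons_up.sum()),
        n_conserved_down=int(cons_down.sum()),
        p_hyper_up=_tail(int(cons_up.sum()), int(up_a.sum()), int(up_b.sum())),
        p_hyper_down=_tail(
            int(cons_down.sum()), int(down_a.sum()), int(down_b.sum())
        ),
        r_all=r_all,
        r_conserved=r_cons,
        conserved_genes={
            g: (1 if u else -1)
            for g, u, keep in zip(pairs["gene_a"], cons_up, conserved_mask)
            if keep
        },
    )
    result._n_up_a = int(up_a.sum())
    result._n_up_b = int(up_b.sum())
    return result


def lfc_to_fold(lfc: float) -> tuple[float, float]:
    """Convert a log2 fold change to (fold, percent change).

    ``fold = 2**lfc``; ``pct_change = (fold - 1) * 100`` (negative for
    decreases).
    """
    fold = float(2.0 ** lfc)
    return fold, (fold - 1.0) * 100.0


def share_of_set(
    numerator: int, denominator: int, ndigits: int = 1
) -> float:
    """Percentage ``100 * numerator / denominator``, rounded half-up."""
    if denominator == 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or denominator < 0:
        raise ValueError("counts must be non-negative")
    return round_half_up(100.0 * numerator / denominator, ndigits)
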