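"""Signature-reversal drug scoring and candidate selection.

A disease DEG counts as *reversed* by a drug when it is measured in the
drug's response signature with the opposite sign to its disease direction.
Per cell type, the reversal ratio is the reversed fraction of measured DEGs
and significance is an exact upper-tail binomial test against chance (1/2).
The aggregate drug score sums, over cell types passing a per-drug BH-FDR
gate, the product of cell-type proportion, reversal ratio and a capped
-log10(FDR) — monotone in all three ingredients and zero without any
significant cell type.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .de import SignedGeneSet, bh_fdr
from .simulate import DrugSignatureLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "reversal_stats",
    "reversal_table",
    "drug_score",
    "select_candidates",
    "cross_dataset_consensus",
    "permutation_reversal_pvalue",
]


def reversal_stats(sig: SignedGeneSet, drug_signature: pd.Series) -> dict:
    """Reversal statistics of one drug against one signed DEG set.

    Returns ``n_degs_measured`` (DEGs present in the drug signature),
    ``n_reversed`` (measured DEGs with strictly opposite drug-response sign),
    ``reversal_ratio``, the exact binomial ``p_value``
    P(X >= n_reversed), X ~ Binom(n_measured, 1/2), and ``testable``
    (False with p = 1 and undefined ratio when nothing is measured).
    """
    if len(sig) == 0:
        raise ValueError("signed gene set is empty")
    disease = sig.sign_series()
    measured = disease.index.intersection(drug_signature.index)
    n = len(measured)
    if n == 0:
        return {
            "n_degs_measured": 0,
            "n_reversed": 0,
            "reversal_ratio": np.nan,
            "p_value": 1.0,
            "testable": False,
        }
    drug_sign = np.sign(drug_signature.loc[measured].to_numpy(dtype=float))
    k = int(np.sum(drug_sign == -disease.loc[measured].to_numpy()))
    return {
        "n_degs_measured": n,
        "n_reversed": k,
        "reversal_ratio": k / n,
        "p_value": float(stats.binom.sf(k - 1, n, 0.5)),
        "testable": True,
    }


def reversal_table(
    signatures_by_celltype: dict[str, SignedGeneSet],
    library: DrugSignatureLibrary,
) -> pd.DataFrame:
    """All drug x cell-type reversal statistics, deterministically sorted."""
    rows = []
    for drug in library.drugs():
        drug_sig = library.get(drug)
        for ctype in sorted(signatures_by_celltype):
            row = reversal_stats(signatures_by_celltype[ctype], drug_sig)
            rows.append({"drug_id": drug, "cell_type": ctype, **row})
    return pd.DataFrame(rows)


def permutation_reversal_pvalue(
    sig: SignedGeneSet,
    drug_signature: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation alternative to the binomial test.

    Shuffles the drug's response values over its covered genes ``n_perm``
    times and reports ``(1 + #{perm n_reversed >= observed}) / (n_perm + 1)``.
    """
    rng = np.random.default_rng(seed)
    observed = reversal_stats(sig, drug_signature)["n_reversed"]
    values = drug_signature.to_numpy(dtype=float)
    genes = drug_signature.index
    count = 0
    for _ in range(n_perm):
        perm = pd.Series(rng.permutation(values), index=genes)
        if reversal_stats(sig, perm)["n_reversed"] >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


def drug_score(
    results: pd.DataFrame,
    proportions: pd.Series | dict,
    fdr_gate: float = 0.1,
    cap: float = 4.0,
) -> pd.DataFrame:
    """Aggregate per-drug therapeutic score across cell types.

    Per drug, the binomial p-values of its testable cell types are BH
    adjusted; the score sums ``proportion * reversal_ratio *
    min(-log10(fdr), cap)`` over cell types with ``fdr < fdr_gate``. A drug
    with no gated cell type scores 0.

    ``proportions`` must cover every cell type in ``results`` and sum to 1
    (±1e-6).
    """
    proportions = pd.Series(proportions, dtype=float)
    if abs(proportions.sum() - 1.0) > 1e-6:
        raise ValueError(
            f"cell-type proportions must sum to 1, got {proportions.sum():.8f}"
        )
    missing = set(results["cell_type"]) - set(proportions.index)
    if missing:
        raise ValueError(f"proportions missing cell types: {sorted(missing)}")

    out_rows = []
    per_type_rows = []
    for drug, grp in results.groupby("drug_id", sort=True):
        testable = grp[grp["testable"]].copy()
        if len(testable):
            testable["fdr"] = bh_fdr(testable["p_value"].to_numpy())
        score = 0.0
        contributing = []
        for row in testable.itertuples():
            per_type_rows.append(
                {"drug_id": drug, "cell_type": row.cell_type, "fdr": row.fdr}
            )
            if row.fdr < fdr_gate:
                score += (
                    proportions[row.cell_type]
                    * row.reversal_ratio
                    * min(-np.log10(max(row.fdr, 1e-300)), cap)
                )
                contributing.append(row.cell_type)
        out_rows.append(
            {
                "drug_id": drug,
                "score": score,
                "n_sig_types": len(contributing),
                "contributing_types": ",".join(sorted(contributing)),
                "best_fdr": float(testable["fdr"].min()) if len(testable) else 1.0,
            }
        )
    table = pd.DataFrame(out_rows).sort_values(
        ["score", "drug_id"], ascending=[False, True]
    )
    table.attrs["per_type_fdr"] = pd.DataFrame(per_type_rows)
    return table.reset_index(drop=True)


def select_candidates(
    scores: pd.DataFrame, fdr_gate: float = 0.1, quantile: float = 0.9
) -> pd.DataFrame:
    """Gate by per-type FDR then keep drugs at or above the score quantile.

    Candidates have at least one cell type passing ``fdr_gate`` (reflected in
    ``n_sig_types``) and a score at or above the ``quantile`` of all nonzero
    scores; when every nonzero score is equal the quantile is degenerate and
    all gated drugs are returned. Sorted by descending score, then drug id.
    """
    gated = scores[(scores["n_sig_types"] > 0) & (scores["best_fdr"] < fdr_gate)]
    nonzero = scores.loc[scores["score"] > 0, "score"]
    if len(nonzero) == 0:
        return gated.iloc[0:0]
    cutoff = float(np.quantile(nonzero, quantile))
    out = gated[gated["score"] >= cutoff]
    return out.sort_values(
        ["score", "drug_id"], ascending=[False, True]
    ).reset_index(drop=True)


def cross_dataset_consensus(
    score_tables: dict[str, pd.DataFrame], fdr_gate: float = 0.1
) -> pd.DataFrame:
    """Drugs passing the per-type FDR gate in every dataset.

    Returns one row per consensus drug with per-dataset scores and ranks
    (rank 1 = highest score within that dataset). A drug absent from any
    dataset's library is excluded (logged).
    """
    if not score_tables:
        raise ValueError("no score tables provided")
    names = sorted(score_tables)
    passing: list[set[str]] = []
    all_drugs: list[set[str]] = []
    for name in names:
        t = score_tables[name]
        all_drugs.append(set(t["drug_id"]))
        passing.append(
            set(t.loc[(t["n_sig_types"] > 0) & (t["best_fdr"] < fdr_gate), "drug_id"])
        )
    present_everywhere = set.intersection(*all_drugs)
    for drug in sorted(set.union(*all_drugs) - present_everywhere):
        logger.info("consensus: %s absent from at least one dataset, excluded", drug)
    consensus = set.intersection(*passing) & present_everywhere

    rows = []
    for drug in sorted(consensus):
        row = {"drug_id": drug}
        for name in names:
            t = score_tables[name].sort_values(
                ["score", "drug_id"], ascending=[False, True]
            )
            ranks = {d: i + 1 for i, d in enumerate(t["drug_id"])}
            score = float(t.loc[t["drug_id"] == drug, "score"].iloc[0])
            row[f"score_{name}"] = score
            row[f"rank_{name}"] = ranks[drug]
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            [f"score_{names[0]}", "drug_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return out
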