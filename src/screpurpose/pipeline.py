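"""End-to-end orchestration of the repurposing pipeline on synthetic data.

Each ``run_*`` function wires the stage modules together exactly as the
library API intends them to be composed, and returns both the stage outputs
and the planted-truth bookkeeping needed to quantify recovery. ``run_all``
executes the full study: QC and doublet re-annotation, per-cell-type DE,
signature-reversal drug scoring with cross-dataset consensus, transfer
scoring with reverse/mimic queries, cross-species conservation, and the
spatial eigengene overlay.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import convergence, de, drugs, preprocess, simulate, spatial, transfer

__all__ = [
    "drug_gene_set",
    "run_celltype_repurposing",
    "run_consensus",
    "run_transfer",
    "run_crossspecies",
    "run_spatial",
    "run_all",
    "singlet_type_recovery",
    "doublet_pair_recovery",
]


def drug_gene_set(
    library: simulate.DrugSignatureLibrary,
    drug_id: str,
    magnitude_quantile: float = 0.9,
) -> list[str]:
    """Upregulated portion of a drug's signature above a magnitude quantile.

    Genes with a positive response value whose magnitude is at or above the
    given quantile of the drug's absolute response values.
    """
    sig = library.get(drug_id)
    thr = float(np.quantile(np.abs(sig.to_numpy()), magnitude_quantile))
    return sorted(sig.index[(sig > 0) & (np.abs(sig) >= thr)])


def singlet_type_recovery(
    scores: pd.DataFrame, truth: simulate.SimTruth
) -> float:
    """Fraction of singlets whose argmax marker score is the planted type."""
    singlets = [
        c for c, t in truth.cell_type_of_cell.items()
        if t != "doublet" and c in scores.index
    ]
    hits = sum(
        scores.loc[c].idxmax() == truth.cell_type_of_cell[c] for c in singlets
    )
    return hits / len(singlets)


def doublet_pair_recovery(
    annotation: pd.DataFrame, truth: simulate.SimTruth
) -> float:
    """Fraction of doublets whose re-annotated pair matches the parents."""
    cells = [c for c in truth.doublet_parents if c in annotation.index]
    if not cells:
        return float("nan")
    hits = sum(
        (annotation.loc[c, "type_a"], annotation.loc[c, "type_b"])
        == truth.doublet_parents[c]
        for c in cells
    )
    return hits / len(cells)


def run_celltype_repurposing(
    config: simulate.SimConfig,
    reverser_idx: int | None = None,
    mimic_idx: int | None = None,
    p_cut: float = 0.05,
    lfc_cut: float = 0.58,
    fdr_gate: float = 0.1,
    quantile: float = 0.9,
    context: str | None = "CNS",
) -> dict:
    """Simulate one dataset and score the drug library against it."""
    adata, truth = simulate.gen_sc_dataset(config)
    library = simulate.gen_drug_library(
        config, truth, reverser_idx=reverser_idx, mimic_idx=mimic_idx
    )
    filtered = preprocess.qc_filter(
        adata,
        min_genes_per_cell=min(200, config.n_genes // 2),
        min_cells_per_gene=3,
    )
    norm = preprocess.normalize_log(filtered)
    scores = preprocess.marker_scores(norm, truth.marker_genes_by_type)
    doublet_ids = list(norm.obs_names[norm.obs["is_doublet"]])
    annotation = (
        preprocess.annotate_doublets(scores, doublet_ids)
        if doublet_ids
        else pd.DataFrame()
    )
    proportions = preprocess.celltype_proportions(norm.obs["cell_type"])

    signatures: dict[str, de.SignedGeneSet] = {}
    for ctype in sorted(norm.obs["cell_type"].unique()):
        sub = norm[norm.obs["cell_type"] == ctype]
        if (sub.obs["condition"] == "case").sum() < 2 or (
            sub.obs["condition"] == "control"
        ).sum() < 2:
            continue
        table = de.fit_moderated_de(sub, sub.obs["condition"], "case")
        signed = de.significant_genes(
            table, p_cut=p_cut, lfc_cut=lfc_cut,
            provenance={"cell_type": ctype},
        )
        if len(signed):
            signatures[ctype] = signed

    lib = library.filter_context(context) if context else library
    results = drugs.reversal_table(signatures, lib)
    score_table = drugs.drug_score(results, proportions, fdr_gate=fdr_gate)
    candidates = drugs.select_candidates(
        score_table, fdr_gate=fdr_gate, quantile=quantile
    )
    return {
        "adata": norm,
        "truth": truth,
        "library": library,
        "marker_scores": scores,
        "doublet_annotation": annotation,
        "proportions": proportions,
        "signatures": signatures,
        "reversal": results,
        "scores": score_table,
        "candidates": candidates,
    }


def run_consensus(
    config: simulate.SimConfig, n_datasets: int = 3, fdr_gate: float = 0.1
) -> dict:
    """Repurposing over independent datasets sharing the planted drugs."""
    rng = np.random.default_rng(config.seed + 5)
    picks = rng.choice(config.n_drugs, size=2, replace=False)
    reverser_idx, mimic_idx = int(picks[0]), int(picks[1])
    runs = {}
    for i in range(n_datasets):
        name = f"dataset{i}"
        cfg = config.replace(seed=config.seed + 1000 * (i + 1))
        runs[name] = run_celltype_repurposing(
            cfg, reverser_idx=reverser_idx, mimic_idx=mimic_idx,
            fdr_gate=fdr_gate,
        )
    consensus = drugs.cross_dataset_consensus(
        {name: run["scores"] for name, run in runs.items()}, fdr_gate=fdr_gate
    )
    return {
        "runs": runs,
        "consensus": consensus,
        "reverser_drug_id": f"drug{reverser_idx:03d}",
        "mimic_drug_id": f"drug{mimic_idx:03d}",
    }


def run_transfer(
    config: simulate.SimConfig,
    target_cell_type: str = "neuron",
    p_cut: float = 0.05,
    lfc_cut: float = 0.58,
) -> dict:
    """Patient-to-cell transfer scoring with reverse/mimic library queries."""
    adata, truth = simulate.gen_sc_dataset(config)
    library = simulate.gen_drug_library(config, truth)
    patients = simulate.gen_patient_cohort(config, truth)
    norm = preprocess.normalize_log(adata)
    features = sorted(truth.disease_signature)
    model = transfer.train_hazard_model(
        patients, patients.obs["condition"], features, seed=config.seed
    )
    if target_cell_type not in set(norm.obs["cell_type"]):
        raise ValueError(f"cell type {target_cell_type!r} not in the dataset")
    cells = norm[norm.obs["cell_type"] == target_cell_type]
    scores = transfer.score_cells(model, cells)
    strata = transfer.median_split(scores)
    table = de.fit_moderated_de(cells, strata["stratum"], "high")
    signature = de.significant_genes(
        table, p_cut=p_cut, lfc_cut=lfc_cut,
        provenance={"contrast": "high-vs-low hazard"},
    )
    reverse_q = (
        transfer.signature_query(signature, library, mode="reverse")
        if len(signature)
        else pd.DataFrame()
    )
    mimic_q = (
        transfer.signature_query(signature, library, mode="mimic")
        if len(signature)
        else pd.DataFrame()
    )
    return {
        "truth": truth,
        "library": library,
        "model": model,
        "hazard": strata,
        "signature": signature,
        "reverse_query": reverse_q,
        "mimic_query": mimic_q,
    }


def run_crossspecies(config: simulate.SimConfig) -> dict:
    de_a, de_b, orth_map, truth = simulate.gen_ortholog_study(config)
    result = convergence.conserved_response(de_a, de_b, orth_map)
    return {
        "de_a": de_a,
        "de_b": de_b,
        "ortholog_map": orth_map,
        "truth": truth,
        "conservation": result,
    }


def run_spatial(
    config: simulate.SimConfig,
    gene_set: list[str] | None = None,
    n_perm: int = 1000,
) -> dict:
    if gene_set is None:
        # default overlay set: a planted transcriptional program
        rng = np.random.default_rng(config.seed + 6)
        idx = rng.choice(config.n_genes, size=min(30, config.n_genes), replace=False)
        gene_set = sorted(f"g{i:04d}" for i in idx)
    frame, enriched = simulate.gen_spatial(config, gene_set)
    grid = spatial.SpatialGrid.from_frame(frame)
    emap = spatial.eigengene(grid, gene_set)
    table = spatial.region_enrichment(
        emap, grid, n_perm=n_perm, seed=config.seed
    )
    return {
        "grid": grid,
        "gene_set": gene_set,
        "eigengene": emap,
        "regions": table,
        "enriched_region_id": enriched,
    }


def run_all(config: simulate.SimConfig) -> dict:
    """Run every stage and summarize planted-truth recovery."""
    cons = run_consensus(config)
    first = cons["runs"]["dataset0"]
    tr = run_transfer(config.replace(seed=config.seed + 11))
    cs = run_crossspecies(config)
    sp = run_spatial(config)

    reverse_q = tr["reverse_query"]
    reverser = cons["reverser_drug_id"]
    tr_reverser = tr["truth"].reverser_drug_id
    report = {
        "seed": config.seed,
        "planted_reverser": reverser,
        "planted_mimic": cons["mimic_drug_id"],
        "top_consensus_drug": (
            cons["consensus"]["drug_id"].iloc[0]
            if len(cons["consensus"])
            else None
        ),
        "consensus_drugs": list(cons["consensus"].get("drug_id", [])),
        "singlet_type_recovery": singlet_type_recovery(
            first["marker_scores"], first["truth"]
        ),
        "doublet_pair_recovery": doublet_pair_recovery(
            first["doublet_annotation"], first["truth"]
        ),
        "reverse_query_rank_of_reverser": (
            int(
                reverse_q.loc[
                    reverse_q["drug_id"] == tr_reverser, "rank"
                ].iloc[0]
            )
            if len(reverse_q) and (reverse_q["drug_id"] == tr_reverser).any()
            else None
        ),
        "conserved_fraction_estimate": (
            cs["conservation"].n_conserved / cs["conservation"].n_sig_a
        ),
        "conservation_p_up": cs["conservation"].p_hyper_up,
        "spatial_top_region": sp["regions"]["region"].iloc[0],
        "spatial_planted_region": sp["enriched_region_id"],
        "proportions": first["proportions"].to_dict(),
    }
    return {
        "report": report,
        "consensus": cons,
        "transfer": tr,
        "crossspecies": cs,
        "spatial": sp,
    }
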