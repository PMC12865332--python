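"""File I/O for the pipeline's plain-text interchange formats.

Matrices travel as MatrixMarket (.mtx) plus two annotation tables (features,
barcodes-with-metadata); gene sets as GMT; drug libraries, ortholog maps,
score tables and reports as TSV/JSON. Readers validate headers, uniqueness
and numeric fields and reject malformed input with line numbers where
possible; write-then-read round-trips are exact for integer matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import DrugSignatureLibrary, SimTruth

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_gmt",
    "read_gmt",
    "write_drug_library",
    "read_drug_library",
    "write_ortholog_map",
    "read_ortholog_map",
    "write_truth",
    "read_truth",
    "write_report",
]


def write_matrix(adata: ad.AnnData, outdir) -> None:
    """Write cells x genes counts as MTX + features.tsv + barcodes.tsv.

    The MTX stores genes x cells (the conventional orientation); barcodes.tsv
    carries the per-cell metadata columns.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = np.asarray(adata.layers.get("counts", adata.X))
    spio.mmwrite(str(outdir / "matrix.mtx"), sparse.csr_matrix(X.T))
    pd.Series(adata.var_names, name="gene").to_csv(
        outdir / "features.tsv", sep="\t", index=False
    )
    barcodes = adata.obs.copy()
    barcodes.insert(0, "cell_id", adata.obs_names)
    barcodes.to_csv(outdir / "barcodes.tsv", sep="\t", index=False)


def read_matrix(indir) -> ad.AnnData:
    """Read a matrix directory written by :func:`write_matrix`."""
    indir = Path(indir)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing {name} in {indir}")
    X = np.asarray(spio.mmread(str(indir / "matrix.mtx")).todense()).T
    features = pd.read_csv(indir / "features.tsv", sep="\t")
    if "gene" not in features.columns:
        raise ValueError("features.tsv missing required column: gene")
    if features["gene"].duplicated().any():
        raise ValueError("duplicated gene ids in features.tsv")
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t")
    if "cell_id" not in barcodes.columns:
        raise ValueError("barcodes.tsv missing required column: cell_id")
    if barcodes["cell_id"].duplicated().any():
        raise ValueError("duplicated cell ids in barcodes.tsv")
    obs = barcodes.set_index("cell_id")
    adata = ad.AnnData(
        X=X.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(features["gene"], name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    return adata


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, name] + list(sets[name])) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file (name, description, genes...); duplicate names reject."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    "at least one gene"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


_DRUG_COLUMNS = ["drug_id", "context", "gene", "value"]


def write_drug_library(library: DrugSignatureLibrary, path) -> None:
    rows = []
    for drug in library.drugs():
        context = library.meta.loc[drug, "context"]
        sig = library.get(drug)
        for gene, value in sig.items():
            rows.append((drug, context, gene, value))
    pd.DataFrame(rows, columns=_DRUG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_drug_library(path) -> DrugSignatureLibrary:
    table = pd.read_csv(path, sep="\t", dtype={"value": str})
    missing = [c for c in _DRUG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"drug library missing column(s): {missing}")
    values = pd.to_numeric(table["value"], errors="coerce")
    bad = values.isna() & table["value"].notna()
    if bad.any():
        # +2: header line plus 1-based indexing
        lines = (table.index[bad] + 2).tolist()
        raise ValueError(
            f"non-numeric value(s) in drug library at line(s) {lines[:5]}"
        )
    table["value"] = values
    signatures: dict[str, pd.Series] = {}
    contexts: dict[str, str] = {}
    for drug, grp in table.groupby("drug_id", sort=True):
        if grp["gene"].duplicated().any():
            raise ValueError(f"duplicated genes for drug {drug}")
        signatures[drug] = pd.Series(
            grp["value"].to_numpy(), index=grp["gene"].to_numpy(), name=drug
        )
        contexts[drug] = str(grp["context"].iloc[0])
    meta = pd.DataFrame(
        {"context": pd.Series(contexts)}, index=pd.Index(sorted(signatures))
    )
    meta.index.name = "drug_id"
    return DrugSignatureLibrary(signatures, meta)


def write_ortholog_map(orth_map: pd.DataFrame, path) -> None:
    orth_map.iloc[:, :2].to_csv(path, sep="\t", index=False)


def read_ortholog_map(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ValueError("ortholog map needs two columns")
    a, b = table.columns[:2]
    if table[a].duplicated().any() or table[b].duplicated().any():
        raise ValueError("ortholog map is not strictly 1:1 (duplicated ids)")
    return table


def write_truth(truth: SimTruth, path) -> None:
    payload = {
        "cell_type_of_cell": truth.cell_type_of_cell,
        "doublet_parents": {k: list(v) for k, v in truth.doublet_parents.items()},
        "marker_genes_by_type": truth.marker_genes_by_type,
        "de_genes_by_type": truth.de_genes_by_type,
        "reverser_drug_id": truth.reverser_drug_id,
        "mimic_drug_id": truth.mimic_drug_id,
        "conserved_gene_set": truth.conserved_gene_set,
        "enriched_region_id": truth.enriched_region_id,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return SimTruth(
        cell_type_of_cell=payload["cell_type_of_cell"],
        doublet_parents={
            k: tuple(v) for k, v in payload["doublet_parents"].items()
        },
        marker_genes_by_type=payload["marker_genes_by_type"],
        de_genes_by_type={
            t: {g: int(s) for g, s in signed.items()}
            for t, signed in payload["de_genes_by_type"].items()
        },
        reverser_drug_id=payload["reverser_drug_id"],
        mimic_drug_id=payload["mimic_drug_id"],
        conserved_gene_set={
            g: int(s) for g, s in payload["conserved_gene_set"].items()
        },
        enriched_region_id=payload["enriched_region_id"],
    )


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
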