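"""Synthetic data generation with planted ground truth.

Every input the repurposing pipeline consumes can be generated here:
a single-cell count matrix with marker-driven cell types, condition-dependent
differential expression and heterotypic doublets; a drug-signature library
containing a planted reverser and a planted mimic; a labeled patient cohort;
a two-species differential-expression study linked by a 1:1 ortholog map;
and a spatial expression grid with one gene-set-enriched region.

All randomness flows from ``SimConfig.seed`` through a single
:class:`numpy.random.Generator` per call, so outputs are reproducible
byte-for-byte under a fixed configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "CELL_TYPE_NAMES",
    "gen_sc_dataset",
    "gen_drug_library",
    "gen_patient_cohort",
    "gen_ortholog_study",
    "gen_spatial",
]

#: Brain cell-type vocabulary used for synthetic type labels (first
#: ``n_cell_types`` entries are used).
CELL_TYPE_NAMES = (
    "astrocyte",
    "microglia",
    "neuron",
    "oligodendrocyte",
    "opc",
    "endothelial",
    "unidentified",
    "hybrid",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Counts follow a negative-binomial model with per-gene dispersion drawn
    uniformly from ``dispersion_range``; each cell type overexpresses its
    (disjoint) marker block by ``marker_lfc`` log2 units, and case cells shift
    each type's DE block by ``±de_effect_lfc`` log2 units (first half Up,
    second half Down).
    """

    n_genes: int = 300
    n_cell_types: int = 4
    cells_per_type: int = 120
    n_marker_genes_per_type: int = 15
    n_de_genes_per_type: int = 25
    de_effect_lfc: float = 1.0
    doublet_fraction: float = 0.06
    n_drugs: int = 50
    n_patients_per_class: int = 20
    grid_side: int = 15
    n_regions: int = 4
    conserved_fraction: float = 0.7
    seed: int = 0

    # secondary knobs (defaults are the study conditions; see docs/methods.md)
    marker_lfc: float = 2.0
    dispersion_range: tuple[float, float] = (0.1, 0.5)
    library_size_sigma: float = 0.2
    drug_coverage: float = 0.8
    drug_noise_sd: float = 0.15
    drug_magnitude: float = 1.0
    spatial_effect: float = 1.0
    n_ortholog_genes: int = 2000
    ortholog_sig_fraction: float = 0.15
    ortholog_lfc_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_cell_types": self.n_cell_types,
            "cells_per_type": self.cells_per_type,
            "n_marker_genes_per_type": self.n_marker_genes_per_type,
            "n_de_genes_per_type": self.n_de_genes_per_type,
            "n_drugs": self.n_drugs,
            "n_patients_per_class": self.n_patients_per_class,
            "grid_side": self.grid_side,
            "n_regions": self.n_regions,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.de_effect_lfc < 0:
            raise ValueError("de_effect_lfc must be >= 0")
        if not 0.0 <= self.doublet_fraction < 0.5:
            raise ValueError(
                "doublet_fraction must lie in [0, 0.5); a doublet fraction at "
                "or above one half is a degenerate mixture"
            )
        if not 0.0 <= self.conserved_fraction <= 1.0:
            raise ValueError("conserved_fraction must lie in [0, 1]")
        if self.n_cell_types > len(CELL_TYPE_NAMES):
            raise ValueError(
                f"at most {len(CELL_TYPE_NAMES)} cell types supported"
            )
        needed = self.n_cell_types * (
            self.n_marker_genes_per_type + self.n_de_genes_per_type
        )
        if needed > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for disjoint marker and DE "
                f"blocks ({needed} genes required)"
            )

    @property
    def cell_types(self) -> list[str]:
        return list(CELL_TYPE_NAMES[: self.n_cell_types])

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimTruth:
    """Planted ground truth recorded by the generators."""

    cell_type_of_cell: dict[str, str] = field(default_factory=dict)
    doublet_parents: dict[str, tuple[str, str]] = field(default_factory=dict)
    marker_genes_by_type: dict[str, list[str]] = field(default_factory=dict)
    de_genes_by_type: dict[str, dict[str, int]] = field(default_factory=dict)
    reverser_drug_id: str | None = None
    mimic_drug_id: str | None = None
    conserved_gene_set: dict[str, int] = field(default_factory=dict)
    enriched_region_id: str | None = None

    def __post_init__(self) -> None:
        if (
            self.reverser_drug_id is not None
            and self.reverser_drug_id == self.mimic_drug_id
        ):
            raise ValueError("reverser and mimic drugs must be distinct")

    @property
    def disease_signature(self) -> dict[str, int]:
        """Pooled gene -> sign (+1 Up in case, -1 Down) over all cell types."""
        pooled: dict[str, int] = {}
        for signed in self.de_genes_by_type.values():
            pooled.update(signed)
        return pooled


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, size_param: np.ndarray
) -> np.ndarray:
    """Negative-binomial draws with mean ``mu`` and shape ``size_param``."""
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def gen_sc_dataset(config: SimConfig) -> tuple[ad.AnnData, SimTruth]:
    """Generate a single-cell count matrix with planted structure.

    Returns an :class:`anndata.AnnData` (cells x genes, raw counts in ``X``
    and in ``layers["counts"]``) whose ``obs`` carries ``condition``
    ("case"/"control"), ``sample``, ``cell_type`` ("doublet" for planted
    doublets) and ``is_doublet``, together with the :class:`SimTruth`.

    Doublets are formed by summing the counts of two parent singlets of
    distinct types and multinomially downsampling to the median singlet
    library size, so both parents' marker signal survives at singlet depth.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    types = config.cell_types

    base_mu = rng.lognormal(mean=1.0, sigma=0.6, size=config.n_genes)
    disp = rng.uniform(*config.dispersion_range, size=config.n_genes)
    size_param = 1.0 / disp

    truth = SimTruth()
    nm, nde = config.n_marker_genes_per_type, config.n_de_genes_per_type
    for i, t in enumerate(types):
        truth.marker_genes_by_type[t] = genes[i * nm : (i + 1) * nm]
    de_start = config.n_cell_types * nm
    for i, t in enumerate(types):
        block = genes[de_start + i * nde : de_start + (i + 1) * nde]
        n_up = (nde + 1) // 2
        truth.de_genes_by_type[t] = {
            g: (1 if j < n_up else -1) for j, g in enumerate(block)
        }

    gene_index = {g: k for k, g in enumerate(genes)}
    count_blocks: list[np.ndarray] = []
    meta_rows: list[tuple[str, str, str, bool]] = []  # id, type, condition
    cell_counter = 0
    singlet_lookup: dict[str, list[int]] = {}  # "type|condition" -> row idx

    for t in types:
        mu_t = base_mu.copy()
        for g in truth.marker_genes_by_type[t]:
            mu_t[gene_index[g]] *= 2.0 ** config.marker_lfc
        n_case = config.cells_per_type // 2
        n_control = config.cells_per_type - n_case
        for condition, n_cells in (("control", n_control), ("case", n_case)):
            mu_c = mu_t.copy()
            if condition == "case":
                for g, sign in truth.de_genes_by_type[t].items():
                    mu_c[gene_index[g]] *= 2.0 ** (sign * config.de_effect_lfc)
            lib = rng.lognormal(0.0, config.library_size_sigma, size=n_cells)
            mu_mat = lib[:, None] * mu_c[None, :]
            counts = _nb_counts(rng, mu_mat, size_param[None, :])
            count_blocks.append(counts)
            for _ in range(n_cells):
                cid = f"cell{cell_counter:05d}"
                meta_rows.append((cid, t, condition, False))
                truth.cell_type_of_cell[cid] = t
                singlet_lookup.setdefault(f"{t}|{condition}", []).append(
                    cell_counter
                )
                cell_counter += 1

    singlets = np.vstack(count_blocks)
    n_singlets = singlets.shape[0]
    median_depth = int(np.median(singlets.sum(axis=1)))
    n_doublets = int(round(config.doublet_fraction * n_singlets))

    doublet_rows: list[np.ndarray] = []
    for _ in range(n_doublets):
        ta, tb = rng.choice(len(types), size=2, replace=False)
        condition = rng.choice(["control", "case"])
        ia = rng.choice(singlet_lookup[f"{types[ta]}|{condition}"])
        ib = rng.choice(singlet_lookup[f"{types[tb]}|{condition}"])
        summed = singlets[ia] + singlets[ib]
        total = summed.sum()
        if total > 0:
            downsampled = rng.multinomial(
                min(median_depth, total), summed / total
            )
        else:  # pragma: no cover - degenerate empty parents
            downsampled = summed
        doublet_rows.append(downsampled)
        cid = f"cell{cell_counter:05d}"
        pair = tuple(sorted((types[ta], types[tb])))
        meta_rows.append((cid, "doublet", condition, True))
        truth.cell_type_of_cell[cid] = "doublet"
        truth.doublet_parents[cid] = pair
        cell_counter += 1

    X = np.vstack([singlets] + doublet_rows) if doublet_rows else singlets
    obs = pd.DataFrame(
        meta_rows, columns=["cell_id", "cell_type", "condition", "is_doublet"]
    ).set_index("cell_id")
    obs["sample"] = np.where(obs["condition"] == "case", "case_s1", "ctrl_s1")
    adata = ad.AnnData(
        X=X.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    return adata, truth


class DrugSignatureLibrary:
    """Drug -> per-gene signed response values with per-drug context metadata.

    ``signatures`` maps drug id to a :class:`pandas.Series` indexed by gene;
    ``meta`` is indexed by drug id and carries a ``context`` label (e.g.
    "CNS") usable as a tissue filter.
    """

    def __init__(
        self, signatures: dict[str, pd.Series], meta: pd.DataFrame
    ) -> None:
        missing = set(signatures) ^ set(meta.index)
        if missing:
            raise ValueError(f"signature/meta drug id mismatch: {missing}")
        for drug, sig in signatures.items():
            values = np.asarray(sig.values, dtype=float)
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite values in signature of {drug}")
            if sig.index.duplicated().any():
                raise ValueError(f"duplicated genes in signature of {drug}")
        self.signatures = signatures
        self.meta = meta

    def drugs(self) -> list[str]:
        return sorted(self.signatures)

    def get(self, drug_id: str) -> pd.Series:
        return self.signatures[drug_id]

    def coverage(self, drug_id: str) -> int:
        return len(self.signatures[drug_id])

    def filter_context(self, context: str) -> "DrugSignatureLibrary":
        keep = self.meta.index[self.meta["context"] == context]
        return DrugSignatureLibrary(
            {d: self.signatures[d] for d in keep}, self.meta.loc[keep].copy()
        )

    def __len__(self) -> int:
        return len(self.signatures)


def gen_drug_library(
    config: SimConfig,
    truth: SimTruth,
    reverser_idx: int | None = None,
    mimic_idx: int | None = None,
) -> DrugSignatureLibrary:
    """Generate a signature library with a planted reverser and mimic.

    Decoy drugs receive standard-normal signed values on a random
    ``drug_coverage`` fraction of genes; the reverser's signature is the
    sign-flip of the pooled disease signature (magnitude ``drug_magnitude``)
    plus Gaussian noise of sd ``drug_noise_sd``, and the mimic copies the
    disease signature with the same noise. ``reverser_idx``/``mimic_idx``
    pin the planted drug identities (used to share a reverser across
    datasets); otherwise they are drawn from the seeded stream.
    """
    if not truth.de_genes_by_type:
        raise ValueError("truth carries no planted DE genes")
    rng = np.random.default_rng(config.seed + 1)
    genes = np.array(_gene_ids(config.n_genes))
    n_cov = max(1, int(round(config.drug_coverage * config.n_genes)))
    disease = truth.disease_signature

    if reverser_idx is None or mimic_idx is None:
        picks = rng.choice(config.n_drugs, size=2, replace=False)
        reverser_idx = int(picks[0]) if reverser_idx is None else reverser_idx
        mimic_idx = int(picks[1]) if mimic_idx is None else mimic_idx
    if reverser_idx == mimic_idx:
        raise ValueError("reverser and mimic indices must differ")

    signatures: dict[str, pd.Series] = {}
    contexts: dict[str, str] = {}
    for i in range(config.n_drugs):
        drug = f"drug{i:03d}"
        covered = np.sort(rng.choice(config.n_genes, size=n_cov, replace=False))
        covered_genes = genes[covered]
        if i == reverser_idx or i == mimic_idx:
            orient = -1.0 if i == reverser_idx else 1.0
            values = rng.normal(0.0, 1.0, size=n_cov)
            for k, g in enumerate(covered_genes):
                if g in disease:
                    values[k] = orient * disease[g] * config.drug_magnitude
            values += rng.normal(0.0, config.drug_noise_sd, size=n_cov)
            contexts[drug] = "CNS"
        else:
            values = rng.normal(0.0, 1.0, size=n_cov)
            contexts[drug] = "CNS" if rng.random() < 0.7 else "non-CNS"
        signatures[drug] = pd.Series(values, index=covered_genes, name=drug)

    truth.reverser_drug_id = f"drug{reverser_idx:03d}"
    truth.mimic_drug_id = f"drug{mimic_idx:03d}"
    meta = pd.DataFrame(
        {"context": pd.Series(contexts)}, index=pd.Index(sorted(signatures))
    )
    meta.index.name = "drug_id"
    return DrugSignatureLibrary(signatures, meta)


def gen_patient_cohort(config: SimConfig, truth: SimTruth) -> ad.AnnData:
    """Generate balanced pseudobulk-style patient profiles.

    Case patients shift the union of the planted DE genes in the disease
    direction by ``de_effect_lfc`` log2 units; profiles are low-dispersion
    negative-binomial pseudobulk counts.
    """
    if config.n_patients_per_class < 3:
        raise ValueError(
            "n_patients_per_class must be >= 3 to support bootstrapping"
        )
    rng = np.random.default_rng(config.seed + 2)
    genes = _gene_ids(config.n_genes)
    gene_index = {g: k for k, g in enumerate(genes)}
    base_mu = rng.lognormal(mean=3.0, sigma=0.6, size=config.n_genes)
    size_param = np.full(config.n_genes, 20.0)  # pseudobulk: low dispersion
    disease = truth.disease_signature

    rows, ids, labels = [], [], []
    for cls in ("control", "case"):
        mu = base_mu.copy()
        if cls == "case":
            for g, sign in disease.items():
                mu[gene_index[g]] *= 2.0 ** (sign * config.de_effect_lfc)
        for j in range(config.n_patients_per_class):
            lib = rng.lognormal(0.0, 0.1)
            rows.append(_nb_counts(rng, lib * mu, size_param))
            ids.append(f"{cls}_pt{j:03d}")
            labels.append(cls)
    obs = pd.DataFrame(
        {"condition": labels}, index=pd.Index(ids, name="patient_id")
    )
    adata = ad.AnnData(
        X=np.vstack(rows).astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    return adata


def gen_ortholog_study(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate paired two-species DE tables with a planted conserved core.

    Returns ``(de_a, de_b, ortholog_map, truth)`` where the DE tables have
    columns ``gene``, ``log2FC``, ``p_value``, ``fdr`` and the map is a
    strictly 1:1 two-column frame (``gene_a``, ``gene_b``). A fraction
    ``conserved_fraction`` of species-A significant genes are significant in
    species B with the same sign (log2FC copied plus noise of sd
    ``ortholog_lfc_noise_sd``); all other significance is independent
    between species.
    """
    rng = np.random.default_rng(config.seed + 3)
    n = config.n_ortholog_genes
    genes_a = [f"mA_{i:05d}" for i in range(n)]
    perm = rng.permutation(n)
    genes_b = [f"hB_{i:05d}" for i in perm]
    orth_map = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})

    n_sig = int(round(config.ortholog_sig_fraction * n))
    sig_a = rng.choice(n, size=n_sig, replace=False)
    n_core = int(round(config.conserved_fraction * n_sig))
    core = sig_a[:n_core]
    non_core_pool = np.setdiff1d(np.arange(n), core)
    sig_b_extra = rng.choice(
        non_core_pool, size=max(0, n_sig - n_core), replace=False
    )
    sig_b = np.concatenate([core, sig_b_extra])

    def _table(sig_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lfc = rng.normal(0.0, 0.15, size=n)
        p = rng.uniform(0.0, 1.0, size=n)
        signs = rng.choice([-1.0, 1.0], size=len(sig_idx))
        lfc[sig_idx] = signs * (0.8 + rng.exponential(0.5, size=len(sig_idx)))
        p[sig_idx] = rng.uniform(1e-12, 1e-4, size=len(sig_idx))
        return lfc, p, signs

    lfc_a, p_a, _ = _table(sig_a)
    lfc_b, p_b, _ = _table(sig_b)
    # conserved core: same direction in both species
    lfc_b[core] = lfc_a[core] + rng.normal(
        0.0, config.ortholog_lfc_noise_sd, size=n_core
    )

    from .de import bh_fdr  # local import to avoid a cycle at module load

    a_of = dict(zip(genes_a, range(n)))
    de_a = pd.DataFrame(
        {"gene": genes_a, "log2FC": lfc_a, "p_value": p_a, "fdr": bh_fdr(p_a)}
    )
    b_order = orth_map["gene_b"].tolist()
    de_b = pd.DataFrame(
        {"gene": b_order, "log2FC": lfc_b, "p_value": p_b, "fdr": bh_fdr(p_b)}
    )
    truth = SimTruth(
        conserved_gene_set={
            genes_a[i]: int(np.sign(lfc_a[i])) for i in core
        }
    )
    # shuffle table row order deterministically so order carries no signal
    de_a = de_a.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    de_a = de_a.reset_index(drop=True)
    de_b = de_b.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    de_b = de_b.reset_index(drop=True)
    return de_a, de_b, orth_map, truth


def gen_spatial(
    config: SimConfig, gene_set: list[str], effect: float | None = None
) -> tuple["pd.DataFrame", str]:
    """Generate a spot x gene spatial grid with one enriched region.

    The ``grid_side**2`` spots are partitioned into ``n_regions`` contiguous
    vertical bands; in one band (returned as the enriched region id) every
    gene of ``gene_set`` gains ``effect`` log-units plus a coherent per-spot
    factor, emulating a regionally active transcriptional program.

    Returns ``(frame, enriched_region_id)`` where the frame has columns
    ``spot``, ``x``, ``y``, ``region`` followed by one column per gene
    (the on-disk grid layout).
    """
    if effect is None:
        effect = config.spatial_effect
    rng = np.random.default_rng(config.seed + 4)
    side = config.grid_side
    n_spots = side * side
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    xs, ys = xs.ravel(), ys.ravel()
    region_of = np.minimum(
        (xs * config.n_regions) // side, config.n_regions - 1
    )
    regions = np.array([f"region{r}" for r in region_of])
    enriched = f"region{int(rng.integers(config.n_regions))}"

    genes = sorted(set(_gene_ids(config.n_genes)) | set(gene_set))
    mu = rng.normal(1.0, 0.5, size=len(genes))
    logx = mu[None, :] + rng.normal(0.0, 0.4, size=(n_spots, len(genes)))
    in_region = regions == enriched
    spot_factor = 1.0 + 0.5 * rng.normal(0.0, 1.0, size=n_spots)
    set_cols = [j for j, g in enumerate(genes) if g in set(gene_set)]
    for j in set_cols:
        logx[in_region, j] += effect * spot_factor[in_region]
    values = np.exp(logx)

    frame = pd.DataFrame(values, columns=genes)
    frame.insert(0, "region", regions)
    frame.insert(0, "y", ys)
    frame.insert(0, "x", xs)
    frame.insert(0, "spot", [f"spot{i:04d}" for i in range(n_spots)])
    return frame, enriched
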