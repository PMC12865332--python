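"""Patient-to-cell disease-association transfer scoring.

A bootstrap-aggregated ridge-regularized logistic classifier is trained on
patient-level case/control labels over a fixed gene feature panel, after a
sample-wise preprocessing chain (log2, z-score, min-max to [0,1]). The
averaged logistic outputs assign each single cell a disease-association
("hazard") score in [0,1]; cells are stratified at the median, and the
high-vs-low DE signature can be queried against a drug-signature library in
reverse (therapeutic) or mimic (adverse) mode by signed cosine similarity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .de import SignedGeneSet
from .simulate import DrugSignatureLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "HazardModel",
    "degas_preprocess",
    "train_hazard_model",
    "score_cells",
    "median_split",
    "signature_query",
]


def degas_preprocess(X) -> np.ndarray:
    """Sample-wise transform: log2(x+1), z-score, min-max rescale to [0,1].

    Each row is one sample (a patient profile, or a single cell treated as
    its own sample): values are log2(x+1) transformed, z-scored across that
    row's features, then min-max rescaled to [0,1]. A constant row maps to
    0.5 everywhere. The chain is deliberately not idempotent (re-applying it
    re-standardizes already-rescaled values).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    logx = np.log2(X + 1.0)
    mu = logx.mean(axis=1, keepdims=True)
    sd = logx.std(axis=1, keepdims=True)
    constant = (sd < 1e-12).ravel()
    sd[sd < 1e-12] = 1.0
    z = (logx - mu) / sd
    lo = z.min(axis=1, keepdims=True)
    hi = z.max(axis=1, keepdims=True)
    span = hi - lo
    span[span < 1e-12] = 1.0
    out = (z - lo) / span
    out[constant] = 0.5
    return out


@dataclass
class HazardModel:
    """Bootstrap-aggregated linear hazard scorer.

    ``weights`` has one row per bootstrap fit over ``features`` (gene names,
    fixed order); scoring averages the logistic outputs of all fits on
    preprocessed inputs.
    """

    features: list[str]
    weights: np.ndarray  # (n_boot, n_features)
    intercepts: np.ndarray  # (n_boot,)
    n_bootstraps: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")
        if self.weights.shape != (self.n_bootstraps, len(self.features)):
            raise ValueError("weights shape inconsistent with features")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite model weights")

    def to_json(self, path) -> None:
        payload = {
            "features": self.features,
            "weights": self.weights.tolist(),
            "intercepts": self.intercepts.tolist(),
            "n_bootstraps": self.n_bootstraps,
            "preprocessing": "log2(x+1); sample-wise z-score; min-max to [0,1]",
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HazardModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            features=payload["features"],
            weights=np.asarray(payload["weights"]),
            intercepts=np.asarray(payload["intercepts"]),
            n_bootstraps=payload["n_bootstraps"],
        )


def _feature_matrix(m, features: list[str]) -> np.ndarray:
    if hasattr(m, "X"):
        names = list(m.var_names)
        X = np.asarray(
            m.layers["counts"] if "counts" in m.layers else m.X, dtype=float
        )
    else:
        names = list(m.columns)
        X = np.asarray(m, dtype=float)
    col = {g: i for i, g in enumerate(names)}
    missing = [g for g in features if g not in col]
    if missing:
        raise ValueError(f"features absent from the matrix: {missing[:10]}")
    return X[:, [col[g] for g in features]]


def train_hazard_model(
    patients,
    labels,
    features: list[str],
    positive_label: str = "case",
    n_boot: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> HazardModel:
    """Fit the bootstrap-aggregated ridge logistic scorer on patients.

    Each of ``n_boot`` bootstrap resamples of the patients (redrawn until
    both classes are present, bounded retries) gets a full L2-regularized
    logistic fit on the preprocessed feature panel.
    """
    X = degas_preprocess(_feature_matrix(patients, features))
    y = (np.asarray(labels) == positive_label).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present in the training cohort")
    rng = np.random.default_rng(seed)
    n = len(y)
    weights, intercepts = [], []
    for b in range(n_boot):
        for attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        else:  # pragma: no cover - pathological class imbalance
            raise RuntimeError("could not draw a bootstrap with both classes")
        clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
        clf.fit(X[idx], y[idx])
        weights.append(clf.coef_.ravel())
        intercepts.append(float(clf.intercept_[0]))
    return HazardModel(
        features=list(features),
        weights=np.vstack(weights),
        intercepts=np.asarray(intercepts),
        n_bootstraps=n_boot,
    )


def score_cells(model: HazardModel, cells) -> pd.Series:
    """Per-cell hazard score: mean logistic output over bootstrap fits.

    Each cell is preprocessed as its own "sample"; scores lie in [0,1]. A
    model with all-zero weights scores every cell 0.5.
    """
    X = degas_preprocess(_feature_matrix(cells, model.features))
    logits = X @ model.weights.T + model.intercepts[None, :]
    probs = 1.0 / (1.0 + np.exp(-logits))
    scores = probs.mean(axis=1)
    if hasattr(cells, "obs_names"):
        index = list(cells.obs_names)
    else:
        index = list(cells.index)
    return pd.Series(scores, index=index, name="hazard_score")


def median_split(scores: pd.Series) -> pd.DataFrame:
    """Stratify scores at the median: strictly above -> "high", else "low".

    Ties at the median fall in the low stratum ("above the median" taken
    literally). An all-equal score vector yields an all-low stratification
    with a warning.
    """
    med = float(scores.median())
    stratum = np.where(scores > med, "high", "low")
    if (stratum == "low").all():
        logger.warning(
            "median_split: no score strictly above the median "
            "(all-equal or heavily tied scores); all cells in the low stratum"
        )
    out = pd.DataFrame({"hazard_score": scores, "stratum": stratum})
    logger.info(
        "median_split: %d high / %d low (median=%.6g)",
        int((stratum == "high").sum()),
        int((stratum == "low").sum()),
        med,
    )
    return out


def signature_query(
    sig: SignedGeneSet,
    library: DrugSignatureLibrary,
    mode: str = "reverse",
    min_shared: int = 5,
) -> pd.DataFrame:
    """Rank library drugs by signed cosine similarity to a DEG signature.

    The signature is the ±1 signed indicator of the DEG set; each drug's
    response vector is compared on the genes shared with the signature
    (unit-normalized there), giving a similarity in [-1, 1]. ``mimic`` ranks
    by descending similarity, ``reverse`` by ascending (strongest
    anti-correlation first). Drugs sharing fewer than ``min_shared`` genes
    are excluded.
    """
    if mode not in {"reverse", "mimic"}:
        raise ValueError(f"mode must be 'reverse' or 'mimic', got {mode!r}")
    u_full = sig.sign_series()
    rows = []
    for drug in library.drugs():
        v_full = library.get(drug)
        shared = u_full.index.intersection(v_full.index)
        if len(shared) < min_shared:
            continue
        u = u_full.loc[shared].to_numpy()
        v = v_full.loc[shared].to_numpy(dtype=float)
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        cos = float(u @ v / (nu * nv)) if nu > 0 and nv > 0 else 0.0
        rows.append({"drug_id": drug, "similarity": cos, "mode": mode})
    table = pd.DataFrame(rows)
    if not len(table):
        return table
    ascending = mode == "reverse"
    table = table.sort_values(
        ["similarity", "drug_id"], ascending=[ascending, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
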