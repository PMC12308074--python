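"""Canonical correlation analysis between deformation and morphology.

Finds the linear combinations of per-cell morphological features (u-set) and
strain components (v-set: ϵn, ϵc, ϵcell) that are maximally correlated. The
solution is computed from first principles: columns are standardized, the
cross-covariance is whitened with inverse square roots of the (lightly
ridge-regularized) within-set covariances, and its SVD yields the canonical
weights and correlations. A multicellular mode augments each cell's 19
features with those of its three nearest neighbours (76 features total),
capturing the mechanical context of a confluent monolayer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "CCAInput",
    "CCAResult",
    "fit_cca",
    "build_multicellular_features",
    "predict_strain_correlations",
]

STRAIN_COLUMNS = ("eps_n", "eps_c", "eps_cell")


@dataclass
class CCAInput:
    """Aligned morphology matrix X (n × p) and deformation matrix Y (n × 3)."""

    X: np.ndarray
    Y: np.ndarray
    feature_names: tuple[str, ...]
    strain_names: tuple[str, ...] = STRAIN_COLUMNS
    cell_ids: np.ndarray | None = None


@dataclass
class CCAResult:
    """Canonical weights, correlations and variates.

    ``weights_x`` (p × m) and ``weights_y`` (q × m) act on standardized
    columns; ``correlations`` are the canonical correlations ρ1 ≥ … ≥ ρm;
    ``variates_x``/``variates_y`` are the training-data canonical variate
    pairs (U = Xs·a, V = Ys·b). The standardization record (per-column mean
    and sd) allows new data to be projected.
    """

    weights_x: np.ndarray
    weights_y: np.ndarray
    correlations: np.ndarray
    variates_x: np.ndarray
    variates_y: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    feature_names: tuple[str, ...] | None = None
    strain_names: tuple[str, ...] | None = None

    def project_x(self, X: np.ndarray) -> np.ndarray:
        return ((np.asarray(X, float) - self.x_mean) / self.x_sd) @ self.weights_x

    def project_y(self, Y: np.ndarray) -> np.ndarray:
        return ((np.asarray(Y, float) - self.y_mean) / self.y_sd) @ self.weights_y


def _inv_sqrt(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    w = np.clip(w, 1e-14, None)
    return v @ np.diag(1.0 / np.sqrt(w)) @ v.T


def fit_cca(
    X,
    Y,
    n_components: int | None = None,
    ridge: float = 1e-8,
    feature_names: tuple[str, ...] | None = None,
    strain_names: tuple[str, ...] | None = None,
) -> CCAResult:
    """Fit canonical correlation analysis between X (n × p) and Y (n × q).

    Columns are standardized; the whitened cross-covariance
    Sxx^(−1/2)·Sxy·Syy^(−1/2) is decomposed by SVD. The within-set
    covariances carry a small ridge (relative to their unit diagonal) for
    numerical stability; a rank-deficient X triggers a warning and relies on
    that regularization. Signs follow a deterministic convention: the
    largest-magnitude morphology weight of each component is positive.
    Correlations are clipped to [0, 1] and returned in non-increasing order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n, p = X.shape
    q = Y.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing values must be filtered before CCA")
    x_sd = X.std(axis=0, ddof=1)
    y_sd = Y.std(axis=0, ddof=1)
    if (x_sd == 0).any() or (y_sd == 0).any():
        raise ValueError("zero-variance column; drop constant features first")
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    Xs = (X - x_mean) / x_sd
    Ys = (Y - y_mean) / y_sd

    sxx = Xs.T @ Xs / (n - 1)
    syy = Ys.T @ Ys / (n - 1)
    sxy = Xs.T @ Ys / (n - 1)
    eig = np.linalg.eigvalsh(sxx)
    if eig[0] < 1e-10 * max(eig[-1], 1.0) or n <= p:
        warnings.warn(
            "rank-deficient morphology matrix; falling back to ridge-regularized CCA",
            RuntimeWarning,
            stacklevel=2,
        )
    sxx = sxx + ridge * np.eye(p)
    syy = syy + ridge * np.eye(q)

    isx = _inv_sqrt(sxx)
    isy = _inv_sqrt(syy)
    u, d, vt = np.linalg.svd(isx @ sxy @ isy)
    m = min(p, q) if n_components is None else min(n_components, p, q)
    a = isx @ u[:, :m]
    b = isy @ vt.T[:, :m]
    rho = np.clip(d[:m], 0.0, 1.0)
    for j in range(m):
        i_max = int(np.argmax(np.abs(a[:, j])))
        if a[i_max, j] < 0:
            a[:, j] *= -1
            b[:, j] *= -1
    return CCAResult(
        weights_x=a,
        weights_y=b,
        correlations=rho,
        variates_x=Xs @ a,
        variates_y=Ys @ b,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        feature_names=feature_names,
        strain_names=strain_names,
    )


def build_multicellular_features(
    morphology: pd.DataFrame,
    strain_table: pd.DataFrame | None = None,
    feature_columns: tuple[str, ...] | None = None,
    k: int = 3,
) -> CCAInput:
    """Augment each cell's features with its k nearest neighbours' features.

    Neighbours are ranked by centroid Euclidean distance (nearest first, ties
    broken by lower cell label); cells flagged as touching the border or
    lacking ``k`` valid neighbours are dropped. With the default 19 features
    and k = 3 the output matrix has 76 columns (target cell #0 plus
    neighbours #1–#3). When ``strain_table`` is given, Y holds its strain
    columns aligned to the surviving cells.
    """
    from .measure import MORPHOLOGY_FEATURES

    if feature_columns is None:
        feature_columns = tuple(
            c for c in MORPHOLOGY_FEATURES if c in morphology.columns
        )
    df = morphology.copy()
    if "touches_border" in df.columns:
        df = df[~df["touches_border"].astype(bool)]
    df = df.dropna(subset=list(feature_columns)).reset_index(drop=True)
    if len(df) < k + 1:
        raise ValueError(f"need at least {k + 1} cells with valid features")
    cents = df[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
    labels = df["cell_id"].to_numpy()
    tree = cKDTree(cents)
    dist, idx = tree.query(cents, k=min(len(df), k + 4))
    rows, kept_ids = [], []
    feats = df[list(feature_columns)].to_numpy(dtype=float)
    for i in range(len(df)):
        order = [
            j
            for _, _, j in sorted(
                (round(float(dist[i, m]), 9), int(labels[idx[i, m]]), int(idx[i, m]))
                for m in range(dist.shape[1])
                if idx[i, m] != i and idx[i, m] < len(df)
            )
        ]
        if len(order) < k:
            continue
        rows.append(np.concatenate([feats[i]] + [feats[j] for j in order[:k]]))
        kept_ids.append(labels[i])
    if not rows:
        raise ValueError("no cell has enough valid neighbours")
    names = tuple(feature_columns) + tuple(
        f"{c}_nb{j + 1}" for j in range(k) for c in feature_columns
    )
    X = np.vstack(rows)
    kept_ids = np.asarray(kept_ids)
    Y = None
    if strain_table is not None:
        st = strain_table.set_index("cell_id")
        keep = [i for i, cid in enumerate(kept_ids) if cid in st.index]
        X = X[keep]
        kept_ids = kept_ids[keep]
        Y = st.loc[kept_ids, list(STRAIN_COLUMNS)].to_numpy(dtype=float)
    return CCAInput(
        X=X,
        Y=Y if Y is not None else np.empty((len(X), 0)),
        feature_names=names,
        cell_ids=kept_ids,
    )


def predict_strain_correlations(result: CCAResult, Y) -> pd.DataFrame:
    """Correlate each measured strain with the morphology canonical variates.

    Returns one row per strain component with the Pearson r against every
    morphology variate U_i, the best (largest |r|) single variate and its
    correlation — the "measured strain versus predicted variate" read-out —
    plus ``r_fit``, the correlation of the strain with its least-squares
    projection onto all morphology variates (1 for a perfectly linear
    strain–morphology relation).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    U = result.variates_x
    names = result.strain_names or tuple(f"y{i}" for i in range(Y.shape[1]))
    design = np.column_stack([np.ones(len(U)), U])
    rows = []
    for j in range(Y.shape[1]):
        rs = []
        for i in range(U.shape[1]):
            if Y[:, j].std() == 0 or U[:, i].std() == 0:
                rs.append(np.nan)
            else:
                rs.append(float(np.corrcoef(Y[:, j], U[:, i])[0, 1]))
        best = int(np.nanargmax(np.abs(rs)))
        fitted = design @ np.linalg.lstsq(design, Y[:, j], rcond=None)[0]
        r_fit = (
            float(np.corrcoef(Y[:, j], fitted)[0, 1])
            if fitted.std() > 0 and Y[:, j].std() > 0
            else np.nan
        )
        row = {
            "strain": names[j],
            "best_variate": best + 1,
            "best_r": rs[best],
            "r_fit": r_fit,
        }
        row.update({f"r_u{i + 1}": rs[i] for i in range(len(rs))})
        rows.append(row)
    return pd.DataFrame(rows)
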