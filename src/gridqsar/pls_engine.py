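"""Partial least squares (PLS1, NIPALS) with leave-one-out model selection.

The engine is written for wide field matrices (columns >> rows). X is
column-centered internally and y is centered, never scaled; any column
scaling is the descriptor block's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import DescriptorBlock

__all__ = [
    "PLSModel",
    "fit_pls",
    "loo_q2",
    "loo_predictions",
    "select_components",
    "final_stats",
    "field_contributions",
    "stdev_coeff_grid",
    "StdevCoeffGrids",
]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


@dataclass
class PLSModel:
    ncomp: int
    x_weights: np.ndarray  # (p, a)
    x_loadings: np.ndarray  # (p, a)
    x_scores: np.ndarray  # (n, a)
    y_loadings: np.ndarray  # (a,)
    coef: np.ndarray  # (p,) on original (uncentered) columns
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    stats: dict = field(default_factory=dict)
    contributions: dict | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "ncomp": self.ncomp,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "stats": self.stats,
            "contributions": self.contributions,
        }


def fit_pls(X: np.ndarray, y: np.ndarray, ncomp: int) -> PLSModel:
    """Deterministic NIPALS PLS1 fit with ``ncomp`` latent components.

    For a single response NIPALS converges in one pass per component; the
    iteration is still run to the documented tolerance for robustness.
    Raises if ``ncomp`` exceeds what the data can support.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y row counts differ")
    if ncomp < 1:
        raise ValueError("ncomp must be >= 1")
    if ncomp > min(n - 1, p):
        raise ValueError(f"ncomp={ncomp} exceeds min(n-1, p)={min(n - 1, p)}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean

    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    T = np.zeros((n, ncomp))
    q = np.zeros(ncomp)
    for a in range(ncomp):
        # deterministic start: covariance direction with y
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ValueError(f"ncomp={ncomp} exceeds the effective rank of X ({a})")
        w /= norm
        for _ in range(_NIPALS_MAX_ITER):
            t = E @ w
            tt = float(t @ t)
            if tt < 1e-24:
                raise ValueError(f"ncomp={ncomp} exceeds the effective rank of X ({a})")
            c = float(f @ t) / tt
            u = f * c
            w_new = E.T @ u
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w = w_new
        t = E @ w
        tt = float(t @ t)
        p_a = E.T @ t / tt
        q_a = float(f @ t) / tt
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a

    # coefficients on original columns: B = W (P'W)^-1 q
    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        ncomp=ncomp,
        x_weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=q,
        coef=coef,
        intercept=intercept,
        x_mean=x_mean,
        y_mean=y_mean,
    )


def loo_predictions(X: np.ndarray, y: np.ndarray, ncomp: int) -> np.ndarray:
    """Leave-one-out predictions, each from a model refit without that row."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 rows")
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_pls(X[keep], y[keep], ncomp)
        preds[i] = model.predict(X[i : i + 1])[0]
    return preds


def loo_q2(X: np.ndarray, y: np.ndarray, ncomp: int) -> tuple[float, float]:
    """Leave-one-out cross-validated (q2, SEP).

    ``q2 = 1 - PRESS / sum (y_i - mean(y))^2`` with each prediction from a
    model excluding compound i; ``SEP = sqrt(PRESS / (n - ncomp - 1))``.
    """
    y = np.asarray(y, dtype=float).ravel()
    ss = float(np.sum((y - y.mean()) ** 2))
    if ss <= 0:
        raise ValueError("constant response: q2 denominator is zero")
    preds = loo_predictions(X, y, ncomp)
    press = float(np.sum((y - preds) ** 2))
    n = len(y)
    sep = float(np.sqrt(press / (n - ncomp - 1))) if n - ncomp - 1 > 0 else float("inf")
    return 1.0 - press / ss, sep


def select_components(X: np.ndarray, y: np.ndarray, max_comp: int | None = None) -> int:
    """Number of components maximizing LOO q2 over 1..max_comp (ties -> fewer).

    Default cap: ``min(15, n // 3)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if max_comp is None:
        max_comp = min(15, n // 3)
    max_comp = max(1, min(max_comp, n - 2, p))
    best_a, best_q2 = 1, -np.inf
    for a in range(1, max_comp + 1):
        try:
            q2, _ = loo_q2(X, y, a)
        except ValueError:
            break
        if q2 > best_q2 + 1e-12:
            best_a, best_q2 = a, q2
    return best_a


def final_stats(model: PLSModel, X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Non-cross-validated (r2_ncv, SEE, F) of a fitted model on its data.

    ``r2_ncv`` is the squared Pearson correlation of fitted vs observed,
    ``SEE = sqrt(RSS / (n - PCs - 1))`` and
    ``F = (r2/PCs) / ((1 - r2)/(n - PCs - 1))`` (infinite for a perfect fit).
    """
    y = np.asarray(y, dtype=float).ravel()
    n, a = len(y), model.ncomp
    if n <= a + 1:
        raise ValueError("need n > ncomp + 1 for SEE/F degrees of freedom")
    fitted = model.predict(X)
    r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    rss = float(np.sum((y - fitted) ** 2))
    see = float(np.sqrt(rss / (n - a - 1)))
    if r2 >= 1.0 - 1e-12:
        f_stat = float("inf")
    else:
        f_stat = (r2 / a) / ((1.0 - r2) / (n - a - 1))
    model.stats.update({"r2_ncv": r2, "SEE": see, "F": f_stat})
    return r2, see, f_stat


def field_contributions(model: PLSModel, block: DescriptorBlock) -> dict[str, float]:
    """Per-field relative contributions: sum |b_j| * sd_j, normalized to 1."""
    sd = block.column_sd()
    raw = {}
    for kind in block.fields:
        cols = block.columns_for(kind)
        raw[kind] = float(np.sum(np.abs(model.coef[cols]) * sd[cols]))
    total = sum(raw.values())
    if total <= 0:
        # degenerate all-zero model: uniform attribution
        frac = {k: 1.0 / len(raw) for k in raw}
    else:
        frac = {k: v / total for k, v in raw.items()}
    model.contributions = frac
    return frac


@dataclass
class StdevCoeffGrids:
    """Per-field 3D lattice of column-sd x PLS-coefficient values."""

    grids: dict[str, np.ndarray]  # field spec -> (nx, ny, nz)
    active: dict[str, np.ndarray]  # field spec -> boolean (nx, ny, nz) mask
    grid_spec: "object"
    fill_value: float = 0.0


def stdev_coeff_grid(
    model: PLSModel, block: DescriptorBlock, fill_value: float = 0.0
) -> StdevCoeffGrids:
    """Map sd_j * b_j back onto the lattice, one scalar grid per field kind.

    Columns dropped by the minimum-sigma filter take ``fill_value`` and are
    flagged inactive in the accompanying mask.
    """
    sd = block.column_sd()
    grids: dict[str, np.ndarray] = {}
    active: dict[str, np.ndarray] = {}
    n_pts = block.grid.n_points
    for kind in block.fields:
        cols = block.columns_for(kind)
        flat = np.full(n_pts, fill_value, dtype=float)
        mask = np.zeros(n_pts, dtype=bool)
        flat[block.lattice_idx[cols]] = sd[cols] * model.coef[cols]
        mask[block.lattice_idx[cols]] = True
        grids[kind] = block.grid.to_3d(flat)
        active[kind] = block.grid.to_3d(mask)
    return StdevCoeffGrids(grids=grids, active=active, grid_spec=block.grid, fill_value=fill_value)
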