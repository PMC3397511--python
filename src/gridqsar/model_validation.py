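"""External-validation metrics, the five-condition acceptability gate, and
robustness checks (y-randomization, bootstrap, repeated k-fold CV).

All metric functions are pure; every stochastic routine takes an explicit
seed and uses one ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pls_engine import fit_pls, loo_q2, select_components

__all__ = [
    "ValidationReport",
    "r2_pred",
    "r2_simple",
    "origin_regressions",
    "rm2",
    "rmsep",
    "tropsha_gate",
    "validate_external",
    "y_randomization",
    "bootstrap_r2",
    "repeated_kfold_q2",
]


def _check_pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if len(y) != len(p):
        raise ValueError("observed/predicted length mismatch")
    return y, p


def r2_pred(test_observed, test_predicted, train_mean: float) -> float:
    """External predictivity: ``1 - PRESS / SD``.

    ``SD`` sums squared deviations of the test observations from the
    training-set mean activity.
    """
    y, p = _check_pair(test_observed, test_predicted)
    if len(y) < 2:
        raise ValueError("need at least 2 test compounds")
    sd = float(np.sum((y - train_mean) ** 2))
    if sd <= 0:
        raise ValueError("SD is zero: test observations equal the training mean")
    press = float(np.sum((y - p) ** 2))
    return 1.0 - press / sd


def r2_simple(observed, predicted) -> float:
    """Conventional squared Pearson correlation."""
    y, p = _check_pair(observed, predicted)
    return float(np.corrcoef(y, p)[0, 1] ** 2)


def origin_regressions(observed, predicted) -> dict[str, float]:
    """Through-origin regression diagnostics on a test set.

    With predicted on the X axis and observed on Y (intercept zero):
    ``k = sum(y*yhat) / sum(yhat^2)`` and ``r2_o`` is the coefficient of the
    through-origin line on those axes. Primed variants swap the axes.
    ``r2_test`` is the conventional squared correlation.
    """
    y, p = _check_pair(observed, predicted)
    if len(y) < 2:
        raise ValueError("need at least 2 points")
    if np.allclose(p, 0.0) or np.allclose(y, 0.0):
        raise ValueError("degenerate (all-zero) axis for through-origin regression")
    if np.std(p) == 0 or np.std(y) == 0:
        raise ValueError("constant axis: correlation undefined")
    k = float(np.sum(y * p) / np.sum(p * p))
    k_prime = float(np.sum(y * p) / np.sum(y * y))
    r2_o = 1.0 - float(np.sum((y - k * p) ** 2) / np.sum((y - y.mean()) ** 2))
    r2_o_prime = 1.0 - float(np.sum((p - k_prime * y) ** 2) / np.sum((p - p.mean()) ** 2))
    return {
        "k": k,
        "k_prime": k_prime,
        "r2_o": r2_o,
        "r2_o_prime": r2_o_prime,
        "r2_test": r2_simple(y, p),
    }


def rm2(r2_test: float, r2_o: float) -> float:
    """Roy's metric: ``r2_test * (1 - sqrt(r2_test - r2_o))``."""
    if r2_o > r2_test:
        raise ValueError("invalid pair: r2_o exceeds r2_test")
    if r2_o < 0:
        raise ValueError("invalid pair: negative r2_o")
    return r2_test * (1.0 - np.sqrt(r2_test - r2_o))


def rmsep(observed, predicted) -> float:
    """Root-mean-squared error of prediction."""
    y, p = _check_pair(observed, predicted)
    if len(y) < 1:
        raise ValueError("need at least 1 pair")
    return float(np.sqrt(np.mean((y - p) ** 2)))


def tropsha_gate(
    r2_pred_value: float,
    r2_test: float,
    r2_o: float,
    k: float,
    r2_m: float,
) -> dict:
    """Five-condition acceptability rule set; verdict is the AND of all."""
    degradation = (r2_test - r2_o) / r2_test if r2_test != 0 else np.inf
    conditions = {
        "r2_pred_gt_0.5": bool(r2_pred_value > 0.5),
        "r2_test_gt_0.6": bool(r2_test > 0.6),
        "origin_degradation_lt_0.1": bool(degradation < 0.1),
        "k_in_0.85_1.15": bool(0.85 <= k <= 1.15),
        "r2_m_gt_0.5": bool(r2_m > 0.5),
    }
    return {"conditions": conditions, "verdict": all(conditions.values())}


@dataclass
class ValidationReport:
    r2_pred: float
    r2_test: float
    r2_o: float
    r2_o_prime: float
    k: float
    k_prime: float
    r2_m: float | None
    r2_m_prime: float | None
    rmsep: float
    origin_degradation: float
    gate: dict = field(default_factory=dict)
    y_randomization_q2: list[float] | None = None
    bootstrap: dict | None = None
    r2_cv_mean: float | None = None
    seeds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "r2_pred": self.r2_pred,
            "r2_test": self.r2_test,
            "r2_o": self.r2_o,
            "r2_o_prime": self.r2_o_prime,
            "k": self.k,
            "k_prime": self.k_prime,
            "r2_m": self.r2_m,
            "r2_m_prime": self.r2_m_prime,
            "rmsep": self.rmsep,
            "origin_degradation": self.origin_degradation,
            "gate": self.gate,
            "seeds": self.seeds,
        }
        if self.y_randomization_q2 is not None:
            out["y_randomization"] = {
                "q2": self.y_randomization_q2,
                "min": min(self.y_randomization_q2) if self.y_randomization_q2 else None,
                "max": max(self.y_randomization_q2) if self.y_randomization_q2 else None,
            }
        if self.bootstrap is not None:
            out["bootstrap"] = self.bootstrap
        if self.r2_cv_mean is not None:
            out["r2_cv_mean"] = self.r2_cv_mean
        return out


def _safe_rm2(r2_test: float, r2_o: float) -> float | None:
    try:
        return rm2(r2_test, r2_o)
    except ValueError:
        return None


def validate_external(train_observed, test_observed, test_predicted) -> ValidationReport:
    """Full external-metric layer for one model's test-set predictions."""
    y_tr = np.asarray(train_observed, dtype=float).ravel()
    reg = origin_regressions(test_observed, test_predicted)
    rp = r2_pred(test_observed, test_predicted, float(y_tr.mean()))
    rm = _safe_rm2(reg["r2_test"], reg["r2_o"])
    rm_p = _safe_rm2(reg["r2_test"], reg["r2_o_prime"])
    report = ValidationReport(
        r2_pred=rp,
        r2_test=reg["r2_test"],
        r2_o=reg["r2_o"],
        r2_o_prime=reg["r2_o_prime"],
        k=reg["k"],
        k_prime=reg["k_prime"],
        r2_m=rm,
        r2_m_prime=rm_p,
        rmsep=rmsep(test_observed, test_predicted),
        origin_degradation=(reg["r2_test"] - reg["r2_o"]) / reg["r2_test"],
    )
    report.gate = tropsha_gate(
        rp, reg["r2_test"], reg["r2_o"], reg["k"], rm if rm is not None else -np.inf
    )
    return report


# ---------------------------------------------------------------------------
# robustness checks


def y_randomization(
    X: np.ndarray,
    y: np.ndarray,
    runs: int = 50,
    seed: int = 0,
    max_comp: int | None = None,
) -> list[float]:
    """LOO q2 after permuting the response, one value per run.

    Components are re-selected for every permutation (conservative).
    ``runs=0`` returns an empty list.
    """
    if runs < 0:
        raise ValueError("runs must be >= 0")
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    out: list[float] = []
    for _ in range(runs):
        y_perm = y[rng.permutation(len(y))]
        a = select_components(X, y_perm, max_comp)
        q2, _ = loo_q2(X, y_perm, a)
        out.append(q2)
    return out


def bootstrap_r2(
    X: np.ndarray,
    y: np.ndarray,
    runs: int = 100,
    seed: int = 0,
    ncomp: int = 2,
) -> tuple[float, float]:
    """Mean non-cross-validated (r2_bs, SEE_bs) over seeded bootstrap refits.

    Resamples rows with replacement at fixed component count; draws with too
    few distinct rows to support the fit are redrawn.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    rng = np.random.default_rng(seed)
    r2s, sees = [], []
    for _ in range(runs):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(idx)) >= ncomp + 2 and np.std(y[idx]) > 0:
                break
        else:
            raise RuntimeError("could not draw a usable bootstrap resample")
        model = fit_pls(X[idx], y[idx], ncomp)
        fitted = model.predict(X[idx])
        resid = y[idx] - fitted
        r2s.append(float(np.corrcoef(fitted, y[idx])[0, 1] ** 2))
        sees.append(float(np.sqrt(np.sum(resid**2) / max(n - ncomp - 1, 1))))
    return float(np.mean(r2s)), float(np.mean(sees))


def repeated_kfold_q2(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    ncomp: int = 2,
) -> float:
    """Mean grouped cross-validated q2-analogue over seeded repeats.

    Each repeat shuffles compounds into ``folds`` groups; every group is
    predicted by a model trained on the remainder. With ``folds == n`` this
    reduces exactly to leave-one-out q2.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if folds > n:
        raise ValueError(f"folds={folds} exceeds number of rows {n}")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    ss = float(np.sum((y - y.mean()) ** 2))
    vals = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        preds = np.empty(n)
        for fold in np.array_split(perm, folds):
            keep = np.setdiff1d(np.arange(n), fold)
            model = fit_pls(X[keep], y[keep], ncomp)
            preds[fold] = model.predict(X[fold])
        vals.append(1.0 - float(np.sum((y - preds) ** 2)) / ss)
    return float(np.mean(vals))
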