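"""Collapse-pressure curve normalization, sigmoid fitting and bootstrap.

The optical density of a vesicle suspension drops as hydrostatic pressure
collapses the population; after min-max normalization the curve is fitted
with ``OD_norm = 1 / (1 + exp(k (p - p0)))`` where ``p0`` is the critical
collapse pressure (inflection, OD_norm = 0.5) and ``k`` the width.
Uncertainty on ``p0`` is estimated by an n-of-n bootstrap (resample the
measurement points with replacement, refit, report mean and SD over the
resamples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CollapseCurve",
    "SigmoidFit",
    "BootstrapResult",
    "sigmoid",
    "normalize_od",
    "fit_sigmoid",
    "bootstrap_p0",
    "read_collapse_table",
    "summarize_replicates",
]


def sigmoid(p: np.ndarray, p0: float, k: float) -> np.ndarray:
    """Decreasing logistic: 1 / (1 + exp(k (p - p0)))."""
    return 1.0 / (1.0 + np.exp(np.clip(k * (np.asarray(p, float) - p0), -500, 500)))


@dataclass(frozen=True)
class CollapseCurve:
    """One pressure series of raw OD500 readings."""

    pressures: np.ndarray
    od500: np.ndarray
    replicate: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures, float)
        od = np.asarray(self.od500, float)
        if p.ndim != 1 or p.shape != od.shape:
            raise ValueError("pressures and od500 must be matching 1-D arrays")
        if len(p) < 4:
            raise ValueError("a collapse curve needs at least 4 points")
        if np.any(np.diff(p) <= 0):
            raise ValueError("pressures must be strictly increasing")
        object.__setattr__(self, "pressures", p)
        object.__setattr__(self, "od500", od)


@dataclass(frozen=True)
class SigmoidFit:
    p0: float
    k: float
    rss: float
    n_points: int
    weighted: bool = False


@dataclass(frozen=True)
class BootstrapResult:
    p0_mean: float
    p0_sd: float
    k_mean: float
    k_sd: float
    n_boot: int
    n_failed: int
    fits: tuple = field(repr=False, default=())


def normalize_od(curve: CollapseCurve) -> CollapseCurve:
    """Min-max normalize one measurement to [0, 1]."""
    od = curve.od500
    lo, hi = od.min(), od.max()
    if hi <= lo:
        raise ValueError("cannot normalize a constant OD series")
    return CollapseCurve(curve.pressures, (od - lo) / (hi - lo), curve.replicate)


def _initial_guess(p: np.ndarray, od: np.ndarray) -> tuple[float, float]:
    # p0: first downward crossing of 0.5, linearly interpolated
    p0 = p[len(p) // 2]
    below = np.flatnonzero(od < 0.5)
    if len(below) and below[0] > 0:
        i = below[0]
        f = (od[i - 1] - 0.5) / (od[i - 1] - od[i])
        p0 = p[i - 1] + f * (p[i] - p[i - 1])
    elif len(below):
        p0 = p[0]

    def crossing(level: float) -> float | None:
        idx = np.flatnonzero(od < level)
        if len(idx) == 0 or idx[0] == 0:
            return None
        i = idx[0]
        f = (od[i - 1] - level) / (od[i - 1] - od[i])
        return p[i - 1] + f * (p[i] - p[i - 1])

    hi, lo = crossing(0.75), crossing(0.25)
    k = 1.0
    if hi is not None and lo is not None and lo > hi:
        k = 4.0 / (lo - hi)
    return float(p0), float(k)


def fit_sigmoid(pressures: np.ndarray, od_norm: np.ndarray,
                weights: np.ndarray | None = None) -> SigmoidFit:
    """Bounded least-squares fit of (p0, k), k > 0.

    ``weights`` are per-point standard deviations; residuals are divided by
    them (inverse-variance weighting), with zero SDs clamped to the smallest
    positive one.
    """
    p = np.asarray(pressures, float)
    od = np.asarray(od_norm, float)
    if p.shape != od.shape or p.ndim != 1:
        raise ValueError("pressures and od_norm must be matching 1-D arrays")
    if len(p) < 4:
        raise ValueError("need at least 4 points to fit")
    sd = None
    if weights is not None:
        sd = np.asarray(weights, float).copy()
        positive = sd[sd > 0]
        if len(positive) == 0:
            sd = None
        else:
            sd[sd <= 0] = positive.min()

    def residuals(theta: np.ndarray) -> np.ndarray:
        res = sigmoid(p, theta[0], theta[1]) - od
        return res / sd if sd is not None else res

    x0 = np.array(_initial_guess(p, od))
    result = least_squares(residuals, x0, bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
                           xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=500 * 3)
    if not result.success:
        raise RuntimeError(f"sigmoid fit did not converge: {result.message}")
    rss = float(np.sum((sigmoid(p, *result.x) - od) ** 2))
    return SigmoidFit(p0=float(result.x[0]), k=float(result.x[1]), rss=rss,
                      n_points=len(p), weighted=sd is not None)


def bootstrap_p0(pressures: np.ndarray, od_norm: np.ndarray,
                 n_boot: int = 50, seed: int = 0,
                 weights: np.ndarray | None = None) -> BootstrapResult:
    """n-of-n bootstrap of the sigmoid fit.

    Resamples (pressure, od) pairs with replacement ``n_boot`` times, refits
    each resample and reports the mean and SD of the parameters over the
    successful refits.  Fails if more than half the refits fail.
    """
    p = np.asarray(pressures, float)
    od = np.asarray(od_norm, float)
    fit_sigmoid(p, od, weights)  # must be fittable at all
    rng = np.random.default_rng(seed)
    n = len(p)
    fits: list[SigmoidFit] = []
    n_failed = 0
    for _ in range(n_boot):
        idx = np.sort(rng.integers(0, n, size=n))
        w = None if weights is None else np.asarray(weights, float)[idx]
        try:
            fits.append(fit_sigmoid(p[idx], od[idx], w))
        except (RuntimeError, ValueError):
            n_failed += 1
    if n_failed > n_boot / 2:
        raise RuntimeError(f"bootstrap failed: {n_failed}/{n_boot} refits did not converge")
    p0s = np.array([f.p0 for f in fits])
    ks = np.array([f.k for f in fits])
    return BootstrapResult(
        p0_mean=float(p0s.mean()), p0_sd=float(p0s.std(ddof=1)),
        k_mean=float(ks.mean()), k_sd=float(ks.std(ddof=1)),
        n_boot=n_boot, n_failed=n_failed, fits=tuple(fits))


def read_collapse_table(path, sep=None) -> list[CollapseCurve]:
    """Read a delimited table with columns pressure_bar, od500[, replicate]."""
    df = pd.read_csv(path, sep=sep, engine="python")
    cols = {c.lower(): c for c in df.columns}
    try:
        p_col, od_col = cols["pressure_bar"], cols["od500"]
    except KeyError as exc:
        raise ValueError("table needs columns 'pressure_bar' and 'od500'") from exc
    rep_col = cols.get("replicate")
    curves = []
    if rep_col is None:
        df = df.sort_values(p_col)
        curves.append(CollapseCurve(df[p_col].to_numpy(), df[od_col].to_numpy()))
    else:
        for rep, grp in df.groupby(rep_col):
            grp = grp.sort_values(p_col)
            curves.append(CollapseCurve(grp[p_col].to_numpy(), grp[od_col].to_numpy(),
                                        replicate=int(rep)))
    return curves


def summarize_replicates(curves: list[CollapseCurve],
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Normalize each replicate, then mean and SD of OD per pressure.

    Returns ``(pressures, mean_od, sd_od)``; SD is None for a single curve.
    Replicates must share one pressure grid.
    """
    if not curves:
        raise ValueError("no curves given")
    p = curves[0].pressures
    for c in curves[1:]:
        if len(c.pressures) != len(p) or not np.allclose(c.pressures, p):
            raise ValueError("replicates must share the same pressure grid")
    normalized = np.array([normalize_od(c).od500 for c in curves])
    mean = normalized.mean(axis=0)
    sd = normalized.std(axis=0, ddof=1) if len(curves) >= 2 else None
    return p, mean, sd
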