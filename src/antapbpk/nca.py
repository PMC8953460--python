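"""Noncompartmental analysis and model-verification statistics.

AUC by linear-up/log-down trapezoid (linear variant available), terminal
slope by log-linear regression over the best adjusted-R² window, and the
derived parameters CL = Dose/AUC_inf, MRT (infusion-corrected) and
Vss = CL·MRT.  Verification statistics follow predicted-vs-observed
practice: average fold difference (geometric mean of per-time-point
predicted/observed ratios, arithmetic variant behind a flag), per-subject
AUC max/min fold spread, and simple AUC ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "NCAResult",
    "nca",
    "partial_auc",
    "average_fold_difference",
    "auc_fold_spread",
    "auc_ratio",
]


@dataclass(frozen=True)
class NCAResult:
    """Noncompartmental parameters for one concentration-time profile.

    Concentrations in ng/mL, times in h, dose in mg: AUCs are ng·h/mL,
    clearance L/h, volumes L.  Parameters depending on the terminal slope
    are ``None`` when lambda_z is not estimable.
    """

    auc_last: float
    cmax: float
    tmax: float
    lambda_z: Optional[float] = None        # 1/h
    t_half: Optional[float] = None          # h
    auc_inf: Optional[float] = None
    aumc_inf: Optional[float] = None
    extrapolated_fraction: Optional[float] = None
    cl: Optional[float] = None              # L/h
    mrt: Optional[float] = None             # h
    vss: Optional[float] = None             # L
    lambda_z_n_points: int = 0
    lambda_z_r2adj: Optional[float] = None


def _trapezoid_increment(t1, t2, c1, c2, method: str) -> tuple[float, float]:
    """(AUC, AUMC) increment over one interval."""
    dt = t2 - t1
    if method == "linear" or c2 >= c1 or c1 <= 0 or c2 <= 0:
        auc = 0.5 * (c1 + c2) * dt
        aumc = 0.5 * (c1 * t1 + c2 * t2) * dt
    else:  # log-down
        k = math.log(c1 / c2) / dt
        auc = (c1 - c2) / k
        aumc = (c1 * t1 - c2 * t2) / k + (c1 - c2) / k**2
    return auc, aumc


def _auc_aumc(times: np.ndarray, conc: np.ndarray, method: str) -> tuple[float, float]:
    auc = aumc = 0.0
    for i in range(len(times) - 1):
        da, dm = _trapezoid_increment(times[i], times[i + 1],
                                      conc[i], conc[i + 1], method)
        auc += da
        aumc += dm
    return auc, aumc


def _fit_lambda_z(times: np.ndarray, conc: np.ndarray,
                  tmax: float) -> tuple[Optional[float], int, Optional[float]]:
    """Best-window log-linear terminal slope (adjusted-R² selection).

    Candidate windows are the last n ≥ 3 positive concentrations strictly
    after Tmax; among windows whose adjusted R² is within 1e-4 of the best,
    the longest is kept.
    """
    mask = (times > tmax) & (conc > 0)
    t, c = times[mask], np.log(conc[mask])
    best: tuple[float, int, float] | None = None  # (r2adj, n, slope)
    for n in range(3, len(t) + 1):
        tt, cc = t[-n:], c[-n:]
        slope, intercept = np.polyfit(tt, cc, 1)
        if slope >= 0:
            continue
        resid = cc - (slope * tt + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((cc - cc.mean()) ** 2).sum())
        if ss_tot == 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or r2adj > best[0] + 1e-4 or (
                abs(r2adj - best[0]) <= 1e-4 and n > best[1]):
            best = (r2adj, n, slope)
    if best is None:
        return None, 0, None
    return -best[2], best[1], best[0]


def nca(
    times: Sequence[float],
    conc: Sequence[float],
    dose_mg: Optional[float] = None,
    infusion_duration_h: float = 0.0,
    *,
    method: str = "linear-up-log-down",
) -> NCAResult:
    """Noncompartmental analysis of one profile.

    ``times`` must be strictly increasing; ``dose_mg`` enables CL and Vss.
    ``method`` is ``"linear-up-log-down"`` (default) or ``"linear"``.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.ndim != 1 or t.shape != c.shape or len(t) < 3:
        raise ValueError("need matched 1-D arrays of ≥ 3 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    trap = "linear" if method == "linear" else "lin-log"

    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_last, aumc_last = _auc_aumc(t, c, trap)

    lam, n_pts, r2adj = _fit_lambda_z(t, c, tmax)
    if lam is None:
        return NCAResult(auc_last=auc_last, cmax=cmax, tmax=tmax)

    # extrapolation from the last observed positive concentration
    pos = np.nonzero(c > 0)[0]
    c_last, t_last = float(c[pos[-1]]), float(t[pos[-1]])
    auc_inf = auc_last + c_last / lam
    aumc_inf = aumc_last + c_last * t_last / lam + c_last / lam**2
    mrt = aumc_inf / auc_inf - infusion_duration_h / 2.0
    cl = vss = None
    if dose_mg is not None:
        cl = dose_mg * 1000.0 / auc_inf    # mg·1e6 ng / (ng·h/mL) / 1e3 -> L/h
        vss = cl * mrt
    return NCAResult(
        auc_last=auc_last, cmax=cmax, tmax=tmax,
        lambda_z=lam, t_half=math.log(2) / lam,
        auc_inf=auc_inf, aumc_inf=aumc_inf,
        extrapolated_fraction=(auc_inf - auc_last) / auc_inf,
        cl=cl, mrt=mrt, vss=vss,
        lambda_z_n_points=n_pts, lambda_z_r2adj=r2adj,
    )


def partial_auc(
    times: Sequence[float],
    conc: Sequence[float],
    t_end: float,
    t_start: float = 0.0,
    *,
    method: str = "linear-up-log-down",
) -> float:
    """AUC over [t_start, t_end] with interpolation at the window edges."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if t_end > t[-1] + 1e-9:
        raise ValueError("t_end beyond sampled profile")
    trap = "linear" if method == "linear" else "lin-log"

    def interp(tq: float) -> float:
        return float(np.interp(tq, t, c))

    mask = (t > t_start) & (t < t_end)
    tt = np.concatenate([[t_start], t[mask], [t_end]])
    cc = np.concatenate([[interp(t_start)], c[mask], [interp(t_end)]])
    auc, _ = _auc_aumc(tt, cc, trap)
    return auc


def average_fold_difference(
    predicted: Sequence[float],
    observed: Sequence[float],
    *,
    mean: str = "geometric",
) -> tuple[float, float, float]:
    """Average fold difference between matched curves, with its range.

    Returns (AFE, min ratio, max ratio) over per-time-point
    predicted/observed ratios.  Non-positive observed points are excluded
    with a warning.  ``mean`` is ``"geometric"`` (default) or
    ``"arithmetic"``.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must be matched")
    ok = (o > 0) & (p > 0)
    if not np.all(ok):
        warnings.warn(f"{int((~ok).sum())} non-positive point(s) excluded "
                      "from fold-difference", stacklevel=2)
    ratios = p[ok] / o[ok]
    if ratios.size == 0:
        raise ValueError("no valid predicted/observed pairs")
    if mean == "geometric":
        afe = float(np.exp(np.mean(np.log(ratios))))
    elif mean == "arithmetic":
        afe = float(np.mean(ratios))
    else:
        raise ValueError("mean must be 'geometric' or 'arithmetic'")
    return afe, float(ratios.min()), float(ratios.max())


def auc_fold_spread(aucs: Sequence[float]) -> float:
    """Max/min ratio of per-subject AUCs (≥ 1)."""
    a = np.asarray(aucs, dtype=float)
    if a.size < 2 or np.any(a <= 0):
        raise ValueError("need ≥ 2 positive AUCs")
    return float(a.max() / a.min())


def auc_ratio(predicted_auc: float, observed_auc: float) -> float:
    """Predicted/observed AUC ratio."""
    if predicted_auc <= 0 or observed_auc <= 0:
        raise ValueError("AUCs must be positive")
    return predicted_auc / observed_auc
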