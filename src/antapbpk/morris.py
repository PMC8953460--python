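"""Morris elementary-effects global sensitivity screening.

One-at-a-time screening on a p-level grid over the unit hypercube: r
trajectories of k+1 points, each consecutive pair differing in exactly one
coordinate by the grid jump Δ.  For each parameter and endpoint the
elementary effects EE = (f(x + Δe_i) − f(x))/Δ (unit scale) are summarized
as µ (mean), µ* (mean absolute value) and σ (standard deviation); µ* ranks
overall influence while σ flags nonlinearity/interaction.

The packaged application screens the hydroxy-metabolite model inputs
(logP, acid/base pKa, B:P, systemic clearance, fu) over their uncertainty
ranges against the metabolite's Cmax, AUC0-24 and Tmax from a whole-body
simulation of a single 100-mg antazoline dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .compounds import CompoundParameters, PKaEntry
from .engine import DoseRegimen, build_model, elephant1_regimen, simulate
from .ivive import build_clearance_breakdown
from .nca import partial_auc
from .physiology import VirtualSubject, reference_subject
from .tissue import predict_kp_set

__all__ = [
    "MorrisDesign",
    "MorrisResult",
    "build_trajectories",
    "elementary_effects",
    "metabolite_gsa_design",
    "metabolite_endpoint_function",
    "run_metabolite_gsa",
]


@dataclass(frozen=True)
class MorrisDesign:
    """Screening design: parameter bounds, levels, trajectories, jump, seed."""

    parameters: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    n_trajectories: int = 100
    n_levels: int = 4
    delta: Optional[float] = None   # default p / (2(p-1))
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.parameters) != len(self.bounds):
            raise ValueError("parameters and bounds must be matched")
        for name, (lo, hi) in zip(self.parameters, self.bounds):
            if not lo < hi:
                raise ValueError(f"degenerate bounds for {name}: [{lo}, {hi}]")
        if self.n_levels < 2 or self.n_trajectories < 1:
            raise ValueError("need ≥ 2 levels and ≥ 1 trajectory")
        d = self.grid_jump
        steps = d * (self.n_levels - 1)
        if abs(steps - round(steps)) > 1e-9 or not 0 < d < 1:
            raise ValueError("delta must be a multiple of 1/(p-1) in (0, 1)")

    @property
    def grid_jump(self) -> float:
        if self.delta is not None:
            return self.delta
        p = self.n_levels
        return p / (2.0 * (p - 1))

    @property
    def k(self) -> int:
        return len(self.parameters)

    def to_physical(self, unit: np.ndarray) -> np.ndarray:
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return lo + unit * (hi - lo)


@dataclass(frozen=True)
class SamplingPlan:
    """r trajectories of (k+1) unit-cube points plus step bookkeeping."""

    design: MorrisDesign
    points: np.ndarray        # (r, k+1, k) unit cube
    step_param: np.ndarray    # (r, k) parameter index of step j
    step_sign: np.ndarray     # (r, k) ±1

    @property
    def n_evaluations(self) -> int:
        r, kp1, _ = self.points.shape
        return r * kp1


def build_trajectories(design: MorrisDesign) -> SamplingPlan:
    """Random one-at-a-time trajectories on the level grid, seed-reproducible."""
    rng = np.random.default_rng(design.seed)
    k, r = design.k, design.n_trajectories
    delta = design.grid_jump
    p = design.n_levels
    base_levels = np.arange(p) / (p - 1)
    low_levels = base_levels[base_levels <= 1.0 - delta + 1e-12]

    points = np.empty((r, k + 1, k))
    step_param = np.empty((r, k), dtype=int)
    step_sign = np.empty((r, k), dtype=int)
    for t in range(r):
        signs = rng.choice([-1, 1], size=k)
        base = rng.choice(low_levels, size=k)
        # mirror the start level for descending coordinates
        base = np.where(signs > 0, base, base + delta)
        order = rng.permutation(k)
        x = base.copy()
        points[t, 0] = x
        for j, idx in enumerate(order):
            x = x.copy()
            x[idx] += signs[idx] * delta
            points[t, j + 1] = x
            step_param[t, j] = idx
            step_sign[t, j] = signs[idx]
    if points.min() < -1e-12 or points.max() > 1 + 1e-12:
        raise AssertionError("trajectory left the unit hypercube")
    return SamplingPlan(design=design, points=np.clip(points, 0.0, 1.0),
                        step_param=step_param, step_sign=step_sign)


@dataclass(frozen=True)
class MorrisResult:
    """µ, µ* and σ per endpoint × parameter, with µ*-based ranking."""

    table: pd.DataFrame     # endpoint, parameter, mu, mu_star, sigma, rank
    n_evaluations: int
    n_dropped_trajectories: int
    seed: int

    def ranking(self, endpoint: str) -> list[str]:
        sel = self.table[self.table.endpoint == endpoint]
        return list(sel.sort_values("mu_star", ascending=False).parameter)

    def mu_star(self, endpoint: str, parameter: str) -> float:
        sel = self.table[(self.table.endpoint == endpoint)
                         & (self.table.parameter == parameter)]
        return float(sel.mu_star.iloc[0])


def elementary_effects(
    plan: SamplingPlan,
    endpoint_function: Callable[[Mapping[str, float]], Mapping[str, float]],
) -> MorrisResult:
    """Evaluate the plan and summarize elementary effects per endpoint.

    ``endpoint_function`` maps a physical parameter dict to a dict of finite
    endpoint values.  Trajectories yielding any non-finite endpoint are
    dropped with a warning and reported in the result.
    """
    design = plan.design
    r, kp1, k = plan.points.shape
    delta = design.grid_jump

    values: list[list[dict]] = []
    for t in range(r):
        traj = []
        for j in range(kp1):
            phys = design.to_physical(plan.points[t, j])
            traj.append(dict(endpoint_function(
                dict(zip(design.parameters, phys)))))
        values.append(traj)

    endpoints = list(values[0][0])
    ees: dict[str, dict[str, list[float]]] = {
        e: {p: [] for p in design.parameters} for e in endpoints}
    dropped = 0
    for t in range(r):
        finite = all(np.isfinite(list(v.values())).all() for v in values[t])
        if not finite:
            dropped += 1
            warnings.warn(f"trajectory {t} dropped: non-finite endpoint",
                          stacklevel=2)
            continue
        for j in range(k):
            idx = plan.step_param[t, j]
            sign = plan.step_sign[t, j]
            pname = design.parameters[idx]
            for e in endpoints:
                diff = values[t][j + 1][e] - values[t][j][e]
                ees[e][pname].append(diff / (sign * delta))

    rows = []
    for e in endpoints:
        stats = []
        for pname in design.parameters:
            arr = np.asarray(ees[e][pname])
            if arr.size == 0:
                raise RuntimeError("all trajectories dropped")
            mu = float(arr.mean())
            mu_star = float(np.abs(arr).mean())
            sigma = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            stats.append((pname, mu, mu_star, sigma))
        order = np.argsort([-s[2] for s in stats], kind="stable")
        rank = {stats[i][0]: pos + 1 for pos, i in enumerate(order)}
        for pname, mu, mu_star, sigma in stats:
            rows.append({"endpoint": e, "parameter": pname, "mu": mu,
                         "mu_star": mu_star, "sigma": sigma,
                         "rank": rank[pname]})
    return MorrisResult(table=pd.DataFrame(rows),
                        n_evaluations=plan.n_evaluations,
                        n_dropped_trajectories=dropped, seed=design.seed)


# --- packaged application: metabolite-model parameter screening -----------

#: Uncertainty ranges for the metabolite model inputs (uniform).
METABOLITE_GSA_BOUNDS: tuple[tuple[str, float, float], ...] = (
    ("logP", 1.5, 3.5),
    ("pKa_acid", 6.0, 14.0),
    ("pKa_base", 6.0, 14.0),
    ("blood_plasma_ratio", 0.55, 2.0),
    ("clearance", 2.0, 80.0),
    ("fu_plasma", 0.1, 1.0),
)


def metabolite_gsa_design(
    n_trajectories: int = 100,
    seed: int = 0,
    n_levels: int = 4,
) -> MorrisDesign:
    """Default screening design over the metabolite uncertainty ranges."""
    return MorrisDesign(
        parameters=tuple(b[0] for b in METABOLITE_GSA_BOUNDS),
        bounds=tuple((b[1], b[2]) for b in METABOLITE_GSA_BOUNDS),
        n_trajectories=n_trajectories,
        n_levels=n_levels,
        seed=seed,
    )


def metabolite_endpoint_function(
    parent: Optional[CompoundParameters] = None,
    subject: Optional[VirtualSubject] = None,
    regimen: Optional[DoseRegimen] = None,
    duration: float = 24.0,
) -> Callable[[Mapping[str, float]], dict[str, float]]:
    """Endpoint closure: metabolite Cmax, AUC0-24 and Tmax vs its parameters.

    The parent model (single 100-mg dose to the reference adult by default)
    is held fixed; each evaluation rebuilds the metabolite from the sampled
    parameters, re-derives its tissue partitioning and re-simulates the
    coupled system.  Acid-below-base pKa orderings from independent uniform
    sampling are passed through unchanged; the species-fraction model
    handles them.
    """
    from .compounds import antazoline, hydroxyantazoline

    parent = parent or antazoline()
    subject = subject or reference_subject()
    regimen = regimen or elephant1_regimen()
    template = hydroxyantazoline()
    kp_parent = predict_kp_set(parent, hematocrit=subject.hematocrit)
    breakdown = build_clearance_breakdown(parent, subject.liver)
    grid = np.unique(np.concatenate([
        np.linspace(0.0, 2.0, 121), np.linspace(2.0, duration, 150)]))

    def endpoint(params: Mapping[str, float]) -> dict[str, float]:
        met = template.model_copy(update={
            "logP": float(params["logP"]),
            "pKa_values": (
                PKaEntry(value=float(params["pKa_acid"]), role="acid"),
                PKaEntry(value=float(params["pKa_base"]), role="base"),
            ),
            "fu_plasma": float(params["fu_plasma"]),
            "blood_plasma_ratio": float(params["blood_plasma_ratio"]),
            "elimination": template.elimination.model_copy(update={
                "total_systemic_clearance": float(params["clearance"])}),
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kp_met = predict_kp_set(met, hematocrit=subject.hematocrit)
            model = build_model(parent, met, subject, kp_parent, kp_met,
                                breakdown)
            res = simulate(model, regimen, duration=duration, grid=grid)
        conc = res.plasma_conc[met.name]
        i_max = int(np.argmax(conc))
        return {
            "cmax": float(conc[i_max]),
            "auc_0_24": float(partial_auc(res.time, conc, 24.0)),
            "tmax": float(res.time[i_max]),
        }

    return endpoint


def run_metabolite_gsa(
    n_trajectories: int = 100,
    seed: int = 0,
    **endpoint_kwargs,
) -> MorrisResult:
    """Build the default design, run it, and summarize elementary effects."""
    design = metabolite_gsa_design(n_trajectories=n_trajectories, seed=seed)
    plan = build_trajectories(design)
    return elementary_effects(plan, metabolite_endpoint_function(**endpoint_kwargs))
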