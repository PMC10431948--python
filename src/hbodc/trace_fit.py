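"""Global least-squares fitting of kinetic models to oxygraph traces.

A single parameter set is estimated by minimising the sum of squared
residuals between an observed O2 trace and the simulated trace over the
deoxygenation and reoxygenation phases jointly.  Rate constants are
optimised on a log scale (positivity, scale-spanning) with a bounded
trust-region solver and a small seeded multi-start around the initial
values to guard against local minima.

The special label ``"hb_total"`` refines the total heme concentration
(µM) of the protocol alongside the rate constants.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .kinetic_schemes import ConfigurationError, KineticScheme
from .protocol_sim import Protocol, SimulationError, Trace, simulate

__all__ = ["FitSpec", "FitResult", "fit_trace", "calibrate_background", "goodness"]

logger = logging.getLogger(__name__)

HB_TOTAL = "hb_total"
_PENALTY = 1.0e3  # µM residual assigned to failed trial simulations


@dataclass
class FitSpec:
    """What to refine and how.

    ``free``: label -> initial value; ``bounds``: label -> (lo, hi),
    defaulting to a wide positive box around the initial value;
    ``fixed``: label -> value overrides applied before fitting;
    ``phase``: "both", "deox" or "reox" restricts which samples enter
    the residual.
    """

    free: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    phase: str = "both"
    n_starts: int = 5
    seed: int = 0
    start_spread: float = 0.35  # sd of ln-scale perturbations for extra starts
    sim_rtol: float = 1e-8
    sim_atol: float = 1e-10

    def __post_init__(self) -> None:
        if not self.free:
            raise ConfigurationError("at least one free parameter is required")
        if self.phase not in ("both", "deox", "reox"):
            raise ConfigurationError(f"unknown phase mask {self.phase!r}")
        for label, init in self.free.items():
            lo, hi = self.bounds.get(label, (init / 1e4, init * 1e4))
            if not (lo <= init <= hi) or lo <= 0:
                raise ConfigurationError(
                    f"bounds ({lo:g}, {hi:g}) must be positive and contain the "
                    f"initial value {init:g} for {label!r}"
                )
            self.bounds[label] = (lo, hi)


@dataclass
class FitResult:
    """Fitted values with goodness-of-fit and convergence diagnostics."""

    values: dict[str, float]
    sse: float
    r_squared: float
    residuals: np.ndarray
    success: bool
    message: str
    n_starts: int
    nfev: int
    hb_total: float | None = None

    def __post_init__(self) -> None:
        if self.sse < 0 or self.r_squared > 1 + 1e-12:
            raise ValueError("inconsistent goodness-of-fit values")


def goodness(observed: Trace, predicted: Trace) -> tuple[float, float]:
    """Sum of squared errors (µM²) and R² of predicted against observed."""
    if observed.times.shape != predicted.times.shape or not np.allclose(
        observed.times, predicted.times
    ):
        raise ConfigurationError("observed and predicted traces are on different grids")
    resid = observed.o2 - predicted.o2
    sse = float(np.sum(resid**2))
    sst = float(np.sum((observed.o2 - observed.o2.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    return sse, r2


def _simulated_o2(
    scheme: KineticScheme,
    protocol: Protocol,
    updates: Mapping[str, float],
    hb_total: float | None,
    rtol: float,
    atol: float,
) -> np.ndarray:
    sch = scheme.with_params(dict(updates)) if updates else scheme
    proto = protocol if hb_total is None else replace(protocol, hb_heme_total=hb_total)
    traj = simulate(sch, proto, rtol=rtol, atol=atol)
    return traj.conc("O")


def fit_trace(
    scheme: KineticScheme,
    protocol: Protocol,
    observed: Trace,
    spec: FitSpec,
) -> FitResult:
    """Global fit of the free parameters to one observed trace.

    The simulation grid is the observed time grid; deox and reox phases
    are fitted jointly unless masked.  Deterministic for fixed inputs,
    initial values and seed.
    """
    if observed.times[0] < protocol.t_grid[0] - 1e-9 or observed.times[-1] > protocol.t_grid[-1] + 1e-9:
        raise ConfigurationError("observed trace extends outside the protocol span")
    proto = replace(protocol, t_grid=observed.times)
    if spec.fixed:
        rate_fixed = {k: v for k, v in spec.fixed.items() if k != HB_TOTAL}
        scheme = scheme.with_params(rate_fixed) if rate_fixed else scheme
        if HB_TOTAL in spec.fixed:
            proto = replace(proto, hb_heme_total=spec.fixed[HB_TOTAL])
    labels = list(spec.free)
    if spec.phase == "both":
        mask = np.ones(len(observed.times), dtype=bool)
    else:
        mask = proto.phase_of(observed.times) == spec.phase
    obs = observed.o2

    def split(theta: np.ndarray) -> tuple[dict[str, float], float | None]:
        vals = dict(zip(labels, np.exp(theta)))
        hb = vals.pop(HB_TOTAL, None)
        return vals, hb

    n_fail = 0

    def residual(theta: np.ndarray) -> np.ndarray:
        nonlocal n_fail
        vals, hb = split(theta)
        try:
            sim = _simulated_o2(scheme, proto, vals, hb, spec.sim_rtol, spec.sim_atol)
        except (SimulationError, ConfigurationError) as exc:
            n_fail += 1
            logger.warning("trial simulation failed (%s); penalised", exc)
            return np.full(int(mask.sum()), _PENALTY)
        return (sim - obs)[mask]

    x0 = np.log([spec.free[lb] for lb in labels])
    lo = np.log([spec.bounds[lb][0] for lb in labels])
    hi = np.log([spec.bounds[lb][1] for lb in labels])
    rng = np.random.default_rng(spec.seed)
    best = None
    nfev = 0
    for k in range(max(1, spec.n_starts)):
        start = x0 if k == 0 else np.clip(
            x0 + rng.normal(0.0, spec.start_spread, size=len(x0)), lo, hi
        )
        # diff_step well above the ODE-solver noise floor so numerical
        # derivatives of the residual are meaningful
        sol = least_squares(
            residual, start, bounds=(lo, hi), method="trf",
            diff_step=1e-3, ftol=1e-12, xtol=1e-10, gtol=1e-10,
        )
        nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol
    vals, hb = split(best.x)
    sim = _simulated_o2(scheme, proto, vals, hb, spec.sim_rtol, spec.sim_atol)
    pred = Trace(observed.times, sim)
    resid = (sim - obs)[mask]
    sse = float(np.sum(resid**2))
    _, r2 = goodness(Trace(observed.times[mask], obs[mask]),
                     Trace(observed.times[mask], sim[mask]))
    out_vals = dict(zip(labels, np.exp(best.x)))
    converged = bool(best.status > 0)
    if not converged:
        logger.warning("fit did not converge: %s", best.message)
    return FitResult(
        values=out_vals,
        sse=sse,
        r_squared=r2,
        residuals=obs[mask] - sim[mask],
        success=converged,
        message=f"{best.message} ({n_fail} penalised trials)",
        n_starts=max(1, spec.n_starts),
        nfev=nfev,
        hb_total=out_vals.get(HB_TOTAL),
    )


def calibrate_background(
    scheme_no_hb: KineticScheme,
    protocol: Protocol,
    observed: Trace,
    *,
    slope_window: tuple[float, float] = (0.15, 0.85),
) -> tuple[float, float]:
    """Estimate (kcat, k_air) from an Hb-free trace.

    kcat comes from the linear closed-phase decline
    (slope = -kcat * [E]_total; samples with O2 inside ``slope_window``
    as a fraction of the initial O2 are used), k_air from fitting the
    open-phase exponential relaxation toward air saturation.  The two
    estimates are meant to be fixed in subsequent Hb-containing fits.
    """
    if protocol.oxidase_total <= 0:
        raise ConfigurationError("protocol has no oxidase; kcat is undefined")
    t, o2 = observed.times, observed.o2
    closed = (t >= protocol.t_respiration_on) & (t < protocol.t_open)
    frac = o2 / protocol.o2_initial
    lin = closed & (frac > slope_window[0]) & (frac < slope_window[1])
    if lin.sum() < 5:
        raise ConfigurationError(
            "no linear closed-phase segment detected; check that the trace and "
            "protocol event times match"
        )
    fit = linregress(t[lin], o2[lin])
    if fit.slope >= 0:
        raise ConfigurationError("closed-phase O2 is not declining; protocol mismatch?")
    kcat = -fit.slope / protocol.oxidase_total

    open_ = t >= protocol.t_open
    if open_.sum() < 5:
        raise ConfigurationError("too few open-phase samples to estimate k_air")
    t_open = t[open_] - protocol.t_open
    gap = protocol.o2_air - o2[open_]
    gap0 = protocol.o2_air - o2[open_][0]
    # log-linear initial guess on the positive part of the gap
    pos = gap > max(1e-3, 1e-3 * abs(gap0))
    if pos.sum() >= 2:
        k0 = max(1e-5, -linregress(t_open[pos], np.log(gap[pos])).slope)
    else:
        k0 = 1.0 / max(t_open[-1], 1.0)

    def resid(theta):
        k = np.exp(theta[0])
        return gap0 * np.exp(-k * t_open) - gap

    sol = least_squares(resid, [np.log(k0)])
    k_air = float(np.exp(sol.x[0]))
    return float(kcat), k_air
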