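"""Timed deoxygenation/reoxygenation protocol integration.

A respirometry run has three phases:

1. closed cell, quiescent (electrode equilibrated with air-saturated
   buffer) until succinate is added at ``t_respiration_on``;
2. closed cell, respiring — the oxidase sink pulls cell O2 linearly
   toward anaerobiosis, with hemoglobin releasing bound O2 as the free
   concentration falls;
3. at ``t_open`` the respiratory chain is inhibited (antimycin) and the
   stopper removed, so O2 exchanges with air and relaxes back toward
   air saturation while hemoglobin reloads.

The scheme is integrated piecewise with a stiff solver, restarting
exactly at each phase boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetic_schemes import CompiledScheme, ConfigurationError, KineticScheme

__all__ = [
    "Protocol",
    "SpeciesTrajectory",
    "Trace",
    "SimulationError",
    "simulate",
    "o2_trace",
    "species_peak_order",
]


class SimulationError(RuntimeError):
    """Integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class Protocol:
    """Timed experimental phases and cell composition.

    Times in seconds, concentrations in µM.  ``hb_heme_total`` counts
    heme centres (tetramer concentration is a quarter of it).
    """

    t_grid: np.ndarray
    t_respiration_on: float = 50.0
    t_open: float = 1000.0
    o2_initial: float = 183.0
    o2_air: float = 183.0
    hb_heme_total: float = 50.0
    oxidase_total: float = 0.05

    def __post_init__(self) -> None:
        grid = np.asarray(self.t_grid, dtype=float)
        object.__setattr__(self, "t_grid", grid)
        if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
            raise ConfigurationError("t_grid must be strictly increasing, length >= 2")
        if not (grid[0] <= self.t_respiration_on < self.t_open <= grid[-1]):
            raise ConfigurationError(
                "need t_grid[0] <= t_respiration_on < t_open <= t_grid[-1]"
            )
        for name in ("o2_initial", "o2_air", "hb_heme_total", "oxidase_total"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @classmethod
    def default(cls, t_end: float = 1400.0, dt: float = 1.0, **kw) -> "Protocol":
        """1 Hz sampling over 0..t_end with the nominal event times."""
        return cls(t_grid=np.arange(0.0, t_end + dt / 2, dt), **kw)

    def shifted(self, dt: float) -> "Protocol":
        return replace(
            self,
            t_grid=self.t_grid + dt,
            t_respiration_on=self.t_respiration_on + dt,
            t_open=self.t_open + dt,
        )

    @property
    def phase_bounds(self) -> list[tuple[float, float, tuple[str, ...]]]:
        t0, t1 = float(self.t_grid[0]), float(self.t_grid[-1])
        segs = []
        if self.t_respiration_on > t0:
            segs.append((t0, self.t_respiration_on, ("always",)))
        segs.append((self.t_respiration_on, self.t_open, ("always", "respiration")))
        segs.append((self.t_open, t1, ("always", "air_exchange")))
        return segs

    def phase_of(self, times: np.ndarray) -> np.ndarray:
        """Label samples 'deox' (closed phases) or 'reox' (open phase)."""
        return np.where(np.asarray(times) < self.t_open, "deox", "reox")


@dataclass
class SpeciesTrajectory:
    """Per-species time series produced by :func:`simulate`."""

    times: np.ndarray
    concentrations: np.ndarray  # (n_times, n_species)
    scheme: KineticScheme
    protocol: Protocol

    def conc(self, name: str) -> np.ndarray:
        return self.concentrations[:, self.scheme.index(name)]

    def pooled_by_ligation(self) -> dict[int, np.ndarray]:
        """Tetramer concentration per ligation level, conformations pooled."""
        pools: dict[int, np.ndarray] = {}
        for sp in self.scheme.hemoglobin_species:
            pools.setdefault(sp.ligation, np.zeros(len(self.times)))
            pools[sp.ligation] = pools[sp.ligation] + self.conc(sp.name)
        return pools

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations, columns=self.scheme.species_names)
        df.insert(0, "time_s", self.times)
        return df


@dataclass
class Trace:
    """An O2 time series (observed or simulated), µM vs seconds."""

    times: np.ndarray
    o2: np.ndarray
    sigma: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.times.shape != self.o2.shape or self.times.ndim != 1:
            raise ConfigurationError("times and o2 must be 1-D and equally long")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("trace times must be strictly increasing")


def initial_state(
    scheme: KineticScheme, protocol: Protocol, o2: float | None = None
) -> np.ndarray:
    """Default initial condition: Hb equilibrated with the initial O2.

    The hemoglobin pool is distributed over its states using the
    scheme's own equilibrium at ``o2`` (the cell sits open and stirred
    until the electrode reading is stable, so Hb starts at binding
    equilibrium with air-saturated buffer); the oxidase starts free.
    """
    if o2 is None:
        o2 = protocol.o2_initial
    y0 = np.zeros(len(scheme.species))
    y0[scheme.index("O")] = o2
    if scheme.hemoglobin_species and protocol.hb_heme_total > 0:
        dist = scheme.equilibrium_distribution(o2, protocol.hb_heme_total / 4.0)
        for nm, v in dist.items():
            y0[scheme.index(nm)] = v
    names = set(scheme.species_names)
    if "E" in names:
        y0[scheme.index("E")] = protocol.oxidase_total
    for nm, v in scheme.constant_species.items():
        y0[scheme.index(nm)] = v
    return y0


def simulate(
    scheme: KineticScheme,
    protocol: Protocol,
    initial: np.ndarray | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> SpeciesTrajectory:
    """Integrate the scheme through the protocol's phases.

    Phase switches are handled by restarting the solver exactly at
    ``t_respiration_on`` and ``t_open``.  Raises
    :class:`SimulationError` on solver failure or a state that goes
    negative beyond integration tolerance.
    """
    if initial is None:
        y0 = initial_state(scheme, protocol)
    else:
        y0 = np.asarray(initial, dtype=float).copy()
        if y0.shape != (len(scheme.species),):
            raise ConfigurationError("initial state length mismatch")
        if y0.min() < -1e-9:
            raise ConfigurationError("initial concentrations must be non-negative")
    grid = protocol.t_grid
    out = np.empty((len(grid), len(y0)))
    filled = np.zeros(len(grid), dtype=bool)
    neg_floor = -1e3 * atol
    y = y0
    for t_a, t_b, phases in protocol.phase_bounds:
        compiled = CompiledScheme(scheme, phases)
        sel = (grid >= t_a) & (grid <= t_b) & ~filled
        t_eval = grid[sel]
        # always evaluate the segment end so the next phase restarts there
        t_pts = t_eval if len(t_eval) and t_eval[-1] == t_b else np.append(t_eval, t_b)
        sol = solve_ivp(
            compiled.rhs,
            (t_a, t_b),
            y,
            method=method,
            jac=compiled.jac,
            t_eval=t_pts,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(
                f"solver failed in phase {phases}: {sol.message}",
                last_time=float(sol.t[-1]) if len(sol.t) else t_a,
            )
        ys = sol.y.T
        if ys.min() < neg_floor:
            raise SimulationError(
                f"state went negative ({ys.min():.3g} µM) beyond tolerance",
                last_time=float(sol.t[int(np.argmin(ys.min(axis=1)))]),
            )
        if len(t_eval):
            out[sel] = np.clip(ys[: len(t_eval)], 0.0, None)
            filled |= sel
        y = np.clip(ys[-1], 0.0, None).copy()
    if not filled.all():  # pragma: no cover - guarded by Protocol invariants
        raise SimulationError("some grid points were not covered by any phase")
    return SpeciesTrajectory(grid.copy(), out, scheme, protocol)


def o2_trace(traj: SpeciesTrajectory) -> Trace:
    """Extract the cell-O2 time series from a trajectory."""
    if "O" not in traj.scheme.species_names:
        raise ConfigurationError("trajectory has no cell-O2 species 'O'")
    return Trace(
        traj.times.copy(),
        traj.conc("O").copy(),
        metadata={"source": "simulation", "model": traj.scheme.name},
    )


def species_peak_order(
    traj: SpeciesTrajectory, phase: str = "deox"
) -> list[tuple[int, float]]:
    """Hb ligation levels ordered by the time their pooled concentration peaks.

    ``phase`` selects the window: "deox" = [t_respiration_on, t_open],
    "reox" = [t_open, end].  Species that are flat in the window peak at
    its boundary.  Returns (ligation, peak time) pairs sorted by time;
    empty for an Hb-free trajectory.
    """
    pools = traj.pooled_by_ligation()
    # pools at integrator-round-off scale mean there is no hemoglobin
    if not pools or max(float(c.max()) for c in pools.values()) <= 1e-9:
        return []
    p = traj.protocol
    if phase == "deox":
        window = (traj.times >= p.t_respiration_on) & (traj.times <= p.t_open)
    elif phase == "reox":
        window = traj.times >= p.t_open
    else:
        raise ConfigurationError(f"unknown phase {phase!r}")
    t_win = traj.times[window]
    peaks = []
    for lig, conc in sorted(pools.items()):
        c_win = conc[window]
        peaks.append((lig, float(t_win[int(np.argmax(c_win))])))
    peaks.sort(key=lambda p: p[1])
    return peaks
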