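"""Oxygen dissociation curve analysis.

Derives non-equilibrium ODCs and Hill plots from simulated species
trajectories, fits the Adair equation to extract stepwise association
constants and P50, reads dissociation constants off trajectory
crossover points, evaluates the two-state allosteric ladder
L_n = L c^n, and computes the cooperativity-gain statistic

    cgain = rms( S(x) - x/(x + x50) )

i.e. the root-mean-square deviation of a curve from the same-P50
hyperbola of four independent identical sites.  cgain is zero exactly
for a hyperbolic curve and grows with cooperativity; it is invariant
under a uniform rescaling of the O2 axis.

Saturation here is per heme: S = sum_n n*[Hb_n] / (4 * [Hb]_total),
with conformations pooled by ligation level.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.stats import linregress

from .kinetic_schemes import ConfigurationError, MWCParams
from .protocol_sim import SpeciesTrajectory

__all__ = [
    "ALPHA_UM_PER_MMHG",
    "DEFAULT_O2_GRID",
    "ODCCurve",
    "HillPlot",
    "AdairConstants",
    "CrossoverResult",
    "CgainResult",
    "fractional_saturation",
    "fit_adair",
    "equilibrium_saturation",
    "equilibrium_odc",
    "half_saturation",
    "hill_transform",
    "hill_slope_at_half",
    "crossover_kd",
    "allosteric_ladder",
    "cooperativity_gain",
]

#: O2 solubility conversion at 37 °C: air-saturated buffer holds ~183 µM
#: O2 at a humidified-air PO2 of ~149.7 mmHg, i.e. ~1.223 µM per mmHg.
ALPHA_UM_PER_MMHG = 1.223

#: Default O2 grid (µM) for equilibrium ODCs: uniform over the
#: experimentally accessible range 0..183 µM (air saturation) at 0.5 µM.
DEFAULT_O2_GRID = np.arange(0.0, 183.0 + 0.25, 0.5)


@dataclass
class ODCCurve:
    """Fractional saturation vs O2, with per-point phase labels."""

    o2: np.ndarray
    saturation: np.ndarray
    phase: np.ndarray  # "deox" / "reox" per point
    alpha: float = ALPHA_UM_PER_MMHG

    def __post_init__(self) -> None:
        self.o2 = np.asarray(self.o2, dtype=float)
        self.saturation = np.asarray(self.saturation, dtype=float)
        self.phase = np.asarray(self.phase)
        if not (len(self.o2) == len(self.saturation) == len(self.phase)):
            raise ConfigurationError("ODC arrays must have equal length")
        if np.any(self.o2 < -1e-12):
            raise ConfigurationError("O2 concentrations must be non-negative")
        if np.any((self.saturation < -1e-9) | (self.saturation > 1 + 1e-9)):
            raise ConfigurationError("saturation must lie in [0, 1]")

    @property
    def po2_mmhg(self) -> np.ndarray:
        return self.o2 / self.alpha


@dataclass
class HillPlot:
    """log10(PO2) vs log10(S/(1-S)); only points with S strictly in (0,1)."""

    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray


@dataclass
class AdairConstants:
    """Stepwise macroscopic association constants K1..K4 (µM⁻¹)."""

    K1: float
    K2: float
    K3: float
    K4: float
    alpha: float = ALPHA_UM_PER_MMHG

    def __post_init__(self) -> None:
        if min(self.K1, self.K2, self.K3, self.K4) <= 0:
            raise ConfigurationError("Adair constants must be positive")

    @classmethod
    def equal(cls, K: float, alpha: float = ALPHA_UM_PER_MMHG) -> "AdairConstants":
        return cls(K, K, K, K, alpha=alpha)

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.K2, self.K3, self.K4])

    @property
    def betas(self) -> np.ndarray:
        """Overall association constants beta_n = K1..Kn."""
        return np.cumprod(self.as_array)

    def saturation(self, o2):
        return equilibrium_saturation(self, o2)

    @property
    def kd_hill(self) -> float:
        """Half-saturation O2 (µM) of the fitted curve."""
        return half_saturation(self.saturation)[0]

    @property
    def p50_mmhg(self) -> float:
        return self.kd_hill / self.alpha


@dataclass
class Crossing:
    pair: tuple[int, int]  # ligation levels of the two curves
    time: float
    o2: float


@dataclass
class CrossoverResult:
    """Curve-intersection dissociation constants per phase.

    ``kd`` is the mean cell O2 (µM) over the member-curve crossings of
    the group in that phase; None when no crossing occurs in the window.
    """

    group: str
    crossings: dict[str, list[Crossing]]
    kd: dict[str, float | None]


@dataclass
class CgainResult:
    cgain: float
    x50: float
    n_points: int


# ---------------------------------------------------------------------------
# Saturation curves
# ---------------------------------------------------------------------------

def fractional_saturation(traj: SpeciesTrajectory) -> ODCCurve:
    """Per-heme fractional saturation along a trajectory.

    T and R conformations are pooled by ligation level, so the MWC and
    Perutz trajectories yield the same statistic as the single-chain
    models.
    """
    pools = traj.pooled_by_ligation()
    if not pools:
        raise ConfigurationError("trajectory contains no hemoglobin states")
    total = sum(pools.values())
    if np.any(total <= 0):
        raise ConfigurationError("total hemoglobin is zero")
    bound = sum(n * c for n, c in pools.items())
    sat = bound / (4.0 * total)
    return ODCCurve(
        o2=traj.conc("O").copy(),
        saturation=np.clip(sat, 0.0, 1.0),
        phase=traj.protocol.phase_of(traj.times),
    )


def equilibrium_saturation(constants, o2):
    """Closed-form equilibrium saturation.

    For :class:`AdairConstants` this evaluates the Adair equation; for
    :class:`MWCParams` the two-state sequential-chain binding polynomial
    (two geometric ladders weighted by the allosteric constant L), which
    reduces to the single-chain (minimalist) form when c = 1 and to the
    pure R chain as L -> 0.
    """
    x = np.asarray(o2, dtype=float)
    if np.any(x < 0):
        raise ConfigurationError("O2 must be non-negative")
    n = np.arange(5)
    if isinstance(constants, AdairConstants):
        coeff = np.concatenate(([1.0], constants.betas))  # beta_0..beta_4
        terms = coeff * x[..., None] ** n
    elif isinstance(constants, MWCParams):
        qT = (constants.KT * x[..., None]) ** n
        qR = (constants.KR * x[..., None]) ** n
        terms = constants.L * qT + qR
    else:
        raise TypeError(f"unsupported constants type {type(constants).__name__}")
    num = (n * terms).sum(axis=-1)
    den = 4.0 * terms.sum(axis=-1)
    out = num / den
    return out if np.ndim(o2) else float(out)


def equilibrium_odc(
    constants, o2_grid: np.ndarray | None = None, alpha: float = ALPHA_UM_PER_MMHG
) -> ODCCurve:
    """Evaluate an equilibrium saturation curve on a grid as an ODCCurve.

    ``constants`` may be AdairConstants, MWCParams, or a KineticScheme
    (whose own equilibrium binding polynomial is then used).
    """
    grid = DEFAULT_O2_GRID if o2_grid is None else np.asarray(o2_grid, dtype=float)
    if hasattr(constants, "equilibrium_saturation"):
        sat = np.asarray(constants.equilibrium_saturation(grid))
    else:
        sat = equilibrium_saturation(constants, grid)
    return ODCCurve(grid, sat, np.full(len(grid), "deox"), alpha=alpha)


def half_saturation(
    evaluator: Callable[[float], float], alpha: float = ALPHA_UM_PER_MMHG
) -> tuple[float, float]:
    """O2 (µM) and PO2 (mmHg) at S = 0.5 for a monotone saturation curve.

    Bracketing root-find on [0, 1e4] µM to 1e-6 µM.
    """
    f = lambda x: evaluator(x) - 0.5
    lo, hi = 1e-12, 1e4
    if f(hi) < 0 or f(lo) > 0:
        raise ConfigurationError("saturation does not bracket 0.5 on [0, 1e4] µM")
    x50 = brentq(f, lo, hi, xtol=1e-6)
    return float(x50), float(x50) / alpha


def fit_adair(
    odc: ODCCurve,
    *,
    n_starts: int = 3,
    seed: int = 0,
) -> AdairConstants:
    """Nonlinear least-squares fit of the Adair equation to an ODC.

    Constants are optimised on a log scale with a small seeded
    multi-start.  Requires at least 8 points spanning saturation from
    below 0.2 to above 0.8.
    """
    s = odc.saturation
    x = odc.o2
    if len(s) < 8 or s.min() >= 0.2 or s.max() <= 0.8:
        raise ConfigurationError(
            "Adair fit needs >= 8 points spanning S < 0.2 to S > 0.8"
        )
    # initial guess: equal constants at the empirical half-saturation
    order = np.argsort(x)
    k0 = 1.0 / max(float(np.interp(0.5, s[order], x[order])), 1e-6)

    def resid(theta):
        K = np.exp(theta)
        consts = AdairConstants(*K, alpha=odc.alpha)
        return equilibrium_saturation(consts, x) - s

    rng = np.random.default_rng(seed)
    x0 = np.log(np.full(4, k0))
    best = None
    for k in range(max(1, n_starts)):
        start = x0 if k == 0 else x0 + rng.normal(0, 0.5, 4)
        sol = least_squares(resid, start, method="lm", xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    if not best.success:
        raise ConfigurationError(f"Adair fit did not converge: {best.message}")
    K = np.exp(best.x)
    return AdairConstants(*K, alpha=odc.alpha)


# ---------------------------------------------------------------------------
# Hill analysis
# ---------------------------------------------------------------------------

def hill_transform(odc: ODCCurve) -> HillPlot:
    """log-odds transform of an ODC: x = log10 PO2, y = log10(S/(1-S))."""
    s = odc.saturation
    mask = (s > 0) & (s < 1) & (odc.o2 > 0)
    x = np.full(len(s), np.nan)
    y = np.full(len(s), np.nan)
    x[mask] = np.log10(odc.po2_mmhg[mask])
    y[mask] = np.log10(s[mask] / (1.0 - s[mask]))
    return HillPlot(x=x, y=y, mask=mask)


def hill_slope_at_half(hill: HillPlot, window: float = 0.2) -> float:
    """Hill coefficient: regression slope over |S - 0.5| <= window."""
    s = 10.0**hill.y / (1.0 + 10.0**hill.y)
    sel = hill.mask & (np.abs(s - 0.5) <= window)
    if sel.sum() < 4:
        raise ConfigurationError("fewer than 4 Hill-plot points near half saturation")
    return float(linregress(hill.x[sel], hill.y[sel]).slope)


# ---------------------------------------------------------------------------
# Crossover dissociation constants
# ---------------------------------------------------------------------------

def _group_members(traj: SpeciesTrajectory, grouping) -> list[tuple[int, np.ndarray]]:
    """(ligation, concentration curve) members of the requested group."""
    scheme = traj.scheme
    if isinstance(grouping, (list, tuple)):
        return sorted(
            ((scheme.species[scheme.index(nm)].ligation, traj.conc(nm)) for nm in grouping),
            key=lambda p: p[0],
        )
    if grouping == "all":
        return sorted(traj.pooled_by_ligation().items())
    if grouping in ("T", "R"):
        wanted = {grouping, "TR"}
        members = [
            (sp.ligation, traj.conc(sp.name))
            for sp in scheme.hemoglobin_species
            if sp.conformation in wanted
        ]
        if not members:
            raise ConfigurationError(f"scheme has no {grouping}-conformation states")
        return sorted(members, key=lambda p: p[0])
    raise ConfigurationError(f"unknown grouping {grouping!r}")


def crossover_kd(
    traj: SpeciesTrajectory, grouping="all", *, rel_threshold: float = 1e-6
) -> CrossoverResult:
    """Dissociation constants from trajectory curve intersections.

    For each phase, finds (by linear interpolation between samples) the
    times at which adjacent-ligation member curves of the group are
    equal, and reads off the cell O2 there.  At binding equilibrium the
    curves [Hb_n] and [Hb_{n+1}] of an equal-affinity family all cross
    at O2 = 1/K, so the mean crossover O2 estimates the family KD; no
    crossing in a window is reported as absent.

    Crossings whose concentration is below ``rel_threshold`` times the
    group's peak concentration in the window are integrator round-off
    in the anaerobic tail (all member pools effectively zero) and are
    discarded.
    """
    members = _group_members(traj, grouping)
    o2 = traj.conc("O")
    t = traj.times
    p = traj.protocol
    windows = {
        "deox": (t >= p.t_respiration_on) & (t <= p.t_open),
        "reox": t >= p.t_open,
    }
    crossings: dict[str, list[Crossing]] = {}
    kd: dict[str, float | None] = {}
    for phase, win in windows.items():
        found: list[Crossing] = []
        idx = np.where(win)[0]
        floor = rel_threshold * max(
            (float(c[idx].max()) for _, c in members), default=0.0
        )
        for (lig_a, ca), (lig_b, cb) in zip(members, members[1:]):
            d = (ca - cb)[idx]
            m = len(d)
            # strict sign changes, interpolated ...
            hits = [(j, float(d[j] / (d[j] - d[j + 1])))
                    for j in np.where(d[:-1] * d[1:] < 0)[0]]
            # ... plus isolated exact zeros at sample points
            for j in np.where(d == 0)[0]:
                if (j > 0 and d[j - 1] != 0) or (j + 1 < m and d[j + 1] != 0):
                    hits.append((min(j, m - 2), 0.0 if j + 1 < m else 1.0))
            for j, frac in hits:
                i0, i1 = idx[j], idx[j + 1]
                c_star = ca[i0] + frac * (ca[i1] - ca[i0])
                if c_star < floor:
                    continue
                t_star = t[i0] + frac * (t[i1] - t[i0])
                o2_star = o2[i0] + frac * (o2[i1] - o2[i0])
                found.append(Crossing((lig_a, lig_b), float(t_star), float(o2_star)))
        crossings[phase] = found
        kd[phase] = float(np.mean([c.o2 for c in found])) if found else None
    return CrossoverResult(group=str(grouping), crossings=crossings, kd=kd)


# ---------------------------------------------------------------------------
# Allosteric ladder and cooperativity gain
# ---------------------------------------------------------------------------

def allosteric_ladder(L: float, c: float, n: int) -> float:
    """Allosteric constant at ligation level n: L_n = L * c**n."""
    if L <= 0 or c <= 0:
        raise ConfigurationError("L and c must be positive")
    if not 0 <= int(n) <= 4 or n != int(n):
        raise ConfigurationError("ligation level n must be an integer in 0..4")
    return L * c ** int(n)


def cooperativity_gain(odc: ODCCurve, x50: float | None = None) -> CgainResult:
    """RMS deviation of an ODC from the same-P50 independent-sites hyperbola.

    ``x50`` (µM) may be supplied when known exactly (e.g. for a
    closed-form equilibrium curve); otherwise it is taken from the
    half-saturation of an Adair-equation fit to all points, which also
    handles hysteretic (two-phase) point clouds.  The rms runs over the
    ODC's own sample points.
    """
    s = odc.saturation
    if s.min() >= 0.1 or s.max() <= 0.9:
        raise ConfigurationError("ODC must span S < 0.1 to S > 0.9 for cgain")
    if x50 is None:
        x50 = fit_adair(odc).kd_hill
    if x50 <= 0:
        raise ConfigurationError("half-saturation must be positive")
    s_ref = odc.o2 / (odc.o2 + x50)
    cg = float(np.sqrt(np.mean((s - s_ref) ** 2)))
    return CgainResult(cgain=cg, x50=float(x50), n_points=len(s))
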