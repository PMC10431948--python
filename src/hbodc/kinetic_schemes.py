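"""Mass-action reaction networks for hemoglobin oxygenation kinetics.

This module declares the species and elementary (at most bimolecular)
reversible reactions of several kinetic models of tetrameric hemoglobin
(Hb) binding O2:

* ``minimalist`` — four sequential binding steps sharing a single O2
  affinity; no conformational states.
* ``adair`` — four sequential steps, each with its own dissociation rate
  (macroscopic stepwise constants K1..K4).
* ``perutz`` — two-state *sequential* model: T affinity for ligation
  steps 1-2, R affinity for steps 3-4.  The doubly liganded species
  ``TR_O2`` represents the fast T->R conformational switch; because the
  switch is much faster than binding turnover it is modelled as a single
  merged species, which makes the stepwise constants collapse exactly to
  K1=K2=k_on/k_off_T and K3=K4=k_on/k_off_R.
* ``mwc`` — two-state *concerted* model: two parallel sequential chains
  (T0..T4 and R0..R4), each with a single affinity, interconverting at
  every ligation level n with equilibrium [T_n]/[R_n] = L_n = L c^n and
  c = KT/KR.  This is the "two minimalist tetramers in equilibrium"
  picture.
* ``independent_sites`` — reference model of four independent identical
  sites, expressed as a macrostate chain with statistical factors
  (forward 4,3,2,1 x k_on; reverse 1,2,3,4 x k_off); its equilibrium
  curve is exactly hyperbolic.

On top of any Hb scheme, :func:`add_cell_ensemble` appends the open-cell
respirometry machinery: a cytochrome-c-oxidase O2 sink
(E + O <-> EO -> E + W) and first-order exchange of cell O2 with air
(O <-> AIR, AIR an infinite reservoir).

Units: concentrations in µM, unimolecular rate constants in 1/s,
bimolecular rate constants in 1/(µM s).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "Species",
    "Reaction",
    "RateParams",
    "MWCParams",
    "KineticScheme",
    "build_minimalist",
    "build_adair",
    "build_perutz",
    "build_mwc",
    "build_independent_sites",
    "add_cell_ensemble",
    "mass_action_rhs",
    "DEFAULT_K_ON",
    "DEFAULT_K_TR",
]

#: Default association ("on") rate constant for O2 binding, µM⁻¹ s⁻¹.
#: A diffusion-limited order of magnitude; only dissociation rates (and,
#: for MWC, the allosteric constant L) are normally refined.
DEFAULT_K_ON = 100.0

#: Default conformational interconversion rate, s⁻¹ (fast relative to
#: binding turnover; only its equilibrium position matters).
DEFAULT_K_TR = 1.0e3

#: Default oxidase O2-binding rates, chosen so the apparent Michaelis
#: constant KM = (k_off_E + k_cat)/k_on_E is sub-micromolar.
DEFAULT_K_ON_E = 1.0e3
DEFAULT_K_OFF_E = 100.0

_ROLES = frozenset(
    {"hemoglobin_state", "enzyme_state", "ligand", "sink", "reservoir"}
)
_PHASES = ("always", "respiration", "air_exchange")


class ConfigurationError(ValueError):
    """A scheme or parameter set is internally inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Species:
    """A chemical species of the cell ensemble.

    ``ligation`` is the number of bound O2 (hemoglobin states only);
    ``conformation`` is "T", "R" or "TR" for two-state models.
    """

    name: str
    role: str
    ligation: int | None = None
    conformation: str | None = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ConfigurationError(f"unknown species role {self.role!r}")
        if self.role == "hemoglobin_state":
            if self.ligation is None or not 0 <= int(self.ligation) <= 4:
                raise ConfigurationError(
                    f"hemoglobin state {self.name!r} needs ligation 0-4"
                )


@dataclass(frozen=True)
class Reaction:
    """One elementary reversible reaction.

    ``reactants``/``products`` are tuples of (species name, stoichiometry);
    at most bimolecular on each side.  ``kf_scale``/``kr_scale`` carry
    statistical factors (independent-sites model).  ``phase`` gates the
    reaction: "always", "respiration" (active while the respiratory chain
    runs) or "air_exchange" (active while the cell is open to air).
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    kf_name: str
    kr_name: str | None = None
    kf_scale: float = 1.0
    kr_scale: float = 1.0
    phase: str = "always"

    def __post_init__(self) -> None:
        if self.phase not in _PHASES:
            raise ConfigurationError(f"unknown reaction phase {self.phase!r}")
        for side in (self.reactants, self.products):
            if any(s < 1 or s != int(s) for _, s in side):
                raise ConfigurationError("stoichiometries must be positive integers")
            if sum(s for _, s in side) > 2:
                raise ConfigurationError(
                    "elementary reactions are at most bimolecular per side"
                )

    @property
    def reversible(self) -> bool:
        return self.kr_name is not None


class RateParams:
    """Named rate constants with free/fixed flags and bounds.

    Behaves as a read-only mapping label -> value.  Labels marked *free*
    are the ones a fit is allowed to refine.
    """

    def __init__(
        self,
        values: Mapping[str, float],
        free: Iterable[str] = (),
        bounds: Mapping[str, tuple[float, float]] | None = None,
    ) -> None:
        self.values: dict[str, float] = {k: float(v) for k, v in values.items()}
        for label, v in self.values.items():
            if v < 0:
                raise ConfigurationError(f"rate constant {label!r} is negative")
        self.free = set(free)
        missing = self.free - set(self.values)
        if missing:
            raise ConfigurationError(f"free labels without values: {sorted(missing)}")
        self.bounds: dict[str, tuple[float, float]] = dict(bounds or {})

    def __getitem__(self, label: str) -> float:
        try:
            return self.values[label]
        except KeyError:
            raise ConfigurationError(f"missing rate constant {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.values

    def updated(self, updates: Mapping[str, float]) -> "RateParams":
        """Copy with some values replaced (labels must already exist)."""
        unknown = set(updates) - set(self.values)
        if unknown:
            raise ConfigurationError(f"unknown rate labels: {sorted(unknown)}")
        vals = dict(self.values)
        vals.update({k: float(v) for k, v in updates.items()})
        return RateParams(vals, free=self.free, bounds=self.bounds)

    def to_dict(self) -> dict:
        return {
            "values": dict(self.values),
            "free": sorted(self.free),
            "bounds": {k: list(v) for k, v in self.bounds.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RateParams":
        return cls(
            d["values"],
            free=d.get("free", ()),
            bounds={k: tuple(v) for k, v in d.get("bounds", {}).items()},
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RateParams) and self.to_dict() == other.to_dict()

    def __repr__(self) -> str:  # pragma: no cover
        return f"RateParams({self.values!r}, free={sorted(self.free)!r})"


@dataclass(frozen=True)
class MWCParams:
    """Two-state concerted-model parameters.

    L = [T0]/[R0] (allosteric constant), KT and KR the per-step
    association constants (µM⁻¹) of the T and R chains, c = KT/KR.
    """

    L: float
    KT: float
    KR: float
    c: float | None = None

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ConfigurationError("allosteric constant L must be > 0")
        if self.KT <= 0 or self.KR <= 0:
            raise ConfigurationError("KT and KR must be > 0")
        if self.c is None:
            object.__setattr__(self, "c", self.KT / self.KR)
        elif not math.isclose(self.c, self.KT / self.KR, rel_tol=5e-3):
            raise ConfigurationError(
                f"c={self.c} inconsistent with KT/KR={self.KT / self.KR:.6g}"
            )


# Declarative derived-rate formulas, keyed by kind, so schemes stay
# serializable.  MWC interconversion reverse rates enforce the ladder
# L_n = L c^n with c = k_off_R/k_off_T (== KT/KR).
def _derived_value(spec: Mapping, params: RateParams) -> float:
    kind = spec["kind"]
    if kind == "mwc_interconversion_reverse":
        n = int(spec["level"])
        c = params["k_off_R"] / params["k_off_T"]
        L_n = params["L"] * c**n
        return params["k_TR"] / L_n
    raise ConfigurationError(f"unknown derived-rate kind {kind!r}")


@dataclass
class KineticScheme:
    """Species + reactions + rate parameters for one model variant."""

    name: str
    species: list[Species]
    reactions: list[Reaction]
    params: RateParams
    derived: dict[str, dict] = field(default_factory=dict)
    constant_species: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigurationError("species names must be unique")
        known = set(names)
        for rx in self.reactions:
            for nm, _ in rx.reactants + rx.products:
                if nm not in known:
                    raise ConfigurationError(f"reaction references unknown species {nm!r}")
            self.rate_value(rx.kf_name)  # raises if unresolvable
            if rx.kr_name is not None:
                self.rate_value(rx.kr_name)

    # -- lookups ------------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise ConfigurationError(f"no species named {name!r}") from None

    def rate_value(self, label: str) -> float:
        if label in self.derived:
            return _derived_value(self.derived[label], self.params)
        return self.params[label]

    @property
    def hemoglobin_species(self) -> list[Species]:
        return [s for s in self.species if s.role == "hemoglobin_state"]

    def conservation_groups(self) -> dict[str, list[str]]:
        """Species pools whose summed concentration is constant in a closed cell."""
        groups: dict[str, list[str]] = {}
        hb = [s.name for s in self.hemoglobin_species]
        if hb:
            groups["tetramer"] = hb
        enz = [s.name for s in self.species if s.role == "enzyme_state"]
        if enz:
            groups["enzyme"] = enz
        return groups

    def with_params(self, updates: Mapping[str, float]) -> "KineticScheme":
        return replace(self, params=self.params.updated(updates))

    # -- equilibrium --------------------------------------------------
    def equilibrium_weights(self, o2: float) -> dict[str, float]:
        """Relative equilibrium populations of the Hb states at fixed free O2.

        Propagates detailed balance along the reversible binding /
        interconversion reactions (a spanning walk of the state graph;
        the MWC ladder's cycles are consistent by construction).
        """
        hb = {s.name for s in self.hemoglobin_species}
        ligand = {s.name for s in self.species if s.role == "ligand"}
        if not hb:
            return {}
        # adjacency: (u, v, multiplier)
        edges: list[tuple[str, str, float]] = []
        for rx in self.reactions:
            if not rx.reversible or rx.phase != "always":
                continue
            r_hb = [nm for nm, _ in rx.reactants if nm in hb]
            p_hb = [nm for nm, _ in rx.products if nm in hb]
            if len(r_hb) != 1 or len(p_hb) != 1:
                continue
            n_o2 = sum(s for nm, s in rx.reactants if nm in ligand) - sum(
                s for nm, s in rx.products if nm in ligand
            )
            keq = (rx.kf_scale * self.rate_value(rx.kf_name)) / (
                rx.kr_scale * self.rate_value(rx.kr_name)
            )
            mult = keq * o2**n_o2
            edges.append((r_hb[0], p_hb[0], mult))
        weights: dict[str, float] = {}
        start = self.hemoglobin_species[0].name
        weights[start] = 1.0
        frontier = [start]
        while frontier:
            u = frontier.pop()
            for a, b, mult in edges:
                if a == u and b not in weights:
                    weights[b] = weights[u] * mult
                    frontier.append(b)
                elif b == u and a not in weights and mult > 0:
                    weights[a] = weights[u] / mult
                    frontier.append(a)
        if set(weights) != hb:
            raise ConfigurationError(
                "hemoglobin states do not form a connected ladder"
            )
        return weights

    def equilibrium_distribution(self, o2: float, tetramer_total: float) -> dict[str, float]:
        """Equilibrium concentrations (µM tetramer) of the Hb states at fixed O2."""
        w = self.equilibrium_weights(o2)
        total = sum(w.values())
        return {k: tetramer_total * v / total for k, v in w.items()}

    def equilibrium_saturation(self, o2: float | np.ndarray) -> float | np.ndarray:
        """Closed-form equilibrium fractional saturation from the scheme's own constants."""
        o2_arr = np.atleast_1d(np.asarray(o2, dtype=float))
        out = np.empty_like(o2_arr)
        lig = {s.name: s.ligation for s in self.hemoglobin_species}
        for i, x in enumerate(o2_arr):
            w = self.equilibrium_weights(float(x))
            num = sum(lig[k] * v for k, v in w.items())
            out[i] = num / (4.0 * sum(w.values()))
        return out if np.ndim(o2) else float(out[0])

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": [
                {
                    "name": s.name,
                    "role": s.role,
                    "ligation": s.ligation,
                    "conformation": s.conformation,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "reactants": [list(p) for p in rx.reactants],
                    "products": [list(p) for p in rx.products],
                    "kf_name": rx.kf_name,
                    "kr_name": rx.kr_name,
                    "kf_scale": rx.kf_scale,
                    "kr_scale": rx.kr_scale,
                    "phase": rx.phase,
                }
                for rx in self.reactions
            ],
            "params": self.params.to_dict(),
            "derived": {k: dict(v) for k, v in self.derived.items()},
            "constant_species": dict(self.constant_species),
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticScheme":
        return cls(
            name=d["name"],
            species=[Species(**s) for s in d["species"]],
            reactions=[
                Reaction(
                    reactants=tuple((nm, int(s)) for nm, s in rx["reactants"]),
                    products=tuple((nm, int(s)) for nm, s in rx["products"]),
                    kf_name=rx["kf_name"],
                    kr_name=rx["kr_name"],
                    kf_scale=rx.get("kf_scale", 1.0),
                    kr_scale=rx.get("kr_scale", 1.0),
                    phase=rx.get("phase", "always"),
                )
                for rx in d["reactions"]
            ],
            params=RateParams.from_dict(d["params"]),
            derived={k: dict(v) for k, v in d.get("derived", {}).items()},
            constant_species=dict(d.get("constant_species", {})),
            metadata=dict(d.get("metadata", {})),
        )


# ---------------------------------------------------------------------------
# Scheme builders
# ---------------------------------------------------------------------------

_O = Species("O", "ligand")


def _require(params: RateParams, labels: Sequence[str]) -> None:
    missing = [lb for lb in labels if lb not in params]
    if missing:
        raise ConfigurationError(f"missing rate constant labels: {missing}")


def _hb_chain(names: Sequence[str], conformations: Sequence[str | None]) -> list[Species]:
    return [
        Species(nm, "hemoglobin_state", ligation=n, conformation=cf)
        for n, (nm, cf) in enumerate(zip(names, conformations))
    ]


def build_minimalist(params: RateParams) -> KineticScheme:
    """Four sequential O2-binding steps sharing one (k_on, k_off) pair."""
    _require(params, ["k_on", "k_off"])
    names = ["Hb", "HbO2_1", "HbO2_2", "HbO2_3", "HbO2_4"]
    species = _hb_chain(names, [None] * 5) + [_O]
    reactions = [
        Reaction(((names[n], 1), ("O", 1)), ((names[n + 1], 1),), "k_on", "k_off")
        for n in range(4)
    ]
    return KineticScheme("minimalist", species, reactions, params)


def build_adair(params: RateParams) -> KineticScheme:
    """Sequential chain with an independent dissociation rate per step."""
    _require(params, ["k_on", "k_off_1", "k_off_2", "k_off_3", "k_off_4"])
    names = ["Hb", "HbO2_1", "HbO2_2", "HbO2_3", "HbO2_4"]
    species = _hb_chain(names, [None] * 5) + [_O]
    reactions = [
        Reaction(
            ((names[n], 1), ("O", 1)), ((names[n + 1], 1),), "k_on", f"k_off_{n + 1}"
        )
        for n in range(4)
    ]
    return KineticScheme("adair", species, reactions, params)


def build_perutz(params: RateParams) -> KineticScheme:
    """Two-state sequential chain T0-T1-TR_O2-R3-R4.

    The doubly liganded TR_O2 species embodies the fast T->R switch at
    ligation level 2 (merged-species limit, i.e. instantaneous
    interconversion), so exactly two dissociation rates are refined and
    the stepwise constants collapse to K1=K2 and K3=K4.
    """
    _require(params, ["k_on", "k_off_T", "k_off_R"])
    names = ["T0", "T1", "TR_O2", "R3", "R4"]
    species = _hb_chain(names, ["T", "T", "TR", "R", "R"]) + [_O]
    offs = ["k_off_T", "k_off_T", "k_off_R", "k_off_R"]
    reactions = [
        Reaction(((names[n], 1), ("O", 1)), ((names[n + 1], 1),), "k_on", offs[n])
        for n in range(4)
    ]
    return KineticScheme("perutz", species, reactions, params)


def build_mwc(params: RateParams, mwc: MWCParams | None = None) -> KineticScheme:
    """Two-state concerted model: parallel T and R sequential chains.

    Interconversion R_n <-> T_n is fast (rate ``k_TR`` toward T) with the
    reverse rate set per level to k_TR / L_n, L_n = L c^n and
    c = k_off_R/k_off_T, so the allosteric ladder holds exactly with a
    single refined L.  ``L`` itself lives in ``params`` so fits can
    refine it; a consistent :class:`MWCParams` may be passed for
    validation.
    """
    _require(params, ["k_on", "k_off_T", "k_off_R", "k_TR", "L"])
    if params["L"] <= 0:
        raise ConfigurationError("allosteric constant L must be > 0")
    if mwc is not None:
        if not math.isclose(mwc.L, params["L"], rel_tol=1e-9):
            raise ConfigurationError("MWCParams.L disagrees with params['L']")
        c_rates = params["k_off_R"] / params["k_off_T"]
        if not math.isclose(mwc.c, c_rates, rel_tol=5e-3):
            raise ConfigurationError(
                f"MWCParams.c={mwc.c:.4g} inconsistent with rate constants ({c_rates:.4g})"
            )
    t_names = [f"T{n}" for n in range(5)]
    r_names = [f"R{n}" for n in range(5)]
    species = (
        _hb_chain(t_names, ["T"] * 5) + _hb_chain(r_names, ["R"] * 5) + [_O]
    )
    reactions = [
        Reaction(((t_names[n], 1), ("O", 1)), ((t_names[n + 1], 1),), "k_on", "k_off_T")
        for n in range(4)
    ] + [
        Reaction(((r_names[n], 1), ("O", 1)), ((r_names[n + 1], 1),), "k_on", "k_off_R")
        for n in range(4)
    ]
    derived = {}
    for n in range(5):
        label = f"k_TR_rev_{n}"
        derived[label] = {"kind": "mwc_interconversion_reverse", "level": n}
        reactions.append(
            Reaction(((r_names[n], 1),), ((t_names[n], 1),), "k_TR", label)
        )
    return KineticScheme("mwc", species, reactions, params, derived=derived)


def build_independent_sites(params: RateParams) -> KineticScheme:
    """Four independent identical sites as a macrostate chain.

    Statistical factors (4,3,2,1) on association and (1,2,3,4) on
    dissociation make the equilibrium curve exactly hyperbolic,
    S = x / (x + k_off/k_on).
    """
    _require(params, ["k_on", "k_off"])
    names = ["Hb", "HbO2_1", "HbO2_2", "HbO2_3", "HbO2_4"]
    species = _hb_chain(names, [None] * 5) + [_O]
    reactions = [
        Reaction(
            ((names[n], 1), ("O", 1)),
            ((names[n + 1], 1),),
            "k_on",
            "k_off",
            kf_scale=float(4 - n),
            kr_scale=float(n + 1),
        )
        for n in range(4)
    ]
    return KineticScheme("independent_sites", species, reactions, params)


def add_cell_ensemble(
    scheme: KineticScheme,
    oxidase_conc: float,
    kcat: float,
    k_air: float,
    o2_air: float,
) -> KineticScheme:
    """Append the oxidase O2 sink and the open-cell air exchange.

    Adds E + O <-> EO (fast, sub-µM apparent KM) and the practically
    irreversible water-forming turnover EO -> E + W, both gated on the
    "respiration" phase, plus a first-order O <-> AIR exchange gated on
    the "air_exchange" phase that relaxes cell O2 toward ``o2_air``
    (AIR is an infinite reservoir held constant).
    """
    present = set(scheme.species_names)
    clash = present & {"E", "EO", "AIR", "W"}
    if clash:
        raise ConfigurationError(f"ensemble species already present: {sorted(clash)}")
    if "O" not in present:
        raise ConfigurationError("scheme lacks a cell-O2 species 'O'")
    species = list(scheme.species) + [
        Species("E", "enzyme_state"),
        Species("EO", "enzyme_state"),
        Species("W", "sink"),
        Species("AIR", "reservoir"),
    ]
    values = dict(scheme.params.values)
    values.setdefault("k_on_E", DEFAULT_K_ON_E)
    values.setdefault("k_off_E", DEFAULT_K_OFF_E)
    values["k_cat"] = float(kcat)
    values["k_air"] = float(k_air)
    params = RateParams(values, free=scheme.params.free, bounds=scheme.params.bounds)
    reactions = list(scheme.reactions) + [
        Reaction((("E", 1), ("O", 1)), (("EO", 1),), "k_on_E", "k_off_E",
                 phase="respiration"),
        Reaction((("EO", 1),), (("E", 1), ("W", 1)), "k_cat", None,
                 phase="respiration"),
        Reaction((("O", 1),), (("AIR", 1),), "k_air", "k_air",
                 phase="air_exchange"),
    ]
    constant = dict(scheme.constant_species)
    constant["AIR"] = float(o2_air)
    metadata = dict(scheme.metadata)
    metadata["oxidase_total"] = float(oxidase_conc)
    metadata["o2_air"] = float(o2_air)
    return KineticScheme(
        scheme.name,
        species,
        reactions,
        params,
        derived=dict(scheme.derived),
        constant_species=constant,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Rate-law assembly
# ---------------------------------------------------------------------------

class CompiledScheme:
    """Array form of a scheme's rate laws for one set of active phases.

    Each reaction is stored as up to two reactant and two product state
    indices (a virtual extra index holds the constant 1.0 for
    unimolecular sides), so forward and reverse fluxes are plain
    elementwise products.  Rows of the stoichiometric matrix belonging
    to constant (reservoir) species are zeroed.
    """

    def __init__(self, scheme: KineticScheme, active_phases: Iterable[str] = ("always",)):
        phases = set(active_phases)
        unknown = phases - set(_PHASES)
        if unknown:
            raise ConfigurationError(f"unknown phases {sorted(unknown)}")
        self.scheme = scheme
        names = scheme.species_names
        idx = {nm: i for i, nm in enumerate(names)}
        self.n_species = len(names)
        dummy = self.n_species  # index of the constant 1.0 slot
        rxs = [rx for rx in scheme.reactions if rx.phase in phases]
        m = len(rxs)
        a = np.full((m, 2), dummy, dtype=np.intp)
        b = np.full((m, 2), dummy, dtype=np.intp)
        kf = np.zeros(m)
        kr = np.zeros(m)
        N = np.zeros((self.n_species, m))
        for j, rx in enumerate(rxs):
            flat_r = [idx[nm] for nm, s in rx.reactants for _ in range(s)]
            flat_p = [idx[nm] for nm, s in rx.products for _ in range(s)]
            a[j, : len(flat_r)] = flat_r
            b[j, : len(flat_p)] = flat_p
            kf[j] = rx.kf_scale * scheme.rate_value(rx.kf_name)
            kr[j] = (
                rx.kr_scale * scheme.rate_value(rx.kr_name) if rx.kr_name else 0.0
            )
            for nm, s in rx.reactants:
                N[idx[nm], j] -= s
            for nm, s in rx.products:
                N[idx[nm], j] += s
        for nm in scheme.constant_species:
            N[idx[nm], :] = 0.0
        self._a, self._b, self._kf, self._kr, self._N = a, b, kf, kr, N

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        ye = np.append(y, 1.0)
        v = self._kf * ye[self._a[:, 0]] * ye[self._a[:, 1]]
        v -= self._kr * ye[self._b[:, 0]] * ye[self._b[:, 1]]
        return self._N @ v

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        ye = np.append(y, 1.0)
        m = len(self._kf)
        dv = np.zeros((m, self.n_species + 1))
        rows = np.arange(m)
        np.add.at(dv, (rows, self._a[:, 0]), self._kf * ye[self._a[:, 1]])
        np.add.at(dv, (rows, self._a[:, 1]), self._kf * ye[self._a[:, 0]])
        np.add.at(dv, (rows, self._b[:, 0]), -self._kr * ye[self._b[:, 1]])
        np.add.at(dv, (rows, self._b[:, 1]), -self._kr * ye[self._b[:, 0]])
        return self._N @ dv[:, : self.n_species]


def mass_action_rhs(
    scheme: KineticScheme,
    state: np.ndarray,
    phase_flags: Iterable[str] = ("always",),
) -> np.ndarray:
    """Time derivative of the concentration vector under mass action.

    ``state`` is ordered as ``scheme.species_names``.  Reservoir species
    (AIR) get a zero derivative.  Raises if the state is meaningfully
    negative (beyond solver-round-off scale).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (len(scheme.species),):
        raise ConfigurationError(
            f"state length {state.shape} != {len(scheme.species)} species"
        )
    if np.any(state < -1e-9):
        raise ConfigurationError("negative concentrations in state")
    return CompiledScheme(scheme, phase_flags).rhs(0.0, state)
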