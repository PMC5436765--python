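"""Stoichiometric network of the rat HPA axis.

The model tracks 11 circulating species — cholesterol (CHOL), corticotrophin
releasing hormone (CRH), aldosterone (ALDO), adrenocorticotrophic hormone
(ACTH), pregnenolone (PNN), progesterone (PGS), deoxycorticosterone (DCTS),
corticosterone (CTS), 17a-hydroxypregnenolone (HPNN), 17a-hydroxyprogesterone
(HPGS) and cortisol (CORT) — coupled by 25 lumped reactions R1..R25 under the
law of mass action.  Concentrations are molar and time is in minutes, matching
the units of the rate constants; no internal rescaling is performed.

The reactions are not elementary steps but summarized pathway outcomes.  Two
feedback loops drive the ultradian rhythm: cubic autocatalysis of
corticosterone through deoxycorticosterone (R14, DCTS + 2CTS -> 3CTS) and
quadratic autoinhibition through aldosterone (R15, ALDO + 2CTS -> CTS).  CRH
stimulates pituitary ACTH release catalytically (R4, CRH -> CRH + ACTH): CRH
acts as a trigger and is not consumed by the step; its removal is carried by
the corticosterone negative feedback (R16) and first-order elimination (R19).
Glucocorticoid/mineralocorticoid receptor levels are folded into the rate
constants and are not state variables.  Products of the degradation steps
R16–R25 are unmodeled sinks.

CRH production (R2) is modulated by the circadian forcing factor D(t); every
rate function here takes that factor as a plain number so the forcing model
stays decoupled from the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES",
    "N_SPECIES",
    "RATE_CONSTANTS",
    "INITIAL_CONCENTRATIONS",
    "Reaction",
    "ReactionNetwork",
    "SpeciesState",
    "build_rat_network",
    "reaction_rate",
    "mass_action_rhs",
    "mass_action_jacobian",
    "network_to_frame",
]

#: Species identifiers in table-appearance order.  Serialization always uses
#: labeled columns, so this ordering is a convention, never load-bearing.
SPECIES: tuple[str, ...] = (
    "CHOL", "CRH", "ALDO", "ACTH", "PNN", "PGS",
    "DCTS", "CTS", "HPNN", "HPGS", "CORT",
)
N_SPECIES = len(SPECIES)
_IDX = {name: i for i, name in enumerate(SPECIES)}

#: Default rate constants k1..k25.  Units follow reaction order:
#: M min^-1 (order 0), min^-1 (order 1), M^-1 min^-1 (order 2),
#: M^-2 min^-1 (order 3).
RATE_CONSTANTS: dict[str, float] = {
    "k1": 5.5200e-5,
    "k2": 2.2875e-8,
    "k3": 7.3080e-11,
    "k4": 1.0811e4,
    "k5": 3.4240e7,
    "k6": 7.7371,
    "k7": 3.8686,
    "k8": 1.1606e-2,
    "k9": 1.2000e-3,
    "k10": 1.0000e-5,
    "k11": 6.1900e-2,
    "k12": 1.2380e-2,
    "k13": 6.1900e-2,
    "k14": 1.5120e12,
    "k15": 8.4600e10,
    "k16": 3.6000e10,
    "k17": 3.0000e9,
    "k18": 1.6200e-1,
    "k19": 6.6000e-4,
    "k20": 6.4200e2,
    "k21": 7.3800e-2,
    "k22": 1.6200e-1,
    "k23": 1.6200e-1,
    "k24": 1.2840e-2,
    "k25": 1.0000e-5,
}

#: Initial concentrations (M), shared by every scenario.
INITIAL_CONCENTRATIONS: dict[str, float] = {
    "ACTH": 8.00e-13,
    "ALDO": 1.50e-9,
    "CHOL": 3.40e-4,
    "CTS": 4.00e-8,
    "CRH": 1.00e-12,
    "CORT": 1.50e-9,
    "DCTS": 4.00e-9,
    "HPNN": 1.00e-10,
    "HPGS": 4.00e-8,
    "PNN": 1.00e-10,
    "PGS": 4.00e-8,
}

_ORDER_UNITS = {0: "M min^-1", 1: "min^-1", 2: "M^-1 min^-1", 3: "M^-2 min^-1"}


@dataclass(frozen=True)
class Reaction:
    """One stoichiometric relation with its mass-action rate constant."""

    label: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_constant: float
    forced_by_circadian: bool = False

    def __post_init__(self) -> None:
        if self.rate_constant <= 0:
            raise ValueError(f"{self.label}: rate constant must be positive")
        for name in list(self.reactants) + list(self.products):
            if name not in _IDX:
                raise ValueError(f"{self.label}: unknown species {name!r}")
        if self.order not in _ORDER_UNITS:
            raise ValueError(f"{self.label}: unsupported order {self.order}")

    @property
    def order(self) -> int:
        return sum(self.reactants.values())

    @property
    def units(self) -> str:
        return _ORDER_UNITS[self.order]

    def net_stoichiometry(self) -> dict[str, int]:
        """Products minus reactants, dropping zero entries."""
        net: dict[str, int] = {}
        for name, s in self.products.items():
            net[name] = net.get(name, 0) + s
        for name, s in self.reactants.items():
            net[name] = net.get(name, 0) - s
        return {n: s for n, s in net.items() if s != 0}


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations (M) of all species at one instant (minutes since 00:00 day 1)."""

    concentrations: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.shape != (N_SPECIES,):
            raise ValueError(f"expected {N_SPECIES} concentrations, got shape {c.shape}")
        if np.any(c < 0):
            raise ValueError("concentrations must be nonnegative")
        object.__setattr__(self, "concentrations", c)

    def __getitem__(self, species: str) -> float:
        return float(self.concentrations[_IDX[species]])

    def with_concentration(self, species: str, value: float) -> "SpeciesState":
        if species not in _IDX:
            raise KeyError(f"unknown species {species!r}")
        c = self.concentrations.copy()
        c[_IDX[species]] = value
        return replace(self, concentrations=c)

    def as_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(SPECIES, self.concentrations)}

    @classmethod
    def from_dict(cls, values: Mapping[str, float], time: float = 0.0) -> "SpeciesState":
        missing = set(SPECIES) - set(values)
        if missing:
            raise ValueError(f"missing species: {sorted(missing)}")
        c = np.array([values[name] for name in SPECIES], dtype=float)
        return cls(concentrations=c, time=time)


def initial_state(time: float = 0.0) -> SpeciesState:
    """Default initial condition used by all scenarios."""
    return SpeciesState.from_dict(INITIAL_CONCENTRATIONS, time=time)


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    stoichiometry_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("species identifiers must be unique")
        S = np.zeros((len(self.species), len(self.reactions)), dtype=int)
        idx = {name: i for i, name in enumerate(self.species)}
        for j, rxn in enumerate(self.reactions):
            for name, net in rxn.net_stoichiometry().items():
                S[idx[name], j] = net
        object.__setattr__(self, "stoichiometry_matrix", S)
        touched = {n for r in self.reactions for n in (*r.reactants, *r.products)}
        untouched = set(self.species) - touched
        if untouched:
            raise ValueError(f"species in no reaction: {sorted(untouched)}")

    def reaction(self, label: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.label == label:
                return rxn
        raise KeyError(f"no reaction labeled {label!r}")

    def rate_constants(self) -> dict[str, float]:
        return {f"k{i + 1}": r.rate_constant for i, r in enumerate(self.reactions)}


def _r(label, reactants, products, kname, forced=False, k=None):
    kval = RATE_CONSTANTS[kname] if k is None else k[kname]
    return Reaction(label, reactants, products, kval, forced_by_circadian=forced)


def build_rat_network(rate_constants: Mapping[str, float] | None = None) -> ReactionNetwork:
    """Build the 25-reaction, 11-species rat HPA-axis network.

    R2 (CRH production) is flagged as circadian-forced; its effective rate is
    k2 * D(t).  R4 is the catalytic CRH-stimulated ACTH release step.
    """
    k = dict(RATE_CONSTANTS)
    if rate_constants:
        unknown = set(rate_constants) - set(k)
        if unknown:
            raise ValueError(f"unknown rate constants: {sorted(unknown)}")
        k.update(rate_constants)
    rxns = (
        _r("R1", {}, {"CHOL": 1}, "k1", k=k),
        _r("R2", {}, {"CRH": 1}, "k2", forced=True, k=k),
        _r("R3", {}, {"ALDO": 1}, "k3", k=k),
        # CRH triggers ACTH release without being consumed by the step.
        _r("R4", {"CRH": 1}, {"CRH": 1, "ACTH": 1}, "k4", k=k),
        _r("R5", {"ACTH": 1, "CHOL": 1}, {"PNN": 1}, "k5", k=k),
        _r("R6", {"PNN": 1}, {"PGS": 1}, "k6", k=k),
        _r("R7", {"PGS": 1}, {"DCTS": 1}, "k7", k=k),
        _r("R8", {"DCTS": 1}, {"CTS": 1}, "k8", k=k),
        _r("R9", {"CTS": 1}, {"ALDO": 1}, "k9", k=k),
        _r("R10", {"PGS": 1}, {"HPGS": 1}, "k10", k=k),
        _r("R11", {"PNN": 1}, {"HPNN": 1}, "k11", k=k),
        _r("R12", {"HPNN": 1}, {"HPGS": 1}, "k12", k=k),
        _r("R13", {"HPGS": 1}, {"CORT": 1}, "k13", k=k),
        _r("R14", {"DCTS": 1, "CTS": 2}, {"CTS": 3}, "k14", k=k),
        _r("R15", {"ALDO": 1, "CTS": 2}, {"CTS": 1}, "k15", k=k),
        _r("R16", {"CRH": 1, "CTS": 1}, {}, "k16", k=k),
        _r("R17", {"ACTH": 1, "CTS": 1}, {}, "k17", k=k),
        _r("R18", {"CHOL": 1}, {}, "k18", k=k),
        _r("R19", {"CRH": 1}, {}, "k19", k=k),
        _r("R20", {"ACTH": 1}, {}, "k20", k=k),
        _r("R21", {"CTS": 1}, {}, "k21", k=k),
        _r("R22", {"ALDO": 1}, {}, "k22", k=k),
        _r("R23", {"CORT": 1}, {}, "k23", k=k),
        _r("R24", {"PNN": 1}, {}, "k24", k=k),
        _r("R25", {"PGS": 1}, {}, "k25", k=k),
    )
    return ReactionNetwork(species=SPECIES, reactions=rxns)


def reaction_rate(
    reaction: Reaction,
    state: SpeciesState | np.ndarray,
    circadian_factor: float = 1.0,
) -> float:
    """Mass-action flux of one reaction (M min^-1).

    flux = k * prod_i [X_i]^s_i over the reactant stoichiometry; for the
    circadian-forced step the flux is k * circadian_factor (times reactant
    terms, of which R2 has none).
    """
    if circadian_factor <= 0:
        raise ValueError("circadian factor must be positive")
    c = state.concentrations if isinstance(state, SpeciesState) else np.asarray(state, float)
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    flux = reaction.rate_constant
    if reaction.forced_by_circadian:
        flux *= circadian_factor
    for name, s in reaction.reactants.items():
        flux *= c[_IDX[name]] ** s
    return float(flux)


def mass_action_rhs(
    state: SpeciesState | np.ndarray,
    k: Mapping[str, float] | None = None,
    circadian_factor: float = 1.0,
) -> np.ndarray:
    """Time derivatives (M min^-1) of all species under mass action.

    Closed-form per-species balance equations; equals the product of the
    network stoichiometry matrix with the reaction-rate vector.
    """
    if circadian_factor <= 0:
        raise ValueError("circadian factor must be positive")
    c = state.concentrations if isinstance(state, SpeciesState) else np.asarray(state, float)
    if c.shape != (N_SPECIES,):
        raise ValueError(f"state must have {N_SPECIES} entries, got shape {c.shape}")
    kk = RATE_CONSTANTS if k is None else k
    return _rhs_raw(c, _kvec(kk), circadian_factor)


def _kvec(k: Mapping[str, float]) -> np.ndarray:
    """1-based rate-constant vector (index 0 unused) for the fast kernels."""
    v = np.empty(26)
    for i in range(1, 26):
        v[i] = k[f"k{i}"]
    return v


def _rhs_raw(c: np.ndarray, k: np.ndarray, D: float) -> np.ndarray:
    """RHS kernel on a raw concentration vector; used by the simulator."""
    CHOL, CRH, ALDO, ACTH, PNN, PGS, DCTS, CTS, HPNN, HPGS, CORT = c
    v4 = k[4] * CRH
    v5 = k[5] * ACTH * CHOL
    v14 = k[14] * DCTS * CTS * CTS
    v15 = k[15] * ALDO * CTS * CTS
    v16 = k[16] * CRH * CTS
    v17 = k[17] * ACTH * CTS
    return np.array([
        k[1] - v5 - k[18] * CHOL,                                   # CHOL
        k[2] * D - v16 - k[19] * CRH,                               # CRH (R4 catalytic)
        k[3] + k[9] * CTS - v15 - k[22] * ALDO,                     # ALDO
        v4 - v5 - v17 - k[20] * ACTH,                               # ACTH
        v5 - k[6] * PNN - k[11] * PNN - k[24] * PNN,                # PNN
        k[6] * PNN - k[7] * PGS - k[10] * PGS - k[25] * PGS,        # PGS
        k[7] * PGS - k[8] * DCTS - v14,                             # DCTS
        k[8] * DCTS - k[9] * CTS + v14 - v15 - v16 - v17
        - k[21] * CTS,                                              # CTS
        k[11] * PNN - k[12] * HPNN,                                 # HPNN
        k[10] * PGS + k[12] * HPNN - k[13] * HPGS,                  # HPGS
        k[13] * HPGS - k[23] * CORT,                                # CORT
    ])


def _jac_raw(c: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the RHS kernel (D-independent)."""
    CHOL, CRH, ALDO, ACTH, PNN, PGS, DCTS, CTS, HPNN, HPGS, CORT = c
    J = np.zeros((11, 11))
    cts2 = CTS * CTS
    # CHOL
    J[0, 0] = -k[5] * ACTH - k[18]
    J[0, 3] = -k[5] * CHOL
    # CRH
    J[1, 1] = -k[16] * CTS - k[19]
    J[1, 7] = -k[16] * CRH
    # ALDO
    J[2, 2] = -k[15] * cts2 - k[22]
    J[2, 7] = k[9] - 2 * k[15] * ALDO * CTS
    # ACTH
    J[3, 1] = k[4]
    J[3, 0] = -k[5] * ACTH
    J[3, 3] = -k[5] * CHOL - k[17] * CTS - k[20]
    J[3, 7] = -k[17] * ACTH
    # PNN
    J[4, 0] = k[5] * ACTH
    J[4, 3] = k[5] * CHOL
    J[4, 4] = -(k[6] + k[11] + k[24])
    # PGS
    J[5, 4] = k[6]
    J[5, 5] = -(k[7] + k[10] + k[25])
    # DCTS
    J[6, 5] = k[7]
    J[6, 6] = -k[8] - k[14] * cts2
    J[6, 7] = -2 * k[14] * DCTS * CTS
    # CTS
    J[7, 6] = k[8] + k[14] * cts2
    J[7, 7] = (-k[9] + 2 * k[14] * DCTS * CTS - 2 * k[15] * ALDO * CTS
               - k[16] * CRH - k[17] * ACTH - k[21])
    J[7, 2] = -k[15] * cts2
    J[7, 1] = -k[16] * CTS
    J[7, 3] = -k[17] * CTS
    # HPNN
    J[8, 4] = k[11]
    J[8, 8] = -k[12]
    # HPGS
    J[9, 5] = k[10]
    J[9, 8] = k[12]
    J[9, 9] = -k[13]
    # CORT
    J[10, 9] = k[13]
    J[10, 10] = -k[23]
    return J


def mass_action_jacobian(
    state: SpeciesState | np.ndarray,
    k: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Jacobian d(RHS)/d(state); the forcing factor never enters (R2 is order 0)."""
    c = state.concentrations if isinstance(state, SpeciesState) else np.asarray(state, float)
    kk = RATE_CONSTANTS if k is None else k
    return _jac_raw(c, _kvec(kk))


def network_to_frame(network: ReactionNetwork) -> pd.DataFrame:
    """Tabular view of the network (one row per reaction) for CSV export."""

    def side(terms: Mapping[str, int]) -> str:
        return " + ".join(
            (f"{s}{n}" if s > 1 else n) for n, s in sorted(terms.items())
        )

    rows = []
    for rxn in network.reactions:
        rows.append({
            "label": rxn.label,
            "reactants": side(rxn.reactants),
            "products": side(rxn.products),
            "rate_constant": rxn.rate_constant,
            "units": rxn.units,
            "forced_by_circadian": rxn.forced_by_circadian,
        })
    return pd.DataFrame(rows)
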