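"""Species state, the four reaction rate laws, and the ODE right-hand side.

The model tracks four species, all as cytosolic concentrations in M:

* ``LIP``  — labile iron pool, soluble Fe(II);
* ``DFP``  — diferric-peroxo intermediate produced by the ferroxidase
  reaction (each molecule carries two iron atoms);
* ``core`` — mineralized ferrihydrite iron summed over all cages, expressed
  as the iron concentration that would result from solubilizing every core;
* ``FT``   — 24-subunit ferritin cages.

Reactions and stoichiometry (one "event" = one rate-law evaluation):

=================  ==================  =============================
oxidation          2 LIP -> DFP        Hill kinetics in LIP, ~FT
reduction          DFP -> 2 LIP        mass action
nucleation         2 DFP -> 4 core     empirical, core-inhibited
mineralization     DFP -> 2 core       core-catalyzed, capacity-limited
=================  ==================  =============================

The weighted sum ``LIP + 2*DFP + core`` counts every iron atom once and is
conserved by all four reactions (and by ferritin turnover, since iron from
degraded cages returns to the LIP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import SUBUNITS_PER_CAGE, KineticParameters

__all__ = [
    "ModelState",
    "ReactionRates",
    "subunit_oxidation_factor",
    "subunit_nucleation_factor",
    "oxidation_rate",
    "reduction_rate",
    "nucleation_rate",
    "mineralization_rate",
    "atoms_per_cage",
    "reaction_rates",
    "derivatives",
]

SPECIES = ("LIP", "DFP", "core", "FT")


@dataclass(frozen=True)
class ModelState:
    """Concentrations of the four species (M) at time ``t`` (s)."""

    LIP: float
    DFP: float
    core: float
    FT: float
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in SPECIES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.t < 0:
            raise ValueError(f"t must be >= 0, got {self.t}")

    def to_array(self) -> np.ndarray:
        return np.array([self.LIP, self.DFP, self.core, self.FT], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray, t: float = 0.0) -> "ModelState":
        return cls(LIP=float(y[0]), DFP=float(y[1]), core=float(y[2]), FT=float(y[3]), t=t)

    @property
    def total_iron(self) -> float:
        """Iron atoms in all forms, as a concentration: LIP + 2*DFP + core."""
        return self.LIP + 2.0 * self.DFP + self.core

    @property
    def apc(self) -> float:
        """Mean iron atoms per cage (0 when the state holds no cages and no core)."""
        if self.FT > 0:
            return self.core / self.FT
        return 0.0 if self.core == 0 else float("inf")


@dataclass(frozen=True)
class ReactionRates:
    """Instantaneous reaction fluxes (M s^-1 of reaction events).

    ``v_syn`` is the zero-order cage synthesis flux (M s^-1); ``v_degFT``
    the cage degradation flux (M s^-1 of cages).
    """

    v_ox: float
    v_red: float
    v_nuc: float
    v_min: float
    v_syn: float = 0.0
    v_degFT: float = 0.0


def subunit_oxidation_factor(H: int, rO: float = 2.0) -> float:
    """Oxidation scaling (H + rO) / (24 + rO) for a cage with H heavy subunits.

    Equals 1 for the H-homopolymer and rO/(24+rO) for the L-homopolymer,
    encoding the residual ferroxidase-independent oxidation of L-only cages.
    """
    _check_H(H)
    if rO <= 0:
        raise ValueError("rO must be positive")
    return (H + rO) / (SUBUNITS_PER_CAGE + rO)


def subunit_nucleation_factor(H: int, rN: float = 50.0) -> float:
    """Nucleation scaling (L + rN) / (24 + rN) with L = 24 - H.

    Light subunits assist crystal nucleation; the large offset rN keeps the
    composition effect on nucleation much weaker than on oxidation.
    """
    _check_H(H)
    if rN <= 0:
        raise ValueError("rN must be positive")
    return (SUBUNITS_PER_CAGE - H + rN) / (SUBUNITS_PER_CAGE + rN)


def _check_H(H: int) -> None:
    if not (0 <= H <= SUBUNITS_PER_CAGE):
        raise ValueError(f"invalid subunit composition: H={H} not in 0..{SUBUNITS_PER_CAGE}")


def oxidation_rate(state: ModelState, p: KineticParameters) -> float:
    """Ferroxidase flux: ox_kcat * (H+rO)/(24+rO) * FT * LIP^n / (Km^n + LIP^n)."""
    if state.LIP == 0.0 or state.FT == 0.0:
        return 0.0
    hill = state.LIP**p.ox_n / (p.ox_Km**p.ox_n + state.LIP**p.ox_n)
    return p.ox_kcat * subunit_oxidation_factor(p.H, p.rO) * state.FT * hill


def reduction_rate(state: ModelState, p: KineticParameters) -> float:
    """Mass-action DFP reduction flux: red_kdeg * DFP."""
    return p.red_kdeg * state.DFP


def nucleation_rate(state: ModelState, p: KineticParameters) -> float:
    """New-crystal formation flux.

    nuc_kcat * DFP^2 * FT * (L+rN)/(24+rN) * Ki^n / (Ki^n + core^n);
    the last factor is product inhibition by the existing core.
    """
    if state.DFP == 0.0 or state.FT == 0.0:
        return 0.0
    inhib = p.nuc_Ki**p.nuc_n / (p.nuc_Ki**p.nuc_n + state.core**p.nuc_n)
    return (
        p.nuc_kcat
        * state.DFP**2
        * state.FT
        * subunit_nucleation_factor(p.H, p.rN)
        * inhib
    )


def mineralization_rate(state: ModelState, p: KineticParameters) -> float:
    """Core-catalyzed crystal growth flux.

    min_kcat * core * DFP/(Km+DFP) * Ki^n/(Ki^n+core^n)
             * (capacity^m - apc^m)/capacity^m

    The capacity term is clamped at 0 once the mean load reaches
    ``capacity`` atoms per cage; a state with core but no cages has no
    mineralization surface and yields 0.
    """
    if state.core == 0.0 or state.DFP == 0.0:
        return 0.0
    if state.FT > 0:
        apc = state.core / state.FT
    else:
        apc = p.capacity  # degenerate: core without cages mineralizes nothing
    if apc >= p.capacity:  # clamp before exponentiating (huge apc overflows)
        return 0.0
    cap = 1.0 - (apc / p.capacity) ** p.min_m
    sat = state.DFP / (p.min_Km + state.DFP)
    inhib = p.min_Ki**p.min_n / (p.min_Ki**p.min_n + state.core**p.min_n)
    return p.min_kcat * state.core * sat * inhib * cap


def atoms_per_cage(core: float, FT: float) -> float:
    """Mean iron atoms per cage, core / FT.

    Raises for the degenerate core-without-cages state; rate evaluation
    handles that case internally by shutting mineralization off.
    """
    if core < 0 or FT < 0:
        raise ValueError("concentrations must be >= 0")
    if FT == 0:
        if core > 0:
            raise ValueError("degenerate state: core > 0 with no ferritin cages")
        return 0.0
    return core / FT


def reaction_rates(state: ModelState, p: KineticParameters) -> ReactionRates:
    """Evaluate all reaction fluxes at a state."""
    return ReactionRates(
        v_ox=oxidation_rate(state, p),
        v_red=reduction_rate(state, p),
        v_nuc=nucleation_rate(state, p),
        v_min=mineralization_rate(state, p),
        v_syn=p.ft_ksyn,
        v_degFT=p.ft_kdeg * state.FT,
    )


def derivatives(state: ModelState, p: KineticParameters) -> np.ndarray:
    """Time derivatives (dLIP, dDFP, dcore, dFT) in M s^-1.

    Stoichiometry: oxidation consumes 2 LIP per event; reduction returns 2;
    nucleation consumes 2 DFP and deposits 4 core iron; mineralization
    consumes 1 DFP and deposits 2. Cage degradation releases the degraded
    cages' share of the core (ft_kdeg * core) back into the LIP.
    """
    r = reaction_rates(state, p)
    release = p.ft_kdeg * state.core
    dLIP = -2.0 * r.v_ox + 2.0 * r.v_red + release
    dDFP = r.v_ox - r.v_red - 2.0 * r.v_nuc - r.v_min
    dcore = 4.0 * r.v_nuc + 2.0 * r.v_min - release
    dFT = r.v_syn - r.v_degFT
    return np.array([dLIP, dDFP, dcore, dFT])


# ---------------------------------------------------------------------------
# Fast array-based kernels for the integrator. These clip tiny negative
# excursions (within integrator tolerance) to zero before evaluating the
# rate laws, which the dataclass API instead rejects.
# ---------------------------------------------------------------------------

def _rates_vec(y: np.ndarray, p: KineticParameters) -> tuple[float, float, float, float]:
    LIP = y[0] if y[0] > 0.0 else 0.0
    DFP = y[1] if y[1] > 0.0 else 0.0
    core = y[2] if y[2] > 0.0 else 0.0
    FT = y[3] if y[3] > 0.0 else 0.0

    if LIP > 0.0 and FT > 0.0:
        ln = LIP**p.ox_n
        v_ox = p.ox_kcat * ((p.H + p.rO) / (24.0 + p.rO)) * FT * ln / (p.ox_Km**p.ox_n + ln)
    else:
        v_ox = 0.0

    v_red = p.red_kdeg * DFP

    if DFP > 0.0 and FT > 0.0:
        kin = p.nuc_Ki**p.nuc_n
        v_nuc = (
            p.nuc_kcat * DFP * DFP * FT
            * ((24.0 - p.H + p.rN) / (24.0 + p.rN))
            * kin / (kin + core**p.nuc_n)
        )
    else:
        v_nuc = 0.0

    if core > 0.0 and DFP > 0.0:
        apc = core / FT if FT > 0.0 else p.capacity
        cap = 1.0 - (apc / p.capacity) ** p.min_m if apc < p.capacity else 0.0
        if cap > 0.0:
            kim = p.min_Ki**p.min_n
            v_min = (
                p.min_kcat * core
                * DFP / (p.min_Km + DFP)
                * kim / (kim + core**p.min_n)
                * cap
            )
        else:
            v_min = 0.0
    else:
        v_min = 0.0

    return v_ox, v_red, v_nuc, v_min


def _rhs(t: float, y: np.ndarray, p: KineticParameters) -> np.ndarray:
    v_ox, v_red, v_nuc, v_min = _rates_vec(y, p)
    core = y[2] if y[2] > 0.0 else 0.0
    FT = y[3] if y[3] > 0.0 else 0.0
    release = p.ft_kdeg * core
    return np.array(
        [
            -2.0 * v_ox + 2.0 * v_red + release,
            v_ox - v_red - 2.0 * v_nuc - v_min,
            4.0 * v_nuc + 2.0 * v_min - release,
            p.ft_ksyn - p.ft_kdeg * FT,
        ]
    )
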