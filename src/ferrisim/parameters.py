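"""Kinetic parameters of the ferritin iron-sequestration model.

All quantities are in molar (M) and seconds. Saturation constants that the
literature quotes in mM are stored here converted to M; the canonical default
config file (``data/table1_default.cfg``) keeps the mM originals in comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path

__all__ = ["KineticParameters", "load_parameters", "dump_parameters"]

SUBUNITS_PER_CAGE = 24


@dataclass(frozen=True)
class KineticParameters:
    """Rate-law constants for the four sequestration reactions plus ferritin turnover.

    Oxidation (2 LIP -> DFP, Hill kinetics on LIP, catalyzed by H subunits)
    ----------------------------------------------------------------------
    ox_kcat : turnover number of the ferroxidase reaction (s^-1).
    ox_Km   : Hill half-saturation constant for LIP (M).
    ox_n    : Hill coefficient.
    H       : number of heavy subunits per 24-subunit cage (0..24).
    rO      : offset giving an L-homopolymer (H=0) a residual oxidation
              activity of rO/(24+rO) relative to the H-homopolymer.

    Reduction (DFP -> 2 LIP, mass action)
    -------------------------------------
    red_kdeg : first-order rate constant (s^-1).

    Nucleation (2 DFP -> 4 core, empirical, product-inhibited)
    ----------------------------------------------------------
    nuc_kcat : rate constant (M^-2 s^-1; the flux is nuc_kcat*DFP^2*FT*...).
    nuc_Ki   : core product-inhibition constant (M).
    nuc_n    : inhibition Hill coefficient.
    rN       : offset analogous to rO for the L-subunit nucleation advantage.

    Mineralization (DFP -> 2 core, core-catalyzed, capacity-limited)
    ----------------------------------------------------------------
    min_kcat : turnover number (s^-1).
    min_Km   : hyperbolic half-saturation for DFP (M).
    min_Ki   : core inhibition constant (M).
    min_n    : inhibition Hill coefficient.
    min_m    : Hill coefficient of the atoms-per-cage capacity shut-off.
    capacity : maximum iron atoms per cage (dimensionless, 4300).

    Ferritin turnover (off by default)
    ----------------------------------
    ft_ksyn : zero-order cage synthesis rate (M s^-1); synthesized cages are apo.
    ft_kdeg : first-order cage degradation constant (s^-1); the degraded
              cages' share of the core is released back to the LIP.
    """

    ox_kcat: float = 591.0
    ox_Km: float = 3.5e-4
    ox_n: float = 1.3
    H: int = 4
    rO: float = 2.0
    red_kdeg: float = 0.2605
    nuc_kcat: float = 5e7
    nuc_Ki: float = 4.615e-4
    nuc_n: float = 4.0
    rN: float = 50.0
    min_kcat: float = 0.101564
    min_Km: float = 5e-6
    min_Ki: float = 4.6458e-3
    min_n: float = 4.0
    min_m: float = 8.0
    capacity: float = 4300.0
    ft_ksyn: float = 0.0
    ft_kdeg: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.H <= SUBUNITS_PER_CAGE):
            raise ValueError(f"H must be in 0..{SUBUNITS_PER_CAGE}, got {self.H}")
        if self.rO <= 0 or self.rN <= 0:
            raise ValueError("rO and rN must be positive")
        if self.capacity <= 0:
            raise ValueError("capacity must be positive")
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name not in ("H",) and v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")

    @property
    def L(self) -> int:
        """Number of light subunits per cage (24 - H)."""
        return SUBUNITS_PER_CAGE - self.H

    def with_(self, **updates) -> "KineticParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **updates)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        if "H" in d:
            h = d["H"]
            if float(h) != int(float(h)):
                raise ValueError(f"H must be an integer, got {h}")
            d = {**d, "H": int(float(h))}
        return cls(**d)


def load_parameters(path: str | Path | None = None) -> KineticParameters:
    """Read a flat ``key = value`` parameter file (``#`` starts a comment).

    With no path, loads the packaged default set (the published in-vitro
    calibration, hepatocyte-like H=4 composition, turnover off).
    """
    if path is None:
        text = resources.files("ferrisim.data").joinpath("table1_default.cfg").read_text()
    else:
        text = Path(path).read_text()
    d: dict = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        d[key] = float(val)
    return KineticParameters.from_dict(d)


def dump_parameters(p: KineticParameters, path: str | Path) -> None:
    """Write a flat key/value parameter file readable by :func:`load_parameters`."""
    lines = ["# ferrisim kinetic parameters (units: M, s)"]
    lines += [f"{k} = {v!r}" for k, v in p.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")
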