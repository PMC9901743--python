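"""Scenario configuration and the built-in figure-scenario library.

A Scenario bundles a parameter set, initial conditions (ferritin
concentration, initial iron load as atoms per cage, LIP/DFP), a dosing
schedule, horizon, output grid and the compartment volume (metadata only —
the dynamics are concentration-based). Scenarios can be loaded from and
dumped to YAML; the built-in registry reproduces the published simulation
experiments:

* in-vitro APC sweeps (2.32 uM ferritin, 1.09 mM iron dose, 25 s),
* cell-scale buffering runs (nM ferritin, uM doses, hundreds of seconds),
* subunit-composition sweeps (H from 0 to 24),
* ferritin-turnover runs with daily iron dosing (expression/degradation on).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import yaml

from .model import ModelState
from .parameters import KineticParameters
from .simulate import (
    Event,
    EventSchedule,
    Trajectory,
    initial_sequestration_rate,
    max_mineralization_rate,
    simulate,
    time_to_fraction_sequestered,
)

__all__ = [
    "Scenario",
    "ScenarioResult",
    "load_scenario",
    "dump_scenario",
    "run_scenario",
    "builtin_scenario",
    "list_scenarios",
    "parse_concentration",
    "max_apc_fully_sequestered",
]

_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}
_CONC_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([munµp]?M)\s*$")


def parse_concentration(value) -> float:
    """Accept a number (M) or a string with unit suffix ('2.32 uM') -> M."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _CONC_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse concentration {value!r}")
    return float(m.group(1)) * _UNIT_SCALE[m.group(2)]


@dataclass
class Scenario:
    """A fully specified simulation experiment."""

    name: str
    params: KineticParameters = field(default_factory=KineticParameters)
    FT0: float = 5e-9
    apc0: float = 0.0
    LIP0: float = 0.0
    DFP0: float = 0.0
    schedule: EventSchedule = field(default_factory=EventSchedule)
    horizon: float = 25.0
    grid_dt: float = 0.01
    volume: float = 1.4e-12
    description: str = ""

    def __post_init__(self) -> None:
        if self.FT0 < 0 or self.LIP0 < 0 or self.DFP0 < 0:
            raise ValueError("initial concentrations must be >= 0")
        if not (0 <= self.apc0 <= self.params.capacity):
            raise ValueError(f"apc0 must be in [0, {self.params.capacity}]")
        if self.horizon <= 0 or self.grid_dt <= 0:
            raise ValueError("horizon and grid_dt must be positive")

    def initial_state(self) -> ModelState:
        """Initial conditions as a state; core(0) = apc0 * FT(0)."""
        return ModelState(
            LIP=self.LIP0, DFP=self.DFP0, core=self.apc0 * self.FT0, FT=self.FT0
        )

    def with_(self, **updates) -> "Scenario":
        return replace(self, **updates)


@dataclass
class ScenarioResult:
    """Trajectory of a scenario run plus its summary metrics."""

    scenario: Scenario
    trajectory: Trajectory
    metrics: dict


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "name", "parameters", "initial", "events", "horizon", "grid_dt", "volume",
    "description",
}
_INITIAL_KEYS = {"FT", "apc", "LIP", "DFP"}
_EVENT_KEYS = {"t", "target", "action", "value"}


def load_scenario(source: str | Path | dict) -> Scenario:
    """Build a validated Scenario from a YAML file/string or a dict.

    Concentrations may be plain numbers (M) or strings with a unit suffix
    (mM, uM, nM, pM). Unknown keys are rejected, naming the offender.
    """
    if isinstance(source, dict):
        cfg = dict(source)
    else:
        try:
            is_file = Path(str(source)).is_file()
        except OSError:  # e.g. a multi-line YAML string too long for a filename
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        cfg = yaml.safe_load(text)
        if not isinstance(cfg, dict):
            raise ValueError("scenario config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown scenario key(s): {sorted(unknown)}")
    if "name" not in cfg:
        raise ValueError("scenario config missing required field 'name'")

    pdict = dict(cfg.get("parameters", {}))
    for key in ("ox_Km", "nuc_Ki", "min_Km", "min_Ki"):
        if key in pdict:
            pdict[key] = parse_concentration(pdict[key])
    params = KineticParameters().from_dict({**KineticParameters().to_dict(), **pdict})

    init = dict(cfg.get("initial", {}))
    unknown = set(init) - _INITIAL_KEYS
    if unknown:
        raise ValueError(f"unknown initial-condition key(s): {sorted(unknown)}")

    events = []
    for i, e in enumerate(cfg.get("events", [])):
        unknown = set(e) - _EVENT_KEYS
        if unknown:
            raise ValueError(f"unknown event key(s) in event {i}: {sorted(unknown)}")
        value = e["value"] if e.get("action") == "scale" else parse_concentration(e["value"])
        events.append(Event(t=float(e["t"]), target=e["target"], action=e["action"], value=value))

    return Scenario(
        name=str(cfg["name"]),
        params=params,
        FT0=parse_concentration(init.get("FT", 5e-9)),
        apc0=float(init.get("apc", 0.0)),
        LIP0=parse_concentration(init.get("LIP", 0.0)),
        DFP0=parse_concentration(init.get("DFP", 0.0)),
        schedule=EventSchedule(events),
        horizon=float(cfg.get("horizon", 25.0)),
        grid_dt=float(cfg.get("grid_dt", 0.01)),
        volume=float(cfg.get("volume", 1.4e-12)),
        description=str(cfg.get("description", "")),
    )


def dump_scenario(s: Scenario) -> dict:
    """Scenario as a plain dict (all concentrations in M) that round-trips
    through :func:`load_scenario`."""
    defaults = KineticParameters().to_dict()
    overrides = {k: v for k, v in s.params.to_dict().items() if v != defaults[k]}
    return {
        "name": s.name,
        "parameters": overrides,
        "initial": {"FT": s.FT0, "apc": s.apc0, "LIP": s.LIP0, "DFP": s.DFP0},
        "events": [
            {"t": e.t, "target": e.target, "action": e.action, "value": e.value}
            for e in s.schedule
        ],
        "horizon": s.horizon,
        "grid_dt": s.grid_dt,
        "volume": s.volume,
        "description": s.description,
    }


def dump_scenario_yaml(s: Scenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dump_scenario(s), sort_keys=False))


# ---------------------------------------------------------------------------
# Built-in figure scenarios
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, Callable[[], Scenario]] = {}


def _register(fn: Callable[[], Scenario]) -> Callable[[], Scenario]:
    s = fn()
    _REGISTRY[s.name] = fn
    return fn


@_register
def _fig3() -> Scenario:
    return Scenario(
        name="fig3_apc_sweep",
        params=KineticParameters(H=4),
        FT0=2.32e-6,
        apc0=0.0,
        LIP0=1.09e-3,
        horizon=25.0,
        grid_dt=0.01,
        description=(
            "In-vitro APC sweep: 2.32 uM ferritin (H=4) receives a 1.09 mM "
            "ferrous dose (470 atoms/cage); initial core load apc0 is swept "
            "0..4300 across runs."
        ),
    )


@_register
def _fig4() -> Scenario:
    return Scenario(
        name="fig4_cell_scale",
        params=KineticParameters(H=4),
        FT0=5e-9,
        schedule=EventSchedule(
            [
                Event(t=0.0, target="LIP", action="set", value=1e-6),
                Event(t=400.0, target="LIP", action="set", value=2e-6),
            ]
        ),
        horizon=800.0,
        grid_dt=1.0,
        description=(
            "Cell-scale buffering: LIP set to 1 uM at t=0 and to 2 uM at "
            "400 s; ferritin concentration is the swept factor."
        ),
    )


@_register
def _fig5() -> Scenario:
    return Scenario(
        name="fig5_lip_depletion",
        params=KineticParameters(H=4),
        FT0=5e-9,
        schedule=EventSchedule(
            [
                Event(t=0.0, target="LIP", action="set", value=1e-6),
                Event(t=400.0, target="LIP", action="set", value=0.0),
            ]
        ),
        horizon=600.0,
        grid_dt=0.1,
        description=(
            "Iron release: after 400 s of sequestration the LIP is zeroed; "
            "non-mineralized DFP iron partially restores it."
        ),
    )


@_register
def _fig6() -> Scenario:
    return Scenario(
        name="fig6_apc_tuning",
        params=KineticParameters(H=4),
        FT0=5e-9,
        apc0=0.0,
        schedule=EventSchedule([Event(t=0.0, target="LIP", action="set", value=2.5e-6)]),
        horizon=800.0,
        grid_dt=1.0,
        description=(
            "Fine tuning by core load: 2.5 uM LIP addition at fixed 5 nM "
            "ferritin; apc0 swept 0..4300."
        ),
    )


@_register
def _fig7() -> Scenario:
    return Scenario(
        name="fig7_subunit_sweep",
        params=KineticParameters(H=12),
        FT0=5e-9,
        schedule=EventSchedule(
            [
                Event(t=0.0, target="LIP", action="set", value=1e-6),
                Event(t=400.0, target="LIP", action="set", value=2e-6),
            ]
        ),
        horizon=800.0,
        grid_dt=1.0,
        description=(
            "Subunit composition: cell-scale base conditions with H swept "
            "over 0,2,...,24 across runs."
        ),
    )


_KDEG = 1.203e-5
_KSYN = {"low": 3.075e-14, "mid": 6.015e-14, "high": 1.203e-13}


def _fig8(level: str) -> Scenario:
    ksyn = _KSYN[level]
    doses = [
        Event(t=1e4 + k * 1e5, target="LIP", action="add", value=5e-7) for k in range(40)
    ]
    return Scenario(
        name=f"fig8_turnover_{level}",
        params=KineticParameters(H=4, ft_ksyn=ksyn, ft_kdeg=_KDEG),
        FT0=ksyn / _KDEG,
        LIP0=0.0,
        schedule=EventSchedule(doses),
        horizon=4.01e6,
        grid_dt=500.0,
        description=(
            "Long-term turnover: expression/degradation hold ferritin at "
            f"{ksyn / _KDEG * 1e9:.3g} nM; 0.5 uM LIP doses every 1e5 s after "
            "a 1e4 s equilibration."
        ),
    )


for _level in _KSYN:
    _REGISTRY[f"fig8_turnover_{_level}"] = (lambda lv: (lambda: _fig8(lv)))(_level)


@_register
def _fig8_pulse() -> Scenario:
    return Scenario(
        name="fig8_pulse",
        params=KineticParameters(H=4, ft_ksyn=_KSYN["mid"], ft_kdeg=_KDEG),
        FT0=_KSYN["mid"] / _KDEG,
        LIP0=1e-6,
        schedule=EventSchedule(
            [
                Event(t=1e4, target="LIP", action="scale", value=2.0),
                Event(t=2.5e4, target="LIP", action="scale", value=0.5),
            ]
        ),
        horizon=4e4,
        grid_dt=10.0,
        description=(
            "Turnover pulse response: after 1e4 s equilibration the LIP is "
            "doubled, then halved at 2.5e4 s."
        ),
    )


def list_scenarios() -> list[str]:
    return sorted(_REGISTRY)


def builtin_scenario(name: str, **overrides) -> Scenario:
    """Fetch a built-in scenario by name, optionally overriding fields
    (e.g. ``apc0=2000`` for a sweep member)."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown scenario {name!r}; available: {list_scenarios()}")
    s = _REGISTRY[name]()
    return s.with_(**overrides) if overrides else s


def max_apc_fully_sequestered(
    fraction: float = 0.99,
    scenario: Scenario | None = None,
    *,
    lo: int = 0,
    hi: int | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> tuple[int, int]:
    """Largest integer initial APC at which ``fraction`` of the iron dose is
    still sequestered within the scenario horizon.

    Pre-loaded cages sequester a dose more slowly as they approach capacity,
    so the time to e.g. 99% sequestration is monotone in the initial load
    and the boundary can be found by bisection on integer APC. Returns the
    threshold and the number of simulations spent. Defaults to the in-vitro
    APC-sweep scenario.
    """
    if scenario is None:
        scenario = builtin_scenario("fig3_apc_sweep")
    if hi is None:
        hi = int(scenario.params.capacity)

    n_runs = 0

    def reaches(apc: int) -> bool:
        nonlocal n_runs
        n_runs += 1
        s = scenario.with_(apc0=float(apc))
        traj = simulate(
            s.initial_state(), s.params, s.schedule,
            horizon=s.horizon, grid_dt=s.grid_dt, rtol=rtol, atol=atol,
        )
        return time_to_fraction_sequestered(traj, fraction) is not None

    if not reaches(lo):
        raise ValueError(f"no APC in [{lo}, {hi}] sequesters the dose in time")
    if reaches(hi):
        return hi, n_runs
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if reaches(mid):
            lo = mid
        else:
            hi = mid
    return lo, n_runs


def run_scenario(
    s: Scenario, *, rtol: float = 1e-8, atol: float = 1e-12
) -> ScenarioResult:
    """Simulate a scenario and compute its summary metrics.

    Metrics: maximum mineralization flux and its time, time to 99% LIP
    sequestration, initial sequestration rate over the first 10 s (where
    the grid allows), final APC, and the final cage concentration.
    """
    traj = simulate(
        s.initial_state(), s.params, s.schedule,
        horizon=s.horizon, grid_dt=s.grid_dt, rtol=rtol, atol=atol,
    )
    vmax, t_at = max_mineralization_rate(traj)
    metrics: dict = {
        "max_v_min": vmax,
        "t_at_max_v_min": t_at,
        "final_apc": float(traj.apc[-1]),
        "final_FT": float(traj.species("FT")[-1]),
        "final_LIP": float(traj.species("LIP")[-1]),
        "core_gain": float(traj.species("core")[-1] - traj.species("core")[0]),
        "conservation_error": traj.conservation_error(),
    }
    t99 = time_to_fraction_sequestered(traj, 0.99)
    metrics["time_to_99pct"] = t99
    try:
        metrics["initial_sequestration_rate"] = initial_sequestration_rate(traj, 10.0)
    except ValueError:
        metrics["initial_sequestration_rate"] = None
    return ScenarioResult(scenario=s, trajectory=traj, metrics=metrics)
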