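"""Piecewise-constant schedule engine.

A simulation is a sequence of segments, each with its own chamber/device
parameters and an optional instantaneous injection of activity at the segment
start (modelling a known activity released into the space at once).  Within a
segment everything is evaluated with the exact closed forms; the end state of
one segment seeds the next, so chaining introduces no numerical error.

Bundled presets reproduce the canonical chamber scenarios used throughout the
package documentation: radon or thoron delivered at 1 Bq/s into 20 m^3 or
1 m^3 chambers, with a 10 L/min, 100%-efficiency filtering device switched on
during a fixed window or running continuously.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics
from .kernels import ChainState, SystemParameters, concentrations_at
from .nuclear_data import DecayChain, load_chain

__all__ = [
    "Segment",
    "Schedule",
    "ConcentrationSeries",
    "simulate",
    "preset",
    "PRESET_NAMES",
    "load_schedule",
    "schedule_from_config",
    "schedule_to_config",
    "MAX_SUBINTERVALS",
]

#: cap on the number of output sub-intervals per requested interval
MAX_SUBINTERVALS = 1000

HOUR = 3600.0

#: tolerance (relative to total duration) for matching a sample time to a
#: segment boundary
_BOUNDARY_RTOL = 1e-12


@dataclass(frozen=True)
class Segment:
    """One constant-parameter stretch of a schedule.

    ``injection`` (optional, Bq/m^3, aligned with chain.members) is added to
    the state instantaneously at the segment start.
    """

    duration: float
    params: SystemParameters
    injection: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("segment duration must be > 0")
        if self.injection is not None:
            inj = np.asarray(self.injection, dtype=float)
            if np.any(inj < 0) or not np.all(np.isfinite(inj)):
                raise ValueError("injection entries must be finite and >= 0")
            object.__setattr__(self, "injection", inj)


@dataclass(frozen=True)
class Schedule:
    """A chain, an initial state, ordered segments and an output grid.

    ``output_times`` defaults to ``MAX_SUBINTERVALS`` equal sub-intervals over
    the total duration.
    """

    chain: DecayChain
    initial_state: ChainState
    segments: tuple[Segment, ...]
    output_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("schedule needs at least one segment")
        total = self.total_duration
        if self.output_times is None:
            grid = np.linspace(0.0, total, MAX_SUBINTERVALS + 1)
        else:
            grid = np.asarray(self.output_times, dtype=float)
            if grid.ndim != 1 or len(grid) < 1:
                raise ValueError("output grid must be a non-empty 1-d array")
            if np.any(np.diff(grid) <= 0):
                raise ValueError("output times must be strictly increasing")
            if grid[0] < 0 or grid[-1] > total * (1 + _BOUNDARY_RTOL):
                raise ValueError("output times must lie within the schedule duration")
            if len(grid) - 1 > MAX_SUBINTERVALS:
                raise ValueError(f"at most {MAX_SUBINTERVALS} sub-intervals are supported")
        object.__setattr__(self, "output_times", grid)

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @property
    def boundaries(self) -> np.ndarray:
        """Segment start times plus the final end time."""
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])


@dataclass(frozen=True)
class ConcentrationSeries:
    """Sampled trajectory with derived radiometric metrics.

    When an injection falls on a sampled boundary the series carries two rows
    at that time — the incoming segment's end state and the post-injection
    state — distinguished by ``post_injection``.
    """

    chain: DecayChain
    times: np.ndarray
    C: np.ndarray
    post_injection: np.ndarray
    paec: np.ndarray = field(init=False)
    shares: np.ndarray = field(init=False)
    equilibrium_factor: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        totals, shares = metrics.paec_series(self.chain, self.C)
        object.__setattr__(self, "paec", totals)
        object.__setattr__(self, "shares", shares)
        object.__setattr__(
            self, "equilibrium_factor", metrics.equilibrium_factor_series(self.chain, self.C)
        )

    def to_frame(self, *, si: bool = False) -> pd.DataFrame:
        """Tabulate the series.

        Default units are hours and uJ/m^3 (concentrations always Bq/m^3);
        ``si=True`` keeps seconds and J/m^3.
        """
        tcol = "time_s" if si else "time_h"
        data: dict[str, np.ndarray] = {tcol: self.times if si else self.times / HOUR}
        for k, name in enumerate(self.chain.names):
            data[f"C_{name.replace('-', '')}"] = self.C[:, k]
        data["PAEC_J_m3" if si else "PAEC_uJ_m3"] = self.paec if si else self.paec * 1e6
        for k, n in enumerate(self.chain.members):
            if n.parent is not None:
                data[f"share_{n.name.replace('-', '')}"] = self.shares[:, k]
        data["eq_factor"] = self.equilibrium_factor
        df = pd.DataFrame(data)
        df["post_injection"] = self.post_injection
        return df


def simulate(schedule: Schedule, *, engine: str = "closed") -> ConcentrationSeries:
    """Run a schedule and sample it on its output grid.

    Segments are left-closed/right-open: a sample exactly on a boundary
    reports the incoming segment's end state (pre-injection); if the next
    segment carries an injection a second, post-injection row is emitted at
    the same time.

    ``engine="oracle"`` replaces the closed forms with the numerical
    reference (matrix exponential) for cross-checking.
    """
    if engine == "closed":
        evaluate = concentrations_at
    elif engine == "oracle":
        from . import oracle

        def evaluate(chain, params, state0, t):
            return oracle.integrate(chain, params, state0, t)
    else:
        raise ValueError(f"unknown engine {engine!r}; use 'closed' or 'oracle'")
    chain = schedule.chain
    bounds = schedule.boundaries
    total = bounds[-1]
    atol = _BOUNDARY_RTOL * max(total, 1.0)
    grid = schedule.output_times

    rows_t: list[float] = []
    rows_c: list[np.ndarray] = []
    rows_post: list[bool] = []

    state = schedule.initial_state.values.copy()
    for k, seg in enumerate(schedule.segments):
        t0, t1 = bounds[k], bounds[k + 1]
        pre_state = state
        if seg.injection is not None:
            if len(seg.injection) != len(chain):
                raise ValueError("injection length does not match chain")
            state = state + seg.injection
        start_state = ChainState(state)

        # sample at the segment start: pre-injection row (for k = 0 this is
        # the initial state; for k > 0 the previous segment already emitted
        # it), plus a post-injection row if the state jumped
        on_start = np.abs(grid - t0) <= atol
        if np.any(on_start):
            if k == 0:
                rows_t.append(t0)
                rows_c.append(pre_state.copy())
                rows_post.append(False)
            if seg.injection is not None and np.any(seg.injection > 0):
                rows_t.append(t0)
                rows_c.append(state.copy())
                rows_post.append(True)

        interior = grid[(grid > t0 + atol) & (grid <= t1 + atol)]
        if len(interior) > 0:
            rel = np.minimum(interior - t0, seg.duration)
            C = evaluate(chain, seg.params, start_state, rel)
            for tt, row in zip(interior, C):
                rows_t.append(float(tt))
                rows_c.append(row)
                rows_post.append(False)

        state = evaluate(chain, seg.params, start_state, seg.duration)

    return ConcentrationSeries(
        chain=chain,
        times=np.array(rows_t),
        C=np.array(rows_c),
        post_injection=np.array(rows_post, dtype=bool),
    )


def _device(V: float, E1: float, flow_L_per_min: float, F: float) -> SystemParameters:
    return SystemParameters.with_device(V=V, E1=E1, flow_L_per_min=flow_L_per_min, F=F)


def _windowed(
    gas: str, V: float, E1: float, window_h: tuple[float, float], total_h: float,
    flow_L_per_min: float = 10.0, F: float = 1.0,
) -> Schedule:
    chain = load_chain(gas)
    off = _device(V, E1, 0.0, 0.0)
    on = _device(V, E1, flow_L_per_min, F)
    a, b = window_h
    segs = (
        Segment(duration=a * HOUR, params=off),
        Segment(duration=(b - a) * HOUR, params=on),
        Segment(duration=(total_h - b) * HOUR, params=off),
    )
    return Schedule(chain=chain, initial_state=ChainState.zeros(chain), segments=segs)


def _presets() -> dict[str, Schedule]:
    rn = load_chain("Rn-222")
    # fig4: radon at gas steady state from the start, device running throughout
    p4 = _device(V=20.0, E1=1.0, flow_L_per_min=10.0, F=1.0)
    fig4 = Schedule(
        chain=rn,
        initial_state=ChainState.gas_only(rn, p4.S1 / rn.gas.decay_constant),
        segments=(Segment(duration=24 * HOUR, params=p4),),
    )
    tn = load_chain("Rn-220")
    # fig7/fig8: constant thoron inflow, no device, up to full equilibration
    fig7 = Schedule(
        chain=tn,
        initial_state=ChainState.zeros(tn),
        segments=(Segment(duration=100 * HOUR, params=_device(20.0, 1.0, 0.0, 0.0)),),
    )
    fig9 = _windowed("Rn-220", 20.0, 1.0, (40.0, 60.0), 100.0)
    fig10 = _windowed("Rn-220", 1.0, 1.0, (40.0, 60.0), 100.0)
    return {
        "fig4": fig4,
        "fig5": _windowed("Rn-222", 20.0, 1.0, (4.0, 6.0), 12.0),
        "fig6": _windowed("Rn-222", 1.0, 1.0, (4.0, 6.0), 12.0),
        "fig7": fig7,
        "fig8": fig7,   # same run, viewed as PAEC shares
        "fig9": fig9,
        "fig10": fig10,
        "fig11": fig9,  # same run, viewed as PAEC
        "fig12": fig10,
    }


PRESET_NAMES = ("fig4", "fig5", "fig6", "fig7", "fig8", "fig9", "fig10", "fig11", "fig12")


def preset(name: str) -> Schedule:
    """Return a bundled chamber scenario by name (``fig4`` … ``fig12``)."""
    table = _presets()
    if name not in table:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    return table[name]


# ---------------------------------------------------------------------------
# config serialization


def schedule_from_config(cfg: dict) -> Schedule:
    """Build a schedule from a plain config mapping.

    Keys: ``gas``, ``volume_m3``, ``inflow_Bq_per_s``, optional
    ``initial_Bq_per_m3`` (list aligned with the chain or mapping by nuclide
    name), ``segments`` (list of ``{hours, device_flow_L_per_min,
    filter_efficiency, injection_Bq_per_m3, inflow_Bq_per_s}``) and optional
    ``output {points}``.
    """
    try:
        gas = cfg["gas"]
        V = float(cfg["volume_m3"])
        segments_cfg = cfg["segments"]
    except KeyError as exc:
        raise ValueError(f"config is missing required key {exc.args[0]!r}") from None
    chain = load_chain(gas)
    e1_default = float(cfg.get("inflow_Bq_per_s", 0.0))

    init = cfg.get("initial_Bq_per_m3", None)
    if init is None:
        state0 = ChainState.zeros(chain)
    elif isinstance(init, dict):
        state0 = ChainState.from_mapping(chain, {k: float(v) for k, v in init.items()})
    else:
        state0 = ChainState(np.asarray(init, dtype=float))

    segments = []
    for k, seg in enumerate(segments_cfg):
        try:
            hours = float(seg["hours"])
        except KeyError:
            raise ValueError(f"segments[{k}] is missing required key 'hours'") from None
        params = SystemParameters.with_device(
            V=V,
            E1=float(seg.get("inflow_Bq_per_s", e1_default)),
            flow_L_per_min=float(seg.get("device_flow_L_per_min", 0.0)),
            F=float(seg.get("filter_efficiency", 0.0)),
        )
        inj_cfg = seg.get("injection_Bq_per_m3", None)
        if inj_cfg is None:
            inj = None
        elif isinstance(inj_cfg, dict):
            inj = ChainState.from_mapping(
                chain, {k2: float(v) for k2, v in inj_cfg.items()}
            ).values
        else:
            inj = np.asarray(inj_cfg, dtype=float)
        segments.append(Segment(duration=hours * HOUR, params=params, injection=inj))

    out_times = None
    points = int(cfg.get("output", {}).get("points", 0))
    if points:
        total = sum(s.duration for s in segments)
        out_times = np.linspace(0.0, total, points + 1)
    return Schedule(
        chain=chain, initial_state=state0, segments=tuple(segments), output_times=out_times
    )


def schedule_to_config(schedule: Schedule) -> dict:
    """Inverse of :func:`schedule_from_config` (times in hours, flows L/min)."""
    segs = []
    for seg in schedule.segments:
        entry: dict = {
            "hours": seg.duration / HOUR,
            "device_flow_L_per_min": seg.params.Q_D * 60000.0,
            "filter_efficiency": seg.params.F,
            "inflow_Bq_per_s": seg.params.E1,
        }
        if seg.injection is not None:
            entry["injection_Bq_per_m3"] = list(map(float, seg.injection))
        segs.append(entry)
    return {
        "gas": schedule.chain.gas.name,
        "volume_m3": schedule.segments[0].params.V,
        "inflow_Bq_per_s": schedule.segments[0].params.E1,
        "initial_Bq_per_m3": list(map(float, schedule.initial_state.values)),
        "segments": segs,
        "output": {"points": len(schedule.output_times) - 1},
    }


def load_schedule(path: str | Path) -> Schedule:
    """Read a schedule config from a JSON or TOML file."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        cfg = tomllib.loads(path.read_text())
    else:
        cfg = json.loads(path.read_text())
    return schedule_from_config(cfg)
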