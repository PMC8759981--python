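"""Cooling-protocol execution and time-series analysis.

The simulated experiment mirrors the bench protocol: equilibrate the
cross-section with the pump off (stationary solve), then hold the catheter
lumen at the coolant set-point for the cooling phase, then switch the lumen
to zero-flux for the post-stoppage phase, stepping implicitly throughout.
Named probe points (by default the cord-region centroid) are sampled on a
uniform reporting interval; optional field snapshots go to VTK files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .bioheat_solver import (BoundarySpec, PennesOperator, SkinModel,
                             TemperatureField, TransientStepper)
from .geometry import LabelGrid, probe_index
from .tissue_db import BloodModel, TissueProperties

__all__ = [
    "Protocol",
    "ProbeSeries",
    "ProtocolResult",
    "PlateauResult",
    "RecoveryResult",
    "run_protocol",
    "plateau_temperature",
    "time_to_recover",
]


@dataclass(frozen=True)
class Protocol:
    """Timing and boundary settings of one cooling experiment.

    Durations in seconds; the default mirrors the reference protocol of
    30 min of cooling at a 20 degC set-point followed by 30 min with the
    pump stopped.  ``probes`` maps a name to a physical point (m) or to
    ``None`` for the canonical cord-center probe.
    """

    coolant_setpoint: float = 20.0
    cooling_duration: float = 1800.0
    stoppage_duration: float = 1800.0
    dt: float = 0.5
    report_interval: float = 10.0
    snapshot_times: tuple = ()
    probes: Mapping[str, tuple[float, float] | None] = dc_field(
        default_factory=lambda: {"cord_center": None})

    def validate(self) -> None:
        if self.cooling_duration <= 0 or self.stoppage_duration <= 0:
            raise ValueError("phase durations must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.report_interval < self.dt:
            raise ValueError("report_interval must be >= dt")
        total = self.cooling_duration + self.stoppage_duration
        for t in self.snapshot_times:
            if not 0 <= t <= total:
                raise ValueError(f"snapshot time {t} outside [0, {total}]")


@dataclass
class ProbeSeries:
    """Temperature history at one probe across both phases.

    ``times`` are seconds from the start of cooling; ``phase`` marks each
    sample 'cooling' or 'stoppage' (the sample at the switch belongs to
    cooling).  The first cooling sample equals the stationary field at the
    probe.
    """

    name: str
    times: np.ndarray
    temperatures: np.ndarray
    phase: np.ndarray
    baseline: float
    stoppage_start: float

    def phase_slice(self, phase: str) -> "ProbeSeries":
        m = self.phase == phase
        return ProbeSeries(self.name, self.times[m], self.temperatures[m],
                           self.phase[m], self.baseline, self.stoppage_start)

    def at_time(self, t: float) -> float:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-6 + 1e-9 * abs(t):
            raise KeyError(f"no sample at t = {t} s")
        return float(self.temperatures[i])


@dataclass
class ProtocolResult:
    protocol: Protocol
    series: dict[str, ProbeSeries]
    stationary: TemperatureField
    final: TemperatureField
    snapshots: list[tuple[float, Path]]

    def frame(self) -> pd.DataFrame:
        first = next(iter(self.series.values()))
        data = {"time_s": first.times, "phase": first.phase}
        for name, s in self.series.items():
            data[name] = s.temperatures
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        df = self.frame()
        df["time_s"] = df["time_s"].map(lambda v: f"{v:.3f}")
        for name in self.series:
            df[name] = df[name].map(lambda v: f"{v:.6f}")
        df.to_csv(path, index=False)


def _resolve_probes(grid: LabelGrid, probes) -> dict[str, tuple[int, int]]:
    out = {}
    for name, point in probes.items():
        out[name] = grid.cord_center() if point is None else probe_index(grid, point)
    return out


def run_protocol(grid: LabelGrid,
                 registry: Mapping[str, TissueProperties],
                 blood: BloodModel,
                 protocol: Protocol | None = None,
                 *,
                 skin: SkinModel | None = None,
                 csf_conductivity_factor: float = 1.0,
                 extra_density_factor: bool = False,
                 snapshot_dir=None,
                 log=None) -> ProtocolResult:
    """Run stationary init + cooling + stoppage and sample the probes.

    The stationary field (pump off) is the t = 0 state; the cooling-phase
    terminal field seeds the stoppage phase unchanged, matching the
    continuity of the physical experiment.
    """
    proto = protocol or Protocol()
    proto.validate()
    skin = skin or SkinModel()
    probes = _resolve_probes(grid, proto.probes)
    opts = dict(csf_conductivity_factor=csf_conductivity_factor,
                extra_density_factor=extra_density_factor)

    def say(msg):
        if log is not None:
            log(msg)

    say("stationary equilibration (pump off)")
    op0 = PennesOperator(grid, registry, blood, BoundarySpec.stoppage(skin),
                         **opts)
    stationary = op0.solve_stationary()

    snapshot_times = sorted(proto.snapshot_times)
    snapshots: list[tuple[float, Path]] = []

    def maybe_snapshot(t_abs: float, fieldvec, op):
        nonlocal snapshot_times
        if snapshot_dir is None:
            return
        while snapshot_times and t_abs >= snapshot_times[0] - 1e-9:
            t_req = snapshot_times.pop(0)
            from .vtkio import write_vtk
            path = Path(snapshot_dir) / f"snapshot_t{int(round(t_req)):05d}s.vtk"
            write_vtk(path, op.to_field(fieldvec, time=t_abs))
            snapshots.append((t_req, path))

    # reporting bookkeeping
    every = int(round(proto.report_interval / proto.dt))
    if abs(every * proto.dt - proto.report_interval) > 1e-9:
        raise ValueError("report_interval must be an integer multiple of dt")

    times: list[float] = []
    phases: list[str] = []
    samples: dict[str, list[float]] = {name: [] for name in probes}

    def record(t_abs: float, fieldvec, op, phase: str):
        times.append(t_abs)
        phases.append(phase)
        full = op.to_field(fieldvec, time=t_abs)
        for name, ij in probes.items():
            samples[name].append(full.at(ij))

    # ---- cooling phase --------------------------------------------------
    say(f"cooling phase: set-point {proto.coolant_setpoint} degC, "
        f"{proto.cooling_duration:.0f} s, dt {proto.dt} s")
    op_cool = PennesOperator(grid, registry, blood,
                             BoundarySpec.cooling(proto.coolant_setpoint, skin),
                             **opts)
    T = op_cool.to_vector(stationary)
    # impose the coolant on the lumen cells of the initial state
    T[op_cool.is_dirichlet] = proto.coolant_setpoint
    stepper = TransientStepper(op_cool, proto.dt, T_ref=op_cool.to_vector(stationary))
    record(0.0, op_cool.to_vector(stationary), op_cool, "cooling")
    maybe_snapshot(0.0, op_cool.to_vector(stationary), op_cool)
    n_cool = int(round(proto.cooling_duration / proto.dt))
    t = 0.0
    for i in range(1, n_cool + 1):
        t = i * proto.dt
        T = stepper.step(T, t)
        if i % every == 0:
            record(t, T, op_cool, "cooling")
        maybe_snapshot(t, T, op_cool)

    # ---- stoppage phase -------------------------------------------------
    say(f"stoppage phase: adiabatic lumen, {proto.stoppage_duration:.0f} s")
    op_stop = PennesOperator(grid, registry, blood, BoundarySpec.stoppage(skin),
                             lumen_pin_value=proto.coolant_setpoint, **opts)
    stepper = TransientStepper(op_stop, proto.dt, T_ref=T)
    n_stop = int(round(proto.stoppage_duration / proto.dt))
    t0 = n_cool * proto.dt
    for i in range(1, n_stop + 1):
        t = t0 + i * proto.dt
        T = stepper.step(T, t)
        if i % every == 0:
            record(t, T, op_stop, "stoppage")
        maybe_snapshot(t, T, op_stop)

    final = op_stop.to_field(T, time=t)
    series = {}
    for name in probes:
        series[name] = ProbeSeries(
            name=name,
            times=np.asarray(times),
            temperatures=np.asarray(samples[name]),
            phase=np.asarray(phases),
            baseline=float(stationary.at(probes[name])),
            stoppage_start=t0,
        )
    say("protocol complete")
    return ProtocolResult(protocol=proto, series=series, stationary=stationary,
                          final=final, snapshots=snapshots)


# ---------------------------------------------------------------------------
# series analysis

@dataclass(frozen=True)
class PlateauResult:
    temperature: float   # degC
    time: float          # s at which the rate first dropped below threshold
    converged: bool


@dataclass(frozen=True)
class RecoveryResult:
    time: float          # s after stoppage start; nan if never recovered
    recovered: bool


def plateau_temperature(series: ProbeSeries,
                        rate_threshold: float = 0.02) -> PlateauResult:
    """Temperature at which the probe's cooling response flattens.

    Scans the centered rate of change (degC/min) and returns the first
    sample *after the main transient* at which it stays below
    ``rate_threshold`` — i.e. the sample following the last
    above-threshold rate, so the quiescent lag before the cooling front
    arrives is not mistaken for the plateau.  A series whose rate never
    exceeds the threshold is already flat (first sample); one whose rate
    never drops below it returns the final value flagged not-converged.
    """
    if rate_threshold <= 0:
        raise ValueError("rate_threshold must be > 0")
    t, T = series.times, series.temperatures
    if len(t) < 3:
        raise ValueError("series must contain at least 3 samples")
    rate = np.gradient(T, t) * 60.0   # degC/min, centered differences
    above = np.nonzero(np.abs(rate) >= rate_threshold)[0]
    if len(above) == 0:
        return PlateauResult(float(T[0]), float(t[0]), True)
    i = int(above[-1]) + 1
    if i >= len(t):
        return PlateauResult(float(T[-1]), float(t[-1]), False)
    return PlateauResult(float(T[i]), float(t[i]), True)


def time_to_recover(series: ProbeSeries, baseline: float,
                    tolerance: float) -> RecoveryResult:
    """First stoppage-phase time (s after stoppage onset) at which the
    probe is within ``tolerance`` of ``baseline``."""
    stop = series.phase_slice("stoppage")
    if len(stop.times) == 0:
        raise ValueError("series has no stoppage-phase samples")
    within = np.abs(stop.temperatures - baseline) <= tolerance
    hits = np.nonzero(within)[0]
    if len(hits) == 0:
        return RecoveryResult(math.nan, False)
    return RecoveryResult(float(stop.times[hits[0]] - series.stoppage_start),
                          True)
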