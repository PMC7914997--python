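"""One-way coupling of channel transport to single-cell Ca2+ dynamics.

A chip experiment runs the transport solver once, samples the wall stimulus
{ATP(t), tau_w(t)} at each observation point (by default four positions
x = W/5 .. 4W/5 at the channel outlet z = L), integrates the Ca2+ model at
every point, and summarises each response.  Cells do not release ATP back
into the channel, so the coupling is strictly transport -> calcium, and the
two solvers keep independent time grids (the PDE step is much smaller than
the ODE output step).

The module also provides the frequency/amplitude sweep used to characterise
the channel as a chemical signal transmission line, and a classifier that
labels a Ca2+ trajectory as ``unimodal`` (single sustained rise, weak
ripple) or ``oscillatory`` (sustained oscillation, typically entrained to
the drive).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calcium import CalciumParams, CalciumTrajectory, simulate_calcium
from .io import write_field_snapshots, write_manifest
from .transport import (
    ConcentrationField,
    Grid,
    TransportParams,
    WallStimulus,
    sample_wall_stimulus,
    simulate_transport,
)
from .waveforms import (
    ChannelGeometry,
    FlowProgram,
    SinusoidalFlow,
    SteadyFlow,
    SignalMetrics,
    TimeSeries,
    signal_metrics,
)

__all__ = [
    "ExperimentConfig",
    "PointResult",
    "ChipResult",
    "Classification",
    "SweepResult",
    "default_observation_points",
    "run_chip_experiment",
    "frequency_sweep",
    "classify_response",
    "transient_cutoff",
]

_log = logging.getLogger(__name__)


def default_observation_points(geometry: ChannelGeometry) -> List[Tuple[float, float]]:
    """Four floor positions x in {W/5, 2W/5, 3W/5, 4W/5} at the outlet z=L."""
    W, L = geometry.width, geometry.length
    return [(k * W / 5.0, L) for k in (1, 2, 3, 4)]


@dataclass(frozen=True)
class ExperimentConfig:
    geometry: ChannelGeometry
    transport: TransportParams
    program: FlowProgram
    grid: Grid
    calcium: CalciumParams
    observation_points: Optional[Sequence[Tuple[float, float]]] = None
    calcium_t_end: Optional[float] = None  # defaults to grid.t_end
    calcium_output_dt: float = 0.1
    output_dir: Optional[str] = None
    oscillation_fraction: float = 0.1  # classifier threshold

    def points(self) -> List[Tuple[float, float]]:
        pts = (
            list(self.observation_points)
            if self.observation_points is not None
            else default_observation_points(self.geometry)
        )
        W, L = self.geometry.width, self.geometry.length
        for (x, z) in pts:
            if not (0 <= x <= W and 0 <= z <= L):
                raise ValueError(f"observation point ({x}, {z}) outside channel")
        return pts

    def digest(self) -> str:
        blob = repr(self).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass(frozen=True)
class Classification:
    mode: str  # "unimodal" | "oscillatory"
    oscillation_amplitude: float
    dominant_frequency: Optional[float]
    first_peak_time: Optional[float]
    amplitude_fraction_threshold: float
    transient_cutoff_s: float


@dataclass(frozen=True)
class PointResult:
    position: Tuple[float, float]
    stimulus: WallStimulus
    trajectory: CalciumTrajectory
    atp_metrics: SignalMetrics
    shear_metrics: SignalMetrics
    calcium_metrics: SignalMetrics
    classification: Classification


@dataclass(frozen=True)
class ChipResult:
    field: ConcentrationField
    points: List[PointResult]
    manifest_path: Optional[Path] = None


def transient_cutoff(t: np.ndarray, drive_period: Optional[float],
                     transient_fraction: float = 0.25) -> float:
    """Start of the analysis window: the larger of ``transient_fraction`` of
    the record and two drive periods."""
    span = t[-1] - t[0]
    cut = transient_fraction * span
    if drive_period is not None:
        cut = max(cut, 2.0 * drive_period)
    return float(t[0] + cut)


def classify_response(
    trajectory: CalciumTrajectory,
    drive_period: Optional[float] = None,
    amplitude_fraction: float = 0.1,
    transient_fraction: float = 0.25,
) -> Classification:
    """Label a Ca2+ trajectory ``oscillatory`` or ``unimodal``.

    Oscillatory iff the post-transient peak-to-peak of C exceeds
    ``amplitude_fraction`` of the trajectory's global range AND a dominant
    frequency is detected; otherwise unimodal.  The thresholds used are
    recorded in the result.
    """
    t, C = trajectory.t, trajectory.C
    cut = transient_cutoff(t, drive_period, transient_fraction)
    if drive_period is not None and t[-1] - cut < 2.0 * drive_period:
        raise ValueError(
            "trajectory too short: need at least two drive periods after the "
            "transient window"
        )
    late = C[t >= cut]
    if late.size < 4:
        raise ValueError("trajectory too short to classify")
    grange = float(C.max() - C.min())
    amp = float(late.max() - late.min())
    metrics = signal_metrics(TimeSeries(t, C), transient_fraction=transient_fraction)
    oscillatory = (
        grange > 0
        and amp > amplitude_fraction * grange
        and metrics.dominant_frequency is not None
    )
    return Classification(
        mode="oscillatory" if oscillatory else "unimodal",
        oscillation_amplitude=amp,
        dominant_frequency=metrics.dominant_frequency,
        first_peak_time=metrics.first_peak_time,
        amplitude_fraction_threshold=amplitude_fraction,
        transient_cutoff_s=cut,
    )


def _drive_period(program: FlowProgram) -> Optional[float]:
    q2 = program.q2
    return 1.0 / q2.frequency if isinstance(q2, SinusoidalFlow) else None


def run_chip_experiment(cfg: ExperimentConfig) -> ChipResult:
    """Run the full chip protocol: transport once, then per-point stimulus
    sampling, Ca2+ integration, metrics and classification; optionally write
    all artifacts plus a checksummed run manifest."""
    t0 = time.perf_counter()
    field = simulate_transport(cfg.geometry, cfg.transport, cfg.program, cfg.grid)
    _log.info("transport stage: %.2f s wall", time.perf_counter() - t0)

    period = _drive_period(cfg.program)
    t_end = cfg.calcium_t_end if cfg.calcium_t_end is not None else cfg.grid.t_end
    results: List[PointResult] = []
    for (x_obs, z_obs) in cfg.points():
        t1 = time.perf_counter()
        try:
            stim = sample_wall_stimulus(
                field, cfg.program, cfg.geometry, cfg.transport.viscosity, x_obs, z_obs
            )
            traj = simulate_calcium(
                cfg.calcium, stim, t_end=t_end, output_dt=cfg.calcium_output_dt
            )
        except Exception as exc:
            raise RuntimeError(
                f"chip experiment failed at point ({x_obs:g}, {z_obs:g})"
            ) from exc
        results.append(
            PointResult(
                position=(x_obs, z_obs),
                stimulus=stim,
                trajectory=traj,
                atp_metrics=signal_metrics(TimeSeries(stim.t, stim.atp)),
                shear_metrics=signal_metrics(TimeSeries(stim.t, stim.shear)),
                calcium_metrics=signal_metrics(TimeSeries(traj.t, traj.C)),
                classification=classify_response(
                    traj, drive_period=period,
                    amplitude_fraction=cfg.oscillation_fraction,
                ),
            )
        )
        _log.info("calcium stage at (%.2g, %.2g): %.2f s wall",
                  x_obs, z_obs, time.perf_counter() - t1)

    manifest_path = None
    if cfg.output_dir is not None:
        manifest_path = _write_chip_outputs(cfg, field, results)
    return ChipResult(field=field, points=results, manifest_path=manifest_path)


def _write_chip_outputs(cfg, field, results) -> Path:
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_field_snapshots(field, outdir / "field")
    summary = {}
    for k, pr in enumerate(results, start=1):
        tag = f"point{k}"
        pr.stimulus.to_csv(outdir / f"{tag}_stimulus.csv")
        pr.trajectory.to_csv(outdir / f"{tag}_calcium.csv")
        summary[tag] = {
            "position_m": list(pr.position),
            "atp": _metrics_dict(pr.atp_metrics),
            "shear": _metrics_dict(pr.shear_metrics),
            "calcium": _metrics_dict(pr.calcium_metrics),
            "mode": pr.classification.mode,
            "oscillation_amplitude_uM": pr.classification.oscillation_amplitude,
            "classifier_thresholds": {
                "amplitude_fraction": pr.classification.amplitude_fraction_threshold,
                "transient_cutoff_s": pr.classification.transient_cutoff_s,
            },
        }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return write_manifest(outdir, cfg.digest())


def _metrics_dict(m: SignalMetrics) -> dict:
    return {
        "mean": m.mean,
        "peak_to_peak": m.peak_to_peak,
        "dominant_frequency": m.dominant_frequency,
        "first_peak_time": m.first_peak_time,
    }


@dataclass(frozen=True)
class SweepResult:
    table: pd.DataFrame  # columns: frequency_hz, delta, peak_to_peak_uM, settled
    point: Tuple[float, float]

    def pivot(self) -> pd.DataFrame:
        return self.table.pivot(index="delta", columns="frequency_hz",
                                values="peak_to_peak_uM")


def frequency_sweep(
    cfg: ExperimentConfig,
    frequencies: Sequence[float],
    deltas: Sequence[float],
    point: Optional[Tuple[float, float]] = None,
    settle_time: float = 10.0,
    analysis_periods: int = 3,
) -> SweepResult:
    """Peak-to-peak ATP amplitude at one observation point for each
    (pulsatile frequency, pulsatile amplitude) pair.

    Each cell simulates transport for ``settle_time`` plus
    ``analysis_periods + 1`` drive periods and measures the peak-to-peak of
    the ATP series over the final ``analysis_periods`` periods.  A cell whose
    amplitude still drifts by more than 5 % between the last two periods is
    flagged ``settled=False`` rather than failing the sweep.
    """
    if point is None:
        point = cfg.points()[0]
    q2 = cfg.program.q2
    if isinstance(q2, SinusoidalFlow):
        q2_mean = q2.mean
    elif isinstance(q2, SteadyFlow):
        q2_mean = q2.value
    else:
        raise ValueError("frequency_sweep needs a steady or sinusoidal base program")

    rows = []
    for fq in frequencies:
        period = 1.0 / fq
        t_end = settle_time + (analysis_periods + 1) * period
        output_dt = min(cfg.grid.output_dt, period / 40.0)
        grid = replace(cfg.grid, t_end=t_end, output_dt=output_dt)
        for delta in deltas:
            if delta == 0.0:
                program = FlowProgram(cfg.program.q1, SteadyFlow(q2_mean))
            else:
                program = FlowProgram(
                    cfg.program.q1, SinusoidalFlow(q2_mean, delta, fq)
                )
            field = simulate_transport(cfg.geometry, cfg.transport, program, grid)
            atp = field.sample(*point)
            t = field.t
            window = t >= t_end - analysis_periods * period
            p2p = float(atp[window].max() - atp[window].min())
            last = t >= t_end - period
            prev = (t >= t_end - 2 * period) & (t < t_end - period)
            p2p_last = float(atp[last].max() - atp[last].min())
            p2p_prev = float(atp[prev].max() - atp[prev].min())
            scale = max(p2p_last, p2p_prev, 1e-6 * field.phi0)
            settled = abs(p2p_last - p2p_prev) <= 0.05 * scale
            if not settled:
                _log.warning("sweep cell fQ=%g, delta=%g not settled", fq, delta)
            rows.append(
                {
                    "frequency_hz": fq,
                    "delta": delta,
                    "peak_to_peak_uM": p2p,
                    "settled": settled,
                }
            )
    return SweepResult(table=pd.DataFrame(rows), point=point)
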