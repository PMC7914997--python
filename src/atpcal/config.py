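"""YAML experiment configuration.

A config file maps directly onto :class:`~atpcal.pipeline.ExperimentConfig`:

.. code-block:: yaml

    geometry: reference_shallow        # or {length: 1e-2, height: 5e-5, width: 1e-3}
    transport:
      diffusivity: 5.0e-10
      viscosity: 1.0e-3
      inlet_concentration: 10.0
    flow:
      q1: 1.5e-10
      q2: {kind: sinusoidal, mean: 1.5e-10, amplitude_fraction: 0.5, frequency: 0.1}
    grid: {nx: 64, nz: 256, t_end: 200.0, output_dt: 0.05}
    calcium: {k1: 0.07}                # overrides of the default profile
    calcium_output_dt: 0.1
    output_dir: results/chip

Every section is optional; omitted sections take the package defaults, which
together reproduce the reference chip protocol (shallow channel, equal mean
streams, 50 % pulsatile modulation at 0.1 Hz).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml

from .calcium import default_params
from .pipeline import ExperimentConfig
from .transport import Grid, TransportParams
from .waveforms import ChannelGeometry, FlowProgram, SinusoidalFlow, SteadyFlow

__all__ = ["chip_config", "load_config", "parse_config"]


def chip_config(
    frequency: float = 0.1,
    amplitude_fraction: float = 0.5,
    t_end: float = 200.0,
    output_dir: Optional[str] = None,
) -> ExperimentConfig:
    """The reference chip protocol: shallow channel, Q1 = mean(Q2) = 0.15 uL/s,
    sinusoidal perfusion modulation, 10 uM ATP stock."""
    return ExperimentConfig(
        geometry=ChannelGeometry.reference_shallow(),
        transport=TransportParams(),
        program=FlowProgram(
            q1=1.5e-10,
            q2=SinusoidalFlow(1.5e-10, amplitude_fraction, frequency),
        ),
        grid=Grid(nx=48, nz=160, t_end=t_end, output_dt=0.05),
        calcium=default_params(),
        output_dir=output_dir,
    )


def _parse_geometry(node) -> ChannelGeometry:
    if node is None:
        return ChannelGeometry()
    if isinstance(node, str):
        if node == "reference_shallow":
            return ChannelGeometry.reference_shallow()
        if node == "default":
            return ChannelGeometry()
        raise ValueError(f"unknown geometry preset {node!r}")
    return ChannelGeometry(**node)


def _parse_waveform(node):
    kind = node.pop("kind", "steady")
    if kind == "steady":
        return SteadyFlow(**node)
    if kind == "sinusoidal":
        return SinusoidalFlow(**node)
    raise ValueError(f"unknown waveform kind {kind!r}")


def parse_config(doc: dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a parsed YAML mapping."""
    doc = dict(doc or {})
    geometry = _parse_geometry(doc.pop("geometry", None))
    transport = TransportParams(**(doc.pop("transport", None) or {}))
    flow = dict(doc.pop("flow", None) or {})
    q1 = float(flow.pop("q1", 1.5e-10))
    q2_node = flow.pop("q2", None)
    if flow:
        raise ValueError(f"unknown flow keys: {sorted(flow)}")
    q2 = (
        _parse_waveform(dict(q2_node))
        if q2_node is not None
        else SinusoidalFlow(1.5e-10, 0.5, 0.1)
    )
    grid = Grid(**(doc.pop("grid", None) or {}))
    calcium = default_params(**(doc.pop("calcium", None) or {}))
    pts = doc.pop("observation_points", None)
    if pts is not None:
        pts = [tuple(map(float, p)) for p in pts]
    cfg = ExperimentConfig(
        geometry=geometry,
        transport=transport,
        program=FlowProgram(q1=q1, q2=q2),
        grid=grid,
        calcium=calcium,
        observation_points=pts,
        calcium_t_end=doc.pop("calcium_t_end", None),
        calcium_output_dt=float(doc.pop("calcium_output_dt", 0.1)),
        output_dir=doc.pop("output_dir", None),
        oscillation_fraction=float(doc.pop("oscillation_fraction", 0.1)),
    )
    if doc:
        raise ValueError(f"unknown config keys: {sorted(doc)}")
    return cfg


def load_config(path) -> ExperimentConfig:
    """Read a YAML experiment config from ``path``."""
    with open(Path(path)) as fh:
        doc = yaml.safe_load(fh)
    if doc is not None and not isinstance(doc, dict):
        raise ValueError("config file must contain a YAML mapping")
    return parse_config(doc or {})
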