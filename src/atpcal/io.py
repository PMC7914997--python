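"""CSV/JSON output helpers and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .transport import ConcentrationField

__all__ = ["write_field_snapshots", "write_manifest", "sha256_of"]


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_field_snapshots(
    field: ConcentrationField,
    directory,
    times: Optional[Iterable[float]] = None,
) -> list[Path]:
    """Write one CSV matrix (nx rows, nz columns) per requested snapshot time
    plus a JSON sidecar with the grid metadata.  Returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if times is None:
        times = [float(field.t[-1])]
    written = []
    for t_req in times:
        k = int(np.argmin(np.abs(field.t - t_req)))
        path = directory / f"field_t{field.t[k]:.3f}s.csv"
        np.savetxt(path, field.values[k], delimiter=",")
        written.append(path)
    sidecar = directory / "field_grid.json"
    sidecar.write_text(
        json.dumps(
            {
                "x_m": field.x.tolist(),
                "z_m": field.z.tolist(),
                "snapshot_times_s": [float(field.t[int(np.argmin(np.abs(field.t - t)))]) for t in times],
                "phi0_uM": field.phi0,
                "units": "uM",
                "layout": "rows are transverse nodes (x), columns axial nodes (z)",
            },
            indent=2,
        )
    )
    written.append(sidecar)
    return written


def write_manifest(directory, config_digest: str, extra: Optional[dict] = None) -> Path:
    """List every file in ``directory`` with its checksum so reruns can be
    compared byte-for-byte."""
    directory = Path(directory)
    files = sorted(
        p for p in directory.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config_sha256": config_digest,
        "files": {str(p.relative_to(directory)): sha256_of(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
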