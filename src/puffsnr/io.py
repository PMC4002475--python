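"""File formats: linescan TIFF/text round-trip, moment CSVs, run manifests.

Linescan images travel as single-plane TIFF (rows = space, columns = time) or
delimited text, each with a JSON sidecar ``<image>.json`` carrying the pixel
size, line period and experiment annotations; moment tables are CSV with a
fixed column order.  Every CLI run writes a manifest recording the command,
configuration, seeds and package version so seeded runs are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .linescan import LinescanImage

__all__ = ["read_linescan", "write_linescan", "save_solution",
           "load_solution", "RunManifest"]

_TIFF_SUFFIXES = {".tif", ".tiff"}
_TEXT_SUFFIXES = {".txt", ".csv", ".tsv", ".dat"}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_linescan(image: LinescanImage, path: str | Path) -> None:
    """Write an image plus its JSON metadata sidecar."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile
        tifffile.imwrite(path, image.values.astype(np.float32))
    elif path.suffix.lower() in _TEXT_SUFFIXES:
        np.savetxt(path, image.values, delimiter="\t")
    else:
        raise ParameterError(f"unsupported image format {path.suffix!r}")
    meta = {"pixel_size_um": image.pixel_size_um,
            "line_period_ms": image.line_period_ms,
            "dwell_us": image.dwell_us,
            "annotations": dict(image.annotations)}
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_linescan(path: str | Path, pixel_size_um: float | None = None,
                  line_period_ms: float | None = None,
                  annotations: dict | None = None) -> LinescanImage:
    """Load a linescan image, taking metadata from arguments or the sidecar.

    Explicit arguments win over the sidecar; a missing pixel size or line
    period raises rather than guessing.
    """
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile
        values = np.asarray(tifffile.imread(path), dtype=np.float64)
    elif path.suffix.lower() in _TEXT_SUFFIXES:
        values = np.loadtxt(path, delimiter="\t" if path.suffix != ".csv" else ",")
    else:
        raise ParameterError(f"unsupported image format {path.suffix!r}")
    if values.ndim != 2:
        raise ParameterError(f"expected a single 2-D plane, got shape {values.shape}")

    meta: dict = {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    lp = (line_period_ms if line_period_ms is not None
          else meta.get("line_period_ms"))
    if px is None or lp is None:
        raise ParameterError(
            "pixel_size_um and line_period_ms must be given as arguments or in "
            f"the sidecar {side.name}")
    ann = dict(meta.get("annotations", {}))
    ann.update(annotations or {})
    return LinescanImage(values=values, pixel_size_um=float(px),
                         line_period_ms=float(lp),
                         dwell_us=meta.get("dwell_us"), annotations=ann)


def save_solution(solution, path: str | Path) -> None:
    """Persist an RDSolution as a compressed array container (.npz)."""
    import pickle

    arrays = {"r_um": solution.r_um, "t_ms": solution.t_ms,
              "ca": solution.ca,
              "injected_um_um3": solution.injected_um_um3,
              "pumped_um_um3": solution.pumped_um_um3,
              "closing_times_ms": solution.closing_times_ms,
              "cell_volumes_um3": solution.cell_volumes_um3,
              "config_pickle": np.frombuffer(pickle.dumps(solution.config),
                                             dtype=np.uint8)}
    for name, arr in solution.bound.items():
        arrays[f"bound__{name}"] = arr
    np.savez_compressed(path, **arrays)


def load_solution(path: str | Path):
    """Load an RDSolution written by :func:`save_solution`."""
    import pickle

    from .rd import RDSolution

    with np.load(path) as z:
        bound = {k.removeprefix("bound__"): z[k]
                 for k in z.files if k.startswith("bound__")}
        return RDSolution(
            r_um=z["r_um"], t_ms=z["t_ms"], ca=z["ca"], bound=bound,
            injected_um_um3=z["injected_um_um3"],
            pumped_um_um3=z["pumped_um_um3"],
            closing_times_ms=z["closing_times_ms"],
            cell_volumes_um3=z["cell_volumes_um3"],
            config=pickle.loads(z["config_pickle"].tobytes()),
        )


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    arguments: dict
    seed: int | None
    outputs: list = field(default_factory=list)
    inputs: list = field(default_factory=list)
    package_version: str = ""
    timestamp: str = ""
    config_hash: str = ""

    def finalize(self) -> "RunManifest":
        from . import __version__
        self.package_version = __version__
        self.timestamp = datetime.now(timezone.utc).isoformat()
        payload = json.dumps({"command": self.command,
                              "arguments": self.arguments,
                              "seed": self.seed}, sort_keys=True)
        self.config_hash = hashlib.sha256(payload.encode()).hexdigest()[:16]
        return self

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self.finalize()), indent=2))
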