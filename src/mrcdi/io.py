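"""NIfTI and config I/O plus run manifests.

Volumes travel as NIfTI-1 with a diagonal (axis-aligned RAS) affine derived
from the grid geometry; oblique affines are rejected on read.  Specs and
results are JSON/YAML; tables are CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .grid import GridGeometry
from .phantom import TissueLabelVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "save_echo_series",
    "load_echo_series",
    "RunConfig",
    "load_config",
    "write_manifest",
    "ConfigError",
]


class ConfigError(ValueError):
    pass


def write_volume(path, data: np.ndarray, grid: GridGeometry) -> None:
    """Write a scalar (3-D) or vector (4-D, components last) volume as NIfTI."""
    data = np.asarray(data)
    img = nib.Nifti1Image(data, grid.affine)
    if np.issubdtype(data.dtype, np.integer):
        img.set_data_dtype(data.dtype)
    else:
        img.set_data_dtype(np.float64)
    nib.save(img, str(path))


def read_volume(path):
    """Read a NIfTI volume; returns ``(data, GridGeometry)``.

    Raises :class:`ValueError` for oblique affines (grids must be
    axis-aligned) and preserves the on-disk datatype.
    """
    img = nib.load(str(path))
    grid = GridGeometry.from_affine(img.affine, img.shape[:3])
    data = np.asarray(img.dataobj)
    return data, grid


def write_labels(path, vol: TissueLabelVolume) -> None:
    write_volume(path, vol.labels.astype(np.int16), vol.grid)


def read_labels(path) -> TissueLabelVolume:
    data, grid = read_volume(path)
    return TissueLabelVolume(labels=np.asarray(data).astype(np.int16), grid=grid)


# ---------------------------------------------------------------------------
# echo series (phase/magnitude 4-D NIfTI pair + JSON sidecar)
# ---------------------------------------------------------------------------

def save_echo_series(directory, series) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    r, e = series.phase.shape[:2]
    flat = lambda a: np.moveaxis(a.reshape((r * e,) + tuple(series.grid.shape)), 0, -1)
    write_volume(d / "phase.nii.gz", flat(series.phase), series.grid)
    write_volume(d / "magnitude.nii.gz", flat(series.magnitude), series.grid)
    sidecar = {
        "te_s": list(series.te_s),
        "tr_s": series.tr_s,
        "n_repeats": int(r),
        "polarity": [int(p) for p in series.polarity],
    }
    with open(d / "series.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def load_echo_series(directory):
    from .recon import EchoSeries

    d = Path(directory)
    with open(d / "series.json") as fh:
        side = json.load(fh)
    phase, grid = read_volume(d / "phase.nii.gz")
    mag, _ = read_volume(d / "magnitude.nii.gz")
    r = int(side["n_repeats"])
    e = len(side["te_s"])
    unflat = lambda a: np.moveaxis(np.asarray(a, float), -1, 0).reshape(
        (r, e) + tuple(grid.shape)
    )
    return EchoSeries(
        phase=unflat(phase),
        magnitude=unflat(mag),
        te_s=tuple(side["te_s"]),
        tr_s=float(side["tr_s"]),
        polarity=np.asarray(side["polarity"], float),
        grid=grid,
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_mm: float = 4.0


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    thermal_sd: float = 1.0
    phys_amplitude_T: float = 0.0
    phys_corr_length_mm: float = 30.0


class RunConfig(BaseModel):
    """Validated configuration for the experiment drivers.

    Unknown keys are rejected so that typos fail fast.
    """

    model_config = ConfigDict(extra="forbid")

    experiment: str = Field(pattern="^(loop|noise-floor|loocv)$")
    grid: GridConfig = GridConfig()
    seed: int = 0
    output_dir: str = "results"
    montage: str = "RL"
    total_current_A: float = 1e-3
    te_s: list[float] = [25.6e-3, 63.48e-3]
    tr_s: float = 0.12
    n_repeats: int = 16
    tsnr: float = 40.0
    noise: NoiseConfig = NoiseConfig()
    n_seeds: int = 10
    noise_rms_T: float = 0.3e-9
    n_subjects: int = 5
    max_evaluations: int = 80
    loop_radius_mm: float = 120.0
    loop_current_A: float = 2e-3
    slice_positions_mm: list[float] = [-20.0, -10.0, 0.0, 10.0, 20.0]
    slice_thickness_mm: float = 3.0


def load_config(path) -> RunConfig:
    p = Path(path)
    try:
        with open(p) as fh:
            raw = yaml.safe_load(fh) if p.suffix in {".yaml", ".yml"} else json.load(fh)
        return RunConfig(**(raw or {}))
    except Exception as exc:  # pydantic ValidationError, YAML/JSON errors
        raise ConfigError(f"invalid run config {path}: {exc}") from exc


def write_manifest(directory, config: dict, seed: int) -> Path:
    """Write a run manifest: config hash, seed, package versions."""
    import scipy

    from . import __version__

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=float).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {
            "mrcdi": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "nibabel": nib.__version__,
        },
    }
    out = d / "manifest.json"
    with open(out, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
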