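"""Simulation and reconstruction of MR phase measurements of B_z.

The injected current alternates polarity every repetition, so the
current-induced field adds a phase +/- gamma * TE * B_z to each echo image.
The reconstruction inverts this:

    B_z,c = (phi_plus - phi_minus) / (2 gamma TE)

computed per polarity pair with the phase difference taken as the argument of
the complex ratio (wrap-robust), averaged over pairs, and finally combined
across echoes by inverse-variance weighting with per-echo variances derived
from the temporal SNR of the magnitude images.  Any polarity-independent
phase (B0 drift, receive phase, baseline) cancels exactly.

The noise model has two ingredients emulating the empirical noise floors of
the two acquisition families: white thermal phase noise (dominant for the
fast-sampling double-echo EPI) and a spatially smooth random field redrawn
every repeat (the physiological low-frequency patterns seen with the slower
multi-gradient-echo sequence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .forward import BzField, bz_from_wire
from .grid import GridGeometry
from .phantom import TissueLabelVolume, WirePath

__all__ = [
    "GAMMA_PROTON",
    "EPI_TE_S",
    "EPI_TR_S",
    "MGRE_TE_S",
    "MGRE_TR_S",
    "BRAIN_TISSUES",
    "NoiseModel",
    "EchoSeries",
    "ReconResult",
    "physiological_noise_field",
    "default_baseline_phase",
    "simulate_echo_series",
    "reconstruct_bz_per_echo",
    "estimate_echo_variance",
    "combine_echoes",
    "reconstruct",
    "subtract_stray_field",
    "apply_mask",
    "extract_slices",
]

#: proton gyromagnetic ratio, rad / (s T)
GAMMA_PROTON = 2.6752218744e8

#: double-echo EPI acquisition defaults (seconds)
EPI_TE_S = (25.6e-3, 63.48e-3)
EPI_TR_S = 120e-3

#: multi-gradient-echo acquisition defaults (seconds)
MGRE_TE_S = (5.6e-3, 14.4e-3, 23.2e-3, 32.0e-3, 40.8e-3, 49.6e-3, 58.4e-3, 67.2e-3)
MGRE_TR_S = 80e-3

#: tissues forming the default brain mask for field metrics
BRAIN_TISSUES = ("ccsf", "gm", "wm", "vcsf")


class MaskError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters.

    thermal_sd is the phase noise (rad) of a unit-tSNR voxel; the effective
    per-image phase sd is thermal_sd / tSNR.  phys_amplitude_T is the RMS
    (over the head) of a spatially correlated field redrawn each repeat,
    emulating physiological fluctuations; phys_corr_length_mm is the distance
    at which its autocorrelation drops to exp(-1/2).
    """

    thermal_sd: float = 1.0
    phys_amplitude_T: float = 0.0
    phys_corr_length_mm: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thermal_sd < 0 or self.phys_amplitude_T < 0:
            raise ValueError("noise amplitudes must be non-negative")


@dataclass
class EchoSeries:
    """Repeated multi-echo phase/magnitude images with alternating polarity."""

    phase: np.ndarray        # (n_repeats, n_echoes, *shape), rad, wrapped
    magnitude: np.ndarray    # same shape, arbitrary units
    te_s: tuple
    tr_s: float
    polarity: np.ndarray     # (n_repeats,), +1/-1
    grid: GridGeometry

    def __post_init__(self) -> None:
        if len(self.te_s) < 1:
            raise ValueError("at least one echo time required")
        if self.phase.shape != self.magnitude.shape:
            raise ValueError("phase and magnitude series differ in shape")

    @property
    def n_repeats(self) -> int:
        return self.phase.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.phase.shape[1]


@dataclass
class ReconResult:
    bz_per_echo: list
    variance_per_echo: list
    bz_combined: BzField
    variance_combined: np.ndarray
    mask: np.ndarray | None = None


def _wrap(phase: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.angle(np.exp(1j * phase))


def physiological_noise_field(
    grid: GridGeometry,
    amplitude_T: float,
    corr_length_mm: float,
    rng,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian random field (tesla) with Gaussian autocorrelation.

    White noise is smoothed with a Gaussian kernel of standard deviation
    corr_length / sqrt(2) (so the field autocorrelation is
    exp(-d^2 / (2 L^2))) and rescaled to the requested RMS over ``mask``
    (default: everywhere).
    """
    if corr_length_mm <= 0:
        raise ValueError("correlation length must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if amplitude_T == 0:
        return np.zeros(grid.shape)
    white = rng.standard_normal(grid.shape)
    sig_vox = (corr_length_mm / np.sqrt(2.0)) / np.asarray(grid.voxel_size)
    smooth = ndimage.gaussian_filter(white, sigma=sig_vox, mode="wrap")
    sel = smooth if mask is None else smooth[mask]
    rms = float(np.sqrt(np.mean(sel**2)))
    return smooth * (amplitude_T / rms)


def default_baseline_phase(grid: GridGeometry, amplitude_rad: float = 0.5) -> np.ndarray:
    """Deterministic smooth background phase (a gentle first-order ramp)."""
    X, Y, Z = grid.coordinate_grids()
    span = max(np.ptp(X), 1.0)
    return amplitude_rad * (0.6 * X + 0.3 * Y - 0.2 * Z) / span


def simulate_echo_series(
    bz_true: BzField,
    te_s=EPI_TE_S,
    n_repeats: int = 16,
    tsnr=40.0,
    noise: NoiseModel | None = None,
    tr_s: float = EPI_TR_S,
    baseline_phase: np.ndarray | None = None,
    head_mask: np.ndarray | None = None,
) -> EchoSeries:
    """Simulate the alternating-polarity multi-echo acquisition.

    Phase at echo e, repeat k:  s_k * gamma * TE_e * (B_z + phys_k)
    + baseline + thermal noise (sd = thermal_sd / tSNR), wrapped to
    (-pi, pi].  ``tsnr`` is a scalar or map; voxels with tsnr <= 0 (outside
    the object) get zero magnitude and uniform random phase.
    """
    noise = noise or NoiseModel()
    te_s = tuple(float(t) for t in te_s)
    if sorted(te_s) != list(te_s):
        raise ValueError("echo times must be ascending")
    if n_repeats % 2:
        raise ValueError("n_repeats must be even (polarity pairs)")
    grid = bz_true.grid
    shape = tuple(grid.shape)
    tsnr_map = np.broadcast_to(np.asarray(tsnr, dtype=float), shape).copy()
    if head_mask is not None:
        tsnr_map[~head_mask] = 0.0
    inside = tsnr_map > 0
    if baseline_phase is None:
        baseline_phase = default_baseline_phase(grid)

    max_enc = max(te_s) * GAMMA_PROTON * float(np.max(np.abs(bz_true.bz)))
    if max_enc >= np.pi:
        warnings.warn(
            "gamma*TE*B_z reaches pi: phase wrapping will alias the field "
            "(the pairwise complex-ratio reconstruction handles moderate wraps)",
            stacklevel=2,
        )

    rng = np.random.default_rng(noise.seed)
    polarity = np.where(np.arange(n_repeats) % 2 == 0, 1.0, -1.0)
    phase = np.empty((n_repeats, len(te_s)) + shape)
    mag = np.empty_like(phase)
    with np.errstate(divide="ignore"):
        phase_sd = np.where(inside, noise.thermal_sd / np.where(inside, tsnr_map, 1.0), 0.0)
    for k in range(n_repeats):
        phys = (
            physiological_noise_field(
                grid, noise.phys_amplitude_T, noise.phys_corr_length_mm, rng,
                mask=inside if inside.any() else None,
            )
            if noise.phys_amplitude_T > 0
            else 0.0
        )
        field = bz_true.bz + phys
        for e, te in enumerate(te_s):
            clean = polarity[k] * GAMMA_PROTON * te * field + baseline_phase
            thermal = rng.standard_normal(shape) * phase_sd
            p = clean + thermal
            p = np.where(inside, p, rng.uniform(-np.pi, np.pi, size=shape))
            phase[k, e] = _wrap(p)
            m = np.where(inside, 1.0 + rng.standard_normal(shape) / np.where(inside, tsnr_map, 1.0), 0.0)
            mag[k, e] = m
    return EchoSeries(
        phase=phase, magnitude=mag, te_s=te_s, tr_s=tr_s, polarity=polarity, grid=grid
    )


def reconstruct_bz_per_echo(series: EchoSeries):
    """Per-echo B_z estimate and variance map.

    The wrap-safe phase difference (argument of the complex ratio of + and -
    repeats) is averaged over polarity pairs and divided by 2 gamma TE.
    """
    pos = np.where(series.polarity > 0)[0]
    neg = np.where(series.polarity < 0)[0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("series must contain both current polarities")
    n_pairs = min(len(pos), len(neg))
    bz_fields, var_maps = [], []
    for e, te in enumerate(series.te_s):
        dphi = _wrap(series.phase[pos[:n_pairs], e] - series.phase[neg[:n_pairs], e])
        bz = dphi.mean(axis=0) / (2.0 * GAMMA_PROTON * te)
        var = estimate_echo_variance(series.magnitude[:, e], te, n_pairs)
        bz_fields.append(BzField(bz=bz, grid=series.grid, provenance="measured"))
        var_maps.append(var)
    return bz_fields, var_maps


def estimate_echo_variance(
    magnitude: np.ndarray, te_s: float, n_pairs: int | None = None
) -> np.ndarray:
    """Variance (T^2) of the per-echo B_z estimate from magnitude tSNR.

    In the high-SNR regime the phase noise sd of one image is 1/tSNR, so

        var(B_z,e) = 1 / (2 n_pairs gamma^2 TE_e^2 tSNR^2).
    """
    n_rep = magnitude.shape[0]
    if n_rep < 8:
        raise ValueError("need >= 8 repeats for a stable tSNR estimate")
    if n_pairs is None:
        n_pairs = n_rep // 2
    mean = magnitude.mean(axis=0)
    sd = magnitude.std(axis=0, ddof=1)
    bad = sd == 0
    if (bad & (mean > 0)).any():
        warnings.warn(
            "zero temporal sd in magnitude series; variance floored at machine epsilon",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(bad, np.inf, mean / np.where(bad, 1.0, sd))
    var = 1.0 / (2.0 * n_pairs * GAMMA_PROTON**2 * te_s**2 * tsnr**2)
    # zero-sd (infinite tSNR) voxels: floor so inverse-variance weights stay finite
    return np.where(bad, np.finfo(float).eps, var)


def combine_echoes(bz_per_echo, variance_per_echo):
    """Voxelwise inverse-variance weighted combination across echoes."""
    if len(bz_per_echo) != len(variance_per_echo) or not bz_per_echo:
        raise ValueError("need matching, non-empty per-echo field and variance lists")
    grid = bz_per_echo[0].grid
    shape = bz_per_echo[0].bz.shape
    for f, v in zip(bz_per_echo, variance_per_echo):
        if f.bz.shape != shape or v.shape != shape:
            raise ValueError("per-echo fields and variances differ in shape")
        if np.any(v <= 0):
            raise ValueError("variances must be positive")
    w = np.stack([1.0 / v for v in variance_per_echo])
    b = np.stack([f.bz for f in bz_per_echo])
    wsum = w.sum(axis=0)
    combined = (w * b).sum(axis=0) / wsum
    return (
        BzField(bz=combined, grid=grid, provenance="measured"),
        1.0 / wsum,
    )


def reconstruct(series: EchoSeries) -> ReconResult:
    """Full reconstruction: per-echo estimates + inverse-variance combination."""
    bz_e, var_e = reconstruct_bz_per_echo(series)
    combined, var_c = combine_echoes(bz_e, var_e)
    return ReconResult(
        bz_per_echo=bz_e, variance_per_echo=var_e,
        bz_combined=combined, variance_combined=var_c,
    )


def subtract_stray_field(bz_measured: BzField, paths) -> BzField:
    """Subtract modelled lead/loop stray fields (Biot-Savart along the paths)."""
    if isinstance(paths, WirePath):
        paths = [paths]
    grid = bz_measured.grid
    pts = grid.voxel_centres()
    stray = np.zeros(grid.shape)
    for p in paths:
        stray += bz_from_wire(p, pts, eps_mm=0.1 * max(grid.voxel_size)).reshape(grid.shape)
    return BzField(bz=bz_measured.bz - stray, grid=grid, provenance="measured")


def apply_mask(field: BzField, labels: TissueLabelVolume, tissues=BRAIN_TISSUES):
    """Restrict a field to a tissue mask; values outside become NaN.

    Returns ``(masked_field, mask)``.  The default brain mask (cCSF, GM, WM,
    vCSF) excludes scalp and skull, where the MR signal is unreliable.
    """
    if tuple(labels.grid.shape) != tuple(field.grid.shape):
        raise ValueError("field and label volume are on different grids")
    mask = labels.tissue_mask(tissues)
    if not mask.any():
        raise MaskError(f"mask over tissues {tuple(tissues)} is empty")
    data = np.where(mask, field.bz, np.nan)
    return BzField(bz=data, grid=field.grid, provenance=field.provenance), mask


def extract_slices(
    field: BzField, slice_positions_mm, thickness_mm: float, axis: int = 2
):
    """Through-thickness slab averages of the field at given axial positions."""
    grid = field.grid
    ax = grid.axes()[axis]
    out = []
    for pos in slice_positions_mm:
        lo, hi = pos - thickness_mm / 2.0, pos + thickness_mm / 2.0
        sel = np.where((ax >= lo - 1e-9) & (ax <= hi + 1e-9))[0]
        if len(sel) == 0:
            near = int(np.argmin(np.abs(ax - pos)))
            if not (ax[0] - grid.voxel_size[axis] / 2 <= pos <= ax[-1] + grid.voxel_size[axis] / 2):
                raise ValueError(f"slice position {pos} mm is outside the grid")
            sel = np.array([near])
        sl = [slice(None)] * 3
        sl[axis] = sel
        out.append(np.nanmean(field.bz[tuple(sl)], axis=axis))
    return out
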