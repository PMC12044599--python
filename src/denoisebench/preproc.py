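"""Minimal preprocessing shared by every processing condition.

Three steps, in order: spatial Gaussian smoothing (mask-renormalized),
grand-mean scaling of the within-scan spatiotemporal mean to a fixed target,
and Gaussian-weighted running-line temporal high-pass filtering.  The
temporal filter is exposed as a reusable operator so that the exact same
filter applied to voxel series is also applied to every nuisance series
before regression (the filter-parity contract: variance removed from the
data must not be re-introduced by unfiltered regressors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .types import BoldVolume, MotionTrace

__all__ = [
    "PreprocConfig",
    "smooth_spatial",
    "grand_mean_scale",
    "temporal_filter",
    "apply_minimal",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PreprocConfig:
    """Minimal-preprocessing parameters.

    ``smooth_fwhm_mm``: spatial Gaussian kernel FWHM in mm (0 disables).
    ``grand_mean``: target for the within-scan mean over all in-mask voxels
    and time points (``None`` disables scaling).
    ``temporal_fwhm_s``: FWHM in seconds of the Gaussian running-line
    high-pass (``None`` disables filtering).
    """

    smooth_fwhm_mm: float = 6.0
    grand_mean: float | None = 10000.0
    temporal_fwhm_s: float | None = 125.0

    def __post_init__(self) -> None:
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be >= 0")
        if self.grand_mean is not None and self.grand_mean <= 0:
            raise ValueError("grand_mean must be positive")
        if self.temporal_fwhm_s is not None and self.temporal_fwhm_s <= 0:
            raise ValueError("temporal_fwhm_s must be positive")


def smooth_spatial(vol: BoldVolume, fwhm_mm: float) -> BoldVolume:
    """Per-volume 3D Gaussian smoothing with brain-mask renormalization.

    The kernel SD per axis is ``fwhm / (2 sqrt(2 ln 2))`` divided by the
    voxel size.  Voxels outside the mask are treated as missing (zero-padded
    and renormalized by the smoothed mask) so the brain rim is not darkened
    by averaging with background zeros.  ``fwhm=0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return vol.copy_with(vol.data.copy())
    sigma_vox = tuple(
        fwhm_mm * _FWHM_TO_SIGMA / vs for vs in vol.grid.voxel_size
    )
    mask = vol.mask.astype(float)
    norm = ndimage.gaussian_filter(mask, sigma_vox)
    masked = vol.data * mask[..., None]
    out = ndimage.gaussian_filter(masked, sigma=(*sigma_vox, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm[..., None] > 1e-12, out / np.maximum(norm, 1e-12)[..., None], 0.0)
    out *= vol.mask[..., None]
    return vol.copy_with(out)


def grand_mean_scale(vol: BoldVolume, target: float) -> BoldVolume:
    """Scale so the mean over all in-mask voxels and time points is ``target``."""
    current = vol.data[vol.mask].mean()
    if not np.isfinite(current) or current <= 0:
        raise ValueError(f"in-mask mean must be positive, got {current}")
    return vol.copy_with(vol.data * (target / current))


def temporal_filter(series: np.ndarray, tr: float, fwhm_s: float) -> np.ndarray:
    """Gaussian-weighted running-line high-pass along the last axis.

    At each time point a local line is fitted under Gaussian weights with SD
    ``fwhm_s / (2 sqrt(2 ln 2))`` seconds; the fitted trend is subtracted
    and the series mean re-added, so slow drifts are removed while the
    overall intensity level (and any grand-mean scaling) is preserved.  The
    kernel is truncated at the series boundaries and the fit renormalized,
    so a purely linear trend is removed exactly everywhere.
    """
    if fwhm_s is None or fwhm_s <= 0:
        raise ValueError("fwhm_s must be positive")
    series = np.asarray(series, dtype=float)
    T = series.shape[-1]
    if T < 3:
        raise ValueError("need at least 3 time points")
    sigma_frames = fwhm_s * _FWHM_TO_SIGMA / tr
    half = int(np.ceil(4 * sigma_frames))
    half = min(half, T - 1)
    if half < 1:
        half = 1
    k = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-0.5 * (k / sigma_frames) ** 2)

    def corr(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
        return ndimage.correlate1d(x, kernel, axis=-1, mode="constant", cval=0.0)

    ones = np.ones(T)
    s0 = corr(ones, w)
    s1 = corr(ones, w * k)
    s2 = corr(ones, w * k * k)
    m0 = corr(series, w)
    m1 = corr(series, w * k)
    denom = s0 * s2 - s1 * s1
    denom = np.where(np.abs(denom) < 1e-30, 1e-30, denom)
    fitted = (s2 * m0 - s1 * m1) / denom
    resid = series - fitted
    # restore the original temporal mean exactly (keeps grand-mean scaling)
    mean = series.mean(axis=-1, keepdims=True)
    return resid - resid.mean(axis=-1, keepdims=True) + mean


def make_temporal_filter(tr: float, fwhm_s: float | None) -> Callable[[np.ndarray], np.ndarray]:
    """Return the exact temporal-filter operator for confound-parity use."""
    if fwhm_s is None:
        return lambda x: np.asarray(x, dtype=float)
    return lambda x: temporal_filter(np.asarray(x, dtype=float).T, tr, fwhm_s).T


@dataclass
class ConfoundSource:
    """The filtered confound source produced by minimal preprocessing.

    ``vol`` is the grand-mean-scaled, temporally filtered but *unsmoothed*
    volume from which data-derived nuisance signals (GS, WM, CSF means,
    anatomical principal components) are extracted — nuisance extraction
    upstream of spatial smoothing keeps thin tissue compartments free of
    smeared gray-matter signal.  ``temporal_filter`` is the exact operator
    applied to the voxel series; it must be applied to every externally
    supplied confound column (motion parameters) before regression so the
    filter-parity contract holds.
    """

    vol: BoldVolume
    temporal_filter: Callable[[np.ndarray], np.ndarray]


def _scale_and_filter(vol: BoldVolume, cfg: PreprocConfig) -> BoldVolume:
    out = vol
    if cfg.grand_mean is not None:
        out = grand_mean_scale(out, cfg.grand_mean)
    if cfg.temporal_fwhm_s is not None:
        data = out.data.copy()
        data[out.mask] = temporal_filter(out.data[out.mask], vol.grid.tr, cfg.temporal_fwhm_s)
        out = out.copy_with(data)
    elif out is vol:
        out = vol.copy_with(vol.data.copy())
    return out


def apply_minimal(
    vol: BoldVolume,
    motion: MotionTrace | None = None,
    cfg: PreprocConfig | None = None,
) -> tuple[BoldVolume, ConfoundSource]:
    """Run the shared minimal preprocessing.

    Returns the processed volume (smoothed, scaled, filtered) and the
    :class:`ConfoundSource`: the unsmoothed scaled+filtered twin plus the
    temporal-filter operator.  Any filter applied to the voxel series is
    applied identically to every nuisance series before regression.
    """
    if cfg is None:
        cfg = PreprocConfig()
    if motion is not None and motion.n_volumes != vol.n_volumes:
        raise ValueError(
            f"motion trace has {motion.n_volumes} rows but volume has "
            f"{vol.n_volumes} time points"
        )
    out = _scale_and_filter(smooth_spatial(vol, cfg.smooth_fwhm_mm), cfg)
    source = ConfoundSource(
        vol=_scale_and_filter(vol, cfg),
        temporal_filter=make_temporal_filter(vol.grid.tr, cfg.temporal_fwhm_s),
    )
    return out, source
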