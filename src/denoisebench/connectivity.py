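"""Atlas-based BOLD extraction and functional-connectivity representations.

Two FC views are computed from ROI-mean time series: the time-domain Pearson
correlation matrix, and time-frequency wavelet coherence split into a
low-frequency band (0.01-0.1 Hz, presumed neural) and a high-frequency band
(above 0.1 Hz up to Nyquist, presumed noise-dominated).  Coherence uses the
analytic Morlet wavelet (center frequency 6) with 12 voices per octave and a
standard smoothed-cross-spectrum estimator; cells inside the cone of
influence (edge-contaminated) are excluded from all band averages.

Band-averaged coherence for every ROI pair is computed in one vectorized
pass (:func:`band_coherence_matrices`), so each pair's coherence field is
evaluated once and reused for both bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .types import BoldVolume, Parcellation

__all__ = [
    "RoiTimeSeries",
    "FCMatrix",
    "BandDifferenceMatrix",
    "CoherenceField",
    "extract_roi_series",
    "pearson_fc",
    "wavelet_coherence",
    "band_average",
    "band_coherence_matrices",
    "coherence_difference_matrix",
    "LF_BAND",
]

#: Low-frequency band in Hz; the high-frequency band is (0.1, Nyquist].
LF_BAND = (0.01, 0.1)

MORLET_OMEGA0 = 6.0
VOICES_PER_OCTAVE = 12
TIME_SMOOTH_FACTOR = 0.6  # boxcar length as a fraction of the wavelet scale
SCALE_SMOOTH_OCTAVES = 1.0


@dataclass
class RoiTimeSeries:
    """ROI-mean BOLD series: ``data`` is (T, R), aligned with ``roi_ids``."""

    data: np.ndarray
    roi_ids: list[int]
    networks: list[str | None]
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.roi_ids):
            raise ValueError("ROI series must be (T, R) matching roi_ids")

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class FCMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    roi_ids: list[int]
    networks: list[str | None]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        self.values = v


@dataclass
class BandDifferenceMatrix:
    """Symmetric pre-minus-post band-averaged coherence differences."""

    values: np.ndarray
    band: str  # "LF" or "HF"
    roi_ids: list[int]
    networks: list[str | None]

    def __post_init__(self) -> None:
        if self.band not in ("LF", "HF"):
            raise ValueError("band tag must be 'LF' or 'HF'")
        v = np.asarray(self.values, dtype=float)
        np.fill_diagonal(v, 0.0)
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("difference matrix must be symmetric")
        self.values = v


def extract_roi_series(
    vol: BoldVolume, parc: Parcellation, exclude: tuple[int, ...] = ()
) -> RoiTimeSeries:
    """Unweighted voxel-mean BOLD series per ROI, optionally excluding ids."""
    if vol.data.shape[:3] != parc.labels.shape:
        raise ValueError("volume and parcellation grids do not match")
    ids = [i for i in parc.roi_ids if i not in set(exclude)]
    cols = []
    for roi_id in ids:
        mask = (parc.labels == roi_id) & vol.mask
        if not mask.any():
            raise ValueError(f"ROI {roi_id} ({parc.roi_names[roi_id]}) has no in-mask voxels")
        cols.append(vol.data[mask].mean(axis=0))
    return RoiTimeSeries(
        data=np.column_stack(cols),
        roi_ids=ids,
        networks=[parc.network_of.get(i) for i in ids],
        tr=vol.grid.tr,
    )


def pearson_fc(ts: RoiTimeSeries) -> FCMatrix:
    """Time-domain Pearson FC matrix of the ROI series."""
    sd = ts.data.std(axis=0)
    if np.any(sd == 0):
        bad = [ts.roi_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant ROI series: {bad}")
    r = np.corrcoef(ts.data.T)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(values=r, roi_ids=list(ts.roi_ids), networks=list(ts.networks))


# ---------------------------------------------------------------------------
# wavelet coherence


def _coherence_grid(T: int, tr: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frequency axis, pywt scales, and COI half-widths (in samples)."""
    fmin = 2.0 / (T * tr)
    fmax = 0.5 / tr
    n_octaves = np.log2(fmax / fmin)
    n_scales = int(np.ceil(n_octaves * VOICES_PER_OCTAVE)) + 1
    freqs = np.geomspace(fmax, fmin, n_scales)  # high to low, matching scales
    center = MORLET_OMEGA0 / (2.0 * np.pi)
    scales = center / (freqs * tr)
    # Morlet cone of influence: e-folding time sqrt(2)*s with the standard
    # scale-frequency relation s = (w0 + sqrt(2 + w0^2)) / (4 pi f)
    w0 = MORLET_OMEGA0
    coi_seconds = np.sqrt(2.0) * (w0 + np.sqrt(2.0 + w0**2)) / (4.0 * np.pi * freqs)
    coi_samples = coi_seconds / tr
    return freqs, scales, coi_samples


def _wavelet_name() -> str:
    # complex Morlet exp(i*w0*t) exp(-t^2/2): pywt cmorB-C with B=2, C=w0/(2pi)
    return f"cmor2.0-{MORLET_OMEGA0 / (2.0 * np.pi):.12f}"


def _cwt_all(series: np.ndarray, tr: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CWT of (T, R) series -> (R, S, T) coefficients, freqs, scales."""
    T = series.shape[0]
    freqs, scales, _ = _coherence_grid(T, tr)
    # demean: the sampled wavelet is only approximately zero-mean, so a DC
    # offset would otherwise leak into the coarsest scales
    x = np.ascontiguousarray((series - series.mean(axis=0)).T)  # (R, T)
    coefs, _ = pywt.cwt(x, scales, _wavelet_name(), method="fft", axis=-1)
    # pywt returns (S, R, T); reorder to (R, S, T)
    return np.moveaxis(coefs, 0, 1), freqs, scales


def _smooth_field(field: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Smoothing operator: per-scale boxcar in time, then boxcar in scale.

    ``field`` has scale on axis -2 and time on axis -1; complex input is
    smoothed component-wise.
    """
    out = np.empty_like(field)
    for si, s in enumerate(scales):
        size = max(1, int(round(TIME_SMOOTH_FACTOR * s)))
        sl = (..., si, slice(None))
        if np.iscomplexobj(field):
            out[sl] = ndimage.uniform_filter1d(
                field[sl].real, size, axis=-1, mode="nearest"
            ) + 1j * ndimage.uniform_filter1d(field[sl].imag, size, axis=-1, mode="nearest")
        else:
            out[sl] = ndimage.uniform_filter1d(field[sl], size, axis=-1, mode="nearest")
    width = max(1, int(round(SCALE_SMOOTH_OCTAVES * VOICES_PER_OCTAVE)))
    if np.iscomplexobj(out):
        out = ndimage.uniform_filter1d(out.real, width, axis=-2, mode="nearest") + (
            1j * ndimage.uniform_filter1d(out.imag, width, axis=-2, mode="nearest")
        )
    else:
        out = ndimage.uniform_filter1d(out, width, axis=-2, mode="nearest")
    return out


def _smooth_stack(fields: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Smooth a real (N, S, T) stack: per-scale boxcar in time, boxcar in scale."""
    out = np.empty_like(fields)
    for si, s in enumerate(scales):
        size = max(1, int(round(TIME_SMOOTH_FACTOR * s)))
        out[:, si, :] = ndimage.uniform_filter1d(fields[:, si, :], size, axis=-1, mode="nearest")
    width = max(1, int(round(SCALE_SMOOTH_OCTAVES * VOICES_PER_OCTAVE)))
    return ndimage.uniform_filter1d(out, width, axis=-2, mode="nearest")


def _coi_mask(T: int, coi_samples: np.ndarray) -> np.ndarray:
    """Boolean (S, T) mask of cells *outside* the cone of influence (valid)."""
    t = np.arange(T)
    return (t[None, :] >= coi_samples[:, None]) & (t[None, :] <= T - 1 - coi_samples[:, None])


@dataclass
class CoherenceField:
    """Time-frequency coherence of one pair of series."""

    values: np.ndarray  # (S, T) in [0, 1]
    freqs: np.ndarray  # Hz, high to low
    valid: np.ndarray  # (S, T) True outside the cone of influence


def wavelet_coherence(x: np.ndarray, y: np.ndarray, tr: float) -> CoherenceField:
    """Wavelet coherence of two series via smoothed Morlet cross-spectra.

    Coherence is |smoothed cross-spectrum|^2 normalized by the product of
    the smoothed auto-spectra, bounded in [0, 1]; the frequency axis spans
    2/(T*tr) up to Nyquist.  Constant inputs are rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input series")
    if tr <= 0:
        raise ValueError("tr must be positive")
    series = np.column_stack([x, y])
    W, freqs, scales = _cwt_all(series, tr)
    auto = _smooth_field(np.abs(W) ** 2, scales)
    cross = _smooth_field(W[0] * np.conj(W[1]), scales)
    denom = np.maximum(auto[0] * auto[1], 1e-300)
    coh = np.clip(np.abs(cross) ** 2 / denom, 0.0, 1.0)
    _, _, coi = _coherence_grid(series.shape[0], tr)
    return CoherenceField(values=coh, freqs=freqs, valid=_coi_mask(series.shape[0], coi))


def band_average(field: CoherenceField, band: tuple[float, float], closed_low: bool = True) -> float:
    """Mean over all in-band, in-cone (time, frequency) cells."""
    lo, hi = band
    in_band = ((field.freqs >= lo) if closed_low else (field.freqs > lo)) & (field.freqs <= hi)
    cells = field.valid & in_band[:, None]
    if not cells.any():
        raise ValueError(f"no valid cells in band {band}")
    return float(field.values[cells].mean())


def band_coherence_matrices(
    ts: RoiTimeSeries, bands: dict[str, tuple[float, float]] | None = None
) -> dict[str, np.ndarray]:
    """Band-averaged wavelet coherence for every ROI pair, vectorized.

    Returns one symmetric (R, R) matrix per band with unit diagonal.  The
    CWT of each ROI and the smoothed auto-spectra are computed once; pair
    cross-spectra are evaluated in chunks, and each pair's coherence field
    is reduced to every requested band in the same pass.
    """
    tr = ts.tr
    nyq = 0.5 / tr
    if bands is None:
        bands = {"LF": LF_BAND, "HF": (LF_BAND[1], nyq)}
    sd = ts.data.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant ROI series cannot enter coherence")
    T, R = ts.data.shape
    W, freqs, scales = _cwt_all(ts.data, tr)  # (R, S, T)
    auto = _smooth_stack((np.abs(W) ** 2).astype(np.float32), scales)
    valid = _coi_mask(T, _coherence_grid(T, tr)[2])

    band_cells = {}
    for name, (lo, hi) in bands.items():
        closed_low = name != "HF"  # HF band is open at its lower edge
        in_band = ((freqs >= lo) if closed_low else (freqs > lo)) & (freqs <= hi)
        cells = valid & in_band[:, None]
        if not cells.any():
            raise ValueError(f"no valid cells in band {name}={lo, hi}")
        band_cells[name] = cells

    out = {name: np.eye(R) for name in bands}
    iu, ju = np.triu_indices(R, k=1)
    chunk = max(1, int(4_000_000 // (W.shape[1] * W.shape[2])))
    for start in range(0, iu.size, chunk):
        ii = iu[start : start + chunk]
        jj = ju[start : start + chunk]
        cross = W[ii] * np.conj(W[jj])
        stack = np.concatenate([cross.real, cross.imag]).astype(np.float32)
        smoothed = _smooth_stack(stack, scales)
        p = ii.size
        cross_pow = smoothed[:p] ** 2 + smoothed[p:] ** 2
        denom = np.maximum(auto[ii] * auto[jj], 1e-30)
        coh = np.clip(cross_pow / denom, 0.0, 1.0)  # (chunk, S, T)
        for name, cells in band_cells.items():
            vals = coh[:, cells].mean(axis=1)
            out[name][ii, jj] = vals
            out[name][jj, ii] = vals
    return out


def coherence_difference_matrix(
    pre_ts: RoiTimeSeries, post_ts: RoiTimeSeries, band: str
) -> BandDifferenceMatrix:
    """Pre-minus-post band-averaged coherence for every ROI pair."""
    if pre_ts.data.shape != post_ts.data.shape:
        raise ValueError("pre and post ROI series have different shapes")
    if band not in ("LF", "HF"):
        raise ValueError("band must be 'LF' or 'HF'")
    pre = band_coherence_matrices(pre_ts)[band]
    post = band_coherence_matrices(post_ts)[band]
    diff = pre - post
    np.fill_diagonal(diff, 0.0)
    return BandDifferenceMatrix(
        values=diff, band=band, roi_ids=list(pre_ts.roi_ids), networks=list(pre_ts.networks)
    )
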