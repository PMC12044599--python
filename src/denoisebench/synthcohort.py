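"""Synthetic resting-state fMRI cohort generator.

Builds everything the benchmark needs with no external data: a phantom
anatomy (tissue classes + blocky ROI parcels assigned to seven resting-state
networks), realistic head-motion traces, structured noise (slow drift,
aliased physiological oscillations, a global low-frequency fluctuation,
white system noise, and motion-coupled intensity artifacts), and a planted
band-limited network signal whose within-network correlation is controlled.

Every generator is a pure function of its parameters and a seed.  Random
streams are split per component (motion / drift / physiological / global /
system / motion-coupling / signal) so changing one amplitude never perturbs
another component's draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .types import (
    CSF,
    EDGE,
    GM,
    NETWORKS,
    WM,
    AcquisitionGrid,
    BoldVolume,
    MotionTrace,
    Parcellation,
    TissueLabelMap,
)

__all__ = [
    "MotionParams",
    "NoiseParams",
    "CohortParams",
    "make_phantom",
    "simulate_motion",
    "simulate_noise",
    "noise_components",
    "simulate_network_signal",
    "compose_subject",
    "simulate_subject",
    "generate_cohort",
]

MIN_ROI_VOXELS = 8


# ---------------------------------------------------------------------------
# parameter schemas


@dataclass(frozen=True)
class MotionParams:
    """Random-walk head-motion model.

    The walk takes Gaussian steps per frame, kept within bounds by
    reflection at the limits; "high" severity adds sparse large
    repositioning jumps.  ``spike_threshold_mm`` is the FD level above which a frame
    counts as a motion spike (a common scrubbing convention).
    """

    step_trans_mm: float = 0.02
    step_rot_rad: float = 2.0e-4
    spike_prob: float = 0.0
    spike_trans_mm: float = 0.7
    bound_trans_mm: float = 2.0
    bound_rot_rad: float = 0.02
    spike_threshold_mm: float = 0.5

    @staticmethod
    def preset(severity: str) -> "MotionParams":
        if severity == "low":
            return MotionParams()
        if severity == "high":
            return MotionParams(step_trans_mm=0.04, step_rot_rad=4.0e-4, spike_prob=0.04)
        raise ValueError(f"unknown motion severity {severity!r}")


@dataclass(frozen=True)
class NoiseParams:
    """Amplitudes and rates of the structured-noise model.

    Amplitudes are fractions of the baseline intensity (so 0.01 means a
    component with temporal SD equal to 1% of baseline at a typical voxel).
    Physiological oscillations are generated at their true rates and sampled
    at TR, so aliasing into the low-frequency band arises naturally.
    """

    baseline: float = 1000.0
    drift_amp: float = 0.01
    physio_amp: float = 0.005
    global_lf_amp: float = 0.01
    system_amp: float = 0.01
    motion_gain: float = 0.5
    resp_hz: float = 0.3
    cardiac_hz: float = 1.23
    csf_physio_factor: float = 3.0
    gm_global_weight: float = 0.25  # WM/CSF share of the GM-dominant global
    fd_ref_mm: float = 0.1  # displacement producing a 1% change at unit gain
    drift_max_hz: float = 0.005

    def __post_init__(self) -> None:
        for name in ("drift_amp", "physio_amp", "global_lf_amp", "system_amp", "motion_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")


@dataclass(frozen=True)
class CohortParams:
    """Everything needed to generate one synthetic cohort."""

    grid: AcquisitionGrid = AcquisitionGrid()
    n_rois: int = 14
    rho: float = 0.8
    snr: float = 1.0
    band: tuple[float, float] = (0.01, 0.1)
    target_networks: tuple[str, ...] = NETWORKS
    high_motion_fraction: float = 0.5
    noise: NoiseParams = field(default_factory=NoiseParams)


# ---------------------------------------------------------------------------
# phantom anatomy


def make_phantom(
    grid: AcquisitionGrid, n_rois: int = 14, seed: int = 0
) -> tuple[TissueLabelMap, Parcellation]:
    """Build a phantom anatomy: tissue classes plus a blocky GM parcellation.

    The brain is an ellipsoid filling the grid; its one-voxel rim is the
    brain-edge class, a central block is CSF (a ventricle stand-in)
    surrounded by a WM core, and the remaining shell is GM.  GM voxels are
    partitioned into ``n_rois`` contiguous blocky parcels, each assigned to
    one of the seven resting-state networks round-robin.

    The construction is deterministic; ``seed`` is accepted for interface
    uniformity with the other generators.
    """
    del seed  # construction is fully deterministic
    if n_rois < len(NETWORKS):
        raise ValueError(
            f"n_rois must be >= {len(NETWORKS)} (one per network), got {n_rois}"
        )
    nx, ny, nz = grid.dims
    center = (np.array(grid.dims) - 1) / 2.0
    radii = np.maximum(np.array(grid.dims) / 2.0 - 1.0, 1.0)
    xx, yy, zz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    dist2 = (
        ((xx - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((zz - center[2]) / radii[2]) ** 2
    )
    brain = dist2 <= 1.0

    interior = ndimage.binary_erosion(brain)
    edge = brain & ~interior

    labels = np.zeros(grid.dims, dtype=np.int16)
    labels[edge] = EDGE

    # central CSF block with a WM core around it, both inside the interior
    csf_half = max(1, min(nx, ny, nz) // 12)
    wm_half = csf_half + max(1, min(nx, ny, nz) // 10)
    ci = np.round(center).astype(int)

    def _block(half: int) -> np.ndarray:
        m = np.zeros(grid.dims, dtype=bool)
        sl = tuple(slice(max(0, c - half), c + half + 1) for c in ci)
        m[sl] = True
        return m

    csf_mask = _block(csf_half) & interior
    wm_mask = _block(wm_half) & interior & ~csf_mask
    gm_mask = interior & ~csf_mask & ~wm_mask
    labels[wm_mask] = WM
    labels[csf_mask] = CSF
    labels[gm_mask] = GM

    n_gm = int(gm_mask.sum())
    if n_gm < n_rois * MIN_ROI_VOXELS:
        raise ValueError(
            f"grid too small: {n_gm} GM voxels cannot host {n_rois} ROIs of "
            f">= {MIN_ROI_VOXELS} voxels each"
        )
    if csf_mask.sum() == 0 or wm_mask.sum() == 0:
        raise ValueError("grid too small to place WM and CSF compartments")

    # blocky parcels: chunk GM voxels in raster order into contiguous slabs
    coords = np.argwhere(gm_mask)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    coords = coords[order]
    bounds = np.linspace(0, n_gm, n_rois + 1).astype(int)
    parc_labels = np.zeros(grid.dims, dtype=np.int16)
    roi_names: dict[int, str] = {}
    network_of: dict[int, str | None] = {}
    for k in range(n_rois):
        chunk = coords[bounds[k] : bounds[k + 1]]
        roi_id = k + 1
        parc_labels[chunk[:, 0], chunk[:, 1], chunk[:, 2]] = roi_id
        net = NETWORKS[k % len(NETWORKS)]
        roi_names[roi_id] = f"ROI_{roi_id:03d}"
        network_of[roi_id] = net

    tissue = TissueLabelMap(labels=labels)
    parc = Parcellation(labels=parc_labels, roi_names=roi_names, network_of=network_of)
    return tissue, parc


# ---------------------------------------------------------------------------
# motion


def simulate_motion(
    T: int,
    severity: str = "low",
    seed: int = 0,
    params: MotionParams | None = None,
) -> MotionTrace:
    """Simulate a bounded random-walk realignment trace.

    High severity adds sparse large repositioning jumps, so mean framewise
    displacement is higher in expectation than for low severity.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if params is None:
        params = MotionParams.preset(severity)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    steps = np.empty((T, 6))
    steps[:, :3] = rng.normal(0.0, params.step_trans_mm or 0.0, size=(T, 3)) if params.step_trans_mm else 0.0
    steps[:, 3:] = rng.normal(0.0, params.step_rot_rad or 0.0, size=(T, 3)) if params.step_rot_rad else 0.0
    steps[0] = 0.0
    if params.spike_prob > 0:
        spikes = rng.random((T, 6)) < params.spike_prob
        spikes[0] = False
        jumps = rng.normal(0.0, params.spike_trans_mm, size=(T, 6))
        jumps[:, 3:] /= 50.0  # rotations jump on the 50 mm sphere scale
        steps = steps + spikes * jumps
    walk = np.cumsum(steps, axis=0)
    # reflect at the bounds: clamping would freeze a parameter and leave its
    # temporal derivative degenerate (single-spike, collinear with its square)
    walk[:, :3] = _reflect(walk[:, :3], params.bound_trans_mm)
    walk[:, 3:] = _reflect(walk[:, 3:], params.bound_rot_rad)
    return MotionTrace(params=walk)


def _reflect(x: np.ndarray, bound: float) -> np.ndarray:
    """Fold values into [-bound, bound] by reflection at the boundaries."""
    if bound <= 0:
        return np.zeros_like(x)
    period = 4.0 * bound
    y = np.mod(x + bound, period)
    return np.where(y <= 2.0 * bound, y - bound, 3.0 * bound - y)


def _fd_series(motion: MotionTrace, radius_mm: float = 50.0) -> np.ndarray:
    """FD per frame with a leading zero (frame 0 has no predecessor)."""
    d = np.diff(motion.params, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


# ---------------------------------------------------------------------------
# noise


def _smooth_map(rng: np.random.Generator, dims: tuple[int, int, int], sigma_vox: float = 2.0) -> np.ndarray:
    """Zero-mean, unit-SD spatially smooth random map."""
    m = ndimage.gaussian_filter(rng.standard_normal(dims), sigma_vox)
    m -= m.mean()
    sd = m.std()
    return m / sd if sd > 0 else m


def _bandlimited_series(
    rng: np.random.Generator, T: int, tr: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-SD series whose spectral support lies inside ``band`` (Hz)."""
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError(f"band {band} contains no resolvable frequency bins")
    coef = np.zeros(freqs.size, dtype=complex)
    n = int(keep.sum())
    coef[keep] = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    x = np.fft.irfft(coef, n=T)
    x -= x.mean()
    return x / x.std()


def noise_components(
    grid: AcquisitionGrid,
    tissue: TissueLabelMap,
    motion: MotionTrace,
    params: NoiseParams | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Generate each noise component separately as a ``(x, y, z, t)`` array.

    Components (all scaled by their amplitude times baseline, zero outside
    the brain):

    - ``drift``: a slow scanner trend, band-limited below ``drift_max_hz``
      (default 0.005 Hz), with a smooth spatial gain.
    - ``physio``: respiratory (~0.3 Hz) and cardiac (~1.2 Hz) sinusoids
      generated at true rates and sampled at TR (aliasing naturally into the
      low-frequency band); CSF voxels get an elevated amplitude.
    - ``global_lf``: a band-limited (0.01-0.1 Hz) global fluctuation, the
      arousal/vascular confound that global-signal regression targets;
      expressed mainly in gray matter (as the global signal is in vivo),
      with a reduced weight in WM/CSF.
    - ``system``: white Gaussian scanner noise.
    - ``motion``: intensity deviations coupled to head motion, with a global
      FD-proportional term plus spatially patterned terms linear in the
      motion-parameter increments (rotations scaled to mm on a 50 mm
      sphere); displacements are normalized by ``fd_ref_mm`` so unit gain
      means a 1% intensity change per reference displacement.

    Each component draws from its own child random stream, so amplitudes can
    be changed independently without perturbing the other components.
    """
    if params is None:
        params = NoiseParams()
    if motion.n_volumes != grid.n_volumes:
        raise ValueError("motion trace length does not match grid n_volumes")
    streams = np.random.SeedSequence(seed).spawn(5)
    rng_drift, rng_physio, rng_global, rng_system, rng_motion = (
        np.random.default_rng(s) for s in streams
    )
    T = grid.n_volumes
    t = grid.times
    brain = tissue.brain.astype(float)
    base = params.baseline
    out: dict[str, np.ndarray] = {}

    # drift: slow band-limited trend, smooth spatial gain around 1
    trend = _bandlimited_series(rng_drift, T, grid.tr, (1e-9, params.drift_max_hz))
    gain = 1.0 + 0.3 * _smooth_map(rng_drift, grid.dims)
    out["drift"] = (
        params.drift_amp * base * (brain * gain)[..., None] * trend[None, None, None, :]
    )

    # physiological: true-rate sinusoids sampled at TR
    phase_r, phase_c = rng_physio.uniform(0, 2 * np.pi, size=2)
    physio_t = np.sin(2 * np.pi * params.resp_hz * t + phase_r) + np.sin(
        2 * np.pi * params.cardiac_hz * t + phase_c
    )
    amp_map = brain.copy()
    amp_map[tissue.csf] = params.csf_physio_factor
    out["physio"] = params.physio_amp * base * amp_map[..., None] * physio_t[None, None, None, :]

    # global low-frequency fluctuation, GM-dominant as the global signal is
    g = _bandlimited_series(rng_global, T, grid.tr, (0.01, 0.1))
    g_map = brain.copy()
    g_map[tissue.wm | tissue.csf] = params.gm_global_weight
    out["global_lf"] = params.global_lf_amp * base * g_map[..., None] * g[None, None, None, :]

    # system: white Gaussian noise
    out["system"] = (
        params.system_amp * base * brain[..., None] * rng_system.standard_normal((*grid.dims, T))
    )

    # motion coupling: global FD term + MP-increment terms with smooth maps
    fd = _fd_series(motion)
    deltas = np.vstack([np.zeros(6), np.diff(motion.params, axis=0)])
    deltas[:, 3:] *= 50.0  # radians -> mm on a 50 mm sphere
    maps = np.stack([_smooth_map(rng_motion, grid.dims) for _ in range(6)], axis=-1)
    mp_part = np.einsum("xyzi,ti->xyzt", maps, deltas)
    motion_dev = (fd[None, None, None, :] + mp_part) / params.fd_ref_mm
    out["motion"] = params.motion_gain * 0.01 * base * brain[..., None] * motion_dev

    return out


def simulate_noise(
    grid: AcquisitionGrid,
    tissue: TissueLabelMap,
    motion: MotionTrace,
    params: NoiseParams | None = None,
    seed: int = 0,
) -> BoldVolume:
    """Sum the structured-noise components over the baseline intensity."""
    if params is None:
        params = NoiseParams()
    comps = noise_components(grid, tissue, motion, params, seed)
    brain = tissue.brain
    data = params.baseline * brain.astype(float)[..., None] * np.ones(grid.n_volumes)
    for comp in comps.values():
        data = data + comp
    return BoldVolume(data=data, grid=grid, mask=brain)


# ---------------------------------------------------------------------------
# planted network signal


def simulate_network_signal(
    parc: Parcellation,
    target_networks: set[str] | tuple[str, ...],
    rho: float,
    band: tuple[float, float] = (0.01, 0.1),
    T: int = 200,
    tr: float = 2.5,
    seed: int = 0,
    grid: AcquisitionGrid | None = None,
) -> BoldVolume:
    """Plant band-limited coherent activity in the requested networks.

    Each target network gets its own latent band-limited source; its ROIs
    receive ``sqrt(rho) * latent + sqrt(1 - rho) * private`` so the expected
    pairwise within-network correlation is approximately ``rho``.  ROIs
    outside the target networks receive independent band-limited series.
    Non-GM voxels are zero.
    """
    if not (0.0 < rho < 1.0):
        raise ValueError("rho must be in (0, 1)")
    if grid is None:
        grid = AcquisitionGrid(dims=parc.labels.shape, tr=tr, n_volumes=T)
    nyq = 1.0 / (2.0 * tr)
    if not (0.0 < band[0] < band[1] <= nyq + 1e-12):
        raise ValueError(f"band {band} must lie within (0, Nyquist={nyq:.4g}]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    targets = set(target_networks)

    latents = {net: _bandlimited_series(rng, T, tr, band) for net in sorted(targets)}
    data = np.zeros((*parc.labels.shape, T))
    for roi_id in parc.roi_ids:
        net = parc.network_of.get(roi_id)
        private = _bandlimited_series(rng, T, tr, band)
        if net in targets:
            series = np.sqrt(rho) * latents[net] + np.sqrt(1.0 - rho) * private
        else:
            series = private
        data[parc.labels == roi_id] = series
    mask = parc.labels > 0
    return BoldVolume(data=data, grid=grid, mask=mask)


def compose_subject(signal: BoldVolume, noise: BoldVolume, snr: float) -> BoldVolume:
    """Combine noise and signal, scaling signal to the requested SNR.

    ``snr`` is defined as the ratio of pooled gray-matter temporal standard
    deviations (signal component vs. noise component), measured over the
    voxels carrying planted signal (``signal.mask``).
    """
    if signal.grid != noise.grid:
        raise ValueError("signal and noise grids do not match")
    if snr < 0:
        raise ValueError("snr must be non-negative")
    if snr == 0:
        return noise.copy_with(noise.data.copy())
    gm = signal.mask
    sd_sig = _pooled_temporal_sd(signal.data[gm])
    sd_noise = _pooled_temporal_sd(noise.data[gm])
    if sd_sig == 0:
        raise ValueError("signal component has zero temporal variance in GM")
    scale = snr * sd_noise / sd_sig
    return noise.copy_with(noise.data + scale * signal.data)


def _pooled_temporal_sd(series: np.ndarray) -> float:
    """SD pooled over voxels: sqrt of the mean temporal variance."""
    return float(np.sqrt(np.var(series, axis=-1).mean()))


# ---------------------------------------------------------------------------
# cohort assembly


def simulate_subject(
    tissue: TissueLabelMap,
    parc: Parcellation,
    grid: AcquisitionGrid,
    severity: str,
    seed: int,
    params: CohortParams,
) -> tuple[BoldVolume, MotionTrace]:
    """Generate one subject's BOLD volume and motion trace in memory."""
    motion = simulate_motion(grid.n_volumes, severity, seed=_child_seed(seed, 0))
    noise = simulate_noise(grid, tissue, motion, params.noise, seed=_child_seed(seed, 1))
    signal = simulate_network_signal(
        parc,
        params.target_networks,
        rho=params.rho,
        band=params.band,
        T=grid.n_volumes,
        tr=grid.tr,
        seed=_child_seed(seed, 2),
        grid=grid,
    )
    bold = compose_subject(signal, noise, params.snr)
    return bold, motion


def _child_seed(seed: int, index: int) -> int:
    """Stable 31-bit child seed for stage ``index`` of subject ``seed``."""
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(index,)).generate_state(1)[0] % (2**31))


def generate_cohort(
    n_subjects: int,
    params: CohortParams | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Generate a cohort and (optionally) write it to disk.

    One phantom anatomy is shared by the whole cohort so parcel identity is
    fixed across subjects; subjects alternate between low- and high-motion
    acquisitions according to ``high_motion_fraction``.  Returns a manifest
    dict; when ``out_dir`` is given, BOLD NIfTI volumes, motion TSVs, the
    shared tissue/parcellation label maps and the manifest JSON are written
    there, and regeneration from the manifest is byte-identical.
    """
    from . import fileio  # local import to keep generator importable standalone

    if params is None:
        params = CohortParams()
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    tissue, parc = make_phantom(params.grid, params.n_rois, seed=seed)
    n_high = int(round(n_subjects * params.high_motion_fraction))
    severities = ["high"] * n_high + ["low"] * (n_subjects - n_high)

    manifest: dict = {
        "seed": int(seed),
        "n_subjects": int(n_subjects),
        "params": _params_to_dict(params),
        "subjects": [],
    }
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        fileio.write_label_map(tissue.labels, params.grid, out_path / "tissue.nii")
        fileio.write_label_map(parc.labels, params.grid, out_path / "parcellation.nii")
        fileio.write_parcellation_tables(parc, out_path / "parcellation.json")

    for i in range(n_subjects):
        subj_seed = _child_seed(seed, 1000 + i)
        severity = severities[i]
        entry = {
            "id": f"sub-{i + 1:03d}",
            "seed": subj_seed,
            "severity": severity,
            "bold": f"sub-{i + 1:03d}_bold.nii",
            "motion": f"sub-{i + 1:03d}_motion.tsv",
        }
        if out_path is not None:
            bold, motion = simulate_subject(tissue, parc, params.grid, severity, subj_seed, params)
            fileio.write_bold(bold, out_path / entry["bold"])
            fileio.write_motion_tsv(motion, out_path / entry["motion"])
        manifest["subjects"].append(entry)

    if out_path is not None:
        with open(out_path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest


def _params_to_dict(params: CohortParams) -> dict:
    d = dataclasses.asdict(params)
    d["grid"] = dataclasses.asdict(params.grid)
    d["noise"] = dataclasses.asdict(params.noise)
    d["target_networks"] = list(params.target_networks)
    return d


def params_from_dict(d: dict) -> CohortParams:
    """Inverse of the manifest serialization of :class:`CohortParams`."""
    grid = AcquisitionGrid(
        dims=tuple(d["grid"]["dims"]),
        voxel_size=tuple(d["grid"]["voxel_size"]),
        tr=d["grid"]["tr"],
        n_volumes=d["grid"]["n_volumes"],
    )
    noise = NoiseParams(**d["noise"])
    return CohortParams(
        grid=grid,
        n_rois=d["n_rois"],
        rho=d["rho"],
        snr=d["snr"],
        band=tuple(d["band"]),
        target_networks=tuple(d["target_networks"]),
        high_motion_fraction=d["high_motion_fraction"],
        noise=noise,
    )
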