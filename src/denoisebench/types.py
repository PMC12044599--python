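"""Core in-memory containers shared across the package.

All spatial arrays are indexed ``(x, y, z)`` with 0-based voxel indices; 4D
BOLD data adds time as the last axis, ``(x, y, z, t)``.  Frequencies are in
Hz, translations in mm, rotations in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Tissue label codes used throughout the package.
BACKGROUND = 0
GM = 1
WM = 2
CSF = 3
EDGE = 4  # one-voxel rim of the brain mask

#: The seven resting-state networks the benchmark assigns ROIs to.
NETWORKS = (
    "basal ganglia",
    "CEN",
    "DMN",
    "motor",
    "salience",
    "visual",
    "auditory",
)


@dataclass(frozen=True)
class AcquisitionGrid:
    """Geometry and timing of an fMRI acquisition.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along x, y, z.
    voxel_size : tuple of float
        Voxel edge length per axis, in mm.
    tr : float
        Repetition time in seconds.
    n_volumes : int
        Number of time points (volumes).
    """

    dims: tuple[int, int, int] = (16, 16, 16)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tr: float = 2.5
    n_volumes: int = 200

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) <= 0 for d in self.dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in Hz, 1 / (2 * tr)."""
        return 1.0 / (2.0 * self.tr)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, ``0, tr, 2*tr, ...``."""
        return np.arange(self.n_volumes) * self.tr

    @property
    def affine(self) -> np.ndarray:
        """Diagonal voxel-to-world affine for NIfTI output."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff


@dataclass
class TissueLabelMap:
    """Per-voxel tissue classes: background, GM, WM, CSF and brain-edge rim."""

    labels: np.ndarray  # (x, y, z) integer array of tissue codes

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("tissue labels must be a 3D array")
        bad = set(np.unique(self.labels)) - {BACKGROUND, GM, WM, CSF, EDGE}
        if bad:
            raise ValueError(f"unknown tissue codes: {sorted(bad)}")

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    @property
    def gm(self) -> np.ndarray:
        return self.mask(GM)

    @property
    def wm(self) -> np.ndarray:
        return self.mask(WM)

    @property
    def csf(self) -> np.ndarray:
        return self.mask(CSF)

    @property
    def edge(self) -> np.ndarray:
        return self.mask(EDGE)

    @property
    def brain(self) -> np.ndarray:
        """Whole-brain mask: every non-background voxel."""
        return self.labels != BACKGROUND


@dataclass
class Parcellation:
    """Per-voxel ROI labels plus ROI naming and network assignment.

    ``labels`` holds integer ROI ids, 0 meaning "no ROI".  Every nonzero id
    must have a name; ``network_of`` maps ids to one of :data:`NETWORKS` or
    ``None`` for ROIs outside any canonical network.
    """

    labels: np.ndarray
    roi_names: dict[int, str]
    network_of: dict[int, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.roi_names)
        if missing:
            raise ValueError(f"ROI ids without names: {sorted(missing)}")

    @property
    def roi_ids(self) -> list[int]:
        """Sorted nonzero ROI ids, the canonical ROI ordering."""
        return sorted(self.roi_names)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def networks_by_index(self) -> list[str | None]:
        """Network label per ROI, aligned with :attr:`roi_ids`."""
        return [self.network_of.get(i) for i in self.roi_ids]


@dataclass
class MotionTrace:
    """Rigid-body realignment parameters over time.

    ``params`` is ``(T, 6)``: columns 0-2 translations (mm), 3-5 rotations
    (radians), the fMRIPrep column convention
    (trans_x, trans_y, trans_z, rot_x, rot_y, rot_z).
    """

    params: np.ndarray

    COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be a (T, 6) array")
        if self.params.shape[0] < 2:
            raise ValueError("motion trace needs at least 2 time points")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters must be finite")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class BoldVolume:
    """A 4D BOLD acquisition: voxel intensities plus grid and brain mask."""

    data: np.ndarray  # (x, y, z, t)
    grid: AcquisitionGrid
    mask: np.ndarray  # (x, y, z) boolean, in-brain voxels

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.data.shape[:3] != tuple(self.grid.dims):
            raise ValueError(
                f"spatial shape {self.data.shape[:3]} does not match grid "
                f"{self.grid.dims}"
            )
        if self.data.shape[3] != self.grid.n_volumes:
            raise ValueError(
                f"time axis {self.data.shape[3]} does not match grid "
                f"n_volumes {self.grid.n_volumes}"
            )
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match data")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data must be finite")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def in_mask(self) -> np.ndarray:
        """In-brain voxel series as a ``(n_voxels, T)`` view-like array."""
        return self.data[self.mask]

    def copy_with(self, data: np.ndarray) -> "BoldVolume":
        return BoldVolume(data=np.asarray(data, dtype=float), grid=self.grid, mask=self.mask)
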