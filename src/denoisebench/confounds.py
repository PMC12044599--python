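"""Nuisance-regressor construction for every denoising strategy.

Covers motion-parameter expansions (6/12/24 columns), mean tissue signals
(global, white-matter, CSF), anatomical component-based correction
(principal components of WM/CSF voxel series), and ICA-based automatic
motion-artifact removal: a spatial ICA decomposition, four per-component
features (edge fraction, CSF fraction, high-frequency content, maximum
realignment-parameter correlation), a rule-based noise classifier, and
nonaggressive removal of the noise components.

Temporal degrees-of-freedom accounting: every column of a confound matrix
costs one tDOF; for ICA-based removal the cost is the number of
noise-classified components, which varies across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .types import BoldVolume, MotionTrace, TissueLabelMap

__all__ = [
    "ConfoundMatrix",
    "IcaComponentSet",
    "ComponentFeatures",
    "expand_motion",
    "tissue_signals",
    "acompcor",
    "spatial_ica",
    "aroma_features",
    "classify_aroma",
    "nonaggressive_remove",
    "AROMA_HYPERPLANE",
]

#: Linear decision boundary in (max RP correlation, edge fraction) space,
#: taken from the original ICA-AROMA classifier: a component is noise when
#: ``b0 + b1 * max_rp_correlation + b2 * edge_fraction > 0``.
AROMA_HYPERPLANE = (-19.9751070082159, 9.95127547670627, 24.8333160239175)


@dataclass
class ConfoundMatrix:
    """Named T x K nuisance-regressor matrix with tDOF accounting."""

    values: np.ndarray
    names: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("confound matrix must be 2D (T, K)")
        if self.values.shape[1] != len(self.names):
            raise ValueError("column count does not match number of names")

    @property
    def tdof_cost(self) -> int:
        """One temporal degree of freedom per regressor column."""
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @staticmethod
    def concat(parts: list["ConfoundMatrix"]) -> "ConfoundMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        T = parts[0].n_timepoints
        if any(p.n_timepoints != T for p in parts):
            raise ValueError("confound matrices have inconsistent lengths")
        return ConfoundMatrix(
            values=np.hstack([p.values for p in parts]),
            names=[n for p in parts for n in p.names],
            source="+".join(p.source for p in parts),
        )


# ---------------------------------------------------------------------------
# motion expansions


def _backward_diff(x: np.ndarray) -> np.ndarray:
    """Backward differences with first row zero (keeps T rows)."""
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


def expand_motion(motion: MotionTrace, scheme: str = "mp24") -> ConfoundMatrix:
    """Expand realignment parameters into an mp6 / mp12 / mp24 design.

    Column order is fixed: the 6 parameters; then (mp24 only) their squares;
    then the 6 backward-difference temporal derivatives; then (mp24 only)
    the squared derivatives.  Zero-variance columns (e.g. derivatives of a
    constant trace) are dropped with a warning since they carry no
    regressable variance.
    """
    base = motion.params
    names6 = list(MotionTrace.COLUMNS)
    deriv = _backward_diff(base)
    if scheme == "mp6":
        cols, names = [base], [names6]
    elif scheme == "mp12":
        cols = [base, deriv]
        names = [names6, [f"{n}_derivative1" for n in names6]]
    elif scheme == "mp24":
        cols = [base, base**2, deriv, deriv**2]
        names = [
            names6,
            [f"{n}_power2" for n in names6],
            [f"{n}_derivative1" for n in names6],
            [f"{n}_derivative1_power2" for n in names6],
        ]
    else:
        raise ValueError(f"unknown motion expansion scheme {scheme!r}")
    values = np.hstack(cols)
    all_names = [n for group in names for n in group]
    keep = values.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(all_names, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance motion regressors: {dropped}",
            stacklevel=2,
        )
        values = values[:, keep]
        all_names = [n for n, k in zip(all_names, keep) if k]
    return ConfoundMatrix(values=values, names=all_names, source=scheme)


# ---------------------------------------------------------------------------
# tissue mean signals


_TISSUE_ATTR = {"GS": "brain", "WM": "wm", "CSF": "csf"}


def tissue_signals(
    vol: BoldVolume, tissue: TissueLabelMap, which: tuple[str, ...] = ("GS", "WM", "CSF")
) -> ConfoundMatrix:
    """Mean-signal regressors: global (whole brain), WM and/or CSF means."""
    cols = []
    names = []
    for key in which:
        if key not in _TISSUE_ATTR:
            raise ValueError(f"unknown tissue signal {key!r}; use GS, WM or CSF")
        mask = getattr(tissue, _TISSUE_ATTR[key]) if key != "GS" else vol.mask
        if not mask.any():
            raise ValueError(f"tissue class for {key} is empty")
        cols.append(vol.data[mask].mean(axis=0))
        names.append(f"mean_{key.lower()}")
    return ConfoundMatrix(values=np.column_stack(cols), names=names, source="tissue")


# ---------------------------------------------------------------------------
# aCompCor


def acompcor(
    vol: BoldVolume,
    tissue: TissueLabelMap,
    n_components: int = 5,
    csf_only: bool = False,
) -> ConfoundMatrix:
    """Principal components of WM and CSF voxel series.

    Voxel series from the union of the WM and CSF masks are temporally
    demeaned and variance-normalized, and the leading principal component
    time series are returned in descending explained-variance order
    (mutually orthogonal by construction).  ``csf_only=True`` reproduces the
    known fMRIPrep/HALFpipe behavior of drawing components exclusively from
    the CSF mask; the default uses the intended WM+CSF union.
    """
    mask = tissue.csf if csf_only else (tissue.wm | tissue.csf)
    series = vol.data[mask]  # (V, T)
    nz = series.std(axis=1) > 0
    series = series[nz]
    if series.shape[0] <= n_components:
        raise ValueError(
            f"need more than {n_components} non-constant WM/CSF voxels, "
            f"got {series.shape[0]}"
        )
    series = series - series.mean(axis=1, keepdims=True)
    series = series / series.std(axis=1, keepdims=True)
    # PCA of the T x V matrix via SVD; U columns are component time series
    u, s, _ = np.linalg.svd(series.T, full_matrices=False)
    comps = u[:, :n_components] * np.sign(u[:, :n_components].sum(axis=0) + 1e-300)
    names = [f"a_comp_cor_{i:02d}" for i in range(n_components)]
    return ConfoundMatrix(values=comps, names=names, source="acompcor")


# ---------------------------------------------------------------------------
# spatial ICA and the AROMA-style classifier


@dataclass
class IcaComponentSet:
    """Spatial-ICA decomposition of a BOLD volume.

    ``maps`` holds the spatial maps over in-mask voxels (components x
    voxels); ``mixing`` the component time series (T x components), ordered
    by descending explained variance.
    """

    maps: np.ndarray
    mixing: np.ndarray
    mask: np.ndarray
    mean: np.ndarray = field(repr=False, default=None)  # voxel temporal means

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def map_volume(self, index: int) -> np.ndarray:
        out = np.zeros(self.mask.shape)
        out[self.mask] = self.maps[index]
        return out


def spatial_ica(
    vol: BoldVolume, n_components: int = 20, seed: int = 0, tol: float = 1e-3
) -> IcaComponentSet:
    """Spatial ICA (whitening + fixed-point rotation) of a BOLD volume.

    Decomposes the in-mask data into statistically independent spatial maps
    and their mixing time series, deterministic given ``seed``.  Components
    are canonicalized (descending explained variance, positive map skew) so
    repeated runs agree up to numerical noise.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    X = vol.data[vol.mask]  # (V, T)
    V, T = X.shape
    if n_components >= min(T, V):
        raise ValueError(
            f"n_components={n_components} must be < min(T={T}, voxels={V})"
        )
    mean_t = X.mean(axis=1, keepdims=True)
    Xc = X - mean_t
    ica = FastICA(
        n_components=n_components,
        random_state=int(seed) % (2**31),
        whiten="unit-variance",
        max_iter=1000,
        tol=tol,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        maps = ica.fit_transform(Xc)  # (V, n): independent spatial sources
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            raise RuntimeError(
                f"spatial ICA did not converge within {ica.max_iter} iterations"
            )
    mixing = ica.mixing_  # (T, n)
    # canonicalize: positive map skew, descending explained variance
    signs = np.sign(np.sum(maps**3, axis=0))
    signs[signs == 0] = 1.0
    maps = maps * signs
    mixing = mixing * signs
    power = (mixing**2).sum(axis=0) * (maps**2).sum(axis=0)
    order = np.argsort(power)[::-1]
    return IcaComponentSet(
        maps=maps[:, order].T, mixing=mixing[:, order], mask=vol.mask, mean=mean_t[:, 0]
    )


@dataclass(frozen=True)
class ComponentFeatures:
    """The four AROMA classification features of one ICA component."""

    edge_fraction: float
    csf_fraction: float
    hf_content: float
    max_rp_correlation: float

    def __post_init__(self) -> None:
        for name in ("edge_fraction", "csf_fraction", "hf_content", "max_rp_correlation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 + 1e-9):
                raise ValueError(f"{name}={v} outside [0, 1]")


def aroma_features(
    comps: IcaComponentSet,
    index: int,
    tissue: TissueLabelMap,
    motion: MotionTrace,
    tr: float,
) -> ComponentFeatures:
    """Compute the four noise-classification features for one component.

    - edge fraction: share of the map's absolute weight in the brain-edge rim;
    - CSF fraction: analogous share inside CSF;
    - high-frequency content: the frequency at which the cumulative power
      spectrum of the mixing series reaches 50%, as a fraction of Nyquist;
    - max RP correlation: maximum absolute correlation between the mixing
      series and the 6 realignment parameters plus their derivatives.
    """
    if comps.mask.shape != tissue.labels.shape:
        raise ValueError("component maps and tissue map are on different grids")
    amap = np.abs(comps.maps[index])
    total = amap.sum()
    if total == 0:
        raise ValueError("component map is identically zero")
    edge_in_mask = tissue.edge[comps.mask]
    csf_in_mask = tissue.csf[comps.mask]
    edge_fraction = float(amap[edge_in_mask].sum() / total)
    csf_fraction = float(amap[csf_in_mask].sum() / total)

    ts = comps.mixing[:, index]
    if ts.std() == 0:
        raise ValueError("mixing time series has zero power")
    freqs, pxx = sp_signal.periodogram(ts - ts.mean(), fs=1.0 / tr)
    pxx = pxx[freqs > 0]
    freqs = freqs[freqs > 0]
    cum = np.cumsum(pxx) / pxx.sum()
    f50 = freqs[np.searchsorted(cum, 0.5)]
    hf_content = float(min(f50 / (0.5 / tr), 1.0))

    rp = np.hstack([motion.params, _backward_diff(motion.params)])
    rp_sd = rp.std(axis=0)
    usable = rp_sd > 0
    if usable.any():
        tsz = (ts - ts.mean()) / ts.std()
        rpz = (rp[:, usable] - rp[:, usable].mean(axis=0)) / rp_sd[usable]
        corrs = np.abs(tsz @ rpz) / len(ts)
        max_rp = float(min(corrs.max(), 1.0))
    else:
        max_rp = 0.0
    return ComponentFeatures(
        edge_fraction=edge_fraction,
        csf_fraction=csf_fraction,
        hf_content=hf_content,
        max_rp_correlation=max_rp,
    )


def classify_aroma(
    f: ComponentFeatures,
    csf_threshold: float = 0.10,
    hf_threshold: float = 0.35,
    hyperplane: tuple[float, float, float] = AROMA_HYPERPLANE,
) -> bool:
    """Rule-based motion-component classification.

    A component is noise when it meets at least one of: CSF fraction above
    10%, high-frequency content above 35%, or the point (max RP correlation,
    edge fraction) lying on the noise side of the fixed linear decision
    boundary.  Monotone: increasing any feature never flips noise -> signal.
    """
    if f.csf_fraction > csf_threshold:
        return True
    if f.hf_content > hf_threshold:
        return True
    b0, b1, b2 = hyperplane
    return bool(b0 + b1 * f.max_rp_correlation + b2 * f.edge_fraction > 0)


def nonaggressive_remove(
    vol: BoldVolume, comps: IcaComponentSet, noise_ids: set[int] | list[int]
) -> BoldVolume:
    """Remove noise components while sparing shared signal variance.

    Each voxel series is regressed on *all* mixing time series jointly (with
    an intercept) and only the fitted contribution of the noise-classified
    components is subtracted, so variance shared between signal and noise
    components is preserved.
    """
    noise_ids = sorted(set(int(i) for i in noise_ids))
    if any(i < 0 or i >= comps.n_components for i in noise_ids):
        raise ValueError("noise_ids outside component range")
    if not noise_ids:
        return vol.copy_with(vol.data.copy())
    Y = vol.data[vol.mask].T  # (T, V)
    X = np.column_stack([np.ones(Y.shape[0]), comps.mixing])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("joint mixing design is singular; components are collinear")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    noise_cols = [i + 1 for i in noise_ids]  # offset for intercept
    fitted_noise = X[:, noise_cols] @ beta[noise_cols]
    out = vol.data.copy()
    out[vol.mask] = (Y - fitted_noise).T
    return vol.copy_with(out)
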