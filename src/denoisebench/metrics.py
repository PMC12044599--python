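"""Per-subject, per-pipeline data-quality metrics.

Noise-sensitive: the FD-DVARS correlation (residual motion) and the
high-frequency coherence destroyed by denoising.  Network-sensitive: signed
Louvain modularity of the Pearson connectome, and the functional
connectivity contrast (FCC) — the Wilcoxon rank-sum Z separating
within-network from between-network edges — in its time-based and
frequency-based forms.  Signal-sensitive: the fraction of low-frequency
BOLD power preserved, and the temporal-degrees-of-freedom loss.

Motion-bias diagnostics correlate each metric with per-subject mean FD.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sp_signal
from scipy import stats

from .connectivity import BandDifferenceMatrix, FCMatrix, RoiTimeSeries
from .types import BoldVolume, MotionTrace

__all__ = [
    "framewise_displacement",
    "dvars",
    "fd_dvars_metric",
    "hf_fc_content",
    "modularity",
    "signed_modularity_matrix",
    "partition_quality",
    "rank_sum_z",
    "fcc_time",
    "fcc_frequency",
    "lf_bold_content",
    "tdof_loss",
    "bias_correlation",
    "METRIC_NAMES",
]

METRIC_NAMES = (
    "fd_dvars",
    "hf_fc_content",
    "modularity",
    "fcc_time",
    "fcc_freq",
    "lf_bold_content",
    "tdof_loss",
)


def framewise_displacement(motion: MotionTrace, radius_mm: float = 50.0) -> np.ndarray:
    """FD per frame transition: sum of absolute backward differences of the
    six realignment parameters, rotations converted to displacements on a
    sphere of ``radius_mm``.  Returns T-1 values aligned to frames 2..T."""
    d = np.diff(motion.params, axis=0)
    return np.abs(d[:, :3]).sum(axis=1) + radius_mm * np.abs(d[:, 3:]).sum(axis=1)


def dvars(vol: BoldVolume) -> np.ndarray:
    """Spatial RMS of the temporally differentiated in-mask voxel series."""
    if not vol.mask.any():
        raise ValueError("empty brain mask")
    series = vol.data[vol.mask]  # (V, T)
    d = np.diff(series, axis=1)
    return np.sqrt((d**2).mean(axis=0))


def fd_dvars_metric(fd: np.ndarray, dv: np.ndarray) -> float:
    """Pearson correlation of the FD and DVARS series (frames 2..T).

    Lower |r| means less residual motion coupling.  Returns NaN (flagged
    missing) when either series is constant.
    """
    fd = np.asarray(fd, dtype=float)
    dv = np.asarray(dv, dtype=float)
    if fd.shape != dv.shape or fd.size < 3:
        raise ValueError("FD and DVARS must be equal-length series of >= 3 frames")
    if fd.std() == 0 or dv.std() == 0:
        warnings.warn("constant FD or DVARS series; FD-DVARS undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(fd, dv)[0, 1])


def hf_fc_content(diff: BandDifferenceMatrix) -> float:
    """Mean of the strict upper triangle of the HF pre-minus-post matrix."""
    if diff.band != "HF":
        raise ValueError(f"expected an HF difference matrix, got {diff.band}")
    iu = np.triu_indices_from(diff.values, k=1)
    return float(diff.values[iu].mean())


# ---------------------------------------------------------------------------
# signed-network modularity (Louvain)


def signed_modularity_matrix(w: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """Modularity matrix for a signed weighted network.

    Positive and negative weights get separate null models with asymmetric
    weighting: the positive part is normalized by the total positive weight
    and the negative part by the total weight of both signs, so negative
    edges influence but never dominate the partition quality.
    """
    w = np.asarray(w, dtype=float)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    wp = np.clip(w, 0.0, None)
    wn = np.clip(-w, 0.0, None)
    vp = wp.sum()
    vn = wn.sum()
    if vp == 0 and vn == 0:
        raise ValueError("all-zero connectivity matrix")
    b = np.zeros_like(w)
    if vp > 0:
        kp = wp.sum(axis=1)
        b += (wp - gamma * np.outer(kp, kp) / vp) / vp
    if vn > 0:
        kn = wn.sum(axis=1)
        b -= (wn - gamma * np.outer(kn, kn) / vn) / (vp + vn)
    return b


def partition_quality(b: np.ndarray, labels: np.ndarray) -> float:
    """Q of a partition: sum of modularity-matrix entries within communities."""
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    return float(b[same].sum())


def _louvain_once(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One greedy run: randomized node sweeps plus community merges.

    Maintains per-community row sums incrementally (``m[:, c]`` is the sum
    of ``b`` columns over community ``c``), so each candidate evaluation is
    O(n) and a move costs one column update.
    """
    n = b.shape[0]
    labels = np.arange(n)
    m = b.copy()  # community slot c holds node c initially
    counts = np.ones(n, dtype=int)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            cur = labels[i]
            gains = m[i].copy()
            gains[cur] -= b[i, i]
            gains[counts == 0] = -np.inf
            best = int(np.argmax(gains))
            if best != cur and gains[best] > gains[cur] + 1e-12:
                m[:, cur] -= b[:, i]
                m[:, best] += b[:, i]
                counts[cur] -= 1
                counts[best] += 1
                labels[i] = best
                improved = True
        # merge sweep on the aggregated community matrix
        active = np.flatnonzero(counts > 0)
        if active.size > 1:
            onehot = np.zeros((n, active.size))
            for ci, c in enumerate(active):
                onehot[labels == c, ci] = 1.0
            agg = onehot.T @ m[:, active]
            merged = True
            while merged and active.size > 1:
                merged = False
                off = agg - np.diag(np.diag(agg))
                a, c2 = np.unravel_index(np.argmax(off), off.shape)
                if a != c2 and off[a, c2] > 1e-12:
                    ca, cb = active[a], active[c2]
                    members = labels == cb
                    labels[members] = ca
                    m[:, ca] += m[:, cb]
                    m[:, cb] = 0.0
                    counts[ca] += counts[cb]
                    counts[cb] = 0
                    agg[a] += agg[c2]
                    agg[:, a] += agg[:, c2]
                    agg = np.delete(np.delete(agg, c2, 0), c2, 1)
                    active = np.delete(active, c2)
                    merged = True
                    improved = True
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def modularity(
    fc: FCMatrix | np.ndarray,
    gamma: float = 1.0,
    n_restarts: int = 100,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Best signed-modularity Q over Louvain restarts, with its partition.

    The connectome keeps its signed weights; Q uses the asymmetric
    positive/negative normalization of :func:`signed_modularity_matrix`.
    Deterministic given ``seed``; never below the single-community Q.
    """
    w = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    if w.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    b = signed_modularity_matrix(w, gamma)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    best_q = partition_quality(b, np.zeros(w.shape[0], dtype=int))
    best_labels = np.zeros(w.shape[0], dtype=int)
    for _ in range(n_restarts):
        labels = _louvain_once(b, rng)
        q = partition_quality(b, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return float(best_q), best_labels


# ---------------------------------------------------------------------------
# functional connectivity contrast (rank-sum Z)


def rank_sum_z(group1: np.ndarray, group2: np.ndarray) -> float:
    """Normal-approximation Wilcoxon rank-sum Z with tie correction.

    Positive when ``group1`` is stochastically larger.  Returns 0 when every
    pooled value is tied (the statistic is then degenerate).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = g1.size, g2.size
    pooled = np.concatenate([g1, g2])
    ranks = stats.rankdata(pooled)
    w1 = ranks[:n1].sum()
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((n) * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    return float((w1 - mean) / np.sqrt(var))


def _edge_groups(
    values: np.ndarray, networks: list[str | None], restrict_to: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split upper-triangle edges into within- and between-network groups.

    Within-network edges join two ROIs of the same named network (optionally
    only ``restrict_to``); everything else — including edges touching
    unassigned ROIs — counts as between-network.
    """
    r = len(networks)
    iu, ju = np.triu_indices(r, k=1)
    nets = np.array([n if n is not None else "" for n in networks], dtype=object)
    same = (nets[iu] == nets[ju]) & (nets[iu] != "")
    if restrict_to is not None:
        wne_mask = same & (nets[iu] == restrict_to)
        bne_mask = ~same
    else:
        wne_mask = same
        bne_mask = ~same
    vals = values[iu, ju]
    return vals[wne_mask], vals[bne_mask]


def fcc_time(
    fc: FCMatrix, restrict_to: str | None = None
) -> float:
    """Time-based FCC: rank-sum Z of within- vs between-network edges.

    Positive when within-network Pearson correlations are stochastically
    larger, i.e. when resting-state networks stand out from the background.
    ``restrict_to`` limits the within-network group to one network.
    """
    wne, bne = _edge_groups(fc.values, fc.networks, restrict_to)
    if wne.size == 0 or bne.size == 0:
        raise ValueError("empty within- or between-network edge group")
    return rank_sum_z(wne, bne)


def fcc_frequency(diff: BandDifferenceMatrix) -> float:
    """Frequency-based FCC from the pre-vs-post LF coherence differences.

    Small within-network differences mean the pipeline preserved the
    low-frequency links carrying network structure, so the rank-sum Z is
    computed on the negated differences: preserved within-network edges and
    removed between-network coherence both push the score up.
    """
    if diff.band != "LF":
        raise ValueError(f"expected an LF difference matrix, got {diff.band}")
    wne, bne = _edge_groups(diff.values, diff.networks)
    if wne.size == 0 or bne.size == 0:
        raise ValueError("empty within- or between-network edge group")
    return rank_sum_z(-wne, -bne)


# ---------------------------------------------------------------------------
# signal-sensitive metrics


def lf_bold_content(
    pre_ts: RoiTimeSeries,
    post_ts: RoiTimeSeries,
    band: tuple[float, float] = (0.01, 0.1),
) -> float:
    """Fraction of low-frequency ROI power surviving denoising.

    Per ROI, the raw periodogram power summed over ``band`` (bin edges
    inclusive) after denoising is divided by the same quantity before;
    the subject-level value is the mean over ROIs.  ROIs with zero
    pre-denoising band power are skipped with a warning.
    """
    if pre_ts.data.shape != post_ts.data.shape:
        raise ValueError("pre and post ROI series have different shapes")
    fs = 1.0 / pre_ts.tr
    ratios = []
    for r in range(pre_ts.n_rois):
        pre = pre_ts.data[:, r] - pre_ts.data[:, r].mean()
        post = post_ts.data[:, r] - post_ts.data[:, r].mean()
        freqs, p_pre = sp_signal.periodogram(pre, fs=fs, window="boxcar", detrend=False)
        _, p_post = sp_signal.periodogram(post, fs=fs, window="boxcar", detrend=False)
        sel = (freqs >= band[0]) & (freqs <= band[1])
        denom = p_pre[sel].sum()
        if denom <= 1e-12 * max(p_pre.sum(), 1e-300):
            warnings.warn(f"ROI {pre_ts.roi_ids[r]} has zero pre-denoising LF power; skipped",
                          stacklevel=2)
            continue
        ratios.append(p_post[sel].sum() / denom)
    if not ratios:
        raise ValueError("no ROI had positive pre-denoising LF power")
    return float(np.mean(ratios))


def tdof_loss(tdof_used: int, n_volumes: int) -> float:
    """Fraction of temporal degrees of freedom spent on regressors."""
    if not 0 <= tdof_used <= n_volumes:
        raise ValueError(f"tdof_used={tdof_used} outside [0, {n_volumes}]")
    return tdof_used / n_volumes


def bias_correlation(metric_values: np.ndarray, mean_fd: np.ndarray) -> tuple[float, float]:
    """Pearson r (and two-sided p) between a metric and per-subject mean FD."""
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(mean_fd, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired subject values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input; bias correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
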