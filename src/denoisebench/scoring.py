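"""Metric normalization, the summary performance index, and group statistics.

The metric panel is a (subject x pipeline) by metric table.  FD-DVARS and
tDOF loss, which live in [0, 1] by magnitude, are inverted to ``1 - |x|``
so that higher always means better; every metric column is then z-scored
over all rows jointly (subjects and pipelines pooled), so pipeline
contrasts survive normalization.  The summary performance index is the mean
of the three category means (noise-, network- and signal-sensitive); two
variants aggregate by geometric mean or balance noise against the pooled
network/signal categories.

Pipelines are compared per metric with the Kruskal-Wallis test followed by
Dunn-type pairwise comparisons on the pooled ranks, flagged at a family
threshold that Bonferroni-corrects for the parallel metric families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CATEGORIES",
    "INVERTED_METRICS",
    "invert_metric",
    "build_panel",
    "apply_inversions",
    "zscore_columns",
    "summary_index",
    "summary_variants",
    "KWResult",
    "kruskal_wallis",
    "posthoc_pairwise",
    "family_threshold",
    "score_panel",
]

#: Metric families by what they are sensitive to.
CATEGORIES: dict[str, tuple[str, ...]] = {
    "noise": ("fd_dvars", "hf_fc_content"),
    "network": ("modularity", "fcc_time", "fcc_freq"),
    "signal": ("lf_bold_content", "tdof_loss"),
}

#: Metrics inverted (1 - |x|) before normalization so higher = better.
INVERTED_METRICS = ("fd_dvars", "tdof_loss")

ALL_METRICS = tuple(m for metrics in CATEGORIES.values() for m in metrics)


def invert_metric(x: float | np.ndarray) -> float | np.ndarray:
    """``1 - |x|``: maps a [0, 1]-magnitude badness score to a goodness score."""
    return 1.0 - np.abs(x)


def build_panel(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format records (subject, pipeline, metric, value) to wide."""
    required = {"subject", "pipeline", "metric", "value"}
    if not required.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    panel = records.pivot_table(
        index=["subject", "pipeline"], columns="metric", values="value", aggfunc="first"
    )
    panel.columns.name = None
    return panel


def apply_inversions(panel: pd.DataFrame) -> pd.DataFrame:
    """Invert the magnitude-bounded metrics so that higher means better."""
    out = panel.copy()
    for m in INVERTED_METRICS:
        if m in out.columns:
            out[m] = invert_metric(out[m].to_numpy())
    return out


def zscore_columns(panel: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardize each metric column over ALL rows jointly (sample SD)."""
    out = panel.copy()
    for col in out.columns:
        x = out[col].to_numpy(dtype=float)
        sd = np.nanstd(x, ddof=ddof)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"metric column {col!r} is constant; cannot z-score")
        out[col] = (x - np.nanmean(x)) / sd
    return out


def _category_means(zpanel: pd.DataFrame) -> pd.DataFrame:
    missing = [m for m in ALL_METRICS if m not in zpanel.columns]
    if missing:
        raise ValueError(f"panel is missing metrics: {missing}")
    return pd.DataFrame(
        {cat: zpanel[list(metrics)].mean(axis=1) for cat, metrics in CATEGORIES.items()}
    )


def summary_index(zpanel: pd.DataFrame) -> pd.Series:
    """Mean of the noise, network and signal category means, per row."""
    cats = _category_means(zpanel)
    return cats.mean(axis=1).rename("summary")


def summary_variants(zpanel: pd.DataFrame, variant: str, epsilon: float = 1e-6) -> pd.Series:
    """Alternative aggregations of the normalized metrics.

    ``geometric``: geometric mean of the seven metrics after min-max
    rescaling each column into (0, 1] (z-scores can be negative, so a shift
    is required before a geometric mean is meaningful).
    ``balanced``: noise weighted equally against the pooled network/signal
    side, i.e. mean of {noise mean, mean(network mean, signal mean)}.
    """
    if variant == "geometric":
        rescaled = zpanel[list(ALL_METRICS)].copy()
        for col in rescaled.columns:
            x = rescaled[col].to_numpy(dtype=float)
            rng = x.max() - x.min()
            if rng == 0:
                raise ValueError(f"metric column {col!r} is constant")
            rescaled[col] = (x - x.min()) / rng + epsilon
        return np.exp(np.log(rescaled).mean(axis=1)).rename("summary_geometric")
    if variant == "balanced":
        cats = _category_means(zpanel)
        inner = (cats["network"] + cats["signal"]) / 2.0
        return ((cats["noise"] + inner) / 2.0).rename("summary_balanced")
    raise ValueError(f"unknown summary variant {variant!r}")


# ---------------------------------------------------------------------------
# group statistics


@dataclass(frozen=True)
class KWResult:
    H: float
    p: float
    degenerate: bool = False


def kruskal_wallis(panel: pd.DataFrame, metric: str) -> KWResult:
    """Tie-corrected Kruskal-Wallis H over the pipeline groups of one metric."""
    groups = [g.dropna().to_numpy() for _, g in panel[metric].groupby(level="pipeline")]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        raise ValueError("need at least 2 pipelines with >= 2 values each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return KWResult(H=0.0, p=1.0, degenerate=True)
    h, p = stats.kruskal(*groups)
    return KWResult(H=float(h), p=float(p))


def posthoc_pairwise(
    panel: pd.DataFrame, metric: str, threshold: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dunn-type pairwise comparisons reusing the pooled Kruskal-Wallis ranks.

    Returns the symmetric p-value matrix (diagonal set to 0 by convention)
    and the boolean significance flags at the family threshold.
    """
    if threshold is None:
        threshold = family_threshold()
    series = panel[metric].dropna()
    pipelines = list(series.groupby(level="pipeline").groups)
    values = series.to_numpy(dtype=float)
    ranks = stats.rankdata(values)
    labels = series.index.get_level_values("pipeline")
    n = values.size
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term

    k = len(pipelines)
    pmat = np.zeros((k, k))
    for a in range(k):
        for b2 in range(a + 1, k):
            ra = ranks[labels == pipelines[a]]
            rb = ranks[labels == pipelines[b2]]
            se = math.sqrt(base_var * (1.0 / ra.size + 1.0 / rb.size))
            if se == 0:
                p = 1.0
            else:
                z = (ra.mean() - rb.mean()) / se
                p = 2.0 * stats.norm.sf(abs(z))
            pmat[a, b2] = pmat[b2, a] = p
    pdf = pd.DataFrame(pmat, index=pipelines, columns=pipelines)
    flags = (pdf < threshold) & ~np.eye(k, dtype=bool)
    return pdf, flags


def family_threshold(alpha: float = 0.05, n_families: int = 8) -> float:
    """Family-wise significance threshold for the parallel metric comparisons.

    Bonferroni-corrects ``alpha`` across the metric families and then rounds
    down to the conventional 1-2-5 grid, yielding a threshold at least as
    strict as the exact correction (0.05 over 8 families gives 0.005).
    """
    if alpha <= 0 or n_families < 1:
        raise ValueError("alpha must be positive and n_families >= 1")
    t = alpha / n_families
    mag = 10.0 ** math.floor(math.log10(t))
    for m in (5.0, 2.0, 1.0):
        if m * mag <= t * (1 + 1e-12):
            return m * mag
    return mag / 2.0


def score_panel(raw_panel: pd.DataFrame) -> dict[str, pd.DataFrame | pd.Series]:
    """Full scoring pass: inversion, z-scoring, summary index and variants."""
    inverted = apply_inversions(raw_panel)
    z = zscore_columns(inverted)
    return {
        "raw": raw_panel,
        "inverted": inverted,
        "z": z,
        "summary": summary_index(z),
        "summary_geometric": summary_variants(z, "geometric"),
        "summary_balanced": summary_variants(z, "balanced"),
    }
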