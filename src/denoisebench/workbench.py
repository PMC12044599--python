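"""End-to-end benchmark driver, run configuration, and reporting.

The workflow mirrors the three blocks of the comparison framework:
(i) simulate (or load) and minimally preprocess a cohort, (ii) apply every
processing condition in parallel, (iii) compute the quality metrics, the
summary performance index and the group statistics.  Subjects are processed
one at a time so memory stays flat; expensive intermediates (the ICA
decomposition, the pre-denoising coherence matrices) are computed once per
subject and shared across pipelines.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as qm
from . import scoring
from .connectivity import BandDifferenceMatrix, band_coherence_matrices, extract_roi_series, pearson_fc
from .pipelines import (
    PipelineOptions,
    PipelineSpec,
    SubjectData,
    all_pipelines,
    apply_pipeline,
    get_pipeline,
)
from .preproc import PreprocConfig, apply_minimal
from .synthcohort import CohortParams, _child_seed, make_phantom, simulate_subject
from .types import BoldVolume, MotionTrace, Parcellation, TissueLabelMap

__all__ = [
    "MetricsConfig",
    "RunConfig",
    "BenchmarkResult",
    "prepare_subject",
    "subject_records",
    "run_benchmark",
    "compute_stats",
    "report",
]


@dataclass(frozen=True)
class MetricsConfig:
    """Options of the metric layer."""

    gamma: float = 1.0
    n_restarts: int = 100
    lf_band: tuple[float, float] = (0.01, 0.1)
    fd_radius_mm: float = 50.0
    include_network_fcc: bool = True


@dataclass
class RunConfig:
    """Serializable description of one full benchmark run."""

    n_subjects: int = 20
    seed: int = 0
    cohort: CohortParams = field(default_factory=CohortParams)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    pipelines: tuple[str, ...] = tuple(p.id for p in all_pipelines())
    options: PipelineOptions = field(default_factory=PipelineOptions)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["grid"] = dataclasses.asdict(self.cohort.grid)
        d["cohort"]["target_networks"] = list(self.cohort.target_networks)
        d["pipelines"] = list(self.pipelines)
        return d

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        from .synthcohort import params_from_dict

        cohort = params_from_dict(d["cohort"]) if "cohort" in d else CohortParams()
        pre = PreprocConfig(**d.get("preproc", {}))
        opts = PipelineOptions(**d.get("options", {}))
        md = dict(d.get("metrics", {}))
        if "lf_band" in md:
            md["lf_band"] = tuple(md["lf_band"])
        met = MetricsConfig(**md)
        return RunConfig(
            n_subjects=d.get("n_subjects", 20),
            seed=d.get("seed", 0),
            cohort=cohort,
            preproc=pre,
            pipelines=tuple(d.get("pipelines", tuple(p.id for p in all_pipelines()))),
            options=opts,
            metrics=met,
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @staticmethod
    def load(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return RunConfig.from_dict(yaml.safe_load(fh))


def prepare_subject(
    subject_id: str,
    bold: BoldVolume,
    tissue: TissueLabelMap,
    motion: MotionTrace,
    cfg: PreprocConfig,
    seed: int = 0,
) -> SubjectData:
    """Minimally preprocess one subject and bundle the executor inputs."""
    vol, source = apply_minimal(bold, motion, cfg)
    return SubjectData(
        subject_id=subject_id,
        vol=vol,
        tissue=tissue,
        motion=motion,
        confound_filter=source.temporal_filter,
        confound_vol=source.vol,
        seed=seed,
    )


def subject_records(
    subject: SubjectData,
    parc: Parcellation,
    specs: list[PipelineSpec],
    opts: PipelineOptions | None = None,
    mcfg: MetricsConfig | None = None,
) -> list[dict]:
    """All quality metrics for one subject under every processing condition.

    Returns long-format records ``{subject, pipeline, metric, value}``.  The
    pre-denoising (minimally preprocessed) state supplies the reference ROI
    series and coherence matrices for the pre-vs-post metrics; the baseline
    condition is the pre state itself, so its difference matrices are zero
    and its LF power ratio is one by construction.
    """
    if mcfg is None:
        mcfg = MetricsConfig()
    if opts is None:
        opts = PipelineOptions()
    pre_ts = extract_roi_series(subject.vol, parc)
    nyq = subject.vol.grid.nyquist
    bands = {"LF": mcfg.lf_band, "HF": (mcfg.lf_band[1], nyq)}
    pre_bands = band_coherence_matrices(pre_ts, bands)
    fd = qm.framewise_displacement(subject.motion, mcfg.fd_radius_mm)

    networks_present = sorted({n for n in pre_ts.networks if n is not None})
    records: list[dict] = []
    cache: dict = {}
    for k, spec in enumerate(specs):
        result = apply_pipeline(subject, spec, opts, cache)
        if spec.id == "baseline":
            post_ts, post_bands = pre_ts, pre_bands
        else:
            post_ts = extract_roi_series(result.vol, parc)
            post_bands = band_coherence_matrices(post_ts, bands)
        diff = {
            b: BandDifferenceMatrix(
                values=pre_bands[b] - post_bands[b],
                band=b,
                roi_ids=list(pre_ts.roi_ids),
                networks=list(pre_ts.networks),
            )
            for b in ("LF", "HF")
        }
        fc = pearson_fc(post_ts)
        q, _ = qm.modularity(
            fc,
            gamma=mcfg.gamma,
            n_restarts=mcfg.n_restarts,
            seed=_child_seed(subject.seed, 5000 + k),
        )
        values = {
            "fd_dvars": qm.fd_dvars_metric(fd, qm.dvars(result.vol)),
            "hf_fc_content": qm.hf_fc_content(diff["HF"]),
            "modularity": q,
            "fcc_time": qm.fcc_time(fc),
            "fcc_freq": qm.fcc_frequency(diff["LF"]),
            "lf_bold_content": qm.lf_bold_content(pre_ts, post_ts, mcfg.lf_band),
            "tdof_loss": qm.tdof_loss(result.tdof_used, subject.vol.n_volumes),
        }
        if mcfg.include_network_fcc:
            for net in networks_present:
                values[f"fcc_time_{net}"] = qm.fcc_time(fc, restrict_to=net)
        values["mean_fd"] = float(fd.mean())
        for metric, value in values.items():
            records.append(
                {
                    "subject": subject.subject_id,
                    "pipeline": spec.id,
                    "metric": metric,
                    "value": value,
                }
            )
    return records


@dataclass
class BenchmarkResult:
    """Everything one benchmark run produces."""

    records: pd.DataFrame  # long format incl. per-network FCC and mean FD
    panel: pd.DataFrame  # raw wide panel of the seven headline metrics
    scored: dict  # raw / inverted / z panels + summary indices
    stats: dict  # per-family KW + post hoc
    bias: dict  # per-pipeline metric-vs-meanFD correlations
    failures: dict = field(default_factory=dict)  # skipped subjects, if any

    def summary_by_pipeline(self) -> pd.Series:
        """Median summary performance index per pipeline."""
        return self.scored["summary"].groupby(level="pipeline").median()


def run_benchmark(config: RunConfig | None = None) -> BenchmarkResult:
    """Simulate a cohort and run the full comparison end to end."""
    if config is None:
        config = RunConfig()
    params = config.cohort
    tissue, parc = make_phantom(params.grid, params.n_rois, seed=config.seed)
    specs = [get_pipeline(p) for p in config.pipelines]
    n_high = int(round(config.n_subjects * params.high_motion_fraction))
    severities = ["high"] * n_high + ["low"] * (config.n_subjects - n_high)

    all_records: list[dict] = []
    failures: dict[str, str] = {}
    for i in range(config.n_subjects):
        sid = f"sub-{i + 1:03d}"
        subj_seed = _child_seed(config.seed, 1000 + i)
        bold, motion = simulate_subject(
            tissue, parc, params.grid, severities[i], subj_seed, params
        )
        subject = prepare_subject(sid, bold, tissue, motion, config.preproc, seed=subj_seed)
        try:
            all_records.extend(
                subject_records(subject, parc, specs, config.options, config.metrics)
            )
        except Exception as exc:  # noqa: BLE001 - cohort runs must survive
            warnings.warn(f"subject {sid} failed and was skipped: {exc}", stacklevel=2)
            failures[sid] = str(exc)
    if not all_records:
        raise RuntimeError(f"every subject failed: {failures}")
    records = pd.DataFrame(all_records)
    result = analyze_records(records)
    result.failures = failures
    return result


def analyze_records(records: pd.DataFrame) -> BenchmarkResult:
    """Scoring + statistics from long-format metric records."""
    headline = records[records["metric"].isin(qm.METRIC_NAMES)]
    panel = scoring.build_panel(headline)
    scored = scoring.score_panel(panel)
    stats_panel = scored["z"].copy()
    stats_panel["summary"] = scored["summary"]
    stats = compute_stats(stats_panel)
    bias = bias_report(records)
    return BenchmarkResult(
        records=records, panel=panel, scored=scored, stats=stats, bias=bias
    )


def compute_stats(panel: pd.DataFrame, threshold: float | None = None) -> dict:
    """Kruskal-Wallis plus Dunn-type post hoc for every metric family."""
    if threshold is None:
        threshold = scoring.family_threshold()
    out: dict = {"threshold": threshold, "families": {}}
    for metric in panel.columns:
        kw = scoring.kruskal_wallis(panel, metric)
        entry = {"H": kw.H, "p": kw.p, "degenerate": kw.degenerate}
        if not kw.degenerate:
            pmat, flags = scoring.posthoc_pairwise(panel, metric, threshold)
            entry["posthoc_p"] = pmat.to_dict()
            entry["significant"] = flags.to_dict()
        out["families"][metric] = entry
    return out


def bias_report(records: pd.DataFrame) -> dict:
    """Metric-vs-mean-FD Pearson correlations per pipeline.

    Quantifies motion-related bias: a pipeline whose quality score tracks
    how much the subject moved behaves differently on low- and high-motion
    scans.  Computed for the FD-DVARS metric and for modularity.
    """
    fd = (
        records[records["metric"] == "mean_fd"]
        .drop_duplicates(subset=["subject"])
        .set_index("subject")["value"]
    )
    out: dict = {}
    for metric in ("fd_dvars", "modularity"):
        rows = records[records["metric"] == metric]
        per_pipe = {}
        for pipe, group in rows.groupby("pipeline"):
            vals = group.set_index("subject")["value"].reindex(fd.index)
            ok = vals.notna()
            if ok.sum() >= 3 and vals[ok].std() > 0 and fd[ok].std() > 0:
                r, p = qm.bias_correlation(vals[ok].to_numpy(), fd[ok].to_numpy())
                per_pipe[pipe] = {"r": r, "p": p}
            else:
                per_pipe[pipe] = {"r": None, "p": None}
        out[metric] = per_pipe
    return out


# ---------------------------------------------------------------------------
# reporting


def report(result: BenchmarkResult, out_dir: str | Path | None = None) -> dict:
    """Median/quartile tables by pipeline, plus optional figures.

    Returns a dict with the per-metric quartile table (z-scores), the median
    summary index per pipeline, and the significance flags; when ``out_dir``
    is given, writes the tables as CSV/JSON and saves a median heat-line
    plot and summary-index boxplots.
    """
    z = result.scored["z"].copy()
    z["summary"] = result.scored["summary"]
    grouped = z.groupby(level="pipeline")
    tables = {
        "median": grouped.median(),
        "q1": grouped.quantile(0.25),
        "q3": grouped.quantile(0.75),
    }
    bundle = {
        "tables": tables,
        "summary_median": result.summary_by_pipeline(),
        "stats": result.stats,
        "bias": result.bias,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"table_{name}.csv")
        with open(out / "stats.json", "w") as fh:
            json.dump(_jsonable(result.stats), fh, indent=2)
        with open(out / "bias.json", "w") as fh:
            json.dump(_jsonable(result.bias), fh, indent=2)
        _figures(tables["median"], z, out)
    return bundle


def _figures(median: pd.DataFrame, z: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 5))
    for metric in median.columns:
        ax.plot(median.index, median[metric], marker="o", label=metric)
    ax.set_ylabel("median z-score")
    ax.tick_params(axis="x", rotation=60)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "median_metrics.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 4))
    pipes = sorted(z.index.get_level_values("pipeline").unique())
    data = [z.xs(p, level="pipeline")["summary"].to_numpy() for p in pipes]
    ax.boxplot(data, tick_labels=pipes)
    ax.set_ylabel("summary performance index")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(out / "summary_boxplot.png", dpi=120)
    plt.close(fig)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
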