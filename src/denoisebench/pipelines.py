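"""The ten processing conditions and the confound-regression executor.

The registry holds the baseline (minimal preprocessing only) plus nine
denoising strategies built from motion-parameter expansions, tissue mean
signals, anatomical principal components and ICA-based motion-artifact
removal.  Simple-regressor pipelines run as a single joint ordinary
least-squares regression of the union of their confounds (joint OLS is
order-invariant; sequential partial regression is not).  Combined pipelines
that start with ICA-based removal are sequential: downstream confounds are
recomputed from the already-cleaned data.

Temporal degrees of freedom are accounted per removed regressor; ICA-based
removal costs one tDOF per noise-classified component even under
nonaggressive removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import confounds as cf
from .types import BoldVolume, MotionTrace, TissueLabelMap

__all__ = [
    "PipelineSpec",
    "PipelineOptions",
    "SubjectData",
    "DenoiseResult",
    "PIPELINE_IDS",
    "get_pipeline",
    "all_pipelines",
    "regress_confounds",
    "apply_pipeline",
    "run_cohort",
]


@dataclass(frozen=True)
class PipelineOptions:
    """Tunables shared by the confound builders."""

    n_ica_components: int = 20
    acompcor_components: int = 5
    acompcor_csf_only: bool = False
    nonaggressive: bool = True
    ica_seed: int | None = None  # default: the subject's seed


@dataclass(frozen=True)
class PipelineSpec:
    """One processing condition: an id and an ordered stage list.

    A stage is ``("aroma", ())`` for ICA-based removal or
    ``("regress", (confound names...))`` for a joint confound regression;
    recognized confound names are mp6/mp12/mp24, gs, wm, csf, acompcor.
    """

    id: str
    stages: tuple[tuple[str, tuple[str, ...]], ...]


_REGISTRY: dict[str, PipelineSpec] = {
    spec.id: spec
    for spec in (
        PipelineSpec("baseline", ()),
        PipelineSpec("aroma", (("aroma", ()),)),
        PipelineSpec("acompcor", (("regress", ("acompcor",)),)),
        PipelineSpec("aroma+acompcor", (("aroma", ()), ("regress", ("acompcor",)))),
        PipelineSpec("mp24", (("regress", ("mp24",)),)),
        PipelineSpec("mp24+wm+csf+gs", (("regress", ("mp24", "wm", "csf", "gs")),)),
        PipelineSpec("wm+csf+gs", (("regress", ("wm", "csf", "gs")),)),
        PipelineSpec("aroma+gs", (("aroma", ()), ("regress", ("gs",)))),
        PipelineSpec("acompcor+gs", (("regress", ("acompcor", "gs")),)),
        PipelineSpec("acompcor+mp12", (("regress", ("acompcor", "mp12")),)),
    )
}

PIPELINE_IDS = tuple(_REGISTRY)


def get_pipeline(pipeline_id: str) -> PipelineSpec:
    try:
        return _REGISTRY[pipeline_id]
    except KeyError:
        raise ValueError(
            f"unknown pipeline {pipeline_id!r}; valid ids: {', '.join(PIPELINE_IDS)}"
        ) from None


def all_pipelines() -> list[PipelineSpec]:
    return [_REGISTRY[i] for i in PIPELINE_IDS]


@dataclass
class SubjectData:
    """Everything the executor needs for one subject.

    ``vol`` is the minimally preprocessed volume; ``confound_filter`` is the
    temporal-filter operator returned by the preprocessing step, applied to
    motion-derived confounds so the filter-parity contract holds (confounds
    extracted from ``vol`` itself already live in the filtered space).
    """

    subject_id: str
    vol: BoldVolume
    tissue: TissueLabelMap
    motion: MotionTrace
    confound_filter: Callable[[np.ndarray], np.ndarray] = staticmethod(lambda x: x)
    confound_vol: BoldVolume | None = None  # unsmoothed twin; defaults to vol
    seed: int = 0


@dataclass
class DenoiseResult:
    vol: BoldVolume
    tdof_used: int
    regressor_names: list[str]
    log: list[dict] = field(default_factory=list)


def regress_confounds(series: np.ndarray, x: cf.ConfoundMatrix | np.ndarray) -> np.ndarray:
    """OLS residuals of each series column on the confounds, mean re-added.

    The design includes an intercept (confound columns are demeaned, the
    series mean is restored afterwards), so the demeaned residuals are
    exactly orthogonal to every demeaned confound column, and re-running the
    regression on its own output is the identity.  A rank-deficient design
    raises, naming the collinear columns.
    """
    series = np.asarray(series, dtype=float)
    squeeze = series.ndim == 1
    if squeeze:
        series = series[:, None]
    values = x.values if isinstance(x, cf.ConfoundMatrix) else np.asarray(x, dtype=float)
    names = x.names if isinstance(x, cf.ConfoundMatrix) else [
        f"c{i}" for i in range(values.shape[1])
    ]
    if values.shape[1] == 0:
        out = series.copy()
        return out[:, 0] if squeeze else out
    if values.shape[0] != series.shape[0]:
        raise ValueError("confound matrix and series have different lengths")
    xc = values - values.mean(axis=0)
    rank = np.linalg.matrix_rank(xc)
    if rank < xc.shape[1]:
        # identify columns not adding rank, in order
        collinear = []
        kept = np.empty((xc.shape[0], 0))
        for j in range(xc.shape[1]):
            trial = np.column_stack([kept, xc[:, j]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                collinear.append(names[j])
            else:
                kept = trial
        raise ValueError(f"rank-deficient confound design; collinear columns: {collinear}")
    mean = series.mean(axis=0, keepdims=True)
    beta, *_ = np.linalg.lstsq(xc, series - mean, rcond=None)
    resid = (series - mean) - xc @ beta
    out = resid + mean
    return out[:, 0] if squeeze else out


def _build_confounds(
    names: tuple[str, ...],
    cvol: BoldVolume,
    subject: SubjectData,
    opts: PipelineOptions,
) -> cf.ConfoundMatrix:
    """Assemble the requested confound families.

    Data-derived confounds come from the current *confound source* volume
    (the unsmoothed twin, cleaned in parallel with the analysis volume);
    motion-derived confounds come from the realignment trace, passed through
    the shared temporal filter.
    """
    parts: list[cf.ConfoundMatrix] = []
    for name in names:
        if name in ("mp6", "mp12", "mp24"):
            m = cf.expand_motion(subject.motion, name)
            filtered = subject.confound_filter(m.values)
            parts.append(cf.ConfoundMatrix(values=filtered, names=m.names, source=name))
        elif name in ("gs", "wm", "csf"):
            parts.append(
                cf.tissue_signals(cvol, subject.tissue, which=(name.upper(),))
            )
        elif name == "acompcor":
            parts.append(
                cf.acompcor(
                    cvol,
                    subject.tissue,
                    n_components=opts.acompcor_components,
                    csf_only=opts.acompcor_csf_only,
                )
            )
        else:
            raise ValueError(f"unknown confound family {name!r}")
    return cf.ConfoundMatrix.concat(parts)


def apply_pipeline(
    subject: SubjectData,
    spec: PipelineSpec,
    opts: PipelineOptions | None = None,
    cache: dict | None = None,
) -> DenoiseResult:
    """Run one processing condition on a minimally preprocessed subject.

    Stages run in order; sequential combinations recompute downstream
    confounds from the already-cleaned data.  ``cache`` (per subject) lets
    several ICA-containing pipelines share one decomposition of the same
    input volume.
    """
    if opts is None:
        opts = PipelineOptions()
    vol = subject.vol
    cvol = subject.confound_vol if subject.confound_vol is not None else subject.vol
    tdof = 0
    names: list[str] = []
    log: list[dict] = []

    def _regress_vol(v: BoldVolume, x) -> BoldVolume:
        data = v.data.copy()
        data[v.mask] = regress_confounds(v.data[v.mask].T, x).T
        return v.copy_with(data)

    for stage, args in spec.stages:
        try:
            if stage == "aroma":
                vol, cvol, n_noise, noise_names, info = _run_aroma(
                    subject, vol, cvol, opts, cache
                )
                tdof += n_noise
                names.extend(noise_names)
                log.append({"stage": "aroma", **info})
            elif stage == "regress":
                x = _build_confounds(args, cvol, subject, opts)
                vol = _regress_vol(vol, x)
                if cvol is not subject.vol or subject.confound_vol is not None:
                    cvol = _regress_vol(cvol, x)
                else:
                    cvol = vol
                tdof += x.tdof_cost
                names.extend(x.names)
                log.append({"stage": "regress", "confounds": list(args), "k": x.tdof_cost})
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"pipeline {spec.id!r} failed at stage {stage!r}: {exc}") from exc
    return DenoiseResult(vol=vol, tdof_used=tdof, regressor_names=names, log=log)


def _run_aroma(
    subject: SubjectData,
    vol: BoldVolume,
    cvol: BoldVolume,
    opts: PipelineOptions,
    cache: dict | None,
) -> tuple[BoldVolume, BoldVolume, int, list[str], dict]:
    seed = opts.ica_seed if opts.ica_seed is not None else subject.seed
    key = ("aroma", id(vol.data), opts.n_ica_components, seed, opts.nonaggressive)
    if cache is not None and key in cache:
        return cache[key]
    # the fixed-point iteration occasionally stalls from an unlucky start;
    # retry a few deterministically derived seeds before giving up
    comps = None
    last_error: Exception | None = None
    for attempt in range(4):
        try:
            comps = cf.spatial_ica(
                vol, n_components=opts.n_ica_components, seed=seed + attempt * 1_000_003
            )
            break
        except RuntimeError as exc:
            last_error = exc
    if comps is None:
        raise RuntimeError(f"spatial ICA failed after 4 restarts: {last_error}")
    noise_ids = []
    feature_log = []
    for i in range(comps.n_components):
        f = cf.aroma_features(comps, i, subject.tissue, subject.motion, vol.grid.tr)
        is_noise = cf.classify_aroma(f)
        if is_noise:
            noise_ids.append(i)
        feature_log.append(
            {
                "component": i,
                "edge_fraction": f.edge_fraction,
                "csf_fraction": f.csf_fraction,
                "hf_content": f.hf_content,
                "max_rp_correlation": f.max_rp_correlation,
                "is_noise": is_noise,
            }
        )
    if opts.nonaggressive:
        cleaned = cf.nonaggressive_remove(vol, comps, noise_ids)
        cleaned_src = cf.nonaggressive_remove(cvol, comps, noise_ids)
    else:
        x = cf.ConfoundMatrix(
            values=comps.mixing[:, noise_ids],
            names=[f"aroma_{i:02d}" for i in noise_ids],
            source="aroma",
        )

        def _rm(v: BoldVolume) -> BoldVolume:
            data = v.data.copy()
            data[v.mask] = regress_confounds(v.data[v.mask].T, x).T
            return v.copy_with(data)

        cleaned, cleaned_src = _rm(vol), _rm(cvol)
    result = (
        cleaned,
        cleaned_src,
        len(noise_ids),
        [f"aroma_noise_{i:02d}" for i in noise_ids],
        {"n_components": comps.n_components, "n_noise": len(noise_ids), "features": feature_log},
    )
    if cache is not None:
        cache[key] = result
    return result


@dataclass
class CohortResults:
    """Denoising results for every (subject, pipeline) pair."""

    results: dict[tuple[str, str], DenoiseResult]
    failures: dict[str, str]

    def __len__(self) -> int:
        return len(self.results)


def run_cohort(
    subjects: list[SubjectData],
    specs: list[PipelineSpec] | None = None,
    opts: PipelineOptions | None = None,
) -> CohortResults:
    """Apply every pipeline to every subject; per-subject failures are
    collected (with their message) instead of aborting the cohort."""
    if specs is None:
        specs = all_pipelines()
    results: dict[tuple[str, str], DenoiseResult] = {}
    failures: dict[str, str] = {}
    for subject in subjects:
        cache: dict = {}
        try:
            for spec in specs:
                results[(subject.subject_id, spec.id)] = apply_pipeline(
                    subject, spec, opts, cache
                )
        except Exception as exc:  # noqa: BLE001 - cohort runs must survive
            failures[subject.subject_id] = str(exc)
            results = {
                k: v for k, v in results.items() if k[0] != subject.subject_id
            }
    return CohortResults(results=results, failures=failures)
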