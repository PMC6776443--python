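"""End-to-end analysis runs: traces -> QC -> idealization -> kinetics/occupancy.

The two study designs have one driver each:

* :func:`analyze_selection` — stop-flow delivery datasets: QC filtering,
  4-state idealization, event classification, cumulative-arrival fitting,
  photobleach correction and kcat/KM with a trace-level bootstrap SEM.
* :func:`analyze_pretranslocation` — equilibrium pre-translocation
  datasets: QC, 3-state idealization, dwell-time occupancy and the
  three-Gaussian histogram fit.

:func:`run_all` wraps either driver behind a :class:`RunConfig`, writing
every stage artifact (TSV tables, JSON reports) into a run directory; reruns
on an existing directory reuse the stored traces, so runs are resumable and
deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bootstrap as bstats
from .errors import ValidationError
from .idealize import idealize_dataset
from .io import (
    IdealizedSet,
    TraceSet,
    read_traces,
    write_idealization,
    write_report,
    write_traces,
)
from .kinetics import (
    ArrivalFit,
    classify_events,
    cumulative_arrival,
    estimate_bleach_rate,
    fit_arrival,
    kcat_km,
)
from .occupancy import dwell_fractions, fit_three_gaussians, fret_histogram
from .qc import QCCriteria, select_traces
from .schemes import builtin_model
from .simulate import get_preset, simulate_dataset

log = logging.getLogger("ribofret")

__all__ = [
    "RunConfig",
    "SelectionAnalysis",
    "PretransAnalysis",
    "analyze_selection",
    "analyze_pretranslocation",
    "accommodated_fret_mean",
    "kcat_km_estimator",
    "classical_occupancy_estimator",
    "run_all",
]


@dataclass
class TraceRecord:
    """Per-trace summary consumed by the kinetics bootstrap."""

    trace_id: str
    passed: bool
    arrival_frame: int | None
    bleach_time: float | None  # s, None if never bleached
    observed_time: float  # s, movie length (censoring time)


@dataclass
class SelectionAnalysis:
    preset: str
    n_total: int
    n_passed: int
    n_productive: int
    qc_report: pd.DataFrame
    classifications: list
    records: list
    times: np.ndarray
    curve: np.ndarray
    curve_sem: np.ndarray | None
    fit: ArrivalFit
    transition_fit: object
    paths: dict
    ideal: IdealizedSet
    concentration_uM: float
    bootstrap_replicates: np.ndarray | None = None
    seed: int | None = None

    def report_dict(self) -> dict:
        d = self.fit.to_dict()
        d.update(
            {
                "preset": self.preset,
                "n_traces_total": self.n_total,
                "n_traces_passed": self.n_passed,
                "n_productive": self.n_productive,
                "concentration_uM": self.concentration_uM,
                "seed": self.seed,
                "transition_pooling": "one shared transition matrix per dataset",
                "bootstrap_unit": "traces",
            }
        )
        return d


@dataclass
class PretransAnalysis:
    preset: str
    n_total: int
    n_passed: int
    qc_report: pd.DataFrame
    occupancy: object
    histogram_fit: object
    transition_fit: object
    paths: dict
    ideal: IdealizedSet
    seed: int | None = None

    def report_dict(self) -> dict:
        occ = self.occupancy
        d = {
            "preset": self.preset,
            "n_traces_total": self.n_total,
            "n_traces_passed": self.n_passed,
            "state_labels": list(occ.state_labels),
            "dwell_fractions": [float(x) for x in occ.fractions],
            "dwell_fractions_per_trace_mean": [float(x) for x in occ.per_trace_mean],
            "gaussian_means": [float(x) for x in self.histogram_fit.means],
            "gaussian_amplitude_shares": [float(x) for x in self.histogram_fit.amplitude_shares],
            "seed": self.seed,
            "transition_pooling": "one shared transition matrix per dataset",
            "bootstrap_unit": "traces",
        }
        if occ.sem is not None:
            d["dwell_fraction_sems"] = [float(x) for x in occ.sem]
        return d


def _records_from_qc(qc_report: pd.DataFrame, classifications, dt: float, n_frames: int):
    arrivals = {c.trace_id: c.arrival_frame for c in classifications}
    records = []
    for row in qc_report.itertuples(index=False):
        bleach_time = None
        if pd.notna(row.bleach_frame):
            bleach_time = (int(row.bleach_frame) + 0.5) * dt
        records.append(
            TraceRecord(
                trace_id=row.trace_id,
                passed=bool(row.passed),
                arrival_frame=arrivals.get(row.trace_id),
                bleach_time=bleach_time,
                observed_time=n_frames * dt,
            )
        )
    return records


def _kinetics_point(records, times, n_frames, dt, conc_uM, k1_starts=None, fix_t0=None):
    """Curve construction + fit + bleach correction from per-trace records."""
    passed = [r for r in records if r.passed]
    if not passed:
        raise ValidationError("no QC-passed traces")

    class _C:  # minimal stand-in for EventClassification
        __slots__ = ("event_class", "arrival_frame")

        def __init__(self, af):
            self.event_class = "productive"
            self.arrival_frame = af

    arrivals = [_C(r.arrival_frame) for r in passed if r.arrival_frame is not None]
    curve, _ = cumulative_arrival(arrivals, n_frames, n_total=len(passed))
    # bleach rate from the total dataset (censored exponential MLE); it also
    # pins the slow-phase rate, whose observed rise is bleach-dominated
    events = [r.bleach_time for r in records if r.bleach_time is not None]
    censored = [r.observed_time for r in records if r.bleach_time is None]
    kb = estimate_bleach_rate(np.array(events), np.array(censored))
    sem = np.sqrt(np.clip(curve * (1.0 - curve), 1e-6, None) / len(passed))
    kwargs = {} if k1_starts is None else {"k1_starts": k1_starts}
    fit = fit_arrival(times, curve, sem=sem, fix_t0=fix_t0, slow_rate=kb, **kwargs)
    kc = kcat_km(fit.k1, kb, conc_uM)
    return curve, fit, kb, kc


def kcat_km_estimator(n_frames: int, dt: float, conc_uM: float, point_fit: ArrivalFit | None = None):
    """Estimator closure (records -> kcat/KM) for bootstrap resampling.

    When a point fit is supplied, replicate fits start from its parameters
    (single start) instead of the full multistart grid.
    """
    times = np.arange(n_frames) * dt
    starts = None if point_fit is None else (point_fit.k1,)

    def _est(records):
        _, fit, kb, kc = _kinetics_point(records, times, n_frames, dt, conc_uM, k1_starts=starts)
        return kc

    return _est


def classical_occupancy_estimator(classical_index: int):
    """Estimator closure (per-trace state-count vectors -> pooled fraction)."""

    def _est(count_vectors):
        mat = np.vstack(count_vectors)
        return float(mat.sum(axis=0)[classical_index] / mat.sum())

    return _est


def analyze_selection(
    traceset: TraceSet,
    concentration_uM: float | None = None,
    criteria: QCCriteria | None = None,
    model: str = "selection4",
    n_boot: int = 200,
    seed: int | None = 0,
    em_max_iter: int = 200,
    curve_sem_boot: int = 0,
) -> SelectionAnalysis:
    """Full selection-kinetics analysis of one dataset."""
    if concentration_uM is None:
        concentration_uM = traceset.meta.ternary_concentration_uM
    if not concentration_uM or concentration_uM <= 0:
        raise ValidationError("a positive ternary-complex concentration is required")
    dt = traceset.meta.frame_interval_s
    n_frames = int(traceset.frames.groupby("trace_id", sort=False)["frame"].size().max())
    times = np.arange(n_frames) * dt

    filtered, qc_report = select_traces(traceset, criteria)
    log.info("QC: %d/%d traces passed", filtered.n_traces, traceset.n_traces)
    bleach_frames = {
        r.trace_id: (int(r.bleach_frame) if pd.notna(r.bleach_frame) else None)
        for r in qc_report.itertuples(index=False)
    }
    ideal, tfit, paths = idealize_dataset(filtered, model, bleach_frames, max_iter=em_max_iter)
    model_spec = tfit.model
    classifications = classify_events(paths, model_spec)
    n_prod = sum(1 for c in classifications if c.event_class == "productive")
    log.info("classified %d productive / %d analyzed traces", n_prod, len(paths))

    records = _records_from_qc(qc_report, classifications, dt, n_frames)
    curve, fit, kb, kc = _kinetics_point(records, times, n_frames, dt, concentration_uM)
    fit.k_bleach = kb
    fit.k_corrected = fit.k1 - kb
    fit.kcat_km = kc

    curve_sem = None
    if curve_sem_boot > 0:
        _, curve_sem = cumulative_arrival(
            classifications, n_frames, n_total=len(paths), n_boot=curve_sem_boot, seed=seed
        )

    reps = None
    if n_boot > 0:
        est = kcat_km_estimator(n_frames, dt, concentration_uM, point_fit=fit)
        reps = bstats.bootstrap_estimator(records, est, n_boot=n_boot, seed=seed)
        fit.sem = {
            "kcat_km": float(reps.std(ddof=1)),
            "k1": float(reps.std(ddof=1) * concentration_uM),
        }
    return SelectionAnalysis(
        preset=traceset.meta.condition,
        n_total=traceset.n_traces,
        n_passed=filtered.n_traces,
        n_productive=n_prod,
        qc_report=qc_report,
        classifications=classifications,
        records=records,
        times=times,
        curve=curve,
        curve_sem=curve_sem,
        fit=fit,
        transition_fit=tfit,
        paths=paths,
        ideal=ideal,
        concentration_uM=concentration_uM,
        bootstrap_replicates=reps,
        seed=seed,
    )


def accommodated_fret_mean(analysis: SelectionAnalysis) -> float:
    """Mean idealized FRET over accommodated-state frames of productive traces."""
    model = analysis.transition_fit.model
    acc = int(np.argmax(model.means))
    productive = {
        c.trace_id for c in analysis.classifications if c.event_class == "productive"
    }
    vals = []
    for tid in productive:
        path = analysis.paths[tid]
        vals.append(path.fret[path.states == acc])
    if not vals:
        raise ValidationError("no productive traces")
    return float(np.concatenate(vals).mean())


def analyze_pretranslocation(
    traceset: TraceSet,
    criteria: QCCriteria | None = None,
    model: str = "pretrans3",
    n_boot: int = 200,
    seed: int | None = 0,
    em_max_iter: int = 200,
    bin_width: float = 0.02,
) -> PretransAnalysis:
    """Occupancy analysis of one pre-translocation dataset."""
    spec = builtin_model(model) if isinstance(model, str) else model
    if spec.variant != "pretranslocation":
        raise ValidationError(
            f"occupancy analysis needs a pre-translocation model, got {spec.name!r}"
        )
    filtered, qc_report = select_traces(traceset, criteria)
    log.info("QC: %d/%d traces passed", filtered.n_traces, traceset.n_traces)
    bleach_frames = {
        r.trace_id: (int(r.bleach_frame) if pd.notna(r.bleach_frame) else None)
        for r in qc_report.itertuples(index=False)
    }
    ideal, tfit, paths = idealize_dataset(filtered, model, bleach_frames, max_iter=em_max_iter)
    model_spec = tfit.model
    occ = dwell_fractions(paths, model_spec.state_labels, n_boot=n_boot, seed=seed)
    edges, mean_counts, _sem = fret_histogram(
        [p.fret for p in paths.values()], bin_width=bin_width
    )
    hist_fit = fit_three_gaussians(
        edges, mean_counts, init_means=tuple(model_spec.means), init_sds=tuple(model_spec.sds)
    )
    return PretransAnalysis(
        preset=traceset.meta.condition,
        n_total=traceset.n_traces,
        n_passed=filtered.n_traces,
        qc_report=qc_report,
        occupancy=occ,
        histogram_fit=hist_fit,
        transition_fit=tfit,
        paths=paths,
        ideal=ideal,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Run orchestration


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: str
    preset: str | None = None  # simulate this preset ...
    traces_path: str | None = None  # ... or read an existing table
    n_traces: int = 400
    seed: int = 0
    model: str | None = None  # default: preset's model
    concentration_uM: float | None = None
    criteria: QCCriteria = field(default_factory=QCCriteria)
    n_boot: int = 200
    n_null: int = 10**4
    em_max_iter: int = 200

    def validate(self) -> None:
        if (self.preset is None) == (self.traces_path is None):
            raise ValidationError("exactly one of preset/traces_path must be set")
        if self.traces_path is not None and not Path(self.traces_path).exists():
            raise ValidationError(f"traces_path {self.traces_path} does not exist")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "out_dir", "preset", "traces_path", "n_traces", "seed", "model",
            "concentration_uM", "n_boot", "n_null", "em_max_iter")}
        d["criteria"] = vars(self.criteria).copy()
        return d


def run_all(config: RunConfig):
    """Execute every stage into ``config.out_dir``; returns the analysis object.

    Existing ``traces.tsv`` in the run directory is reused (resume), so the
    simulate stage is skipped on reruns; all downstream stages are
    recomputed deterministically from it and the seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces_file = out / "traces.tsv"

    if traces_file.exists():
        log.info("resuming from existing %s", traces_file)
        traceset = read_traces(traces_file)
    elif config.preset is not None:
        preset = get_preset(config.preset)
        traceset, gt = simulate_dataset(preset, config.n_traces, config.seed)
        write_traces(traceset, traces_file)
        gt.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    else:
        traceset = read_traces(config.traces_path)
        write_traces(traceset, traces_file)

    model = config.model or traceset.meta.extras.get("model")
    if model is None:
        raise ValidationError("model must be given when the dataset does not name one")
    # an explicitly configured model decides the analysis branch; otherwise
    # the dataset's own metadata does
    if config.model is not None:
        kind = (
            "pretranslocation"
            if builtin_model(config.model).variant == "pretranslocation"
            else "selection"
        )
    else:
        kind = traceset.meta.extras.get("kind") or (
            "pretranslocation"
            if builtin_model(model).variant == "pretranslocation"
            else "selection"
        )

    # validate kinetics inputs before any compute
    if kind == "selection":
        conc = config.concentration_uM or traceset.meta.ternary_concentration_uM
        if not conc or conc <= 0:
            raise ValidationError("selection runs need a positive concentration_uM")
        analysis = analyze_selection(
            traceset,
            concentration_uM=conc,
            criteria=config.criteria,
            model=model,
            n_boot=config.n_boot,
            seed=config.seed,
            em_max_iter=config.em_max_iter,
        )
        report_name = "fit.json"
    else:
        analysis = analyze_pretranslocation(
            traceset,
            criteria=config.criteria,
            model=model,
            n_boot=config.n_boot,
            seed=config.seed,
            em_max_iter=config.em_max_iter,
        )
        report_name = "occupancy.json"

    analysis.qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    write_traces(
        traceset.subset(analysis.qc_report.loc[analysis.qc_report["passed"], "trace_id"]),
        out / "filtered.tsv",
    )
    write_idealization(analysis.ideal, out / "ideal.tsv")
    report = analysis.report_dict()
    report["config"] = config.to_dict()
    write_report(report, out / report_name)
    log.info("run complete: %s", out)
    return analysis


def compare_runs(
    analysis_a: SelectionAnalysis | PretransAnalysis,
    analysis_b,
    estimator: str = "kcat_km",
    n_boot: int = 200,
    n_null: int = 10**4,
    seed: int | None = 0,
):
    """Bootstrap Welch comparison of two analyzed runs (same estimator)."""
    if estimator == "kcat_km":
        a, b = analysis_a, analysis_b
        n_frames = len(a.times)
        dt = a.times[1] - a.times[0]
        est_a = kcat_km_estimator(n_frames, dt, a.concentration_uM, point_fit=a.fit)
        # the estimator closure is per-condition (concentration may differ)
        n_frames_b = len(b.times)
        dt_b = b.times[1] - b.times[0]
        est_b = kcat_km_estimator(n_frames_b, dt_b, b.concentration_uM, point_fit=b.fit)
        ss = np.random.SeedSequence(seed)
        sa, sb, sn = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
        reps_a = bstats.bootstrap_estimator(a.records, est_a, n_boot, seed=sa)
        reps_b = bstats.bootstrap_estimator(b.records, est_b, n_boot, seed=sb)
        t_obs, p, bound = bstats.bootstrap_welch_test(reps_a, reps_b, n_null=n_null, seed=sn)
        return bstats.BootstrapResult(
            estimator_name="kcat_km",
            estimate_a=float(a.fit.kcat_km),
            estimate_b=float(b.fit.kcat_km),
            sem_a=float(reps_a.std(ddof=1)),
            sem_b=float(reps_b.std(ddof=1)),
            replicates_a=reps_a,
            replicates_b=reps_b,
            t_observed=t_obs,
            n_null=n_null,
            p_value=p,
            p_is_upper_bound=bound,
            seed=seed,
            n_boot=n_boot,
        )
    if estimator == "classical_occupancy":
        idx_a = analysis_a.occupancy.state_labels.index("classical")
        est = classical_occupancy_estimator(idx_a)
        items_a = [
            np.bincount(p.states, minlength=len(analysis_a.occupancy.state_labels))
            for p in analysis_a.paths.values()
        ]
        items_b = [
            np.bincount(p.states, minlength=len(analysis_b.occupancy.state_labels))
            for p in analysis_b.paths.values()
        ]
        return bstats.compare_conditions(
            items_a, items_b, est, n_boot=n_boot, n_null=n_null, seed=seed,
            estimator_name="classical_occupancy",
        )
    raise ValidationError(f"unknown estimator {estimator!r}")
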