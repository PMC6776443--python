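"""Pre-translocation tRNA-state occupancy.

Two estimators of how pre-translocation complexes partition their time
between the classical and the two hybrid tRNA configurations:

* dwell-time fractions, read directly off the hidden-Markov idealizations
  (frames in state / total analyzed frames, pooled over traces); and
* amplitude shares of a three-Gaussian fit to the trace-averaged FRET
  histogram.

Both use pre-bleach frames only. The dataset-level dwell fraction is
frame-weighted (pooled frames); the per-trace average is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import EmptyDatasetError, ValidationError
from .idealize import IdealizedPath

__all__ = [
    "OccupancyResult",
    "HistogramFit",
    "dwell_fractions",
    "fret_histogram",
    "fit_three_gaussians",
]

DEFAULT_BIN_WIDTH = 0.02


@dataclass
class OccupancyResult:
    """Fraction of analyzed time spent in each state."""

    state_labels: tuple
    fractions: np.ndarray  # frame-weighted, sums to 1 exactly
    per_trace_fractions: dict  # trace_id -> fraction vector
    per_trace_mean: np.ndarray
    sem: np.ndarray | None = None
    n_frames: int = 0

    def fraction(self, label: str) -> float:
        return float(self.fractions[self.state_labels.index(label)])


@dataclass
class HistogramFit:
    bin_edges: np.ndarray
    mean_counts: np.ndarray
    sem_counts: np.ndarray | None
    means: np.ndarray  # component means, sorted ascending
    sds: np.ndarray
    amplitudes: np.ndarray
    converged: bool = True
    residual_ss: float = 0.0

    @property
    def amplitude_shares(self) -> np.ndarray:
        """Area shares of the components (amp * sd, normalized)."""
        areas = self.amplitudes * self.sds
        return areas / areas.sum()

    def component_sum(self, x: np.ndarray) -> np.ndarray:
        return _three_gaussians(x, *self.means, *self.sds, *self.amplitudes)


def dwell_fractions(
    paths: dict[str, IdealizedPath],
    state_labels,
    n_boot: int = 200,
    seed: int | None = None,
) -> OccupancyResult:
    """Frame-weighted state occupancy from idealized dwell times.

    Frames after the bleach are already absent from the idealized paths.
    The SEM per state comes from bootstrap resampling of traces.
    """
    n_states = len(state_labels)
    counts = {}
    for tid, path in paths.items():
        c = np.bincount(path.states, minlength=n_states).astype(float)
        if c.sum() > 0:
            counts[tid] = c
    if not counts:
        raise EmptyDatasetError("no analyzed frames")
    mat = np.vstack(list(counts.values()))
    total = mat.sum()
    fractions = mat.sum(axis=0) / total
    per_trace = {tid: c / c.sum() for tid, c in counts.items()}
    per_trace_mean = np.vstack(list(per_trace.values())).mean(axis=0)
    sem = None
    if n_boot > 0 and len(counts) > 1:
        rng = np.random.default_rng(seed)
        n = mat.shape[0]
        reps = np.empty((n_boot, n_states))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            sub = mat[idx]
            reps[b] = sub.sum(axis=0) / sub.sum()
        sem = reps.std(axis=0, ddof=1)
    return OccupancyResult(
        state_labels=tuple(state_labels),
        fractions=fractions,
        per_trace_fractions=per_trace,
        per_trace_mean=per_trace_mean,
        sem=sem,
        n_frames=int(total),
    )


def fret_histogram(
    fret_traces: list[np.ndarray],
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Trace-averaged FRET histogram over [0, 1].

    Each trace contributes a histogram normalized to unit total count, so
    long traces do not dominate; the mean and the across-trace SEM per bin
    are returned as ``(bin_edges, mean_counts, sem_counts)``.
    """
    traces = [np.clip(np.asarray(x, dtype=float), 0.0, 1.0) for x in fret_traces if len(x) > 0]
    if not traces:
        raise EmptyDatasetError("no FRET frames to histogram")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    per_trace = np.vstack([np.histogram(x, bins=edges)[0] / len(x) for x in traces])
    mean = per_trace.mean(axis=0)
    sem = per_trace.std(axis=0, ddof=1) / np.sqrt(len(traces)) if len(traces) > 1 else None
    return edges, mean, sem


def _three_gaussians(x, m1, m2, m3, s1, s2, s3, a1, a2, a3):
    out = np.zeros_like(np.asarray(x, dtype=float))
    for m, s, a in ((m1, s1, a1), (m2, s2, a2), (m3, s3, a3)):
        out = out + a * np.exp(-0.5 * ((x - m) / s) ** 2)
    return out


def fit_three_gaussians(
    bin_edges: np.ndarray,
    mean_counts: np.ndarray,
    init_means=(0.22, 0.42, 0.72),
    init_sds=(0.075, 0.075, 0.075),
) -> HistogramFit:
    """Least-squares fit of a sum of three Gaussians to a FRET histogram.

    Initialized at the idealization model's emission means (pass the Lys
    variant's 0.61 classical mean through ``init_means`` where relevant).
    Components are returned sorted by mean. Non-convergence yields a
    flagged result carrying the best residual instead of raising.
    """
    edges = np.asarray(bin_edges, dtype=float)
    y = np.asarray(mean_counts, dtype=float)
    if edges.size != y.size + 1:
        raise ValidationError("bin_edges must have len(mean_counts) + 1 entries")
    if y.size < 10 or not (edges[0] <= 0.05 and edges[-1] >= 0.95):
        raise ValidationError("histogram must span [0, 1]")
    x = 0.5 * (edges[:-1] + edges[1:])
    amp0 = max(float(y.max()), 1e-9)
    p0 = [*init_means, *init_sds, *(amp0 / 2,) * 3]
    lb = [0.0] * 3 + [0.005] * 3 + [0.0] * 3
    ub = [1.0] * 3 + [0.5] * 3 + [10.0 * amp0 + 1e-9] * 3
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_three_gaussians, x, y, p0=p0, bounds=(lb, ub), maxfev=20000)
    except (RuntimeError, ValueError):
        converged = False
        popt = np.asarray(p0, dtype=float)
    means = np.asarray(popt[:3])
    sds = np.asarray(popt[3:6])
    amps = np.asarray(popt[6:9])
    order = np.argsort(means)
    resid = float(np.sum((_three_gaussians(x, *popt) - y) ** 2))
    return HistogramFit(
        bin_edges=edges,
        mean_counts=y,
        sem_counts=None,
        means=means[order],
        sds=sds[order],
        amplitudes=amps[order],
        converged=converged,
        residual_ss=resid,
    )
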