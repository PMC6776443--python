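"""Trace-selection quality control.

A usable single-molecule trace must show exactly one catastrophic donor
photobleaching event, a summed signal at least 8x the background noise and
6x its own noise, fewer than four donor blinking events, and a
donor-acceptor Pearson correlation below 0.5 (anticorrelated FRET traces sit
near -1; uncorrelated junk near 0 still passes, correlated aggregates fail).

"Signal" throughout is the summed donor + acceptor intensity: total emission
is the quantity that disappears in a single step when the donor bleaches.
The paper-style thresholds are the defaults of :class:`QCCriteria` and every
threshold is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .errors import EmptyDatasetError
from .io import TraceSet

__all__ = [
    "QCCriteria",
    "QCMetrics",
    "detect_bleach",
    "count_blinks",
    "compute_snr",
    "donor_acceptor_correlation",
    "select_traces",
]

_MIN_DARK_RUN = 5  # frames a drop must persist to count as sustained
_MAX_BLINK_RUN = 20  # frames; longer recovering dark runs trigger a warning


@dataclass(frozen=True)
class QCCriteria:
    min_snr_background: float = 8.0
    min_snr_signal: float = 6.0
    max_blinks: int = 3  # "less than four blinking events"
    max_correlation: float = 0.5
    require_single_bleach: bool = True


@dataclass
class QCMetrics:
    trace_id: str
    snr_background: float
    snr_signal: float
    n_bleach_steps: int
    bleach_frame: int | None
    n_blinks: int
    donor_acceptor_corr: float
    corr_background_subtracted: float
    passed: bool = False
    failure_reasons: tuple = ()


def _dark_threshold(background_level: float, background_noise_sd: float) -> float:
    # total signal of a dark molecule: two background channels plus 3 sigma
    return 2.0 * background_level + 3.0 * np.sqrt(2.0) * background_noise_sd


def _runs(mask: np.ndarray):
    """(start, length) of maximal True runs."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts, ends - starts))


def detect_bleach(
    donor: np.ndarray,
    acceptor: np.ndarray,
    background_level: float,
    background_noise_sd: float,
) -> tuple[int, int | None]:
    """Count sustained non-recovering intensity drops and locate the bleach.

    The bleach is the final sustained (>= 5 frame) drop of the total
    intensity below the dark threshold that persists to the end of the
    trace. Additional sustained downward level steps that never recover
    (e.g. the first bleach of a two-molecule aggregate) are counted as extra
    bleach steps; dark excursions that recover are blinks, not steps.

    Returns ``(n_bleach_steps, bleach_frame)``; ``(0, None)`` when the trace
    never goes dark.
    """
    total = np.asarray(donor, dtype=float) + np.asarray(acceptor, dtype=float)
    n = total.size
    if n < 20:
        raise EmptyDatasetError("bleach detection needs at least 20 frames")
    thresh = _dark_threshold(background_level, background_noise_sd)

    # segment into sustained-bright and dark-ish stretches; isolated bright
    # noise pops (single frames over threshold) do not interrupt a dark run
    dark = total < thresh
    bright_sustained = np.zeros(n, dtype=bool)
    for start, length in _runs(~dark):
        if length >= 2:
            bright_sustained[start : start + length] = True
    darkish = ~bright_sustained

    # the bleach is the final dark-ish run: it must reach the end of the
    # trace and persist >= 5 frames; earlier dark runs that recover are
    # blinks, not bleach steps
    bleach_frame = None
    runs = _runs(darkish)
    if runs:
        start, length = runs[-1]
        if start + length == n and length >= _MIN_DARK_RUN:
            bleach_frame = int(start)

    # level-step counting on the median-filtered trace (catches the partial
    # first bleach of a multi-molecule aggregate, which never goes dark)
    smooth = medfilt(total, kernel_size=5)
    diffs = np.diff(total)
    sigma = max(1.4826 * np.median(np.abs(diffs)) / np.sqrt(2.0), 1e-9)
    lag = _MIN_DARK_RUN
    drop = smooth[lag:] - smooth[:-lag]
    cand = np.flatnonzero(drop < -6.0 * sigma)
    n_steps = 0
    last_end = -lag
    for cluster_start in _cluster_indices(cand, gap=lag):
        s = cluster_start + lag  # first index at the lower level
        if s <= last_end or n - s < _MIN_DARK_RUN:
            continue
        pre = np.median(smooth[max(0, s - 2 * lag) : max(1, s - 2)])
        # recovering (a blink): some later sustained stretch climbs back to
        # the pre-step level; a true bleach step never does
        post = smooth[s + 2 :]
        above = post > pre - 3.0 * sigma
        recovers = any(length >= 3 for _, length in _runs(above))
        if not recovers:
            n_steps += 1
            last_end = s + lag
    if bleach_frame is not None and n_steps == 0:
        n_steps = 1  # terminal dark run is itself the (single) step
    return n_steps, bleach_frame


def _cluster_indices(idx: np.ndarray, gap: int):
    """First index of each cluster of near-adjacent candidate positions."""
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > gap)
    starts = np.concatenate([[0], breaks + 1])
    return [int(idx[s]) for s in starts]


def count_blinks(
    donor: np.ndarray,
    acceptor: np.ndarray,
    bleach_frame: int | None,
    background_level: float,
    background_noise_sd: float,
) -> int:
    """Number of recovering dark excursions before the bleach.

    A blink is a maximal run of sub-threshold total intensity, 1-20 frames
    long, strictly before ``bleach_frame``. Longer recovering dark runs are
    also counted but flagged with a warning (ambiguous photophysics).
    """
    total = np.asarray(donor, dtype=float) + np.asarray(acceptor, dtype=float)
    end = total.size if bleach_frame is None else int(bleach_frame)
    if end <= 0:
        return 0
    thresh = _dark_threshold(background_level, background_noise_sd)
    dark = total[:end] < thresh
    # isolated bright noise pops do not split a blink in two
    bright_sustained = np.zeros(end, dtype=bool)
    for start, length in _runs(~dark):
        if length >= 2:
            bright_sustained[start : start + length] = True
    count = 0
    for _, length in _runs(~bright_sustained):
        count += 1
        if length > _MAX_BLINK_RUN:
            warnings.warn(
                f"dark run of {length} frames (> {_MAX_BLINK_RUN}) counted as a blink",
                stacklevel=2,
            )
    return count


def compute_snr(
    donor: np.ndarray,
    acceptor: np.ndarray,
    bleach_frame: int | None,
    background_level: float,
    background_noise_sd: float,
    min_post_frames: int = 10,
) -> tuple[float, float]:
    """(signal/background-noise, signal/signal-noise) ratios.

    Background level and noise are estimated from the post-bleach tail when
    at least ``min_post_frames`` frames are available; otherwise the
    metadata values are used as a fallback.
    """
    total = np.asarray(donor, dtype=float) + np.asarray(acceptor, dtype=float)
    n = total.size
    if bleach_frame is not None and n - bleach_frame >= min_post_frames:
        post = total[bleach_frame + 1 :]
        bg_mean = float(np.mean(post))
        bg_sd = float(np.std(post, ddof=1))
        pre = total[:bleach_frame]
    else:
        bg_mean = 2.0 * background_level
        bg_sd = np.sqrt(2.0) * background_noise_sd
        pre = total if bleach_frame is None else total[:bleach_frame]
    if pre.size < 2:
        return np.nan, np.nan
    sig_mean = float(np.mean(pre))
    sig_sd = float(np.std(pre, ddof=1))
    if bg_sd <= 0 or sig_sd <= 0:
        return np.nan, np.nan
    return (sig_mean - bg_mean) / bg_sd, sig_mean / sig_sd


def donor_acceptor_correlation(
    donor: np.ndarray,
    acceptor: np.ndarray,
    bleach_frame: int | None,
    background_level: float = 0.0,
    subtract_background: bool = False,
) -> float:
    """Pearson correlation of donor vs acceptor over pre-bleach frames.

    The correlation is invariant to subtracting a constant background, so
    the raw and background-subtracted variants coincide on constant
    backgrounds; both are reported for transparency.
    """
    end = len(donor) if bleach_frame is None else int(bleach_frame)
    d = np.asarray(donor, dtype=float)[:end]
    a = np.asarray(acceptor, dtype=float)[:end]
    if subtract_background:
        d = d - background_level
        a = a - background_level
    if d.size < 2 or np.std(d) == 0 or np.std(a) == 0:
        return np.nan
    return float(np.corrcoef(d, a)[0, 1])


def qc_metrics(trace_id, donor, acceptor, background_level, background_noise_sd) -> QCMetrics:
    """All per-trace QC metrics (no pass/fail decision)."""
    n_steps, bleach_frame = detect_bleach(donor, acceptor, background_level, background_noise_sd)
    n_blinks = count_blinks(donor, acceptor, bleach_frame, background_level, background_noise_sd)
    snr_bg, snr_sig = compute_snr(donor, acceptor, bleach_frame, background_level, background_noise_sd)
    r = donor_acceptor_correlation(donor, acceptor, bleach_frame)
    r_sub = donor_acceptor_correlation(
        donor, acceptor, bleach_frame, background_level, subtract_background=True
    )
    return QCMetrics(
        trace_id=str(trace_id),
        snr_background=snr_bg,
        snr_signal=snr_sig,
        n_bleach_steps=n_steps,
        bleach_frame=bleach_frame,
        n_blinks=n_blinks,
        donor_acceptor_corr=r,
        corr_background_subtracted=r_sub,
    )


def _apply_criteria(m: QCMetrics, c: QCCriteria) -> QCMetrics:
    reasons = []
    if c.require_single_bleach and not (m.n_bleach_steps == 1 and m.bleach_frame is not None):
        reasons.append("bleach")
    # a non-positive threshold disables a ratio criterion (vacuous filter);
    # an undefined metric fails any active criterion
    if c.min_snr_background > 0 and not (
        np.isfinite(m.snr_background) and m.snr_background >= c.min_snr_background
    ):
        reasons.append("snr_background")
    if c.min_snr_signal > 0 and not (
        np.isfinite(m.snr_signal) and m.snr_signal >= c.min_snr_signal
    ):
        reasons.append("snr_signal")
    if m.n_blinks > c.max_blinks:
        reasons.append("blinks")
    if c.max_correlation < 1 and not (
        np.isfinite(m.donor_acceptor_corr) and m.donor_acceptor_corr < c.max_correlation
    ):
        reasons.append("correlation")
    m.failure_reasons = tuple(reasons)
    m.passed = not reasons
    return m


def select_traces(
    traceset: TraceSet, criteria: QCCriteria | None = None
) -> tuple[TraceSet, pd.DataFrame]:
    """Apply the selection criteria; returns (filtered set, QC report).

    The report has one row per input trace with every metric, the pass flag
    and the failure reasons; the pass flag is the conjunction of the
    individual criterion flags. Filtering is idempotent.
    """
    if criteria is None:
        criteria = QCCriteria()
    if traceset.n_traces == 0:
        raise EmptyDatasetError("select_traces needs a non-empty TraceSet")
    bg = traceset.meta.background_level
    bg_sd = traceset.meta.background_noise_sd
    rows = []
    passed_ids = []
    for tid, sub in traceset.iter_traces():
        m = qc_metrics(tid, sub["donor"].to_numpy(), sub["acceptor"].to_numpy(), bg, bg_sd)
        m = _apply_criteria(m, criteria)
        rows.append(
            {
                "trace_id": m.trace_id,
                "snr_background": m.snr_background,
                "snr_signal": m.snr_signal,
                "n_bleach_steps": m.n_bleach_steps,
                "bleach_frame": m.bleach_frame,
                "n_blinks": m.n_blinks,
                "donor_acceptor_corr": m.donor_acceptor_corr,
                "corr_background_subtracted": m.corr_background_subtracted,
                "passed": m.passed,
                "failure_reasons": ";".join(m.failure_reasons),
            }
        )
        if m.passed:
            passed_ids.append(tid)
    report = pd.DataFrame(rows).astype({"bleach_frame": "Int64"})
    return traceset.subset(passed_ids), report
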