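"""Hidden-Markov idealization of FRET trajectories.

The emission side of the HMM is *fixed*: each state is defined by a Gaussian
at the model's FRET mean/width (the "value ± width" state definitions), so
only the transition matrix is learned. Estimation pools all traces of a
dataset into one expectation-maximization fit (stabilizing rates at
desk-scale trace counts), after which each trace is idealized independently
with the Viterbi algorithm. The numerical engine is ``hmmlearn``'s
GaussianHMM restricted to transition-only updates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .errors import EmptyDatasetError, ValidationError
from .io import IdealizedSet, TraceSet
from .schemes import HMMModelSpec, builtin_model

__all__ = [
    "IdealizedPath",
    "TransitionFit",
    "compute_fret",
    "fit_transitions",
    "viterbi_idealize",
    "idealize_dataset",
    "dwell_segments",
]

FRET_CLAMP = (-0.2, 1.2)  # working range for fitting; reports clamp to [0, 1]
_STICKY_SELF_PROB = 0.95
_EM_TOL_PER_FRAME = 1e-6
_EM_MAX_ITER = 500


@dataclass
class IdealizedPath:
    """Viterbi idealization of one trace."""

    trace_id: str
    states: np.ndarray  # per-frame state index
    fret: np.ndarray  # per-frame FRET used for idealization
    dwells: list  # (state, start_frame, n_frames) partitioning the frames
    log_likelihood: float


@dataclass
class TransitionFit:
    """Pooled transition-matrix estimate with EM diagnostics."""

    model: HMMModelSpec  # includes the fitted transmat
    occupancy: np.ndarray  # expected per-state occupancy under the fit
    log_likelihood: float
    loglik_history: list
    converged: bool
    n_iter: int


def compute_fret(
    donor: np.ndarray,
    acceptor: np.ndarray,
    background_level: float,
    bleach_frame: int | None,
    max_bad_fraction: float = 0.1,
) -> np.ndarray:
    """Background-corrected FRET efficiency over pre-bleach frames.

    E = (A - bg) / ((A - bg) + (D - bg)), clamped to [-0.2, 1.2] for
    fitting. Frames at/after the bleach are excluded. Frames whose total
    background-corrected intensity is non-positive (blinks) are set to 0;
    if they exceed ``max_bad_fraction`` of frames the trace is rejected.
    """
    end = len(donor) if bleach_frame is None else int(bleach_frame)
    d = np.asarray(donor, dtype=float)[:end] - background_level
    a = np.asarray(acceptor, dtype=float)[:end] - background_level
    den = d + a
    bad = den <= 0
    if end > 0 and bad.mean() > max_bad_fraction:
        raise ValidationError(
            f"non-positive total intensity on {bad.mean():.0%} of pre-bleach frames"
        )
    E = np.zeros(end)
    np.divide(a, den, out=E, where=~bad)
    return np.clip(E, *FRET_CLAMP)


def _sticky_transmat(n: int) -> np.ndarray:
    tm = np.full((n, n), (1.0 - _STICKY_SELF_PROB) / max(n - 1, 1))
    np.fill_diagonal(tm, _STICKY_SELF_PROB if n > 1 else 1.0)
    return tm


def _build_hmm(model: HMMModelSpec, n_iter: int, tol: float) -> GaussianHMM:
    hmm = GaussianHMM(
        n_components=model.n_states,
        covariance_type="diag",
        init_params="",
        params="t",  # emissions and start probabilities stay frozen
        n_iter=n_iter,
        tol=tol,
    )
    hmm.startprob_ = model.startprob.copy()
    hmm.transmat_ = (
        model.transmat.copy() if model.transmat is not None else _sticky_transmat(model.n_states)
    )
    hmm.means_ = model.means.reshape(-1, 1).copy()
    hmm.covars_ = (model.sds**2).reshape(-1, 1).copy()
    return hmm


def fit_transitions(
    fret_traces: list[np.ndarray],
    model: HMMModelSpec,
    max_iter: int = _EM_MAX_ITER,
    tol_per_frame: float = _EM_TOL_PER_FRAME,
) -> TransitionFit:
    """Estimate one shared transition matrix from pooled traces by EM.

    Emission means/widths and the initial distribution are held at the model
    values. Convergence: log-likelihood improvement below ``tol_per_frame``
    per frame, or ``max_iter`` sweeps (then a warning is issued and the
    best-so-far estimate returned, flagged via ``converged=False``).
    """
    seqs = [np.asarray(x, dtype=float).reshape(-1, 1) for x in fret_traces if len(x) >= 2]
    if len(seqs) == 0:
        raise EmptyDatasetError("no usable traces for transition fitting")
    lengths = [len(s) for s in seqs]
    X = np.concatenate(seqs)
    hmm = _build_hmm(model, n_iter=max_iter, tol=tol_per_frame * len(X))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # hmmlearn chatters about frozen params
        hmm.fit(X, lengths)
    converged = bool(hmm.monitor_.converged)
    if not converged:
        warnings.warn(
            f"transition EM did not converge within {max_iter} iterations; "
            "returning best-so-far estimate"
        )
    fitted = model.with_transmat(hmm.transmat_)
    post = hmm.predict_proba(X, lengths)
    occupancy = post.mean(axis=0)
    history = list(hmm.monitor_.history)
    return TransitionFit(
        model=fitted,
        occupancy=occupancy,
        log_likelihood=float(history[-1]) if history else float("nan"),
        loglik_history=[float(h) for h in history],
        converged=converged,
        n_iter=int(hmm.monitor_.iter),
    )


def dwell_segments(states: np.ndarray) -> list:
    """Run-length encode a state path into (state, start, n_frames) dwells."""
    states = np.asarray(states, dtype=int)
    if states.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(states) != 0)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [states.size]])
    return [(int(states[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def viterbi_idealize(
    fret: np.ndarray, model: HMMModelSpec, trace_id: str = "trace"
) -> IdealizedPath:
    """Most probable state path under the fixed-emission HMM."""
    fret = np.asarray(fret, dtype=float)
    if fret.size == 0 or not np.all(np.isfinite(fret)):
        raise ValidationError("viterbi_idealize needs a finite, non-empty FRET trace")
    if model.transmat is None:
        raise ValidationError("model has no transition matrix; run fit_transitions first")
    hmm = _build_hmm(model, n_iter=1, tol=1.0)
    loglik, states = hmm.decode(fret.reshape(-1, 1), algorithm="viterbi")
    return IdealizedPath(
        trace_id=trace_id,
        states=states,
        fret=fret,
        dwells=dwell_segments(states),
        log_likelihood=float(loglik),
    )


def idealize_dataset(
    traceset: TraceSet,
    model: HMMModelSpec | str,
    bleach_frames: dict,
    max_iter: int = _EM_MAX_ITER,
) -> tuple[IdealizedSet, TransitionFit, dict]:
    """QC-passed traces -> pooled transition fit -> per-trace Viterbi paths.

    ``bleach_frames`` maps trace_id to the detected bleach frame (or None).
    Traces whose FRET cannot be computed (too many dark frames) are dropped
    with a warning. Returns (IdealizedSet, TransitionFit, {trace_id:
    IdealizedPath}).
    """
    if isinstance(model, str):
        model = builtin_model(model)
    bg = traceset.meta.background_level
    fret_by_id = {}
    for tid, sub in traceset.iter_traces():
        try:
            E = compute_fret(
                sub["donor"].to_numpy(), sub["acceptor"].to_numpy(), bg, bleach_frames.get(tid)
            )
        except ValidationError as exc:
            warnings.warn(f"dropping trace {tid!r}: {exc}")
            continue
        if len(E) >= 2:
            fret_by_id[tid] = E
    if not fret_by_id:
        raise EmptyDatasetError("no traces with usable FRET")
    fit = fit_transitions(list(fret_by_id.values()), model, max_iter=max_iter)
    paths = {}
    parts = []
    labels = np.array(fit.model.state_labels)
    for tid, E in fret_by_id.items():
        path = viterbi_idealize(E, fit.model, trace_id=tid)
        paths[tid] = path
        parts.append(
            pd.DataFrame(
                {
                    "trace_id": tid,
                    "frame": np.arange(len(E)),
                    "fret": np.clip(E, 0.0, 1.0),
                    "state_index": path.states,
                    "state_label": labels[path.states],
                }
            )
        )
    ideal = IdealizedSet(frames=pd.concat(parts, ignore_index=True), model=fit.model.to_dict())
    return ideal, fit, paths
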