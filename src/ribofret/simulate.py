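"""Synthetic smFRET trace generation with known ground truth.

The generator emulates camera-based single-molecule recordings of ribosome
complexes at a 15 ms frame interval:

* **Selection presets** (``ctrl-phe``, ``sg24-phe``, ``ctrl-lys``,
  ``sg24-lys``) model stop-flow delivery of ternary complex to immobilized
  initiation complexes. After the delivery dead time, each molecule draws a
  productive accommodation time from a two-phase hazard (a dominant fast
  phase at rate ``lambda_prod = kcat_km_true * [TC]`` and a minor slow
  phase); before accommodation it shows transient non-productive binding
  excursions (0.2 <-> 0.46 FRET) that end in ternary-complex dissociation,
  and accommodation itself appears as a stepwise 0.2 -> 0.46 -> 0.72
  progression ending in a stable 0.72 dwell.
* **Pre-translocation presets** (``pretrans-low``, ``pretrans-high``) are
  stationary three-state CTMCs over the hybrid-2 / hybrid-1 / classical tRNA
  configurations (0.22 / 0.42 / 0.72 FRET), with exchange rates constructed
  to hit a prescribed classical-state occupancy.

Photophysics: truncated-Gaussian per-frame FRET emission, additive Gaussian
channel noise over a constant background, Poisson donor blinking with
exponential dark durations, and a single catastrophic exponential-time donor
bleach after which both channels fall to background.

All randomness derives from one integer seed through ``numpy`` seed
sequences; each trace uses the substream ``SeedSequence(seed, spawn_key=(i,))``
so datasets are reproducible trace-by-trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .errors import ValidationError
from .io import TraceMeta, TraceSet
from .schemes import KineticScheme, PhotophysicsParams, exchange_scheme

__all__ = [
    "SimulatedTrace",
    "Preset",
    "PRESETS",
    "get_preset",
    "sample_state_path",
    "render_trace",
    "simulate_dataset",
]

# state indices of the selection scheme
_UNBOUND, _INITIAL, _GTPASE, _ACCOM = 0, 1, 2, 3


@dataclass
class SimulatedTrace:
    """One rendered molecule with its ground truth."""

    trace_id: str
    times: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    true_state_path: np.ndarray
    true_fret: np.ndarray
    true_arrival_frame: int | None = None
    bleach_frame: int | None = None
    n_blinks: int = 0
    phase: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0) or np.ptp(dt) > 1e-9:
                raise ValidationError("times must be strictly increasing and uniform")
        if not (np.all(np.isfinite(self.donor)) and np.all(np.isfinite(self.acceptor))):
            raise ValidationError("intensities must be finite")
        if (
            self.true_arrival_frame is not None
            and self.bleach_frame is not None
            and not self.true_arrival_frame < self.bleach_frame
        ):
            # arrival after bleach is unobservable; drop it from the truth
            self.true_arrival_frame = None


def _trace_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _truncnorm01(rng: np.random.Generator, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Normal(mu, sd) truncated to [0, 1], via inverse-CDF sampling."""
    lo = ndtr((0.0 - mu) / sd)
    hi = ndtr((1.0 - mu) / sd)
    u = rng.random(np.shape(mu))
    return np.clip(mu + sd * ndtri(lo + u * (hi - lo)), 0.0, 1.0)


# ---------------------------------------------------------------------------
# CTMC simulation


def _sample_jump_segments(scheme: KineticScheme, duration: float, rng) -> list:
    """Exact Gillespie realization: list of (t_start, t_end, state)."""
    exit_rates = scheme.exit_rates()
    P = scheme.jump_matrix()
    n = scheme.n_states
    s = int(rng.choice(n, p=scheme.initial_distribution))
    t = 0.0
    segs = []
    while t < duration:
        if exit_rates[s] <= 0:  # absorbing
            segs.append((t, duration, s))
            break
        dwell = rng.exponential(1.0 / exit_rates[s])
        segs.append((t, min(t + dwell, duration), s))
        t += dwell
        if t >= duration:
            break
        s = int(rng.choice(n, p=P[s]))
    return segs


def _majority_discretize(segments, n_frames: int, dt: float, n_states: int) -> np.ndarray:
    """Assign each frame the state occupied for the majority of its interval.

    Ties (exactly equal occupation) break toward the lower state index.
    """
    occ = np.zeros((n_frames, n_states))
    t_end = n_frames * dt
    for t0, t1, s in segments:
        a, b = max(t0, 0.0), min(t1, t_end)
        if b <= a:
            continue
        f0 = int(a // dt)
        f1 = min(int(np.ceil(b / dt)), n_frames)
        frames = np.arange(f0, f1)
        lo = np.maximum(a, frames * dt)
        hi = np.minimum(b, (frames + 1) * dt)
        occ[frames, s] += hi - lo
    return occ.argmax(axis=1)


def sample_state_path(
    scheme: KineticScheme,
    duration: float,
    dt: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate the CTMC exactly and discretize to a per-frame state path.

    The continuous jump process is realized with the Gillespie algorithm,
    then each frame of width ``dt`` takes the state occupied for the
    majority of that frame (mimicking camera integration). Once an absorbing
    state is entered the path stays there.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    if duration < dt:
        raise ValidationError("duration must cover at least one frame")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_frames = int(round(duration / dt))
    segs = _sample_jump_segments(scheme, n_frames * dt, rng)
    return _majority_discretize(segs, n_frames, dt, scheme.n_states)


# ---------------------------------------------------------------------------
# Rendering


def render_trace(
    path: np.ndarray,
    scheme: KineticScheme,
    photophysics: PhotophysicsParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    dt: float = 0.015,
    trace_id: str = "trace",
) -> SimulatedTrace:
    """Render a state path into donor/acceptor intensity time series.

    Per live frame the FRET efficiency ``E`` is drawn from a Gaussian at the
    state's mean/width truncated to [0, 1]; acceptor = E * I_tot and donor =
    (1 - E) * I_tot, each plus background and Gaussian channel noise. Donor
    blink intervals and all frames at/after the single-step donor bleach
    drop both channels to background (background noise only).
    """
    path = np.asarray(path, dtype=int)
    if path.size < 1:
        raise ValidationError("path must contain at least one frame")
    if rng is None:
        rng = np.random.default_rng(seed)
    pp = photophysics
    n = path.size
    times = np.arange(n) * dt

    E = _truncnorm01(rng, scheme.fret_mean[path], scheme.fret_sd[path])

    # single catastrophic donor bleach
    bleach_frame: int | None = None
    if pp.donor_bleach_rate > 0:
        t_bleach = rng.exponential(1.0 / pp.donor_bleach_rate)
        if t_bleach < n * dt:
            bleach_frame = int(t_bleach // dt)

    # donor blinking: Poisson arrivals, exponential dark durations
    dark = np.zeros(n, dtype=bool)
    n_blinks = 0
    live_end = n * dt if bleach_frame is None else bleach_frame * dt
    if pp.blink_rate > 0 and pp.blink_mean_duration > 0:
        t = rng.exponential(1.0 / pp.blink_rate)
        while t < live_end:
            dur = rng.exponential(pp.blink_mean_duration)
            f0 = int(t // dt)
            f1 = max(int(np.ceil((t + dur) / dt)), f0 + 1)
            f1 = min(f1, n)
            if f0 < n:
                dark[f0:f1] = True
                n_blinks += 1
            t = t + dur + rng.exponential(1.0 / pp.blink_rate)
    if bleach_frame is not None:
        dark[bleach_frame:] = True

    signal = ~dark
    acceptor = np.empty(n)
    donor = np.empty(n)
    acceptor[signal] = E[signal] * pp.total_intensity
    donor[signal] = (1.0 - E[signal]) * pp.total_intensity
    acceptor[signal] += pp.background_level + rng.normal(0.0, pp.channel_noise_sd, signal.sum())
    donor[signal] += pp.background_level + rng.normal(0.0, pp.channel_noise_sd, signal.sum())
    acceptor[dark] = pp.background_level + rng.normal(0.0, pp.background_noise_sd, dark.sum())
    donor[dark] = pp.background_level + rng.normal(0.0, pp.background_noise_sd, dark.sum())

    return SimulatedTrace(
        trace_id=trace_id,
        times=times,
        donor=donor,
        acceptor=acceptor,
        true_state_path=path,
        true_fret=E,
        bleach_frame=bleach_frame,
        n_blinks=n_blinks,
    )


# ---------------------------------------------------------------------------
# Presets


@dataclass(frozen=True)
class Preset:
    """A named study condition with its ground truth.

    ``ground_truth`` records the quantities the preset encodes (productive
    fast-phase hazard, slow-phase hazard and amplitude, kcat/KM, or the
    classical/hybrid occupancy fractions) so downstream estimates can be
    checked against them.
    """

    name: str
    kind: str  # "selection" | "pretranslocation"
    scheme: KineticScheme
    photophysics: PhotophysicsParams
    ternary_concentration_uM: float
    n_frames: int
    codon: str
    fluorophore_pair: str
    model_name: str
    frame_interval_s: float = 0.015
    ground_truth: dict = field(default_factory=dict)
    # selection-kinetics parameters (unused for pre-translocation presets)
    lambda_slow: float = 0.05
    amp_fast: float = 0.9
    nonproductive_rate: float = 0.25

    def __post_init__(self):
        gt = self.ground_truth
        if self.kind == "selection":
            lam = gt["lambda_prod"]
            expected = gt["kcat_km_true"] * self.ternary_concentration_uM
            if abs(lam - expected) > 1e-9:
                raise ValidationError(
                    "lambda_prod must equal kcat_km_true * ternary_concentration"
                )
        elif self.kind == "pretranslocation":
            occ = np.array(
                [gt["hybrid2_occupancy"], gt["hybrid1_occupancy"], gt["classical_occupancy"]]
            )
            if abs(occ.sum() - 1.0) > 1e-9:
                raise ValidationError("ground-truth occupancies must sum to 1")
        else:
            raise ValidationError(f"unknown preset kind {self.kind!r}")


_SELECTION_SCHEME_STATES = ("unbound", "initial", "gtpase", "accommodated")
_SELECTION_MEANS = np.array([0.0, 0.2, 0.46, 0.72])
_SELECTION_SDS = np.array([0.05, 0.075, 0.075, 0.075])


def _selection_scheme(lambda_prod: float) -> KineticScheme:
    # nominal CTMC representation of the selection pathway; the dataset
    # generator uses the two-phase competing-hazard construction below, with
    # this scheme supplying state definitions and representative rates
    Q = np.zeros((4, 4))
    Q[_UNBOUND, _INITIAL] = lambda_prod
    Q[_INITIAL, _UNBOUND] = 12.0
    Q[_INITIAL, _GTPASE] = 25.0
    Q[_GTPASE, _ACCOM] = 25.0
    return KineticScheme(
        state_names=_SELECTION_SCHEME_STATES,
        fret_mean=_SELECTION_MEANS,
        fret_sd=_SELECTION_SDS,
        rate_matrix=Q,
        initial_distribution=np.array([1.0, 0.0, 0.0, 0.0]),
        absorbing_states=("accommodated",),
    )


def _make_selection_preset(name, codon, fluorophore, kcat_km_true, conc_uM=0.01, n_frames=3000):
    lam = kcat_km_true * conc_uM
    return Preset(
        name=name,
        kind="selection",
        scheme=_selection_scheme(lam),
        photophysics=PhotophysicsParams(),
        ternary_concentration_uM=conc_uM,
        n_frames=n_frames,
        codon=codon,
        fluorophore_pair=fluorophore,
        model_name="selection4",
        ground_truth={
            "kcat_km_true": kcat_km_true,
            "lambda_prod": lam,
            "lambda_slow": 0.05,
            "amp_fast": 0.9,
            "k_bleach": PhotophysicsParams().donor_bleach_rate,
        },
    )


def _make_pretrans_preset(name, classical, n_frames=600, exchange_rate=2.0):
    # split the non-classical remainder between hybrid-1 and hybrid-2 55:45
    rem = 1.0 - classical
    occ = np.array([0.45 * rem, 0.55 * rem, classical])  # H2, H1, C
    scheme = exchange_scheme(
        ("hybrid2", "hybrid1", "classical"),
        fret_mean=np.array([0.22, 0.42, 0.72]),
        fret_sd=np.array([0.075, 0.075, 0.075]),
        occupancy=occ,
        exchange_rate=exchange_rate,
    )
    return Preset(
        name=name,
        kind="pretranslocation",
        scheme=scheme,
        photophysics=PhotophysicsParams(),
        ternary_concentration_uM=0.0,
        n_frames=n_frames,
        codon="UUC",
        fluorophore_pair="Cy3/LD655",
        model_name="pretrans3",
        ground_truth={
            "classical_occupancy": float(occ[2]),
            "hybrid1_occupancy": float(occ[1]),
            "hybrid2_occupancy": float(occ[0]),
            "exchange_rate": exchange_rate,
            "k_bleach": PhotophysicsParams().donor_bleach_rate,
        },
    )


PRESETS: dict[str, Preset] = {
    "ctrl-phe": _make_selection_preset("ctrl-phe", "UUC", "Cy3/LD655", 50.0),
    "sg24-phe": _make_selection_preset("sg24-phe", "UUC", "Cy3/LD655", 71.0),
    "ctrl-lys": _make_selection_preset("ctrl-lys", "AAA", "Cy3/LD650", 27.0),
    "sg24-lys": _make_selection_preset("sg24-lys", "AAA", "Cy3/LD650", 36.0),
    "pretrans-low": _make_pretrans_preset("pretrans-low", 0.15),
    "pretrans-high": _make_pretrans_preset("pretrans-high", 0.20),
}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


# ---------------------------------------------------------------------------
# Selection-event path construction


def _selection_segments(preset: Preset, rng) -> tuple[list, float | None, str]:
    """Continuous-time state segments for one selection molecule.

    Returns (segments, arrival_time or None, phase). The productive
    accommodation time T is drawn from the two-phase hazard starting after
    the delivery dead time; the stepwise 0.2 -> 0.46 progression occupies the
    interval just before T so that reaching 0.72 happens exactly at T.
    """
    pp = preset.photophysics
    t_end = preset.n_frames * preset.frame_interval_s
    lam_fast = preset.ground_truth["lambda_prod"]
    fast = rng.random() < preset.amp_fast
    lam = lam_fast if fast else preset.lambda_slow
    T = pp.dead_time + rng.exponential(1.0 / lam)

    d_gtpase = rng.exponential(0.04)
    d_initial = rng.exponential(0.04)
    prog_start = max(T - d_initial - d_gtpase, pp.dead_time)
    prog_mid = max(T - d_gtpase, prog_start)

    segs = []
    # non-productive excursions while waiting: transient 0.2 (and 0.46)
    # dwells ending in dissociation back to zero FRET
    t = pp.dead_time
    horizon = min(prog_start, t_end)
    t += rng.exponential(1.0 / preset.nonproductive_rate)
    while t < horizon:
        bound = True
        while bound and t < horizon:
            dw = rng.exponential(0.08)
            segs.append((t, min(t + dw, horizon), _INITIAL))
            t += dw
            if t >= horizon:
                break
            if rng.random() < 0.45:
                dw = rng.exponential(0.06)
                segs.append((t, min(t + dw, horizon), _GTPASE))
                t += dw
                bound = rng.random() < 0.5  # fall back to 0.2 or dissociate
            else:
                bound = False
        t += rng.exponential(1.0 / preset.nonproductive_rate)

    arrival: float | None = None
    if prog_start < t_end:
        segs.append((prog_start, min(prog_mid, t_end), _INITIAL))
        if prog_mid < t_end:
            segs.append((prog_mid, min(T, t_end), _GTPASE))
        if T < t_end:
            segs.append((T, t_end, _ACCOM))
            arrival = T

    # fill the complement with the unbound state
    segs = [(a, b, s) for a, b, s in segs if b > a]
    segs.sort(key=lambda x: x[0])
    full = []
    cursor = 0.0
    for a, b, s in segs:
        if a > cursor:
            full.append((cursor, a, _UNBOUND))
        full.append((a, b, s))
        cursor = b
    if cursor < t_end:
        full.append((cursor, t_end, _UNBOUND))
    return full, arrival, "fast" if fast else "slow"


# ---------------------------------------------------------------------------
# Dataset generation


def simulate_dataset(
    preset: Preset | str,
    n_traces: int,
    seed: int,
    return_traces: bool = False,
):
    """Generate a reproducible trace dataset plus its ground-truth table.

    Returns ``(TraceSet, ground_truth_df)`` or, with ``return_traces=True``,
    ``(TraceSet, ground_truth_df, [SimulatedTrace, ...])``.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if n_traces < 1:
        raise ValidationError("n_traces must be >= 1")
    dt = preset.frame_interval_s
    duration = preset.n_frames * dt

    frames_parts = []
    gt_rows = []
    sim_traces = []
    for i in range(n_traces):
        rng = _trace_rng(seed, i)
        tid = f"{preset.name}-{i:04d}"
        if preset.kind == "selection":
            segs, arrival_t, phase = _selection_segments(preset, rng)
            path = _majority_discretize(segs, preset.n_frames, dt, preset.scheme.n_states)
            arrival_frame = None if arrival_t is None else int(arrival_t // dt)
        else:
            path = sample_state_path(preset.scheme, duration, dt, rng=rng)
            arrival_frame, phase = None, ""
        tr = render_trace(
            path, preset.scheme, preset.photophysics, rng=rng, dt=dt, trace_id=tid
        )
        tr.true_arrival_frame = arrival_frame
        tr.phase = phase
        tr.__post_init__()  # re-check arrival/bleach ordering
        gt_rows.append(
            {
                "trace_id": tid,
                "arrival_frame": tr.true_arrival_frame,
                "bleach_frame": tr.bleach_frame,
                "n_blinks": tr.n_blinks,
                "phase": phase,
                "productive": tr.true_arrival_frame is not None,
            }
        )
        frames_parts.append(
            pd.DataFrame(
                {
                    "trace_id": tid,
                    "frame": np.arange(preset.n_frames),
                    "time_s": tr.times,
                    "donor": tr.donor,
                    "acceptor": tr.acceptor,
                }
            )
        )
        if return_traces:
            sim_traces.append(tr)

    meta = TraceMeta(
        frame_interval_s=dt,
        condition=preset.name,
        codon=preset.codon,
        fluorophore_pair=preset.fluorophore_pair,
        ternary_concentration_uM=preset.ternary_concentration_uM,
        background_level=preset.photophysics.background_level,
        background_noise_sd=preset.photophysics.background_noise_sd,
        extras={
            "preset": preset.name,
            "kind": preset.kind,
            "model": preset.model_name,
            "seed": seed,
            "ground_truth": preset.ground_truth,
        },
    )
    traceset = TraceSet(frames=pd.concat(frames_parts, ignore_index=True), meta=meta)
    gt = pd.DataFrame(gt_rows).astype(
        {"arrival_frame": "Int64", "bleach_frame": "Int64"}
    )
    if return_traces:
        return traceset, gt, sim_traces
    return traceset, gt
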