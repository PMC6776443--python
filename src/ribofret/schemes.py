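"""Kinetic schemes and idealization model specifications.

A :class:`KineticScheme` is a labeled continuous-time Markov chain over FRET
states: each state carries a mean FRET efficiency and a Gaussian emission
width, and transitions occur with first-order rates (s^-1) collected in a
generator-style rate matrix (off-diagonal entries only; diagonals are implied
by conservation). Absorbing states (a dissociated complex, a bleached dye)
simply have zero exit rates.

An :class:`HMMModelSpec` is the observation-side counterpart used for
idealization: a fixed set of Gaussian emission means/widths. The two
experimental models are provided as built-ins:

* ``selection4`` — aa-tRNA selection: unbound (0.0), initial binding (0.2),
  GTPase-activated (0.46) and accommodated (0.72) states.
* ``pretrans3`` — pre-translocation complex: hybrid-2 (0.22), hybrid-1
  (0.42) and classical (0.72) tRNA configurations; ``pretrans3-lys`` places
  the classical state at 0.61 for the LD650-labeled Lys-tRNA dye pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml

from .errors import ValidationError

__all__ = [
    "KineticScheme",
    "PhotophysicsParams",
    "HMMModelSpec",
    "exchange_scheme",
    "builtin_model",
    "BUILTIN_MODELS",
]


def _as_prob_vector(p, n, what):
    p = np.asarray(p, dtype=float)
    if p.shape != (n,):
        raise ValidationError(f"{what} must have length {n}, got shape {p.shape}")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"{what} must be a probability vector summing to 1")
    return p


@dataclass(frozen=True)
class KineticScheme:
    """Labeled CTMC over FRET states.

    Parameters
    ----------
    state_names:
        One label per state.
    fret_mean, fret_sd:
        Per-state emission mean (dimensionless, in [0, 1]) and Gaussian width.
    rate_matrix:
        (n, n) array of transition rates in s^-1; only off-diagonal entries
        are read, diagonals are ignored.
    initial_distribution:
        Start-state probabilities.
    absorbing_states:
        Names of states that, once entered, are never left (their rate rows
        must be zero).
    """

    state_names: tuple
    fret_mean: np.ndarray
    fret_sd: np.ndarray
    rate_matrix: np.ndarray
    initial_distribution: np.ndarray
    absorbing_states: tuple = ()

    def __post_init__(self):
        n = len(self.state_names)
        if len(set(self.state_names)) != n:
            raise ValidationError("state names must be unique")
        fm = np.asarray(self.fret_mean, dtype=float)
        fs = np.asarray(self.fret_sd, dtype=float)
        if fm.shape != (n,) or fs.shape != (n,):
            raise ValidationError("fret_mean/fret_sd must have one entry per state")
        if np.any(fm < 0) or np.any(fm > 1):
            raise ValidationError("fret_mean values must lie in [0, 1]")
        if np.any(fs <= 0):
            raise ValidationError("fret_sd values must be positive")
        Q = np.array(self.rate_matrix, dtype=float)
        if Q.shape != (n, n):
            raise ValidationError(f"rate_matrix must be ({n}, {n})")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0) or not np.all(np.isfinite(off)):
            raise ValidationError("off-diagonal rates must be finite and >= 0")
        np.fill_diagonal(Q, -off.sum(axis=1))
        pi0 = _as_prob_vector(self.initial_distribution, n, "initial_distribution")
        for name in self.absorbing_states:
            if name not in self.state_names:
                raise ValidationError(f"unknown absorbing state {name!r}")
            i = self.state_names.index(name)
            if off[i].sum() > 0:
                raise ValidationError(f"absorbing state {name!r} has exit rates")
        object.__setattr__(self, "state_names", tuple(self.state_names))
        object.__setattr__(self, "fret_mean", fm)
        object.__setattr__(self, "fret_sd", fs)
        object.__setattr__(self, "rate_matrix", Q)
        object.__setattr__(self, "initial_distribution", pi0)
        object.__setattr__(self, "absorbing_states", tuple(self.absorbing_states))

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def exit_rates(self) -> np.ndarray:
        off = self.rate_matrix.copy()
        np.fill_diagonal(off, 0.0)
        return off.sum(axis=1)

    def jump_matrix(self) -> np.ndarray:
        """Embedded jump-chain probabilities (rows of absorbing states are
        self-loops so every row sums to 1)."""
        off = self.rate_matrix.copy()
        np.fill_diagonal(off, 0.0)
        out = np.eye(self.n_states)
        exit_ = off.sum(axis=1)
        live = exit_ > 0
        out[live] = off[live] / exit_[live, None]
        out[live, live] = 0.0
        return out

    def stationary_distribution(self) -> np.ndarray:
        """Solve pi @ Q = 0 with sum(pi) = 1 (least squares, oracle-grade)."""
        n = self.n_states
        A = np.vstack([self.rate_matrix.T, np.ones((1, n))])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()


def exchange_scheme(state_names, fret_mean, fret_sd, occupancy, exchange_rate):
    """Build a reversible CTMC with a prescribed stationary distribution.

    Uses the independence-sampler construction Q_ij = k * pi_j (i != j),
    which satisfies pi @ Q = 0 for any target occupancy pi. The mean dwell
    time in state i is 1 / (k * (1 - pi_i)).
    """
    pi = np.asarray(occupancy, dtype=float)
    pi = pi / pi.sum()
    n = len(pi)
    Q = exchange_rate * np.tile(pi, (n, 1))
    np.fill_diagonal(Q, 0.0)
    return KineticScheme(
        state_names=tuple(state_names),
        fret_mean=fret_mean,
        fret_sd=fret_sd,
        rate_matrix=Q,
        initial_distribution=pi,
    )


@dataclass(frozen=True)
class PhotophysicsParams:
    """Fluorophore/detection parameters of a simulated recording.

    Intensities are in arbitrary camera units; rates in s^-1, durations in s.
    ``dead_time`` is the stop-flow delivery delay before ternary complex can
    reach the immobilized ribosomes.
    """

    total_intensity: float = 1000.0
    channel_noise_sd: float = 40.0
    background_level: float = 100.0
    background_noise_sd: float = 40.0
    donor_bleach_rate: float = 0.1
    blink_rate: float = 0.02
    blink_mean_duration: float = 0.06
    dead_time: float = 0.25

    def __post_init__(self):
        for name in ("donor_bleach_rate", "blink_rate", "blink_mean_duration", "dead_time"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.total_intensity <= self.background_level:
            raise ValidationError("total_intensity must exceed background_level")
        if self.channel_noise_sd < 0 or self.background_noise_sd < 0:
            raise ValidationError("noise sds must be >= 0")


@dataclass(frozen=True)
class HMMModelSpec:
    """Fixed Gaussian-emission model for idealization.

    Emission means/sds are state *definitions*, held fixed during fitting;
    only the transition matrix is estimated from data.
    """

    name: str
    state_labels: tuple
    means: np.ndarray
    sds: np.ndarray
    startprob: np.ndarray
    transmat: np.ndarray | None = None
    variant: str = ""

    def __post_init__(self):
        n = len(self.state_labels)
        mu = np.asarray(self.means, dtype=float)
        sd = np.asarray(self.sds, dtype=float)
        if mu.shape != (n,) or sd.shape != (n,):
            raise ValidationError("means/sds must have one entry per state")
        if len(np.unique(mu)) != n:
            raise ValidationError("emission means must be unique")
        if np.any(sd <= 0):
            raise ValidationError("emission sds must be positive")
        sp = _as_prob_vector(self.startprob, n, "startprob")
        tm = self.transmat
        if tm is not None:
            tm = np.asarray(tm, dtype=float)
            if tm.shape != (n, n) or np.any(tm < 0):
                raise ValidationError("transmat must be a nonnegative (n, n) matrix")
            if np.max(np.abs(tm.sum(axis=1) - 1.0)) > 1e-9:
                raise ValidationError("transmat rows must sum to 1")
        object.__setattr__(self, "state_labels", tuple(self.state_labels))
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "sds", sd)
        object.__setattr__(self, "startprob", sp)
        object.__setattr__(self, "transmat", tm)

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def with_transmat(self, transmat) -> "HMMModelSpec":
        return replace(self, transmat=np.asarray(transmat, dtype=float))

    def state_index(self, label: str) -> int:
        return self.state_labels.index(label)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "state_labels": list(self.state_labels),
            "means": [float(x) for x in self.means],
            "sds": [float(x) for x in self.sds],
            "startprob": [float(x) for x in self.startprob],
            "variant": self.variant,
        }
        if self.transmat is not None:
            d["transmat"] = [[float(x) for x in row] for row in self.transmat]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HMMModelSpec":
        return cls(
            name=d["name"],
            state_labels=tuple(d["state_labels"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            startprob=np.asarray(d["startprob"], dtype=float),
            transmat=np.asarray(d["transmat"], dtype=float) if "transmat" in d else None,
            variant=d.get("variant", ""),
        )

    @classmethod
    def from_yaml(cls, path) -> "HMMModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# Built-in idealization models. The selection model starts in the unbound
# (zero-FRET) state; the pre-translocation model starts uniform.
BUILTIN_MODELS = {
    "selection4": HMMModelSpec(
        name="selection4",
        state_labels=("unbound", "initial", "gtpase", "accommodated"),
        means=np.array([0.0, 0.2, 0.46, 0.72]),
        sds=np.array([0.05, 0.075, 0.075, 0.075]),
        startprob=np.array([1.0, 0.0, 0.0, 0.0]),
        variant="selection",
    ),
    "pretrans3": HMMModelSpec(
        name="pretrans3",
        state_labels=("hybrid2", "hybrid1", "classical"),
        means=np.array([0.22, 0.42, 0.72]),
        sds=np.array([0.075, 0.075, 0.075]),
        startprob=np.full(3, 1.0 / 3.0),
        variant="pretranslocation",
    ),
    "pretrans3-lys": HMMModelSpec(
        name="pretrans3-lys",
        state_labels=("hybrid2", "hybrid1", "classical"),
        means=np.array([0.22, 0.42, 0.61]),
        sds=np.array([0.075, 0.075, 0.05]),
        startprob=np.full(3, 1.0 / 3.0),
        variant="pretranslocation",
    ),
}


def builtin_model(name: str) -> HMMModelSpec:
    try:
        return BUILTIN_MODELS[name]
    except KeyError:
        raise ValidationError(
            f"unknown model {name!r}; available: {sorted(BUILTIN_MODELS)}"
        ) from None
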