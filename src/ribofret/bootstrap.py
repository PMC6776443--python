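"""Bootstrap uncertainties and the shifted-mean-null Welch test.

Every pipeline endpoint (kcat/KM, occupancy fractions) gets its uncertainty
from trace-level bootstrap resampling. Two conditions are compared with a
resampled implementation of Welch's t-test: the observed t statistic is
referenced against t statistics computed from *null* distributions obtained
by translating both distributions to their pooled mean, so equality of
means holds by construction and no t-distribution assumption is needed.

Two entry points cover the two kinds of input:

* :func:`welch_t` / :func:`shifted_null_pvalue` act on raw per-unit samples
  (one value per trace or dataset) with the classical var/n denominator.
* :func:`bootstrap_welch_test` acts on *bootstrap replicate distributions*
  of a dataset-level estimator: the replicate spread already estimates the
  estimator's SEM, so t = (mean_A - mean_B) / sqrt(sd_A^2 + sd_B^2) and each
  null t is formed from one draw per shifted replicate set. This is the
  statistic :func:`compare_conditions` reports.

The p-value uses the add-one rule p = (1 + #{|t_null| >= |t_obs|}) /
(n_null + 1); a zero exceedance count is additionally reported as the upper
bound p < 1/n_null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "BootstrapResult",
    "bootstrap_estimator",
    "welch_t",
    "shifted_null_pvalue",
    "bootstrap_welch_test",
    "compare_conditions",
]


@dataclass
class BootstrapResult:
    estimator_name: str
    estimate_a: float
    estimate_b: float
    sem_a: float
    sem_b: float
    replicates_a: np.ndarray
    replicates_b: np.ndarray
    t_observed: float
    n_null: int
    p_value: float
    p_is_upper_bound: bool
    seed: int | None
    n_boot: int = 0
    n_failed_a: int = 0
    n_failed_b: int = 0

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator_name,
            "estimate_a": self.estimate_a,
            "estimate_b": self.estimate_b,
            "sem_a": self.sem_a,
            "sem_b": self.sem_b,
            "t_observed": self.t_observed,
            "n_boot": self.n_boot,
            "n_null": self.n_null,
            "p_value": self.p_value,
            "p_is_upper_bound": self.p_is_upper_bound,
            "p_string": (f"< {1.0 / self.n_null:g}" if self.p_is_upper_bound
                         else f"{self.p_value:g}"),
            "seed": self.seed,
            "n_failed_replicates": [self.n_failed_a, self.n_failed_b],
        }


def bootstrap_estimator(items, estimator, n_boot: int, seed: int | None = None) -> np.ndarray:
    """Resample trace-level items with replacement and re-run the estimator.

    ``items`` is a sequence of per-trace records (whatever the estimator
    consumes as a list). Replicates on which the estimator raises are
    dropped with a warning; :func:`compare_conditions` records the dropped
    count in its report. Reproducible for a fixed seed.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100 for stable SEMs")
    items = list(items)
    n = len(items)
    if n == 0:
        raise ValidationError("cannot bootstrap an empty dataset")
    rng = np.random.default_rng(seed)
    reps = []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            reps.append(float(estimator([items[i] for i in idx])))
        except Exception:  # noqa: BLE001 - estimator may fail on a resample
            failed += 1
    if failed:
        warnings.warn(f"{failed}/{n_boot} bootstrap replicates failed and were dropped")
    out = np.asarray(reps, dtype=float)
    out = out[np.isfinite(out)]
    if out.size < 2:
        raise DegenerateDataError("too few successful bootstrap replicates")
    return out


def welch_t(reps_a, reps_b) -> float:
    """Welch's t on two samples: (mean_a - mean_b)/sqrt(var_a/n_a + var_b/n_b)."""
    a = np.asarray(reps_a, dtype=float)
    b = np.asarray(reps_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("welch_t needs >= 2 values per sample")
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    if va + vb == 0:
        raise DegenerateDataError("zero combined variance")
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def _addone_p(count: int, n_null: int) -> tuple[float, bool]:
    p = (1.0 + count) / (n_null + 1.0)
    return p, count == 0


def shifted_null_pvalue(
    reps_a, reps_b, n_null: int = 10**6, seed: int | None = None, batch: int = 10**5
) -> tuple[float, bool]:
    """Two-sided shifted-mean bootstrap p-value for raw samples.

    Both samples are translated to their pooled mean; ``n_null`` pairs of
    with-replacement resamples (original sizes) provide the null t
    distribution. Returns ``(p, is_upper_bound)`` with the add-one rule.
    """
    a = np.asarray(reps_a, dtype=float)
    b = np.asarray(reps_b, dtype=float)
    if n_null < 10**3:
        raise ValidationError("n_null must be >= 1000")
    t_obs = welch_t(a, b)
    pooled = np.concatenate([a, b]).mean()
    a0 = a - a.mean() + pooled
    b0 = b - b.mean() + pooled
    if np.ptp(a0) == 0 and np.ptp(b0) == 0:
        raise DegenerateDataError("both shifted samples are constant")
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    while done < n_null:
        m = min(batch, n_null - done)
        ra = rng.choice(a0, size=(m, a.size), replace=True)
        rb = rng.choice(b0, size=(m, b.size), replace=True)
        va = ra.var(axis=1, ddof=1) / a.size
        vb = rb.var(axis=1, ddof=1) / b.size
        denom = np.sqrt(va + vb)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = (ra.mean(axis=1) - rb.mean(axis=1)) / denom
        t_null = np.where(denom > 0, t_null, 0.0)
        count += int(np.sum(np.abs(t_null) >= abs(t_obs)))
        done += m
    return _addone_p(count, n_null)


def bootstrap_welch_test(
    reps_a, reps_b, n_null: int = 10**6, seed: int | None = None
) -> tuple[float, float, bool]:
    """Shifted-null Welch test on bootstrap replicate distributions.

    The replicate standard deviations estimate the estimators' SEMs, so
    t_obs = (mean_a - mean_b)/sqrt(sd_a^2 + sd_b^2). Null t statistics are
    formed by drawing one value from each mean-shifted replicate set, whose
    difference has exactly the spread of the numerator under equal means.
    Returns ``(t_obs, p, is_upper_bound)``.
    """
    a = np.asarray(reps_a, dtype=float)
    b = np.asarray(reps_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >= 2 replicates per condition")
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    denom = np.sqrt(sa**2 + sb**2)
    if denom == 0:
        raise DegenerateDataError("zero combined replicate variance")
    t_obs = float((a.mean() - b.mean()) / denom)
    pooled = np.concatenate([a, b]).mean()
    a0 = a - a.mean() + pooled
    b0 = b - b.mean() + pooled
    rng = np.random.default_rng(seed)
    xa = rng.choice(a0, size=n_null, replace=True)
    xb = rng.choice(b0, size=n_null, replace=True)
    t_null = (xa - xb) / denom
    count = int(np.sum(np.abs(t_null) >= abs(t_obs)))
    p, bound = _addone_p(count, n_null)
    return t_obs, p, bound


def compare_conditions(
    items_a,
    items_b,
    estimator,
    n_boot: int = 200,
    n_null: int = 10**4,
    seed: int | None = None,
    estimator_name: str = "estimator",
) -> BootstrapResult:
    """Full two-condition comparison of a dataset-level estimator.

    Bootstraps each condition at the trace level, then runs the shifted-null
    Welch test on the replicate distributions. ``estimator`` maps a list of
    per-trace items to a scalar.
    """
    ss = np.random.SeedSequence(seed)
    seed_a, seed_b, seed_null = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    reps_a = bootstrap_estimator(items_a, estimator, n_boot, seed=seed_a)
    reps_b = bootstrap_estimator(items_b, estimator, n_boot, seed=seed_b)
    t_obs, p, bound = bootstrap_welch_test(reps_a, reps_b, n_null=n_null, seed=seed_null)
    est_a = float(estimator(list(items_a)))
    est_b = float(estimator(list(items_b)))
    return BootstrapResult(
        estimator_name=estimator_name,
        estimate_a=est_a,
        estimate_b=est_b,
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
        n_failed_a=n_boot - reps_a.size,
        n_failed_b=n_boot - reps_b.size,
    )
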