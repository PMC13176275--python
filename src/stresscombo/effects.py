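"""Estimation statistics: unpaired mean differences with BCa bootstrap CIs.

The effect size of a contrast is the unpaired mean difference
Δ-mean = mean(treatment) − mean(baseline); negative values mean the
treatment reduced the trait relative to its baseline.  Uncertainty is a
bias-corrected and accelerated (BCa) bootstrap interval:

* each group is resampled independently with replacement at its own size;
* the bias correction z₀ comes from the proportion of bootstrap statistics
  below the observed value, counting ties as half below;
* the acceleration a comes from a leave-one-out jackknife across all
  observations of both groups (each observation removed from its own group);
* the interval endpoints are percentiles of the bootstrap distribution at
  the BCa-adjusted quantiles.  Adjusted quantiles falling outside (0, 1)
  (extreme z₀) are clamped to the nearest achievable order statistic and
  flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .errors import ConfigurationError, InputError
from .traits import ANALYSIS_TRAITS


def mean_difference(treatment, baseline) -> float:
    """Unpaired Δ-mean: mean(treatment) − mean(baseline)."""
    t = np.asarray(treatment, float)
    b = np.asarray(baseline, float)
    if t.size == 0 or b.size == 0:
        raise InputError("mean_difference needs at least one value per group")
    return float(t.mean() - b.mean())


@dataclass(frozen=True)
class ContrastSpec:
    """One contrast of the plan: a trait, a treatment group and its baseline."""

    trait: str
    treatment: str
    baseline: str

    def __post_init__(self) -> None:
        if self.treatment == self.baseline:
            raise ConfigurationError(f"treatment equals baseline ({self.treatment!r})")

    @property
    def label(self) -> str:
        return f"{self.treatment} vs {self.baseline}"


class BcaInterval(NamedTuple):
    low: float
    high: float
    degenerate: bool
    clamped: bool


def _jackknife_accel(treatment: np.ndarray, baseline: np.ndarray) -> float:
    """Acceleration from leave-one-out jackknife of the mean difference."""
    nt, nb = treatment.size, baseline.size
    jack_t = (treatment.sum() - treatment) / (nt - 1) - baseline.mean()
    jack_b = treatment.mean() - (baseline.sum() - baseline) / (nb - 1)
    jack = np.concatenate([jack_t, jack_b])
    dev = jack.mean() - jack
    denom = (dev**2).sum() ** 1.5
    if denom == 0.0:
        return 0.0
    return float((dev**3).sum() / (6.0 * denom))


def bca_interval(
    treatment,
    baseline,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> BcaInterval:
    """BCa confidence interval for a two-group statistic (default: Δ-mean).

    ``statistic`` must accept (treatment, baseline) arrays and return a
    scalar; when omitted, a vectorized mean-difference path is used.
    """
    t = np.asarray(treatment, float)
    b = np.asarray(baseline, float)
    if t.size < 2 or b.size < 2:
        raise InputError("each group needs n >= 2 for a bootstrap interval")
    if n_boot < 100:
        raise ConfigurationError(f"n_boot must be >= 100, got {n_boot}")
    if rng is None:
        rng = np.random.default_rng(seed)

    stat = statistic or mean_difference
    obs = float(stat(t, b))

    if np.ptp(t) == 0.0 and np.ptp(b) == 0.0:
        return BcaInterval(obs, obs, degenerate=True, clamped=False)

    if statistic is None:
        boot_t = t[rng.integers(0, t.size, size=(n_boot, t.size))].mean(axis=1)
        boot_b = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
        theta = boot_t - boot_b
    else:
        theta = np.empty(n_boot)
        for i in range(n_boot):
            theta[i] = stat(t[rng.integers(0, t.size, t.size)],
                            b[rng.integers(0, b.size, b.size)])

    if np.ptp(theta) == 0.0:
        return BcaInterval(float(theta[0]), float(theta[0]), degenerate=True, clamped=False)

    # bias correction, ties counted half below
    p0 = ((theta < obs).sum() + 0.5 * (theta == obs).sum()) / n_boot
    clamped = False
    if p0 <= 0.0 or p0 >= 1.0:
        z0 = np.inf if p0 >= 1.0 else -np.inf
        clamped = True
    else:
        z0 = stats.norm.ppf(p0)

    if statistic is None:
        a = _jackknife_accel(t, b)
    else:
        n = t.size + b.size
        jack = np.empty(n)
        for i in range(t.size):
            jack[i] = stat(np.delete(t, i), b)
        for j in range(b.size):
            jack[t.size + j] = stat(t, np.delete(b, j))
        dev = jack.mean() - jack
        denom = (dev**2).sum() ** 1.5
        a = 0.0 if denom == 0.0 else float((dev**3).sum() / (6.0 * denom))

    alpha = 1.0 - level
    lo_hi = []
    for z_alpha in (stats.norm.ppf(alpha / 2.0), stats.norm.ppf(1.0 - alpha / 2.0)):
        if not np.isfinite(z0):
            q = 0.0 if z0 < 0 else 1.0
        else:
            num = z0 + z_alpha
            denom = 1.0 - a * num
            if denom <= 0.0:  # acceleration pushed past the pole
                q = 1.0 if num > 0 else 0.0
            else:
                q = float(stats.norm.cdf(z0 + num / denom))
        if q <= 0.0 or q >= 1.0:
            clamped = True
            q = min(max(q, 0.0), 1.0)  # nearest achievable order statistic
        lo_hi.append(float(np.quantile(theta, q)))
    return BcaInterval(lo_hi[0], lo_hi[1], degenerate=False, clamped=clamped)


def default_contrast_plan() -> list[tuple[str, str]]:
    """Single stresses vs the unstressed control; combined stresses vs their
    single-stress baseline at ambient temperature."""
    return [
        ("T1", "WW"),
        ("T2", "WW"),
        ("WS", "WW"),
        ("SS", "WW"),
        ("WS(T1)", "WS"),
        ("WS(T2)", "WS"),
        ("SS(T1)", "SS"),
        ("SS(T2)", "SS"),
    ]


def run_contrast_plan(
    trait_table: pd.DataFrame,
    plan: Sequence[tuple[str, str]] | None = None,
    traits: Sequence[str] | None = None,
    n_boot: int = 5000,
    seed: int = 0,
    level: float = 0.95,
    group_col: str = "treatment",
) -> pd.DataFrame:
    """Δ-mean + BCa CI for every (trait × contrast) of the plan.

    Each contrast draws from its own RNG substream (seed, trait, contrast),
    so results are independent of execution order and of the plan's length.
    """
    plan = list(plan) if plan is not None else default_contrast_plan()
    traits = list(traits) if traits is not None else ANALYSIS_TRAITS
    if group_col not in trait_table.columns:
        raise InputError(f"trait table has no {group_col!r} column")
    groups = {g: sub for g, sub in trait_table.groupby(group_col)}
    needed = {g for pair in plan for g in pair}
    missing = sorted(needed - set(groups))
    if missing:
        raise InputError(f"group(s) missing from the data: {missing}")

    rows = []
    for trait in traits:
        for treatment, baseline in plan:
            spec = ContrastSpec(trait, treatment, baseline)
            tv = groups[treatment][trait].dropna().to_numpy(float)
            bv = groups[baseline][trait].dropna().to_numpy(float)
            if tv.size < 2 or bv.size < 2:
                raise InputError(f"contrast {spec.label!r} on {trait!r}: group n < 2")
            rng = substream(seed, "contrast", trait, treatment, baseline)
            delta = mean_difference(tv, bv)
            ci = bca_interval(tv, bv, n_boot=n_boot, level=level, rng=rng)
            rows.append(
                dict(
                    trait=trait,
                    contrast=spec.label,
                    treatment=treatment,
                    baseline=baseline,
                    delta_mean=delta,
                    ci_low=ci.low,
                    ci_high=ci.high,
                    n_boot=n_boot,
                    seed=seed,
                    n_treatment=tv.size,
                    n_baseline=bv.size,
                    degenerate=ci.degenerate,
                )
            )
    return pd.DataFrame(rows)
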