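"""Bootstrap additivity index for double-stress treatments.

For a trait and a pair of stresses i, j applied alone and in combination,
with all effect sizes measured against the same unstressed control:

    AI = ES_ij − (ES_i + ES_j)
       = [mean(ij) − mean(ctrl)] − [mean(i) − mean(ctrl)] − [mean(j) − mean(ctrl)]

AI = 0 means the combined stress did exactly what the two single stresses
predict; the bootstrap (all four groups resampled jointly per iteration)
gives a CI and a sign-flip p-value.  An interaction is

* additive       — the 95% CI of AI includes zero;
* synergistic    — CI excludes zero and AI has the same sign as the expected
                   additive effect S = ES_i + ES_j (the combination
                   overshoots the additive expectation in the stress
                   direction);
* antagonistic   — CI excludes zero and AI opposes S (the combination is
                   milder than expected).

The default CI is bias-corrected percentile (z₀ only); ``method="bca"``
adds acceleration from a grouped leave-one-pot-out jackknife across all
four groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .errors import ConfigurationError, InputError
from .traits import ANALYSIS_TRAITS

#: double-stress combinations of the reference design: (combo, stress_i, stress_j)
#: where stress_i is the water/salt regime and stress_j the warming regime.
DEFAULT_COMBOS = [
    ("WS(T1)", "WS", "T1"),
    ("WS(T2)", "WS", "T2"),
    ("SS(T1)", "SS", "T1"),
    ("SS(T2)", "SS", "T2"),
]


@dataclass(frozen=True)
class AdditivityResult:
    trait: str
    combo: str
    index: float
    ci_low: float
    ci_high: float
    p_value: float
    classification: str
    pct_of_control: float
    expected_additive: float
    n_boot: int
    seed: int | None
    clamped: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _bc_quantiles(theta: np.ndarray, obs: float, level: float, accel: float) -> tuple[float, float, bool]:
    """Bias-corrected (optionally accelerated) percentile endpoints."""
    n_boot = theta.size
    p0 = ((theta < obs).sum() + 0.5 * (theta == obs).sum()) / n_boot
    clamped = False
    if p0 <= 0.0 or p0 >= 1.0:
        z0 = np.inf if p0 >= 1.0 else -np.inf
        clamped = True
    else:
        z0 = stats.norm.ppf(p0)
    alpha = 1.0 - level
    out = []
    for z_alpha in (stats.norm.ppf(alpha / 2.0), stats.norm.ppf(1.0 - alpha / 2.0)):
        if not np.isfinite(z0):
            q = 0.0 if z0 < 0 else 1.0
        else:
            num = z0 + z_alpha
            denom = 1.0 - accel * num
            if denom <= 0.0:
                q = 1.0 if num > 0 else 0.0
            else:
                q = float(stats.norm.cdf(z0 + num / denom))
        if q <= 0.0 or q >= 1.0:
            clamped = True
            q = min(max(q, 0.0), 1.0)
        out.append(float(np.quantile(theta, q)))
    return out[0], out[1], clamped


def additivity_index(
    values_ww,
    values_i,
    values_j,
    values_ij,
    n_boot: int = 5000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
    method: str = "bc",
    trait: str = "",
    combo: str = "",
) -> AdditivityResult:
    """Point AI, bootstrap CI, p-value and classification for one cell.

    The four groups (control, stress i alone, stress j alone, combined) are
    resampled jointly per iteration, yielding one AI* per iteration, which
    preserves the index's sampling distribution.
    """
    groups = [np.asarray(v, float) for v in (values_ww, values_i, values_j, values_ij)]
    for g, name in zip(groups, ("control", "stress_i", "stress_j", "combined")):
        if g.size < 2:
            raise InputError(f"group {name!r} needs n >= 2, got {g.size}")
    if n_boot < 100:
        raise ConfigurationError(f"n_boot must be >= 100, got {n_boot}")
    if method not in ("bc", "bca"):
        raise ConfigurationError(f"method must be 'bc' or 'bca', got {method!r}")
    if rng is None:
        rng = np.random.default_rng(seed)

    ww, gi, gj, gij = groups
    es_i = gi.mean() - ww.mean()
    es_j = gj.mean() - ww.mean()
    es_ij = gij.mean() - ww.mean()
    ai = float(es_ij - (es_i + es_j))
    expected = float(es_i + es_j)

    boot_means = [
        g[rng.integers(0, g.size, size=(n_boot, g.size))].mean(axis=1) for g in groups
    ]
    theta = boot_means[3] - boot_means[1] - boot_means[2] + boot_means[0]

    if np.ptp(theta) == 0.0:
        low = high = float(theta[0])
        clamped = False
    else:
        accel = 0.0
        if method == "bca":
            # grouped jackknife: leave one pot out of whichever group holds it
            signs = (1.0, -1.0, -1.0, 1.0)  # ww, i, j, ij contributions to AI
            jack = []
            base_terms = [s * g.mean() for s, g in zip(signs, groups)]
            for k, (s, g) in enumerate(zip(signs, groups)):
                loo = (g.sum() - g) / (g.size - 1)
                others = sum(t for m, t in enumerate(base_terms) if m != k)
                jack.append(others + s * loo)
            jack = np.concatenate(jack)
            dev = jack.mean() - jack
            denom = (dev**2).sum() ** 1.5
            accel = 0.0 if denom == 0.0 else float((dev**3).sum() / (6.0 * denom))
        low, high, clamped = _bc_quantiles(theta, ai, level, accel)

    n_le = int((theta <= 0.0).sum())
    n_ge = int((theta >= 0.0).sum())
    p = min(1.0, 2.0 * min(n_le + 1, n_ge + 1) / (n_boot + 1))

    if low <= 0.0 <= high:
        classification = "additive"
    elif expected == 0.0:
        classification = "non-additive-unsigned"
    elif np.sign(ai) == np.sign(expected):
        classification = "synergistic"
    else:
        classification = "antagonistic"

    ctrl_mean = ww.mean()
    pct = float(100.0 * ai / ctrl_mean) if ctrl_mean != 0.0 else float("nan")
    return AdditivityResult(
        trait=trait,
        combo=combo,
        index=ai,
        ci_low=float(low),
        ci_high=float(high),
        p_value=float(p),
        classification=classification,
        pct_of_control=pct,
        expected_additive=expected,
        n_boot=n_boot,
        seed=seed,
        clamped=clamped,
    )


def run_additivity(
    trait_table: pd.DataFrame,
    combos: Sequence[tuple[str, str, str]] | None = None,
    traits: Sequence[str] | None = None,
    control: str = "WW",
    n_boot: int = 5000,
    seed: int = 0,
    level: float = 0.95,
    method: str = "bc",
    group_col: str = "treatment",
) -> pd.DataFrame:
    """Additivity table: one row per (combo × trait).

    ``combos`` lists (combined label, single-stress label i, single-stress
    label j); all effect sizes are taken against ``control``.
    """
    combos = list(combos) if combos is not None else DEFAULT_COMBOS
    traits = list(traits) if traits is not None else ANALYSIS_TRAITS
    if group_col not in trait_table.columns:
        raise InputError(f"trait table has no {group_col!r} column")
    groups = {g: sub for g, sub in trait_table.groupby(group_col)}
    needed = {control} | {g for combo in combos for g in combo}
    missing = sorted(needed - set(groups))
    if missing:
        raise InputError(f"group(s) missing from the data: {missing}")

    rows = []
    for trait in traits:
        for combo, si, sj in combos:
            vals = {
                g: groups[g][trait].dropna().to_numpy(float)
                for g in (control, si, sj, combo)
            }
            rng = substream(seed, "additivity", trait, combo)
            res = additivity_index(
                vals[control], vals[si], vals[sj], vals[combo],
                n_boot=n_boot, rng=rng, level=level, method=method,
                trait=trait, combo=combo,
            )
            d = res.__dict__.copy()
            d["significant"] = res.significant
            d["seed"] = seed
            rows.append(d)
    return pd.DataFrame(rows)


def heatmap_matrix(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pivot an additivity table into combo × trait matrices.

    Returns ``pct`` (AI as % of the control mean; NaN where the control
    mean was zero), ``significant`` (p < 0.05 relative to full additivity)
    and ``classification``.
    """
    for col in ("trait", "combo", "pct_of_control", "p_value", "classification"):
        if col not in results.columns:
            raise InputError(f"additivity results lack column {col!r}")
    pct = results.pivot(index="combo", columns="trait", values="pct_of_control")
    sig = results.pivot(index="combo", columns="trait", values="p_value") < 0.05
    cls = results.pivot(index="combo", columns="trait", values="classification")
    return {"pct": pct, "significant": sig, "classification": cls}
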