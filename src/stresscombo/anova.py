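"""Split-plot two-way ANOVA with nested error strata, plus diagnostics.

A balanced split-plot with t temperature levels on main plots, w water
levels on subplots and r replicates decomposes the total sum of squares
into

    Temperature        df = t−1          tested against Main-plot error
    Main-plot error    df = t(r−1)       (among main plots within temperature)
    Water              df = w−1          tested against Residual
    Temperature:Water  df = (t−1)(w−1)   tested against Residual
    Residual           df = t(r−1)(w−1)

Replicates are nested within temperature (completely randomized main
plots); ``blocks=True`` instead fits a replicate block main effect, giving
Block df = r−1 and Main-plot error df = (t−1)(r−1).

Diagnostics follow the standard univariate checks: Shapiro–Wilk on the
subplot residuals and Brown–Forsythe (median-centered Levene) homogeneity
across the t×w treatment groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError

_TRANSFORMS = {
    "none": lambda y: y,
    "log": np.log,
    "sqrt": np.sqrt,
}


@dataclass
class AnovaTable:
    """Fitted split-plot decomposition for one trait."""

    trait: str
    table: pd.DataFrame              # stratum, SS, df, MS, F, p
    residuals: np.ndarray            # subplot residuals
    group_values: pd.Series          # trait values indexed by (temp, water) group label
    transform: str = "none"
    blocks: bool = False
    design_shape: tuple[int, int, int] = (0, 0, 0)   # (t, w, r)

    def __getitem__(self, stratum: str) -> pd.Series:
        return self.table.set_index("stratum").loc[stratum]


@dataclass
class DiagnosticsReport:
    shapiro_p: float | None
    levene_p: float | None
    transform: str = "none"
    available: bool = True
    refit: "AnovaTable | None" = field(default=None, repr=False)


def _pivot_balanced(trait_table: pd.DataFrame, trait: str,
                    temp_col: str, water_col: str, rep_col: str) -> np.ndarray:
    for col in (trait, temp_col, water_col, rep_col):
        if col not in trait_table.columns:
            raise InputError(f"trait table has no column {col!r}")
    sub = trait_table[[temp_col, water_col, rep_col, trait]]
    if sub[trait].isna().any():
        pots = trait_table.loc[sub[trait].isna()].index.tolist()
        raise InputError(f"missing {trait!r} values for rows {pots}")
    counts = sub.groupby([temp_col, water_col], sort=False).size()
    if counts.nunique() != 1:
        raise InputError(
            f"unbalanced design for {trait!r}: cell counts {sorted(set(counts))}"
        )
    temps = list(dict.fromkeys(sub[temp_col]))
    waters = list(dict.fromkeys(sub[water_col]))
    reps = list(dict.fromkeys(sub[rep_col]))
    t, w, r = len(temps), len(waters), len(reps)
    if t * w * r != len(sub):
        raise InputError("replicate labels do not form a complete t x w x r grid")
    y = np.full((t, w, r), np.nan)
    ti = sub[temp_col].map({v: i for i, v in enumerate(temps)}).to_numpy()
    wi = sub[water_col].map({v: i for i, v in enumerate(waters)}).to_numpy()
    ri = sub[rep_col].map({v: i for i, v in enumerate(reps)}).to_numpy()
    y[ti, wi, ri] = sub[trait].to_numpy(float)
    if np.isnan(y).any():
        raise InputError("duplicate or missing (temp, water, replicate) cells")
    return y


def fit_splitplot(
    trait_table: pd.DataFrame,
    trait: str,
    temp_col: str = "temp",
    water_col: str = "water",
    rep_col: str = "replicate",
    transform: str = "none",
    blocks: bool = False,
) -> AnovaTable:
    """Fit the split-plot ANOVA for one trait of a balanced trait table."""
    if transform not in _TRANSFORMS:
        raise ConfigurationError(f"transform must be one of {sorted(_TRANSFORMS)}")
    y = _pivot_balanced(trait_table, trait, temp_col, water_col, rep_col)
    y = _TRANSFORMS[transform](y)
    if not np.isfinite(y).all():
        raise InputError(f"transform {transform!r} produced non-finite values")
    t, w, r = y.shape

    grand = y.mean()
    m_t = y.mean(axis=(1, 2))            # temperature means
    m_w = y.mean(axis=(0, 2))            # water means
    m_tw = y.mean(axis=2)                # cell means
    m_mp = y.mean(axis=1)                # main-plot means, (t, r)
    m_r = y.mean(axis=(0, 1))            # replicate (block) means

    ss_total = ((y - grand) ** 2).sum()
    ss_temp = w * r * ((m_t - grand) ** 2).sum()
    ss_water = t * r * ((m_w - grand) ** 2).sum()
    ss_tw = r * ((m_tw - m_t[:, None] - m_w[None, :] + grand) ** 2).sum()
    ss_mp_tot = w * ((m_mp - m_t[:, None]) ** 2).sum()   # among main plots within temp

    rows = []
    if blocks:
        ss_block = t * w * ((m_r - grand) ** 2).sum()
        ss_mp_err = ss_mp_tot - ss_block
        df_mp = (t - 1) * (r - 1)
        rows.append(("Block", ss_block, r - 1))
    else:
        ss_mp_err = ss_mp_tot
        df_mp = t * (r - 1)
    ss_resid = ss_total - ss_temp - ss_mp_tot - ss_water - ss_tw
    ss_resid = max(ss_resid, 0.0)
    df_resid = t * (r - 1) * (w - 1)

    strata = rows + [
        ("Temperature", ss_temp, t - 1),
        ("Main-plot error", ss_mp_err, df_mp),
        ("Water", ss_water, w - 1),
        ("Temperature:Water", ss_tw, (t - 1) * (w - 1)),
        ("Residual", ss_resid, df_resid),
    ]
    tab = pd.DataFrame(strata, columns=["stratum", "SS", "df"])
    tab["MS"] = tab["SS"] / tab["df"]
    ms = tab.set_index("stratum")["MS"]

    def f_p(num: str, den: str) -> tuple[float, float]:
        if ms[den] <= 0.0:
            return np.inf if ms[num] > 0 else np.nan, 0.0 if ms[num] > 0 else np.nan
        f = ms[num] / ms[den]
        dfn = int(tab.set_index("stratum").loc[num, "df"])
        dfd = int(tab.set_index("stratum").loc[den, "df"])
        return f, float(stats.f.sf(f, dfn, dfd))

    tab["F"] = np.nan
    tab["p"] = np.nan
    for num, den in (
        ("Temperature", "Main-plot error"),
        ("Water", "Residual"),
        ("Temperature:Water", "Residual"),
    ):
        f, p = f_p(num, den)
        tab.loc[tab["stratum"] == num, ["F", "p"]] = [f, p]

    # subplot residuals: y - cell mean - (main-plot mean - temperature mean)
    resid = y - m_tw[:, :, None] - m_mp[:, None, :] + m_t[:, None, None]
    groups = pd.Series(
        y.reshape(t * w, r).tolist(),
        index=pd.MultiIndex.from_product([range(t), range(w)]),
    )
    return AnovaTable(
        trait=trait,
        table=tab,
        residuals=resid.ravel(),
        group_values=groups,
        transform=transform,
        blocks=blocks,
        design_shape=(t, w, r),
    )


def residual_diagnostics(
    fit: AnovaTable,
    transform: str | None = None,
    trait_table: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> DiagnosticsReport:
    """Shapiro–Wilk normality of subplot residuals and Brown–Forsythe
    homogeneity across the treatment groups.

    If either test fails at ``alpha`` and a ``transform`` is requested
    (with the original ``trait_table``), the model is refitted on the
    transformed trait and the refit attached to the report.
    """
    resid = np.asarray(fit.residuals, float)
    if resid.size < 3 or np.ptp(resid) == 0.0:
        return DiagnosticsReport(None, None, fit.transform, available=False)
    shapiro_p = float(stats.shapiro(resid).pvalue)
    group_arrays = [np.asarray(v, float) for v in fit.group_values]
    levene_p = float(stats.levene(*group_arrays, center="median").pvalue)
    report = DiagnosticsReport(shapiro_p, levene_p, fit.transform)
    if transform and (shapiro_p < alpha or levene_p < alpha):
        if trait_table is None:
            raise InputError("refitting with a transform requires the original trait table")
        report.refit = fit_splitplot(
            trait_table, fit.trait, transform=transform, blocks=fit.blocks
        )
    return report


def fit_all(
    trait_table: pd.DataFrame,
    traits: list[str],
    transform: str = "none",
    blocks: bool = False,
) -> dict[str, AnovaTable]:
    return {tr: fit_splitplot(trait_table, tr, transform=transform, blocks=blocks)
            for tr in traits}
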