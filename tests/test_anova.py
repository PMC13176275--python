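"""Split-plot ANOVA against an explicit projection-matrix oracle, plus
stratum bookkeeping, invariances and diagnostics."""

import numpy as np
import pandas as pd
import pytest

import stresscombo as sc
from stresscombo.errors import InputError


def _table(t, w, r, values=None, seed=0):
    spec = sc.DesignSpec(
        temp_levels=tuple(f"T{i}" for i in range(t)),
        water_levels=tuple(f"W{j}" for j in range(w)),
        replicates=r,
    )
    design = sc.build_design(spec)
    if values is None:
        values = np.random.default_rng(seed).normal(0, 1, len(design))
    design["y"] = np.asarray(values, float)
    return design


def _indicator(labels):
    cats = list(dict.fromkeys(labels))
    M = np.zeros((len(labels), len(cats)))
    for i, lab in enumerate(labels):
        M[i, cats.index(lab)] = 1.0
    return M


def projection_oracle(design, y):
    """Brute-force stratum SS via explicit projections P = X (X'X)^+ X'."""
    y = np.asarray(y, float)

    def proj(X):
        return X @ np.linalg.pinv(X.T @ X) @ X.T

    n = len(y)
    P1 = np.full((n, n), 1.0 / n)
    PT = proj(_indicator(design["temp"]))
    PMP = proj(_indicator(design["mainplot_id"]))
    PW = proj(_indicator(design["water"]))
    PTW = proj(_indicator(list(zip(design["temp"], design["water"]))))
    ss = {
        "Temperature": y @ (PT - P1) @ y,
        "Main-plot error": y @ (PMP - PT) @ y,
        "Water": y @ (PW - P1) @ y,
        "Temperature:Water": y @ (PTW - PT - PW + P1) @ y,
    }
    # residual: everything orthogonal to span(mainplots, cells)
    Xfull = np.hstack([
        _indicator(design["mainplot_id"]),
        _indicator(list(zip(design["temp"], design["water"]))),
    ])
    ss["Residual"] = y @ (np.eye(n) - proj(Xfull)) @ y
    return ss


@pytest.mark.parametrize("t,w,r,seed", [(2, 2, 3, 1), (3, 3, 4, 2), (2, 4, 5, 3)])
def test_ss_match_projection_oracle(t, w, r, seed):
    design = _table(t, w, r, seed=seed)
    fit = sc.fit_splitplot(design, "y")
    oracle = projection_oracle(design, design["y"])
    got = fit.table.set_index("stratum")["SS"]
    for stratum, expect in oracle.items():
        assert got[stratum] == pytest.approx(expect, abs=1e-10), stratum


def test_fixture_dataset_small_balanced():
    """2 temps x 2 waters x 3 reps with fixed values: SS equal the oracle."""
    values = [5.1, 4.2, 6.3, 5.0, 4.4, 5.9, 3.9, 3.0, 4.8, 4.1, 3.2, 5.2]
    design = _table(2, 2, 3, values=values)
    fit = sc.fit_splitplot(design, "y")
    oracle = projection_oracle(design, design["y"])
    got = fit.table.set_index("stratum")
    for stratum, expect in oracle.items():
        assert got.loc[stratum, "SS"] == pytest.approx(expect, abs=1e-10)
    assert got["df"].sum() == len(values) - 1


def test_df_bookkeeping_default_design(trait_table):
    fit = sc.fit_splitplot(trait_table, "shoot")
    df = fit.table.set_index("stratum")["df"]
    assert df["Temperature"] == 2
    assert df["Main-plot error"] == 27
    assert df["Water"] == 2
    assert df["Temperature:Water"] == 4
    assert df["Residual"] == 54
    assert df.sum() == 89
    ss = fit.table.set_index("stratum")["SS"]
    total = ((trait_table["shoot"] - trait_table["shoot"].mean()) ** 2).sum()
    assert ss.sum() == pytest.approx(total, rel=1e-8)
    assert (ss >= 0).all()


def test_error_strata_assignment(trait_table):
    """F(Temperature) uses main-plot error; F(Water), F(TxW) use residual."""
    fit = sc.fit_splitplot(trait_table, "shoot")
    tab = fit.table.set_index("stratum")
    assert tab.loc["Temperature", "F"] == pytest.approx(
        tab.loc["Temperature", "MS"] / tab.loc["Main-plot error", "MS"]
    )
    assert tab.loc["Water", "F"] == pytest.approx(
        tab.loc["Water", "MS"] / tab.loc["Residual", "MS"]
    )
    assert np.isnan(tab.loc["Main-plot error", "F"])


def test_noiseless_cell_means_have_zero_error_ss():
    cells = np.array([[10.0, 8.0, 6.0], [9.0, 7.0, 5.0], [8.0, 6.0, 4.0]])
    model = sc.TraitModel.from_cell_means(cells)
    design = sc.build_design(sc.DesignSpec())
    design["y"] = sc.simulate_trait(design, model, seed=0)
    fit = sc.fit_splitplot(design, "y")
    ss = fit.table.set_index("stratum")["SS"]
    assert ss["Residual"] == pytest.approx(0.0, abs=1e-9)
    assert ss["Main-plot error"] == pytest.approx(0.0, abs=1e-9)
    assert ss["Temperature"] > 0 and ss["Water"] > 0


def test_shift_and_scale_invariance():
    design = _table(3, 3, 4, seed=9)
    base = sc.fit_splitplot(design, "y").table.set_index("stratum")["SS"]
    shifted = design.assign(y=design["y"] + 100.0)
    scaled = design.assign(y=design["y"] * 3.0)
    ss_shift = sc.fit_splitplot(shifted, "y").table.set_index("stratum")["SS"]
    ss_scale = sc.fit_splitplot(scaled, "y").table.set_index("stratum")["SS"]
    assert np.allclose(ss_shift, base, atol=1e-8)
    assert np.allclose(ss_scale, 9.0 * base, rtol=1e-10)


def test_water_permutation_within_main_plot_preserves_whole_plot_ss():
    design = _table(3, 3, 4, seed=13)
    base = sc.fit_splitplot(design, "y").table.set_index("stratum")["SS"]
    perm = design.copy()
    # rotate water labels within one main plot (values stay with the pots)
    mask = (perm["temp"] == "T0") & (perm["replicate"] == 1)
    perm.loc[mask, "water"] = np.roll(perm.loc[mask, "water"].to_numpy(), 1)
    got = sc.fit_splitplot(perm, "y").table.set_index("stratum")["SS"]
    assert got["Temperature"] == pytest.approx(base["Temperature"], abs=1e-10)
    assert got["Main-plot error"] == pytest.approx(base["Main-plot error"], abs=1e-10)


def test_unbalanced_and_missing_rejected(trait_table):
    with pytest.raises(InputError):
        sc.fit_splitplot(trait_table.iloc[:-1], "shoot")
    broken = trait_table.copy()
    broken.loc[broken.index[0], "shoot"] = np.nan
    with pytest.raises(InputError):
        sc.fit_splitplot(broken, "shoot")


def test_blocked_variant_df_and_ss_partition(trait_table):
    fit = sc.fit_splitplot(trait_table, "shoot", blocks=True)
    df = fit.table.set_index("stratum")["df"]
    assert df["Block"] == 9
    assert df["Main-plot error"] == 18
    assert df.sum() == 89
    ss = fit.table.set_index("stratum")["SS"]
    total = ((trait_table["shoot"] - trait_table["shoot"].mean()) ** 2).sum()
    assert ss.sum() == pytest.approx(total, rel=1e-8)


def test_log_transform_equals_fit_on_logged_data(trait_table):
    a = sc.fit_splitplot(trait_table, "shoot", transform="log").table
    logged = trait_table.assign(shoot=np.log(trait_table["shoot"]))
    b = sc.fit_splitplot(logged, "shoot").table
    pd.testing.assert_frame_equal(a, b)


class TestDiagnostics:
    def test_gaussian_residuals_pass(self, trait_table):
        fit = sc.fit_splitplot(trait_table, "shoot")
        rep = sc.residual_diagnostics(fit)
        assert rep.available
        assert 0 < rep.shapiro_p <= 1
        assert 0 < rep.levene_p <= 1

    def test_variance_inflated_group_flagged(self):
        rng = np.random.default_rng(3)
        design = _table(3, 3, 10, values=rng.normal(0, 0.1, 90))
        blowup = (design["temp"] == "T0") & (design["water"] == "W0")
        design.loc[blowup, "y"] = rng.normal(0, 10.0, int(blowup.sum()))
        fit = sc.fit_splitplot(design, "y")
        rep = sc.residual_diagnostics(fit)
        assert rep.levene_p < 0.05

    def test_constant_residuals_unavailable(self):
        design = _table(2, 2, 3, values=np.ones(12))
        fit = sc.fit_splitplot(design, "y")
        rep = sc.residual_diagnostics(fit)
        assert not rep.available
        assert rep.shapiro_p is None

    def test_refit_on_transform_when_assumptions_fail(self):
        rng = np.random.default_rng(8)
        design = _table(3, 3, 10, values=np.exp(rng.normal(0, 1.5, 90)))
        fit = sc.fit_splitplot(design, "y")
        rep = sc.residual_diagnostics(fit, transform="log", trait_table=design)
        if rep.shapiro_p < 0.05 or rep.levene_p < 0.05:
            assert rep.refit is not None
            assert rep.refit.transform == "log"
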