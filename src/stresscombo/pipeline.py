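"""End-to-end orchestration: simulate → traits → contrasts → additivity →
ANOVA → CDA, from one config, into a reproducible report bundle.

Every stochastic stage derives its RNG from the single global seed through
named substreams, so the bundle is bit-identical for identical
(config, seed) regardless of stage order, and the manifest written next to
the outputs is sufficient to re-run the bundle exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .additivity import DEFAULT_COMBOS, heatmap_matrix, run_additivity
from .anova import fit_splitplot, residual_diagnostics
from .cda import fit_cda, mahalanobis_tests
from .effects import default_contrast_plan, run_contrast_plan
from .errors import ConfigurationError, PipelineError
from .synth import DesignSpec, add_treatment_column, default_scenario, simulate_raw_experiment
from .traits import ANALYSIS_TRAITS, IsotopeConstants, derive_all

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "traits", "contrasts", "additivity", "anova", "cda")


@dataclass
class RunConfig:
    seed: int
    out_dir: str | Path = "stresscombo_run"
    input_csv: str | None = None          # None -> synthetic scenario
    n_boot: int = 5000
    stages: tuple[str, ...] = ALL_STAGES
    design: DesignSpec = field(default_factory=DesignSpec)
    constants: IsotopeConstants = field(default_factory=IsotopeConstants)
    biomass: str = "total"
    contrast_plan: list[tuple[str, str]] = field(default_factory=default_contrast_plan)
    combos: list[tuple[str, str, str]] = field(default_factory=lambda: list(DEFAULT_COMBOS))
    additivity_method: str = "bc"
    anova_transform: str = "none"
    anova_blocks: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
        needs_boot = {"contrasts", "additivity"} & set(self.stages)
        if needs_boot and self.seed is None:
            raise ConfigurationError("seed is mandatory when bootstrap stages run")
        if self.input_csv is None and "simulate" not in self.stages and (
            {"traits", "contrasts", "additivity", "anova", "cda"} & set(self.stages)
        ):
            raise ConfigurationError("no input CSV and the simulate stage is disabled")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("seed", "out_dir", "input_csv", "n_boot", "biomass",
                    "additivity_method"):
            if key in raw:
                kwargs[key] = raw[key]
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        if "design" in raw:
            d = raw["design"]
            kwargs["design"] = DesignSpec(
                temp_levels=tuple(d.get("temp_levels", ("Tamb", "T1", "T2"))),
                water_levels=tuple(d.get("water_levels", ("WW", "WS", "SS"))),
                replicates=int(d.get("replicates", 10)),
            )
        if "constants" in raw:
            kwargs["constants"] = IsotopeConstants(**raw["constants"])
        if "contrast_plan" in raw:
            kwargs["contrast_plan"] = [tuple(p) for p in raw["contrast_plan"]]
        if "combos" in raw:
            kwargs["combos"] = [tuple(c) for c in raw["combos"]]
        if "anova" in raw:
            kwargs["anova_transform"] = raw["anova"].get("transform", "none")
            kwargs["anova_blocks"] = bool(raw["anova"].get("blocks", False))
        if "seed" not in kwargs:
            raise ConfigurationError("config must set a seed")
        return cls(**kwargs)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, lineterminator="\n")


def run(config: RunConfig) -> dict:
    """Execute the enabled stages; return the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ALL_STAGES if s in config.stages]
    manifest: dict = {
        "package": "stresscombo",
        "version": __version__,
        "seed": config.seed,
        "n_boot": config.n_boot,
        "stages": stages,
        "skipped_stages": [s for s in ALL_STAGES if s not in config.stages],
        "biomass": config.biomass,
        "additivity_method": config.additivity_method,
        "anova": {"transform": config.anova_transform, "blocks": config.anova_blocks},
        "constants": config.constants.__dict__,
        "design": {
            "temp_levels": list(config.design.temp_levels),
            "water_levels": list(config.design.water_levels),
            "replicates": config.design.replicates,
        },
        "input_csv": config.input_csv,
        "outputs": {},
        "row_counts": {},
    }
    current = "setup"
    try:
        # --- input ----------------------------------------------------
        if config.input_csv is not None:
            current = "load"
            pots = pd.read_csv(config.input_csv)
        else:
            current = "simulate"
            t0 = time.perf_counter()
            scenario = default_scenario(seed=config.seed, design=config.design)
            pots = simulate_raw_experiment(scenario)
            if "simulate" in stages:
                _write_csv(pots, out / "pots.csv")
                manifest["outputs"]["simulate"] = ["pots.csv"]
                manifest["row_counts"]["pots"] = len(pots)
            logger.info("simulate: %d pots in %.2fs", len(pots), time.perf_counter() - t0)

        trait_table = None
        if {"traits", "contrasts", "additivity", "anova", "cda"} & set(stages):
            current = "traits"
            t0 = time.perf_counter()
            trait_table = add_treatment_column(derive_all(pots, config.constants, config.biomass))
            if "traits" in stages:
                _write_csv(trait_table, out / "traits.csv")
                manifest["outputs"]["traits"] = ["traits.csv"]
                manifest["row_counts"]["traits"] = len(trait_table)
            logger.info("traits: %d rows in %.2fs", len(trait_table), time.perf_counter() - t0)

        if "contrasts" in stages:
            current = "contrasts"
            t0 = time.perf_counter()
            contrasts = run_contrast_plan(
                trait_table, plan=config.contrast_plan,
                n_boot=config.n_boot, seed=config.seed,
            )
            _write_csv(contrasts, out / "contrasts.csv")
            manifest["outputs"]["contrasts"] = ["contrasts.csv"]
            manifest["row_counts"]["contrasts"] = len(contrasts)
            logger.info("contrasts: %d rows in %.2fs", len(contrasts), time.perf_counter() - t0)

        if "additivity" in stages:
            current = "additivity"
            t0 = time.perf_counter()
            add = run_additivity(
                trait_table, combos=config.combos,
                n_boot=config.n_boot, seed=config.seed,
                method=config.additivity_method,
            )
            _write_csv(add, out / "additivity.csv")
            hm = heatmap_matrix(add)
            _write_csv(hm["pct"], out / "additivity_heatmap_pct.csv", index=True)
            _write_csv(hm["significant"], out / "additivity_heatmap_significant.csv", index=True)
            _write_csv(hm["classification"], out / "additivity_heatmap_class.csv", index=True)
            manifest["outputs"]["additivity"] = [
                "additivity.csv", "additivity_heatmap_pct.csv",
                "additivity_heatmap_significant.csv", "additivity_heatmap_class.csv",
            ]
            manifest["row_counts"]["additivity"] = len(add)
            logger.info("additivity: %d rows in %.2fs", len(add), time.perf_counter() - t0)

        if "anova" in stages:
            current = "anova"
            t0 = time.perf_counter()
            files, diag_rows = [], []
            for trait in ANALYSIS_TRAITS:
                fit = fit_splitplot(
                    trait_table, trait,
                    transform=config.anova_transform, blocks=config.anova_blocks,
                )
                fname = f"anova_{trait}.csv"
                _write_csv(fit.table, out / fname)
                files.append(fname)
                rep = residual_diagnostics(fit)
                diag_rows.append(dict(
                    trait=trait, shapiro_p=rep.shapiro_p, levene_p=rep.levene_p,
                    transform=rep.transform, available=rep.available,
                ))
            diag = pd.DataFrame(diag_rows)
            _write_csv(diag, out / "anova_diagnostics.csv")
            files.append("anova_diagnostics.csv")
            manifest["outputs"]["anova"] = files
            manifest["row_counts"]["anova_tables"] = len(ANALYSIS_TRAITS)
            logger.info("anova: %d traits in %.2fs", len(ANALYSIS_TRAITS), time.perf_counter() - t0)

        if "cda" in stages:
            current = "cda"
            t0 = time.perf_counter()
            res = fit_cda(trait_table)
            eig = pd.DataFrame({
                "variable": [f"CAN{k + 1}" for k in range(len(res.eigenvalues))],
                "eigenvalue": res.eigenvalues,
                "pct_variance": res.pct_variance,
            })
            _write_csv(eig, out / "cda_eigen.csv")
            _write_csv(res.loadings, out / "cda_loadings.csv", index=True)
            _write_csv(res.coefficients, out / "cda_coefficients.csv", index=True)
            _write_csv(res.centroids, out / "cda_centroids.csv", index=True)
            maha = mahalanobis_tests(trait_table)
            _write_csv(maha.d2, out / "cda_mahalanobis_d2.csv", index=True)
            _write_csv(maha.p_values, out / "cda_mahalanobis_p.csv", index=True)
            manifest["outputs"]["cda"] = [
                "cda_eigen.csv", "cda_loadings.csv", "cda_coefficients.csv",
                "cda_centroids.csv", "cda_mahalanobis_d2.csv", "cda_mahalanobis_p.csv",
            ]
            manifest["row_counts"]["cda_variables"] = len(res.eigenvalues)
            logger.info("cda: %d canonical variables in %.2fs",
                        len(res.eigenvalues), time.perf_counter() - t0)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {current}\nerror: {exc}\n")
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
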