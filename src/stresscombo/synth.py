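"""Synthetic split-plot stress-combination experiments with known ground truth.

The generator emulates a balanced two-factor pot experiment: temperature
regime randomized to main plots, water regime to subplots within each main
plot.  Each simulated measurement is

    y = grand_mean + temp_effect + water_effect + interaction
        + mainplot_draw(sigma_mainplot) + residual_draw(sigma_resid)

with the main-plot draw shared by every pot of a (temperature, replicate)
main plot.  Effects use sum-to-zero coding, so a zero interaction matrix
means the two stresses combine exactly additively — the ground truth the
additivity index is tested against.

Admissibility bounds (positive masses, atom% ¹⁵N between natural abundance
and the fertilizer enrichment) are enforced by rejection sampling of the
subplot residual rather than truncation, so cell means are not biased.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import ConfigurationError, GenerationError

#: fixed CSV header for raw per-pot tables
POT_COLUMNS = [
    "pot_id",
    "replicate",
    "temp",
    "water",
    "shoot_dw_g",
    "root_dw_g",
    "water_applied_L",
    "n_conc_mg_g",
    "atom_pct_15N",
    "delta13C_permil",
]

RAW_MEASUREMENTS = POT_COLUMNS[4:]

_MAX_REJECTION_ATTEMPTS = 1000


@dataclass(frozen=True)
class DesignSpec:
    """Balanced split-plot layout: temperature on main plots, water on subplots."""

    temp_levels: tuple[str, ...] = ("Tamb", "T1", "T2")
    water_levels: tuple[str, ...] = ("WW", "WS", "SS")
    replicates: int = 10

    def __post_init__(self) -> None:
        for name, levels in (("temp", self.temp_levels), ("water", self.water_levels)):
            if len(levels) < 2:
                raise ConfigurationError(f"need >=2 {name} levels, got {levels!r}")
            if len(set(levels)) != len(levels):
                raise ConfigurationError(f"non-unique {name} levels: {levels!r}")
        if self.replicates < 2:
            raise ConfigurationError(
                f"replicates must be >=2 (no error df otherwise), got {self.replicates}"
            )

    @property
    def n_pots(self) -> int:
        return len(self.temp_levels) * len(self.water_levels) * self.replicates


@dataclass(frozen=True)
class TraitModel:
    """Cell-mean and variance structure of one measurement.

    ``temp_effects``/``water_effects`` are ordered like the design's levels
    and sum to zero; ``interaction`` is a (temps x waters) matrix with zero
    row and column sums.  ``lower``/``upper`` are admissibility bounds for
    the generated values (None = unbounded).
    """

    grand_mean: float
    temp_effects: tuple[float, ...]
    water_effects: tuple[float, ...]
    interaction: tuple[tuple[float, ...], ...]
    sigma_mainplot: float = 0.0
    sigma_resid: float = 0.0
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.temp_effects, float)
        b = np.asarray(self.water_effects, float)
        ab = np.asarray(self.interaction, float)
        if ab.shape != (a.size, b.size):
            raise ConfigurationError(
                f"interaction shape {ab.shape} != ({a.size}, {b.size})"
            )
        tol = 1e-8 * max(1.0, abs(self.grand_mean))
        if abs(a.sum()) > tol or abs(b.sum()) > tol:
            raise ConfigurationError("main effects must sum to zero (sum-to-zero coding)")
        if np.abs(ab.sum(axis=0)).max() > tol or np.abs(ab.sum(axis=1)).max() > tol:
            raise ConfigurationError("interaction matrix must have zero row/column sums")
        for s, nm in ((self.sigma_mainplot, "sigma_mainplot"), (self.sigma_resid, "sigma_resid")):
            if not np.isfinite(s) or s < 0:
                raise ConfigurationError(f"{nm} must be finite and >=0, got {s}")

    @classmethod
    def from_cell_means(
        cls,
        cell_means,
        sigma_mainplot: float = 0.0,
        sigma_resid: float = 0.0,
        lower: float | None = None,
        upper: float | None = None,
    ) -> "TraitModel":
        """Decompose a (temps x waters) cell-mean matrix into sum-to-zero effects."""
        m = np.asarray(cell_means, float)
        mu = m.mean()
        a = m.mean(axis=1) - mu
        b = m.mean(axis=0) - mu
        ab = m - mu - a[:, None] - b[None, :]
        return cls(
            grand_mean=float(mu),
            temp_effects=tuple(a),
            water_effects=tuple(b),
            interaction=tuple(tuple(row) for row in ab),
            sigma_mainplot=sigma_mainplot,
            sigma_resid=sigma_resid,
            lower=lower,
            upper=upper,
        )

    def cell_means(self) -> np.ndarray:
        a = np.asarray(self.temp_effects, float)
        b = np.asarray(self.water_effects, float)
        ab = np.asarray(self.interaction, float)
        return self.grand_mean + a[:, None] + b[None, :] + ab

    def with_interaction(self, interaction) -> "TraitModel":
        return replace(self, interaction=tuple(tuple(row) for row in np.asarray(interaction, float)))


@dataclass(frozen=True)
class ScenarioConfig:
    """Full raw-measurement scenario: design plus one TraitModel per measurement."""

    design: DesignSpec = field(default_factory=DesignSpec)
    raw_measurement_models: dict[str, TraitModel] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [m for m in RAW_MEASUREMENTS if m not in self.raw_measurement_models]
        if missing:
            raise ConfigurationError(f"missing TraitModel(s) for: {missing}")
        for name, model in self.raw_measurement_models.items():
            if len(model.temp_effects) != len(self.design.temp_levels) or len(
                model.water_effects
            ) != len(self.design.water_levels):
                raise ConfigurationError(f"model for {name!r} does not match the design")


def build_design(spec: DesignSpec) -> pd.DataFrame:
    """Enumerate the balanced design table.

    One row per pot with ``pot_id, replicate, temp, water, mainplot_id``;
    each (temp, replicate) pair is one main plot containing every water
    level exactly once.
    """
    rows = []
    pot = 0
    for it, t in enumerate(spec.temp_levels):
        for r in range(1, spec.replicates + 1):
            for w in spec.water_levels:
                pot += 1
                rows.append((pot, r, t, w, f"{t}:rep{r}"))
    return pd.DataFrame(rows, columns=["pot_id", "replicate", "temp", "water", "mainplot_id"])


def simulate_trait(
    design: pd.DataFrame,
    model: TraitModel,
    seed: int,
    name: str = "trait",
) -> np.ndarray:
    """Simulate one measurement for every pot of a design table.

    The random substream is derived from (seed, name) so simulating several
    traits from one seed gives independent, order-stable draws.
    """
    rng = substream(seed, "simulate", name)
    temp_levels = list(dict.fromkeys(design["temp"]))
    water_levels = list(dict.fromkeys(design["water"]))
    ti = design["temp"].map({t: i for i, t in enumerate(temp_levels)}).to_numpy()
    wi = design["water"].map({w: i for i, w in enumerate(water_levels)}).to_numpy()
    cell = model.cell_means()
    fixed = cell[ti, wi]

    # one shared draw per main plot, in first-appearance order
    mp_labels = list(dict.fromkeys(design["mainplot_id"]))
    mp_draw = rng.normal(0.0, model.sigma_mainplot, size=len(mp_labels))
    mp = design["mainplot_id"].map({m: i for i, m in enumerate(mp_labels)}).to_numpy()
    base = fixed + mp_draw[mp]

    values = base + rng.normal(0.0, model.sigma_resid, size=len(base))
    lo = -np.inf if model.lower is None else model.lower
    hi = np.inf if model.upper is None else model.upper
    bad = (values < lo) | (values > hi)
    attempts = 0
    while bad.any():
        attempts += 1
        if attempts > _MAX_REJECTION_ATTEMPTS:
            raise GenerationError(
                f"could not draw admissible values for {name!r} within "
                f"{_MAX_REJECTION_ATTEMPTS} rejection attempts (bounds [{lo}, {hi}])"
            )
        values[bad] = base[bad] + rng.normal(0.0, model.sigma_resid, size=int(bad.sum()))
        bad = (values < lo) | (values > hi)
    return values


def simulate_raw_experiment(config: ScenarioConfig) -> pd.DataFrame:
    """Generate the full raw per-pot table (POT_COLUMNS) for a scenario."""
    design = build_design(config.design)
    out = design.drop(columns="mainplot_id").copy()
    for name in RAW_MEASUREMENTS:
        out[name] = simulate_trait(design, config.raw_measurement_models[name], config.seed, name)
    return out[POT_COLUMNS]


# ---------------------------------------------------------------------------
# Default scenario: a maize pot experiment under two warming regimes crossed
# with well-watered / water-stress / salt-stress irrigation.  Cell means and
# dispersions are typical of such experiments: salt stress roughly halves
# biomass and water use, water stress cuts shoot growth ~20% and fertilizer
# recovery ~40%, warming raises water consumption and erodes WUE.
# ---------------------------------------------------------------------------

_NATURAL_ABUNDANCE = 0.3663   # atom% 15N of unlabelled N
_FERT_ATOM_PCT = 10.0         # atom% 15N of the labelled fertilizer
_FERT_N_G = 0.0403            # g N per pot (190 mg ammonium sulfate x 0.212)
_DELTA13C_AIR = -8.15         # per mil vs PDB

# rows: Tamb, T1, T2; cols: WW, WS, SS
_SHOOT = [[1.300, 1.052, 0.688],
          [1.233, 1.000, 0.640],
          [1.242, 0.914, 0.623]]
_ROOT = [[0.690, 0.761, 0.319],
         [0.687, 0.732, 0.260],
         [0.633, 0.697, 0.386]]
_WATER = [[1.640, 1.403, 0.953],
          [1.784, 1.466, 1.004],
          [1.873, 1.554, 1.141]]
_NCONC = [[23.60, 23.69, 27.38],
          [23.59, 24.32, 28.41],
          [23.22, 23.80, 26.91]]
# percentage of applied fertilizer N recovered in the plant
_REC_PCT = [[8.90, 5.36, 6.82],
            [10.02, 5.04, 6.22],
            [9.55, 5.16, 5.43]]
# carbon-isotope discrimination (per mil); converted to delta13C below
_DISCRIM = [[5.800, 5.982, 5.957],
            [5.834, 5.992, 5.806],
            [5.769, 5.870, 5.851]]


def _atom_pct_grid() -> np.ndarray:
    """Back out atom% 15N cell means from recovery%, biomass and N conc grids."""
    biomass = np.asarray(_SHOOT) + np.asarray(_ROOT)            # g
    n_t = biomass * np.asarray(_NCONC) / 1000.0                 # g N per pot
    amount = np.asarray(_REC_PCT) / 100.0 * _FERT_N_G           # g fertilizer N in plant
    excess_frac = amount / n_t
    return _NATURAL_ABUNDANCE + excess_frac * (_FERT_ATOM_PCT - _NATURAL_ABUNDANCE)


def _delta13c_grid() -> np.ndarray:
    d = np.asarray(_DISCRIM)
    return (_DELTA13C_AIR - d) / (1.0 + d / 1000.0)


def default_scenario(seed: int = 0, design: DesignSpec | None = None) -> ScenarioConfig:
    """The package's reference scenario (3 temps x 3 waters x 10 replicates)."""
    design = design or DesignSpec()
    if (len(design.temp_levels), len(design.water_levels)) != (3, 3):
        raise ConfigurationError("default_scenario requires a 3x3 factorial design")
    models = {
        "shoot_dw_g": TraitModel.from_cell_means(_SHOOT, 0.04, 0.13, lower=0.01),
        "root_dw_g": TraitModel.from_cell_means(_ROOT, 0.03, 0.10, lower=0.01),
        "water_applied_L": TraitModel.from_cell_means(_WATER, 0.03, 0.10, lower=0.05),
        "n_conc_mg_g": TraitModel.from_cell_means(_NCONC, 0.35, 1.15, lower=1.0),
        "atom_pct_15N": TraitModel.from_cell_means(
            _atom_pct_grid(), 0.03, 0.095, lower=_NATURAL_ABUNDANCE, upper=_FERT_ATOM_PCT
        ),
        "delta13C_permil": TraitModel.from_cell_means(_delta13c_grid(), 0.03, 0.095),
    }
    return ScenarioConfig(design=design, raw_measurement_models=models, seed=seed)


def treatment_label(temp: str, water: str, ambient: str = "Tamb", control_water: str = "WW") -> str:
    """Collapse (temp, water) into the field's treatment naming.

    Ambient well-watered pots are the control "WW"; warmed well-watered pots
    are named by their temperature regime ("T1", "T2"); stressed pots are
    "WS"/"SS" at ambient and "WS(T1)" etc. under warming.
    """
    if temp == ambient:
        return water
    if water == control_water:
        return temp
    return f"{water}({temp})"


def add_treatment_column(table: pd.DataFrame, ambient: str = "Tamb", control_water: str = "WW") -> pd.DataFrame:
    out = table.copy()
    out["treatment"] = [
        treatment_label(t, w, ambient, control_water)
        for t, w in zip(out["temp"], out["water"])
    ]
    return out
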