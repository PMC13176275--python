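"""Resource-use traits from raw per-pot measurements.

Nine analysis traits are derived per pot:

* shoot, root dry weight (g) — carried through from the raw table
* water_consumption (L) — total water applied over the experiment
* WUE = biomass / water consumption (g L⁻¹)
* n_concentration (mg N g⁻¹ dw) of the composite shoot+root sample
* n_uptake N_t = biomass × N concentration (g N pot⁻¹)
* ¹⁵N fertilizer recovery by isotope dilution, as g N pot⁻¹ and as % of
  the fertilizer N applied:
      amount = N_t × (atom%_plant − 0.3663) / (atom%_fert − 0.3663)
      percent = 100 × amount / f
* NUE = biomass / N_t (g biomass g⁻¹ N)
* carbon-isotope discrimination Δ = (δ_air − δ_plant) / (1 + δ_plant/1000) (‰)

Biomass defaults to shoot + root (the composite sample is whole-plant);
``biomass="shoot"`` restricts it to shoot only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, InputError
from .synth import POT_COLUMNS

logger = logging.getLogger(__name__)

#: TraitTable CSV columns, fixed order
TRAIT_COLUMNS = [
    "shoot",
    "root",
    "water_consumption",
    "WUE",
    "n_concentration",
    "n_uptake",
    "n15_recovery_g",
    "n15_recovery_pct",
    "NUE",
    "delta13C_discrimination",
]

#: the nine traits entering effect-size, additivity and discriminant analyses
ANALYSIS_TRAITS = [
    "shoot",
    "root",
    "water_consumption",
    "WUE",
    "n_concentration",
    "n_uptake",
    "n15_recovery_pct",
    "NUE",
    "delta13C_discrimination",
]


@dataclass(frozen=True)
class IsotopeConstants:
    """Isotope bookkeeping constants.

    natural_abundance_atom_pct
        atom% ¹⁵N of unlabelled nitrogen (0.3663).
    delta13C_air_permil
        δ¹³C of atmospheric CO₂ vs PDB (−8.15‰).
    fert_atom_pct_15N
        atom% ¹⁵N of the labelled fertilizer (10%).
    fert_amount_g
        the divisor f of the percent-recovery equation, in g pot⁻¹.
        Defaults to fertilizer-N mass (0.0403 g N = 190 mg ammonium
        sulfate × 0.212); set to the fertilizer product mass instead if
        recovery is wanted on a product basis.
    """

    natural_abundance_atom_pct: float = 0.3663
    delta13C_air_permil: float = -8.15
    fert_atom_pct_15N: float = 10.0
    fert_amount_g: float = 0.0403

    def __post_init__(self) -> None:
        if self.fert_atom_pct_15N <= self.natural_abundance_atom_pct:
            raise ConfigurationError(
                "fertilizer atom% must exceed natural abundance "
                f"({self.fert_atom_pct_15N} <= {self.natural_abundance_atom_pct})"
            )
        if self.fert_amount_g <= 0:
            raise ConfigurationError("fert_amount_g must be positive")


def n_uptake(biomass_g, n_conc_mg_g):
    """Total N uptake N_t (g N pot⁻¹) = biomass (g) × N concentration (mg g⁻¹)/1000."""
    biomass_g = np.asarray(biomass_g, float)
    n_conc_mg_g = np.asarray(n_conc_mg_g, float)
    if (biomass_g < 0).any() or (n_conc_mg_g < 0).any():
        raise DomainError("biomass and N concentration must be non-negative")
    return biomass_g * n_conc_mg_g / 1000.0


def n15_recovery(n_uptake_g, atom_pct_plant, constants: IsotopeConstants = IsotopeConstants()):
    """Fertilizer-derived N by isotope dilution.

    Returns ``(amount_g, percent)``: grams of fertilizer N in the plant and
    the percentage of the applied amount f that this represents.
    """
    n_uptake_g = np.asarray(n_uptake_g, float)
    atom_pct_plant = np.asarray(atom_pct_plant, float)
    nat = constants.natural_abundance_atom_pct
    if (atom_pct_plant < nat - 1e-12).any():
        raise DomainError(
            f"plant atom% 15N below natural abundance ({nat}); check the input units"
        )
    excess_plant = np.maximum(atom_pct_plant - nat, 0.0)
    excess_fert = constants.fert_atom_pct_15N - nat
    amount = n_uptake_g * excess_plant / excess_fert
    percent = 100.0 * amount / constants.fert_amount_g
    return amount, percent


def discrimination(delta13C_plant, constants: IsotopeConstants = IsotopeConstants()):
    """Carbon-isotope discrimination Δ (‰) from plant δ¹³C."""
    delta13C_plant = np.asarray(delta13C_plant, float)
    if (delta13C_plant <= -1000).any():
        raise DomainError("delta13C <= -1000 per mil is outside the isotope-ratio domain")
    return (constants.delta13C_air_permil - delta13C_plant) / (1.0 + delta13C_plant / 1000.0)


def wue(biomass_g, water_L):
    """Water-use efficiency (g biomass L⁻¹ water)."""
    biomass_g = np.asarray(biomass_g, float)
    water_L = np.asarray(water_L, float)
    if (water_L <= 0).any():
        raise DomainError("water consumption must be strictly positive")
    return biomass_g / water_L


def nue(biomass_g, n_uptake_g):
    """Nitrogen-use efficiency (g biomass g⁻¹ N taken up)."""
    biomass_g = np.asarray(biomass_g, float)
    n_uptake_g = np.asarray(n_uptake_g, float)
    if (n_uptake_g <= 0).any():
        raise DomainError("N uptake must be strictly positive for NUE")
    return biomass_g / n_uptake_g


def derive_all(
    pot_table: pd.DataFrame,
    constants: IsotopeConstants = IsotopeConstants(),
    biomass: str = "total",
) -> pd.DataFrame:
    """Derive the full TraitTable from a raw per-pot table.

    Design columns (pot_id, replicate, temp, water) are carried through.
    Rows with missing raw fields propagate NaN traits with a logged warning.
    """
    required = [c for c in POT_COLUMNS if c != "pot_id"]
    missing = [c for c in required if c not in pot_table.columns]
    if missing:
        raise InputError(f"pot table is missing column(s): {missing}")
    if biomass not in ("total", "shoot"):
        raise ConfigurationError(f"biomass must be 'total' or 'shoot', got {biomass!r}")

    raw = pot_table[[c for c in POT_COLUMNS if c in pot_table.columns]].copy()
    n_missing = int(raw[[c for c in raw.columns if c not in ("pot_id",)]].isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%d pot(s) have missing raw fields; traits propagate NaN", n_missing)

    shoot = raw["shoot_dw_g"].to_numpy(float)
    root = raw["root_dw_g"].to_numpy(float)
    bm = shoot if biomass == "shoot" else shoot + root
    water = raw["water_applied_L"].to_numpy(float)
    nconc = raw["n_conc_mg_g"].to_numpy(float)
    atom = raw["atom_pct_15N"].to_numpy(float)
    d13c = raw["delta13C_permil"].to_numpy(float)

    if np.any(water[~np.isnan(water)] <= 0):
        raise DomainError("water_applied_L must be strictly positive")
    nat = constants.natural_abundance_atom_pct
    if np.any(atom[~np.isnan(atom)] < nat - 1e-12):
        raise DomainError(f"atom_pct_15N below natural abundance ({nat})")

    with np.errstate(invalid="ignore"):
        nt = n_uptake(np.nan_to_num(bm, nan=0.0), np.nan_to_num(nconc, nan=0.0))
        nt = np.where(np.isnan(bm) | np.isnan(nconc), np.nan, nt)
        amount, pct = n15_recovery(np.nan_to_num(nt, nan=0.0),
                                   np.nan_to_num(atom, nan=constants.natural_abundance_atom_pct),
                                   constants)
        amount = np.where(np.isnan(nt) | np.isnan(atom), np.nan, amount)
        pct = np.where(np.isnan(nt) | np.isnan(atom), np.nan, pct)
        disc = np.where(np.isnan(d13c), np.nan,
                        discrimination(np.nan_to_num(d13c, nan=0.0), constants))

    out = raw[[c for c in ("pot_id", "replicate", "temp", "water") if c in raw.columns]].copy()
    out["shoot"] = shoot
    out["root"] = root
    out["water_consumption"] = water
    out["WUE"] = bm / water
    out["n_concentration"] = nconc
    out["n_uptake"] = nt
    out["n15_recovery_g"] = amount
    out["n15_recovery_pct"] = pct
    out["NUE"] = np.where(nt > 0, bm / np.where(nt > 0, nt, 1.0), np.nan)
    out["delta13C_discrimination"] = disc
    return out
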