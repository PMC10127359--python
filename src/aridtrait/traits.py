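"""Derivation of water-balance traits from gravimetric assay series.

An individual beetle is weighed on a fixed daytime schedule (3 h apart during
the day, 15 h overnight) for up to 96 h in dry air. From the resulting series
of wet masses, the alive/dead flag at each weighing, and the post-mortem dry
mass, four traits are derived:

* desiccation resistance (DR): survival time as a proportion of the horizon;
* water loss rate (WLR): OLS slope of water mass on time, as a proportion of
  initial water content per hour (mg mg^-1 h^-1);
* water loss tolerance (WLT): percent of initial water content lost at death;
* fractional water content (fWC): initial water content / dry mass.

Death is only interval-observed: when an individual is first seen dead, the
survival time is taken as the median (midpoint) of the last-alive and
first-dead weighing times, and the mass at death as the mean of the two
bracketing masses. Survivors are censored at the horizon with DR = 1 and
undefined physiological traits.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NESTING_STRATEGIES = ("tunneler", "dweller", "roller")

# Wet mass may dip marginally below dry mass through balance noise; deficits
# up to this fraction of dry mass are clamped, larger deficits at an alive
# observation are data errors.
CLAMP_TOLERANCE = 0.02


class UndefinedTraitError(ValueError):
    """A trait cannot be derived for this individual (e.g. too few points)."""


@dataclasses.dataclass
class MeasurementSeries:
    """One individual's timestamped wet masses plus metadata.

    ``times`` (hours from the first weighing), ``wet_mass`` (mg) and
    ``alive`` flags must be equal-length; times strictly increasing; the
    first observation alive; flags monotone (once dead, always dead).
    """

    individual_id: str
    species: str
    nesting_strategy: str
    dry_mass_mg: float
    times: np.ndarray
    wet_mass: np.ndarray
    alive: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wet_mass = np.asarray(self.wet_mass, dtype=float)
        self.alive = np.asarray(self.alive, dtype=bool)
        if self.nesting_strategy.strip().lower() not in NESTING_STRATEGIES:
            raise ValueError(f"unknown nesting strategy {self.nesting_strategy!r}")
        self.nesting_strategy = self.nesting_strategy.strip().lower()
        if len(self.times) == 0:
            raise ValueError(f"{self.individual_id}: series has no observations")
        if not (len(self.times) == len(self.wet_mass) == len(self.alive)):
            raise ValueError(f"{self.individual_id}: ragged series")
        if self.dry_mass_mg <= 0:
            raise ValueError(f"{self.individual_id}: non-positive dry mass")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.individual_id}: times not strictly increasing")
        if not self.alive[0]:
            raise ValueError(f"{self.individual_id}: first observation must be alive")
        if np.any(np.diff(self.alive.astype(int)) > 0):
            raise ValueError(f"{self.individual_id}: alive flag resurrects")
        self._clamp_to_dry_mass()

    def _clamp_to_dry_mass(self) -> None:
        deficit = self.dry_mass_mg - self.wet_mass
        bad = deficit > CLAMP_TOLERANCE * self.dry_mass_mg
        if np.any(bad & self.alive):
            i = int(np.argmax(bad & self.alive))
            raise ValueError(
                f"{self.individual_id}: wet mass {self.wet_mass[i]:.3f} mg at "
                f"t={self.times[i]} h is more than {CLAMP_TOLERANCE:.0%} below "
                f"dry mass {self.dry_mass_mg:.3f} mg"
            )
        clamp = deficit > 0
        if np.any(clamp & self.alive):
            warnings.warn(
                f"{self.individual_id}: wet mass marginally below dry mass at "
                f"{int(np.sum(clamp & self.alive))} alive observation(s); clamped",
                stacklevel=3,
            )
        self.wet_mass = np.maximum(self.wet_mass, self.dry_mass_mg)

    @property
    def initial_wet_mass(self) -> float:
        return float(self.wet_mass[0])

    @property
    def initial_water(self) -> float:
        return self.initial_wet_mass - self.dry_mass_mg

    def first_dead_index(self) -> int | None:
        dead = np.flatnonzero(~self.alive)
        return int(dead[0]) if dead.size else None


def death_time(series: MeasurementSeries, horizon_h: float) -> tuple[float, bool]:
    """Interval-censored survival time in hours.

    Returns the midpoint (median of the two values) of the last-alive and
    first-dead weighing times when a death is observed, else
    ``(horizon_h, False)`` for a censored survivor. The midpoint rule is
    applied to every death interval, overnight or within-day, for
    consistency.
    """
    i = series.first_dead_index()
    if i is None:
        return float(horizon_h), False
    return float((series.times[i - 1] + series.times[i]) / 2), True


def desiccation_resistance(survival_h: float, horizon_h: float) -> float:
    """Survival time as a proportion of the assay horizon (0 < DR <= 1)."""
    if not 0 < survival_h <= horizon_h:
        raise ValueError(
            f"survival {survival_h} h must lie in (0, {horizon_h}] h"
        )
    return survival_h / horizon_h


def water_loss_rate(series: MeasurementSeries) -> float:
    """WLR: minus the OLS slope of water mass on time over alive observations,
    divided by initial water content (proportion of initial water per hour).

    Requires at least 3 alive observations; a 2-point slope is noise-dominated
    and the individual is excluded from modelling instead.
    """
    mask = series.alive
    if int(mask.sum()) < 3:
        raise UndefinedTraitError(
            f"{series.individual_id}: only {int(mask.sum())} alive observations "
            "(need >= 3 for the water-loss regression)"
        )
    w0 = series.initial_water
    if w0 <= 0:
        raise ValueError(f"{series.individual_id}: initial water content <= 0")
    t = series.times[mask]
    water = series.wet_mass[mask] - series.dry_mass_mg
    slope = np.polyfit(t, water, 1)[0]
    return float(-slope / w0)


def water_loss_tolerance(series: MeasurementSeries) -> float:
    """WLT: percent of initial water content lost at the time of death.

    The wet mass at death is the mean of the last-alive and first-dead
    masses (death is interval-observed).
    """
    i = series.first_dead_index()
    if i is None:
        raise UndefinedTraitError(
            f"{series.individual_id}: survived the assay; WLT undefined"
        )
    w0 = series.initial_water
    if w0 <= 0:
        raise ValueError(f"{series.individual_id}: initial water content <= 0")
    final_wet = (series.wet_mass[i - 1] + series.wet_mass[i]) / 2
    return float(100.0 * (series.initial_wet_mass - final_wet) / w0)


def fractional_water_content(series: MeasurementSeries) -> float:
    """fWC: initial water content divided by dry mass (mg mg^-1)."""
    fwc = series.initial_water / series.dry_mass_mg
    if fwc < 0:
        raise ValueError(f"{series.individual_id}: initial wet mass below dry mass")
    if fwc == 0:
        warnings.warn(
            f"{series.individual_id}: initial wet mass equals dry mass (fWC = 0)",
            stacklevel=2,
        )
    return float(fwc)


TRAIT_COLUMNS = [
    "individual_id",
    "species",
    "nesting_strategy",
    "body_mass_mg",
    "log_body_mass",
    "survival_h",
    "desiccation_resistance",
    "water_loss_rate",
    "water_loss_tolerance",
    "fractional_water_content",
    "died_in_assay",
    "n_alive_obs",
    "excluded_reason",
]


def derive_table(
    series_list: Iterable[MeasurementSeries], horizon_h: float = 96.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual trait table plus per-species summary.

    Physiological traits (WLR, WLT, fWC) and DR are derived only for
    individuals that died in the assay; survivors carry DR = 1 for reference
    but enter the summary's DR/WLR/WLT/fWC columns as missing, mirroring a
    protocol in which traits are measured on dead individuals only.
    Individuals whose WLR cannot be computed (fewer than 3 alive weighings)
    are retained with a logged ``excluded_reason``.
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("derive_table requires at least one series")
    rows = []
    for s in series_list:
        survival, died = death_time(s, horizon_h)
        rec: dict = {
            "individual_id": s.individual_id,
            "species": s.species,
            "nesting_strategy": s.nesting_strategy,
            "body_mass_mg": s.dry_mass_mg,
            "log_body_mass": float(np.log(s.dry_mass_mg)),
            "survival_h": survival,
            "desiccation_resistance": desiccation_resistance(survival, horizon_h),
            "water_loss_rate": np.nan,
            "water_loss_tolerance": np.nan,
            "fractional_water_content": np.nan,
            "died_in_assay": died,
            "n_alive_obs": int(s.alive.sum()),
            "excluded_reason": "",
        }
        if died:
            try:
                rec["water_loss_rate"] = water_loss_rate(s)
            except UndefinedTraitError as exc:
                rec["excluded_reason"] = str(exc)
            rec["water_loss_tolerance"] = water_loss_tolerance(s)
            rec["fractional_water_content"] = fractional_water_content(s)
        else:
            rec["excluded_reason"] = "survived to horizon (censored)"
        rows.append(rec)
    table = pd.DataFrame(rows, columns=TRAIT_COLUMNS)
    return table, species_summary(table)


def species_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-species means and SDs in the layout of the study's trait table.

    Body mass is summarised over all individuals (dry mass is measured for
    everyone post-mortem); DR, WLR, WLT and fWC over individuals that died.
    """
    rows = []
    for sp, grp in table.groupby("species", sort=True):
        dead = grp[grp["died_in_assay"]]
        row = {
            "species": sp,
            "nesting_strategy": grp["nesting_strategy"].iloc[0],
            "n_dead": int(len(dead)),
            "n_total": int(len(grp)),
            "bm_mean": grp["body_mass_mg"].mean(),
            "bm_sd": grp["body_mass_mg"].std(ddof=1),
        }
        for col, key in [
            ("desiccation_resistance", "dr"),
            ("water_loss_rate", "wlr"),
            ("water_loss_tolerance", "wlt"),
            ("fractional_water_content", "fwc"),
        ]:
            vals = dead[col].dropna()
            row[f"{key}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{key}_sd"] = vals.std(ddof=1) if len(vals) > 1 else (
                0.0 if len(vals) == 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


SCALED_TRAITS = {
    "body_mass_mg": "scaled_bm",
    "water_loss_rate": "scaled_wlr",
    "water_loss_tolerance": "scaled_wlt",
}


def scale_within_species(table: pd.DataFrame) -> pd.DataFrame:
    """Add within-species scaled covariates: (x - species mean) / species mean.

    Species means are taken over individuals with the trait defined (i.e.
    those that died, for WLR/WLT). Scaled values are dimensionless relative
    deviations; an individual at the species mean scores 0, one at twice the
    mean scores 1.
    """
    out = table.copy()
    for raw, scaled in SCALED_TRAITS.items():
        means = (
            out[out["died_in_assay"]]
            .groupby("species")[raw]
            .mean()
        )
        if (means.dropna() == 0).any():
            zero = means[means == 0].index.tolist()
            raise ValueError(f"species mean of {raw} is zero for {zero}")
        out[scaled] = out[raw] / out["species"].map(means) - 1.0
        out.loc[~out["died_in_assay"], scaled] = np.nan
    return out


@dataclasses.dataclass
class CollinearityReport:
    """Pairwise Pearson correlations among model covariates."""

    matrix: pd.DataFrame
    max_abs_r: float
    flagged_pairs: list[tuple[str, str, float]]
    constant_columns: list[str]
    threshold: float


def collinearity_check(
    table: pd.DataFrame, threshold: float = 0.7
) -> CollinearityReport:
    """Screen WLR, WLT, fWC and body mass for collinearity before modelling.

    Complete records only. Pairs with |r| above ``threshold`` are flagged;
    constant columns have undefined correlations and are reported as such.
    """
    cols = [
        "water_loss_rate",
        "water_loss_tolerance",
        "fractional_water_content",
        "body_mass_mg",
    ]
    data = table[cols].dropna()
    if len(data) < 3:
        raise ValueError("collinearity check needs at least 3 complete records")
    constant = [c for c in cols if data[c].nunique() == 1]
    corr = data.corr(method="pearson")
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    off = corr.where(~np.eye(len(cols), dtype=bool))
    max_abs = float(np.nanmax(np.abs(off.to_numpy()))) if not off.isna().all().all() else np.nan
    flagged = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                flagged.append((a, b, float(r)))
    if flagged:
        warnings.warn(
            "collinear covariate pairs (|r| > "
            f"{threshold}): {[(a, b, round(r, 3)) for a, b, r in flagged]}",
            stacklevel=2,
        )
    return CollinearityReport(
        matrix=corr,
        max_abs_r=max_abs,
        flagged_pairs=flagged,
        constant_columns=constant,
        threshold=threshold,
    )
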