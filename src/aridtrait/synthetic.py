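"""Synthetic study-design generators with known ground truth.

Everything downstream of raw data — trait derivation, GLM/GLMM inference and
the contrast analyses — is testable against the generators here:

* :func:`simulate_tree` — seeded pure-birth (Yule) trees;
* :func:`simulate_bm_traits` — Brownian-motion trait evolution along a tree;
* :func:`simulate_assay` — a mechanistic desiccation assay: each individual
  loses a fixed proportion of its initial water per hour and dies when its
  species-specific tolerable fraction is gone, observed only at the daytime
  weighing schedule (3 h gaps during the day, 15 h overnight), censored at
  the horizon;
* :func:`simulate_glmm_dataset` — binomial responses with a species random
  intercept for parameter-recovery checks.

All generators are bit-reproducible given their seed.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo import Node, PhyloTree
from .traits import MeasurementSeries, NESTING_STRATEGIES

_MAX_REDRAWS = 100


@dataclasses.dataclass
class SpeciesParams:
    """Population-level water-balance parameters for one species.

    ``mean_wlr_per_h`` is the proportion of initial water lost per hour;
    ``mean_wlt_pct`` the percent of initial water whose loss is fatal;
    ``mean_fwc`` the initial water mass per unit dry mass. Coefficients of
    variation control within-species spread (0 = all individuals identical).
    """

    nesting_strategy: str
    mean_dry_mass_mg: float
    cv_dry_mass: float
    mean_fwc: float
    mean_wlr_per_h: float
    cv_wlr: float
    mean_wlt_pct: float
    cv_fwc: float = 0.0
    cv_wlt: float = 0.0

    def __post_init__(self) -> None:
        if self.nesting_strategy.strip().lower() not in NESTING_STRATEGIES:
            raise ValueError(f"unknown nesting strategy {self.nesting_strategy!r}")
        self.nesting_strategy = self.nesting_strategy.strip().lower()
        for name in ("mean_dry_mass_mg", "mean_fwc", "mean_wlr_per_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.mean_wlt_pct <= 100:
            raise ValueError("mean_wlt_pct must lie in (0, 100]")
        for name in ("cv_dry_mass", "cv_wlr", "cv_fwc", "cv_wlt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclasses.dataclass
class AssayConfig:
    """Full specification of a simulated desiccation assay."""

    species_params: dict[str, SpeciesParams]
    n_individuals: dict[str, int]
    horizon_h: float = 96.0
    daily_weigh_times_h: Sequence[float] = (9.0, 12.0, 15.0, 18.0)
    day_length_h: float = 24.0
    measurement_noise_sd_mg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.n_individuals) - set(self.species_params):
            raise ValueError("n_individuals names species without parameters")
        if any(n < 1 for n in self.n_individuals.values()):
            raise ValueError("n_individuals must be positive")
        if self.horizon_h <= 0:
            raise ValueError("horizon_h must be positive")
        if self.measurement_noise_sd_mg < 0:
            raise ValueError("measurement_noise_sd_mg must be >= 0")
        if len(self.daily_weigh_times_h) < 1:
            raise ValueError("need at least one daily weighing time")


def schedule(config: AssayConfig) -> np.ndarray:
    """Weighing times in hours, with t = 0 at the first weighing of day 1.

    With the default 09:00/12:00/15:00/18:00 times and 24 h days the
    schedule is {0, 3, 6, 9} + 24k for day k, giving 3 h gaps within a day
    and a 15 h overnight gap, through the horizon inclusive.
    """
    within = sorted(set(config.daily_weigh_times_h))
    offsets = np.array(within, dtype=float) - within[0]
    times = []
    day = 0
    while True:
        day_times = offsets + day * config.day_length_h
        keep = day_times[day_times <= config.horizon_h + 1e-9]
        if keep.size == 0:
            break
        times.extend(keep.tolist())
        day += 1
    return np.array(times)


@dataclasses.dataclass
class IndividualTruth:
    """Generator-side ground truth for one individual."""

    species: str
    dry_mass_mg: float
    initial_water_mg: float
    fwc: float
    wlr_per_h: float
    wlt_pct: float
    death_time_h: float | None  # None when beyond the horizon (survivor)
    censored: bool


@dataclasses.dataclass
class GroundTruth:
    """Ground truth for a simulated assay (and optionally Brownian traits)."""

    individuals: dict[str, IndividualTruth]
    species_traits: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=dict
    )


def _draw_positive(
    rng: np.random.Generator,
    mean: float,
    cv: float,
    upper: float | None = None,
) -> float:
    """Normal draw with redraws to keep the value positive (and below upper)."""
    if cv == 0:
        return mean
    sd = cv * mean
    for _ in range(_MAX_REDRAWS):
        x = rng.normal(mean, sd)
        if x > 0 and (upper is None or x <= upper):
            return float(x)
    raise RuntimeError(
        f"could not draw a positive value from N({mean}, {sd}^2) in "
        f"{_MAX_REDRAWS} attempts"
    )


def simulate_assay(
    config: AssayConfig,
) -> tuple[list[MeasurementSeries], GroundTruth]:
    """Mechanistic desiccation assay with interval-observed death.

    Per individual: dry mass, fWC, WLR and WLT are drawn from the species
    distributions; water mass declines linearly at ``wlr * initial_water``
    mg per hour (floored at zero); the true death time is
    ``wlt / (100 * wlr)`` hours. Wet mass (dry + water + optional Gaussian
    noise) is reported at every scheduled weighing up to and including the
    first weighing at which the individual is found dead; death itself is
    never observed exactly. Individuals whose true death time exceeds the
    horizon are censored survivors with a full series of alive observations.
    """
    rng = np.random.default_rng(config.seed)
    times = schedule(config)
    series: list[MeasurementSeries] = []
    truth: dict[str, IndividualTruth] = {}
    for sp in sorted(config.n_individuals):
        params = config.species_params[sp]
        for j in range(config.n_individuals[sp]):
            iid = f"{sp}_{j + 1:03d}"
            dry = _draw_positive(rng, params.mean_dry_mass_mg, params.cv_dry_mass)
            fwc = _draw_positive(rng, params.mean_fwc, params.cv_fwc)
            wlr = _draw_positive(rng, params.mean_wlr_per_h, params.cv_wlr)
            wlt = _draw_positive(rng, params.mean_wlt_pct, params.cv_wlt, upper=100.0)
            w0 = fwc * dry
            t_death = wlt / (100.0 * wlr)
            censored = t_death > config.horizon_h
            alive = times < t_death
            if censored:
                obs_idx = np.arange(len(times))
            else:
                first_dead = int(np.argmax(~alive))
                obs_idx = np.arange(first_dead + 1)
            t_obs = times[obs_idx]
            water = np.maximum(w0 * (1.0 - wlr * t_obs), 0.0)
            wet = dry + water
            if config.measurement_noise_sd_mg > 0:
                wet = wet + rng.normal(0, config.measurement_noise_sd_mg, wet.shape)
            series.append(
                MeasurementSeries(
                    individual_id=iid,
                    species=sp,
                    nesting_strategy=params.nesting_strategy,
                    dry_mass_mg=dry,
                    times=t_obs,
                    wet_mass=wet,
                    alive=alive[obs_idx],
                )
            )
            truth[iid] = IndividualTruth(
                species=sp,
                dry_mass_mg=dry,
                initial_water_mg=w0,
                fwc=fwc,
                wlr_per_h=wlr,
                wlt_pct=wlt,
                death_time_h=None if censored else float(t_death),
                censored=censored,
            )
    return series, GroundTruth(individuals=truth)


def simulate_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> PhyloTree:
    """Seeded pure-birth (Yule) tree with ``n_tips`` tips labelled sp1..spN.

    Lineages split at exponential waiting times; a final exponential waiting
    time after the last split keeps every pendant branch strictly positive.
    """
    if n_tips < 2:
        raise ValueError("a bifurcating tree needs at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    root = Node()
    root.children = [Node(length=0.0), Node(length=0.0)]
    active = list(root.children)
    while len(active) < n_tips:
        k = len(active)
        dt = rng.exponential(1.0 / (birth_rate * k))
        for node in active:
            node.length += dt  # type: ignore[operator]
        i = int(rng.integers(k))
        parent = active.pop(i)
        parent.children = [Node(length=0.0), Node(length=0.0)]
        active.extend(parent.children)
    dt = rng.exponential(1.0 / (birth_rate * n_tips))
    for node in active:
        node.length += dt  # type: ignore[operator]
    for i, node in enumerate(active):
        node.label = f"sp{i + 1}"
    return PhyloTree(root)


def simulate_bm_traits(
    tree: PhyloTree, sigma2: float, root_value: float, seed: int
) -> dict[str, float]:
    """Brownian-motion trait values at the tips of ``tree``.

    Independent normal increments with variance ``sigma2 * branch_length``
    accumulate along every edge from ``root_value``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {tree.root.index: float(root_value)}
    out: dict[str, float] = {}

    # pre-order recursion: parents before children, deterministic draw order
    def visit(node: Node) -> None:
        for child in node.children:
            step = rng.normal(0.0, np.sqrt(sigma2 * child.length))
            values[child.index] = values[node.index] + step
            if child.is_tip:
                out[child.label] = values[child.index]  # type: ignore[index]
            else:
                visit(child)

    visit(tree.root)
    return out


def simulate_glmm_dataset(
    beta: Sequence[float],
    sigma_species: float,
    n_species: int,
    n_per_species: int | Sequence[int],
    trials: int,
    seed: int,
) -> pd.DataFrame:
    """Binomial data with a species random intercept and known coefficients.

    The linear predictor is ``beta[0] + beta[1:] . x + b_species`` with
    covariates ``x`` drawn i.i.d. standard normal and species intercepts
    ``b ~ Normal(0, sigma_species^2)``; successes are
    ``Binomial(trials, logistic(eta))``. Returns a long table with columns
    ``species, x1..xp, successes, trials``.
    """
    beta = np.asarray(beta, dtype=float)
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if sigma_species < 0:
        raise ValueError("sigma_species must be >= 0")
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if np.isscalar(n_per_species):
        counts = [int(n_per_species)] * n_species
    else:
        counts = [int(n) for n in n_per_species]
        if len(counts) != n_species:
            raise ValueError("n_per_species length must equal n_species")
    if any(c < 1 for c in counts):
        raise ValueError("n_per_species must be positive")
    rng = np.random.default_rng(seed)
    p_cov = len(beta) - 1
    rows = []
    intercepts = rng.normal(0.0, sigma_species, size=n_species)
    for s in range(n_species):
        x = rng.standard_normal((counts[s], p_cov))
        eta = beta[0] + x @ beta[1:] + intercepts[s]
        prob = 1.0 / (1.0 + np.exp(-eta))
        y = rng.binomial(trials, prob)
        for i in range(counts[s]):
            row = {"species": f"sp{s + 1}"}
            row.update({f"x{k + 1}": x[i, k] for k in range(p_cov)})
            row["successes"] = int(y[i])
            row["trials"] = trials
            rows.append(row)
    return pd.DataFrame(rows)
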