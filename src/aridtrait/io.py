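"""File formats and cross-file validation.

CSV artifacts (comma-separated, UTF-8, header row mandatory):

* ``individuals.csv`` — individual_id, species, nesting_strategy, dry_mass_mg
* ``weighings.csv``   — individual_id, time_h, wet_mass_mg, alive (0/1)
* ``traits.csv``      — per-individual derived traits
* ``species_summary.csv`` — per-species means and SDs

Ground truth is JSON; trees are strict Newick with mandatory branch lengths.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo import PhyloTree, read_newick
from .synthetic import GroundTruth, IndividualTruth
from .traits import MeasurementSeries

INDIVIDUAL_COLUMNS = ["individual_id", "species", "nesting_strategy", "dry_mass_mg"]
WEIGHING_COLUMNS = ["individual_id", "time_h", "wet_mass_mg", "alive"]


def series_to_frames(
    series_list: list[MeasurementSeries],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    ind_rows, weigh_rows = [], []
    for s in series_list:
        ind_rows.append(
            {
                "individual_id": s.individual_id,
                "species": s.species,
                "nesting_strategy": s.nesting_strategy,
                "dry_mass_mg": s.dry_mass_mg,
            }
        )
        for t, wm, al in zip(s.times, s.wet_mass, s.alive):
            weigh_rows.append(
                {
                    "individual_id": s.individual_id,
                    "time_h": float(t),
                    "wet_mass_mg": float(wm),
                    "alive": int(al),
                }
            )
    return (
        pd.DataFrame(ind_rows, columns=INDIVIDUAL_COLUMNS),
        pd.DataFrame(weigh_rows, columns=WEIGHING_COLUMNS),
    )


def frames_to_series(
    individuals: pd.DataFrame, weighings: pd.DataFrame
) -> list[MeasurementSeries]:
    missing = set(INDIVIDUAL_COLUMNS) - set(individuals.columns)
    if missing:
        raise ValueError(f"individuals table missing columns: {sorted(missing)}")
    missing = set(WEIGHING_COLUMNS) - set(weighings.columns)
    if missing:
        raise ValueError(f"weighings table missing columns: {sorted(missing)}")
    grouped = dict(tuple(weighings.groupby("individual_id", sort=False)))
    out = []
    for _, row in individuals.iterrows():
        iid = row["individual_id"]
        if iid not in grouped:
            raise ValueError(f"individual {iid!r} has no weighings")
        w = grouped[iid].sort_values("time_h")
        out.append(
            MeasurementSeries(
                individual_id=str(iid),
                species=str(row["species"]),
                nesting_strategy=str(row["nesting_strategy"]),
                dry_mass_mg=float(row["dry_mass_mg"]),
                times=w["time_h"].to_numpy(dtype=float),
                wet_mass=w["wet_mass_mg"].to_numpy(dtype=float),
                alive=w["alive"].to_numpy(dtype=int).astype(bool),
            )
        )
    return out


def write_series(series_list: list[MeasurementSeries], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    ind, weigh = series_to_frames(series_list)
    ind.to_csv(out_dir / "individuals.csv", index=False)
    weigh.to_csv(out_dir / "weighings.csv", index=False)


def read_series(
    individuals_path: str | Path, weighings_path: str | Path
) -> list[MeasurementSeries]:
    for p in (individuals_path, weighings_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    return frames_to_series(
        pd.read_csv(individuals_path, float_precision="round_trip"),
        pd.read_csv(weighings_path, float_precision="round_trip"),
    )


def ground_truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "individuals": {
            iid: dataclasses.asdict(t) for iid, t in truth.individuals.items()
        },
        "species_traits": truth.species_traits,
    }


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(ground_truth_to_dict(truth), fh, indent=1)


def load_ground_truth(path: str | Path) -> GroundTruth:
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    individuals = {
        iid: IndividualTruth(**rec) for iid, rec in raw["individuals"].items()
    }
    return GroundTruth(
        individuals=individuals, species_traits=raw.get("species_traits", {})
    )


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def read_tree(path: str | Path) -> PhyloTree:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"tree file not found: {path}")
    return read_newick(path.read_text(encoding="utf-8"))


def write_signal_tsv(results, path: str | Path) -> None:
    """Signal results table: trait, contrast variance, p, replicates."""
    rows = [
        {
            "trait": r.trait,
            "var_contr": r.observed_variance,
            "p_value": r.p_value,
            "n_randomizations": r.n_randomizations,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pic_tsv(results, path: str | Path) -> None:
    """Contrast-correlation table: trait pair, through-origin r, p-values."""
    rows = [
        {
            "trait_x": r.trait_x,
            "trait_y": r.trait_y,
            "r_through_origin": r.r,
            "p_parametric": r.p_parametric,
            "p_randomization": r.p_randomization,
            "n_contrasts": r.n_contrasts,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class ValidationReport:
    """All cross-file violations found in a set of inputs (not just the first)."""

    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "inputs OK: no violations"
        return "\n".join(f"- {v}" for v in self.violations)


def validate_inputs(
    individuals: pd.DataFrame,
    weighings: pd.DataFrame,
    tree: PhyloTree | None = None,
) -> ValidationReport:
    """Cross-check the raw input tables (and optionally the tree).

    Flags orphan weighings, individuals without weighings, non-monotone
    timestamps, resurrecting alive flags, non-positive dry masses, and (for
    phylogenetic stages) species missing from the tree.
    """
    v: list[str] = []
    known = set(individuals["individual_id"])
    for i, row in weighings.iterrows():
        if row["individual_id"] not in known:
            v.append(
                f"weighings row {i}: individual {row['individual_id']!r} "
                "not in individuals.csv"
            )
    with_weighings = set(weighings["individual_id"])
    for iid in sorted(known - with_weighings):
        v.append(f"individual {iid!r} has no weighings")
    dup = individuals["individual_id"][individuals["individual_id"].duplicated()]
    for iid in dup:
        v.append(f"duplicate individual_id {iid!r}")
    bad_dry = individuals[individuals["dry_mass_mg"] <= 0]
    for iid in bad_dry["individual_id"]:
        v.append(f"individual {iid!r}: non-positive dry mass")
    for iid, grp in weighings.groupby("individual_id"):
        t = grp["time_h"].to_numpy()
        if np.any(np.diff(t) <= 0):
            v.append(f"individual {iid!r}: weighing times not strictly increasing")
        alive = grp.sort_values("time_h")["alive"].to_numpy()
        if len(alive) and not alive[0]:
            v.append(f"individual {iid!r}: first observation is dead")
        if np.any(np.diff(alive) > 0):
            v.append(f"individual {iid!r}: alive flag resurrects")
    if tree is not None:
        tips = set(tree.tip_labels)
        for sp in sorted(set(individuals["species"]) - tips):
            v.append(f"species {sp!r} missing from tree tips")
    return ValidationReport(violations=v)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
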