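"""Schema-validated readers and writers for the four CSV data streams.

Schemas (RFC-4180 CSV, one header row):

``counts.csv``            year, habitat, count
``breeding_success.csv``  year, habitat, R, B
``fledglings.csv``        year, habitat, S, F
``encounters.csv``        id, sex, mark_year, mark_age, mark_habitat, then
                          per-year columns event_<year> (codes 0-4, 0 =
                          before marking) and x_<year>, y_<year> sighting
                          coordinates in km (empty when not seen).

Habitat labels are "Short" / "Tall"; years are calendar integers sharing one
contiguous range across streams.  Coordinates live in a local planar frame
(km, x easting / y northing); no CRS handling is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .demography import HABITAT_LABELS
from .movement import BREEDER, FLEDGLING, StudyArea
from .multievent import EVENT_NOT_SEEN, EncounterHistory
from .simulate import SimulatedData

__all__ = [
    "DatasetBundle",
    "SchemaError",
    "read_bundle",
    "write_bundle",
    "bundle_from_sim",
    "encounters_to_histories",
    "load_config",
    "area_from_config",
]

_HAB_TO_INT = {label: i for i, label in enumerate(HABITAT_LABELS)}
_AGE_TO_INT = {"fledgling": FLEDGLING, "breeder": BREEDER}


class SchemaError(ValueError):
    """A CSV stream violated its schema; the message names column and row."""


@dataclass
class DatasetBundle:
    """The four validated data streams plus the study-area geometry.

    All year columns are calendar integers covering the same contiguous
    range ``years``; habitat columns hold integer codes (0 = Short,
    1 = Tall).
    """

    counts: pd.DataFrame
    breeding_success: pd.DataFrame
    fledglings: pd.DataFrame
    encounters: pd.DataFrame
    area: StudyArea
    years: np.ndarray

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    @property
    def start_year(self) -> int:
        return int(self.years[0])


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def _habitat_codes(df: pd.DataFrame, name: str) -> pd.Series:
    bad = ~df["habitat"].isin(HABITAT_LABELS)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(
            f"{name} row {row}: habitat must be one of {HABITAT_LABELS}, "
            f"got {df['habitat'].iloc[row]!r}"
        )
    return df["habitat"].map(_HAB_TO_INT)


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ["year", "habitat", "count"], "counts")
    df = df.copy()
    df["habitat"] = _habitat_codes(df, "counts")
    if (df["count"] < 0).any():
        row = int(np.flatnonzero(df["count"] < 0)[0])
        raise SchemaError(f"counts row {row}: count must be non-negative")
    if df.duplicated(["year", "habitat"]).any():
        raise SchemaError("counts: one record per year x habitat required")
    return df.sort_values(["year", "habitat"], ignore_index=True)


def _validate_breeding(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ["year", "habitat", "R", "B"], "breeding_success")
    df = df.copy()
    df["habitat"] = _habitat_codes(df, "breeding_success")
    bad = (df["B"] < 0) | (df["B"] > df["R"])
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(
            f"breeding_success row {row}: need 0 <= B <= R (binomial trials), "
            f"got B={df['B'].iloc[row]}, R={df['R'].iloc[row]}"
        )
    return df.sort_values(["year", "habitat"], ignore_index=True)


def _validate_fledglings(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ["year", "habitat", "S", "F"], "fledglings")
    df = df.copy()
    df["habitat"] = _habitat_codes(df, "fledglings")
    bad = (df["S"] < 0) | (df["F"] < df["S"])
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(
            f"fledglings row {row}: need F >= S >= 0, "
            f"got F={df['F'].iloc[row]}, S={df['S'].iloc[row]}"
        )
    return df.sort_values(["year", "habitat"], ignore_index=True)


def _validate_encounters(df: pd.DataFrame, years: np.ndarray) -> pd.DataFrame:
    base = ["id", "sex", "mark_year", "mark_age", "mark_habitat"]
    _require_columns(df, base, "encounters")
    for yr in years:
        _require_columns(df, [f"event_{yr}", f"x_{yr}", f"y_{yr}"], "encounters")
    df = df.copy()
    if not df["mark_age"].isin(_AGE_TO_INT).all():
        raise SchemaError("encounters: mark_age must be 'fledgling' or 'breeder'")
    if not df["mark_habitat"].isin(HABITAT_LABELS).all():
        raise SchemaError(f"encounters: mark_habitat must be one of {HABITAT_LABELS}")
    for r in range(len(df)):
        mark_year = int(df["mark_year"].iloc[r])
        if mark_year not in years:
            raise SchemaError(f"encounters row {r}: mark_year {mark_year} outside data years")
        for yr in years:
            ev = int(df[f"event_{yr}"].iloc[r])
            x = df[f"x_{yr}"].iloc[r]
            y_ = df[f"y_{yr}"].iloc[r]
            if yr < mark_year:
                if ev != 0:
                    raise SchemaError(
                        f"encounters row {r}: event_{yr} must be 0 before marking"
                    )
                continue
            if ev not in (1, 2, 3, 4):
                raise SchemaError(
                    f"encounters row {r}: event_{yr} must be in 1-4, got {ev}"
                )
            if ev != EVENT_NOT_SEEN and (pd.isna(x) or pd.isna(y_)):
                raise SchemaError(
                    f"encounters row {r}: x_{yr}/y_{yr} required when event_{yr}={ev}"
                )
            if ev == EVENT_NOT_SEEN and not (pd.isna(x) and pd.isna(y_)):
                raise SchemaError(
                    f"encounters row {r}: coordinates present but event_{yr}=4 (not seen)"
                )
        ev0 = int(df[f"event_{int(df['mark_year'].iloc[r])}"].iloc[r])
        if ev0 not in (1, 2, 3):
            raise SchemaError(f"encounters row {r}: event at marking must be a seen code")
    return df


def _shared_years(*frames: pd.DataFrame) -> np.ndarray:
    years = None
    for df in frames:
        ys = np.sort(df["year"].unique())
        if years is None:
            years = ys
        elif not np.array_equal(years, ys):
            raise SchemaError(
                f"year ranges differ across streams: {years.tolist()} vs {ys.tolist()}"
            )
    if years is None or years.size == 0:
        raise SchemaError("no years found")
    if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
        raise SchemaError(f"years must be contiguous, got {years.tolist()}")
    return years


def read_bundle(directory, area: StudyArea | None = None) -> DatasetBundle:
    """Read and validate the four CSV streams from a directory.

    If ``area`` is not given, an ``area.yaml`` config in the directory is
    used, falling back to the default 60/40 km^2 nested rectangles.
    """
    d = Path(directory)
    paths = {
        name: d / f"{name}.csv"
        for name in ("counts", "breeding_success", "fledglings", "encounters")
    }
    for name, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing input file: {p}")
    counts = _validate_counts(pd.read_csv(paths["counts"]))
    breeding = _validate_breeding(pd.read_csv(paths["breeding_success"]))
    fledglings = _validate_fledglings(pd.read_csv(paths["fledglings"]))
    years = _shared_years(counts, breeding, fledglings)
    encounters = _validate_encounters(pd.read_csv(paths["encounters"]), years)
    if area is None:
        cfg_path = d / "area.yaml"
        area = area_from_config(load_config(cfg_path)) if cfg_path.exists() else StudyArea.default()
    return DatasetBundle(
        counts=counts,
        breeding_success=breeding,
        fledglings=fledglings,
        encounters=encounters,
        area=area,
        years=years,
    )


def write_bundle(sim: SimulatedData, directory, area: StudyArea | None = None) -> None:
    """Write a simulated dataset to CSV files (plus truth.json)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sim.counts.to_csv(d / "counts.csv", index=False)
    sim.breeding_success.to_csv(d / "breeding_success.csv", index=False)
    sim.fledglings.to_csv(d / "fledglings.csv", index=False)
    sim.encounters.to_csv(d / "encounters.csv", index=False)
    truth = {
        "nb": sim.truth["nb"].tolist(),
        "C": sim.truth["C"].tolist(),
        "mean_rates": {k: v.tolist() for k, v in sim.truth["mean_rates"].items()},
        "emigration_rate": np.nan_to_num(sim.truth["emigration_rate"], nan=-1.0).tolist(),
        "extinct": sim.extinct,
    }
    (d / "truth.json").write_text(json.dumps(truth, indent=1))
    if area is not None and area.total_rect is not None:
        cfg = {
            "area": {
                "total_rect": list(area.total_rect),
                "core_rect": list(area.core_rect),
            }
        }
        (d / "area.yaml").write_text(yaml.safe_dump(cfg))


def bundle_from_sim(sim: SimulatedData, area: StudyArea) -> DatasetBundle:
    """Validate a simulated dataset in memory (no file round trip)."""
    counts = _validate_counts(sim.counts)
    breeding = _validate_breeding(sim.breeding_success)
    fledglings = _validate_fledglings(sim.fledglings)
    years = _shared_years(counts, breeding, fledglings)
    encounters = _validate_encounters(sim.encounters, years)
    return DatasetBundle(
        counts=counts,
        breeding_success=breeding,
        fledglings=fledglings,
        encounters=encounters,
        area=area,
        years=years,
    )


def encounters_to_histories(
    df: pd.DataFrame, years: np.ndarray
) -> list[EncounterHistory]:
    """Convert a validated wide encounter table to EncounterHistory objects."""
    histories = []
    for r in range(len(df)):
        mark_year = int(df["mark_year"].iloc[r])
        k0 = int(mark_year - years[0])
        events = np.array([int(df[f"event_{yr}"].iloc[r]) for yr in years[k0:]])
        x = np.array([float(df[f"x_{yr}"].iloc[r]) for yr in years[k0:]])
        y = np.array([float(df[f"y_{yr}"].iloc[r]) for yr in years[k0:]])
        histories.append(
            EncounterHistory(
                id=str(df["id"].iloc[r]),
                sex=str(df["sex"].iloc[r]),
                first_year=k0,
                mark_age=_AGE_TO_INT[df["mark_age"].iloc[r]],
                mark_habitat=_HAB_TO_INT[df["mark_habitat"].iloc[r]],
                events=events,
                x=x,
                y=y,
            )
        )
    return histories


def load_config(path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def area_from_config(cfg: dict) -> StudyArea:
    """Build a StudyArea from config keys.

    Accepts ``area.total_rect`` / ``area.core_rect`` as (xmin, xmax, ymin,
    ymax) in km, or ``area.total_wkt`` / ``area.core_wkt`` polygon strings.
    """
    a = cfg.get("area", cfg)
    if "total_wkt" in a:
        return StudyArea.from_wkt(a["total_wkt"], a["core_wkt"])
    if "total_rect" in a:
        return StudyArea.from_rects(a["total_rect"], a["core_rect"])
    return StudyArea.default()
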