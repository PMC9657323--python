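"""Typed readers and writers for every tabular format the pipeline touches.

All formats are plain CSV/TSV with explicit headers:

* chamber series CSV: session_id, time_s, conc_ppm plus inline physical
  columns (animal_id, gas, volume_m3, n_heads, pressure_pa, temp_c);
* count table TSV: first column feature_id, one column per sample, paired
  with a taxonomy TSV mapping feature_id -> semicolon-delimited lineage;
* sample metadata TSV: sample_id, group, season, regime_membership, animal_id;
* nutrient TSV: group x {DM, CP, NDF, ADF, OM} in % of dry matter.

Readers never reorder rows or columns; writer/reader pairs round-trip
losslessly (numeric values to full float precision).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ruminant_ghg.community import CountTable, RANKS, UNASSIGNED
from ruminant_ghg.flux import ChamberSession, GASES

logger = logging.getLogger("ruminant_ghg")

VALID_GROUPS = ("YWG", "YCG", "YCF")
GROUP_SEASON = {"YWG": "warm", "YCG": "cold", "YCF": "cold"}
GROUP_REGIMES = {
    "YWG": frozenset({"TG", "WGCF"}),
    "YCG": frozenset({"TG"}),
    "YCF": frozenset({"WGCF"}),
}

NUTRIENT_COLUMNS = ("DM", "CP", "NDF", "ADF", "OM")

_CHAMBER_COLUMNS = [
    "session_id", "animal_id", "gas", "time_s", "conc_ppm",
    "volume_m3", "n_heads", "pressure_pa", "temp_c",
]


class FormatError(ValueError):
    """A file violates its documented format."""


@dataclass(frozen=True)
class SampleMetadata:
    """One sample's design-level annotation.

    The group encodes both the season and the regime membership: warm
    grazing (YWG) animals belong to both regimes, cold grazing (YCG) to
    traditional grazing only, cold indoor feeding (YCF) to the
    warm-grazing-cold-feeding regime only.
    """

    sample_id: str
    group: str
    season: str
    regime_membership: frozenset[str]
    animal_id: str

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise FormatError(
                f"unknown group {self.group!r}; valid groups: {list(VALID_GROUPS)}"
            )
        if self.season != GROUP_SEASON[self.group]:
            raise FormatError(
                f"sample {self.sample_id}: group {self.group} implies season "
                f"{GROUP_SEASON[self.group]}, got {self.season!r}"
            )
        if frozenset(self.regime_membership) != GROUP_REGIMES[self.group]:
            raise FormatError(
                f"sample {self.sample_id}: group {self.group} implies regimes "
                f"{sorted(GROUP_REGIMES[self.group])}, got {sorted(self.regime_membership)}"
            )


def metadata_for_group(sample_id: str, group: str, animal_id: str) -> SampleMetadata:
    """Construct metadata with the season/regime fields implied by the group."""
    if group not in VALID_GROUPS:
        raise FormatError(f"unknown group {group!r}; valid groups: {list(VALID_GROUPS)}")
    return SampleMetadata(
        sample_id=sample_id,
        group=group,
        season=GROUP_SEASON[group],
        regime_membership=GROUP_REGIMES[group],
        animal_id=animal_id,
    )


# ---------------------------------------------------------------- chamber CSV

def write_chamber_series(sessions: list[ChamberSession], path: str | Path) -> None:
    rows = []
    for s in sessions:
        for t, c in zip(s.times, s.concentrations):
            rows.append(
                {
                    "session_id": s.session_id, "animal_id": s.animal_id, "gas": s.gas,
                    "time_s": t, "conc_ppm": repr(float(c)),
                    "volume_m3": s.volume_m3, "n_heads": s.n_heads,
                    "pressure_pa": s.pressure_pa, "temp_c": s.temp_c,
                }
            )
    pd.DataFrame(rows, columns=_CHAMBER_COLUMNS).to_csv(path, index=False)


def read_chamber_series(path: str | Path) -> list[ChamberSession]:
    """Parse a chamber concentration CSV into one session per session_id.

    Rows are grouped by session_id in file order; times must be strictly
    increasing within a session and (session_id, time_s) pairs unique.
    """
    df = pd.read_csv(
        path,
        dtype={"session_id": str, "animal_id": str, "gas": str},
        float_precision="round_trip",
    )
    missing = set(_CHAMBER_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("time_s", "conc_ppm", "volume_m3", "n_heads", "pressure_pa", "temp_c"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() & df[col].notna()]
        if len(bad) > 0 or values.isna().any():
            row = int((bad if len(bad) else df.index[values.isna()])[0])
            raise FormatError(f"{path}: non-numeric {col!r} at data row {row + 1}")
        df[col] = values
    dupes = df.duplicated(subset=["session_id", "time_s"])
    if dupes.any():
        sid, t = df.loc[dupes.idxmax(), ["session_id", "time_s"]]
        raise FormatError(f"{path}: duplicate (session_id, time_s) = ({sid}, {t})")
    sessions = []
    for sid, sub in df.groupby("session_id", sort=False):
        gas = sub["gas"].iloc[0]
        if gas not in GASES:
            raise FormatError(f"{path}: session {sid}: gas must be one of {GASES}, got {gas!r}")
        times = sub["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise FormatError(f"{path}: session {sid}: time_s must be strictly increasing")
        sessions.append(
            ChamberSession(
                session_id=sid,
                animal_id=sub["animal_id"].iloc[0],
                gas=gas,
                times=times,
                concentrations=sub["conc_ppm"].to_numpy(dtype=float),
                volume_m3=float(sub["volume_m3"].iloc[0]),
                n_heads=int(sub["n_heads"].iloc[0]),
                pressure_pa=float(sub["pressure_pa"].iloc[0]),
                temp_c=float(sub["temp_c"].iloc[0]),
            )
        )
    return sessions


# ---------------------------------------------------------------- count table

def write_count_table(
    table: CountTable, counts_path: str | Path, taxonomy_path: str | Path
) -> None:
    out = table.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(counts_path, sep="\t")
    lineage = table.lineage.apply(lambda row: ";".join(row.astype(str)), axis=1)
    tax = pd.DataFrame({"feature_id": lineage.index, "lineage": lineage.values})
    tax.to_csv(taxonomy_path, sep="\t", index=False)


def read_count_table(
    path: str | Path,
    taxonomy_path: str | Path,
    kingdom: str = "bacteria",
    metadata: pd.DataFrame | None = None,
) -> CountTable:
    """Read a taxa x samples TSV plus its taxonomy sidecar.

    Features absent from the taxonomy file get an all-Unassigned lineage.
    Sample columns disagreeing with ``metadata`` trigger a warning, not an
    error (partial designs are legitimate).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric counts")
    if (arr < 0).any():
        feat = df.index[np.argwhere(arr < 0)[0][0]]
        raise FormatError(f"{path}: negative count for feature {feat!r}")
    if not np.allclose(arr, np.round(arr)):
        feat = df.index[np.argwhere(arr != np.round(arr))[0][0]]
        raise FormatError(f"{path}: fractional count for feature {feat!r}")
    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str)
    if not {"feature_id", "lineage"} <= set(tax.columns):
        raise FormatError(f"{taxonomy_path}: need columns feature_id, lineage")
    parsed = {}
    for _, row in tax.iterrows():
        parts = str(row["lineage"]).split(";")
        parts = (parts + [UNASSIGNED] * len(RANKS))[: len(RANKS)]
        parsed[row["feature_id"]] = parts
    lineage = pd.DataFrame(parsed, index=list(RANKS)).T
    if metadata is not None:
        extra = set(df.columns) - set(metadata["sample_id"])
        absent = set(metadata["sample_id"]) - set(df.columns)
        if extra or absent:
            logger.warning(
                "count table %s and metadata disagree on samples (extra=%s, absent=%s)",
                path, sorted(extra), sorted(absent),
            )
    return CountTable(df, lineage, kingdom)


# ------------------------------------------------------------------ metadata

def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"sample_id", "group", "season", "regime_membership", "animal_id"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                group=row["group"],
                season=row["season"],
                regime_membership=frozenset(str(row["regime_membership"]).split("|")),
                animal_id=row["animal_id"],
            )
        )
    return out


def metadata_frame(samples: list[SampleMetadata]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "season": s.season,
                "regime_membership": "|".join(sorted(s.regime_membership)),
                "animal_id": s.animal_id,
            }
            for s in samples
        ]
    )


# ----------------------------------------------------------------- nutrients

def write_nutrients(nutrients: pd.DataFrame, path: str | Path) -> None:
    out = nutrients.copy()
    out.index.name = "group"
    out.to_csv(path, sep="\t")


def read_nutrients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="group")
    missing = set(NUTRIENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing nutrient columns {sorted(missing)}")
    df = df[list(NUTRIENT_COLUMNS)].astype(float)
    for group in df.index:
        if group not in VALID_GROUPS:
            raise FormatError(
                f"{path}: unknown group {group!r}; valid groups: {list(VALID_GROUPS)}"
            )
    values = df.to_numpy()
    if not np.isfinite(values).all() or (values < 0).any() or (values > 100).any():
        raise FormatError(f"{path}: nutrient values must be finite and within [0, 100]")
    return df


# ------------------------------------------------------------- report tables

def write_report_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV; letter superscripts stay as plain text
    (e.g. "553.50 b") and missing cells are left empty."""
    table.to_csv(path, sep="\t", index=False, na_rep="")


def read_report_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
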