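"""Plain-text input and output files.

Input: a table of per-fish plasma VTG concentrations, either a bare
one-column list of concentrations or a delimited file with headers.

Output: the three summary files the simulator has always produced —

* ``OGDM_ResultsSummary_<fish>.csv``: per-fish batch log (recruit day,
  batch size, spawn day or UNSPAWNED, interval since previous recruitment)
  preceded by a header block with the input concentrations;
* ``OGDM_ClutchSizeSummary.txt``: tab-delimited day x fish matrix of eggs
  spawned, covering the start-up period (negative days) through the end of
  the exposure window;
* ``OGDM_SpawningSummary.txt``: per-fish totals of spawns and eggs for the
  full period and for the exposure window alone.

The original tool described these files without fixing delimiters or
column order; the dialect here (ResultsSummary as CSV, the two summaries
tab-delimited with a header row) is this package's own and may differ in
layout from the original MATLAB output.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .growth import BatchStatus
from .simulate import FishSpec, SimulationResult

__all__ = [
    "read_vtg_input",
    "specs_from_table",
    "write_results_summary",
    "read_results_summary",
    "write_clutch_size_summary",
    "write_spawning_summary",
]

MAX_FISH = 1000  # concurrent-simulation cap, kept for input-size sanity

_REQUIRED = ["fish_id", "group_id", "treatment", "c_vtg_exposure"]


class VtgInputError(ValueError):
    """Raised for malformed VTG input files."""


def _validate_concentrations(table: pd.DataFrame, path) -> None:
    for col in ("c_vtg_exposure", "c_vtg_pre"):
        if col not in table.columns:
            continue
        values = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[values.isna() & table[col].notna()]
        if len(bad):
            row = int(bad[0])
            raise VtgInputError(
                f"{path}: non-numeric {col} value {table[col].iloc[row]!r} at data row {row + 1}"
            )
        neg = table.index[values < 0]
        if len(neg):
            row = int(neg[0])
            raise VtgInputError(
                f"{path}: negative {col} value {values.iloc[row]} at data row {row + 1}"
            )
        table[col] = values


def read_vtg_input(path: str | Path) -> pd.DataFrame:
    """Read a per-fish plasma VTG table.

    Accepts either a headered delimited file (comma, tab or whitespace)
    with at least a ``c_vtg_exposure`` (or ``c_vtg``) column, or a bare
    single column of concentrations, in which case fish ids ``fish_001``...
    are generated and every fish is placed in its own group (paired design).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text().strip()
    if not text:
        raise VtgInputError(f"{path}: empty input file")
    first = text.splitlines()[0]
    has_header = any(c.isalpha() for c in first.replace("e", "").replace("E", ""))

    if has_header:
        sep = "," if "," in first else ("\t" if "\t" in first else r"\s+")
        table = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
        table.columns = [c.strip().lower() for c in table.columns]
        if "c_vtg" in table.columns and "c_vtg_exposure" not in table.columns:
            table = table.rename(columns={"c_vtg": "c_vtg_exposure"})
        if "c_vtg_exposure" not in table.columns:
            raise VtgInputError(
                f"{path}: need a 'c_vtg_exposure' (or 'c_vtg') column, got {list(table.columns)}"
            )
        if "fish_id" not in table.columns:
            table["fish_id"] = [f"fish_{i + 1:03d}" for i in range(len(table))]
        if "group_id" not in table.columns:
            table["group_id"] = table["fish_id"]
        if "treatment" not in table.columns:
            table["treatment"] = "control"
    else:
        values = []
        for i, line in enumerate(text.splitlines()):
            token = line.split(",")[0].strip()
            if not token:
                continue
            try:
                values.append(float(token))
            except ValueError:
                raise VtgInputError(
                    f"{path}: non-numeric concentration {token!r} at data row {i + 1}"
                ) from None
        table = pd.DataFrame(
            {
                "fish_id": [f"fish_{i + 1:03d}" for i in range(len(values))],
                "group_id": [f"fish_{i + 1:03d}" for i in range(len(values))],
                "treatment": "control",
                "c_vtg_exposure": values,
            }
        )

    _validate_concentrations(table, path)
    if table["fish_id"].duplicated().any():
        dupes = sorted(table.loc[table["fish_id"].duplicated(), "fish_id"].unique())
        raise VtgInputError(f"{path}: duplicate fish_id(s): {dupes}")
    if len(table) > MAX_FISH:
        raise VtgInputError(f"{path}: {len(table)} fish exceeds the {MAX_FISH}-fish limit")
    cols = _REQUIRED + (["c_vtg_pre"] if "c_vtg_pre" in table.columns else [])
    return table[cols].reset_index(drop=True)


def specs_from_table(table: pd.DataFrame) -> list[FishSpec]:
    """Convert a VTG input table into per-fish simulation specs."""
    specs = []
    for row in table.itertuples(index=False):
        pre = getattr(row, "c_vtg_pre", None)
        if pre is not None and (pre != pre):  # NaN -> use default
            pre = None
        specs.append(
            FishSpec(
                fish_id=str(row.fish_id),
                group_id=str(row.group_id),
                treatment=str(row.treatment),
                c_vtg_exposure=float(row.c_vtg_exposure),
                c_vtg_pre=None if pre is None else float(pre),
            )
        )
    return specs


# --- output files ---------------------------------------------------------


def write_results_summary(result: SimulationResult, path_stem: str | Path) -> Path:
    """Write one fish's batch log as ``<stem>OGDM_ResultsSummary_<fish>.csv``."""
    path = Path(f"{path_stem}OGDM_ResultsSummary_{result.fish_id}.csv")
    spec = result.spec
    lines = [
        f"# fish_id,{result.fish_id}",
        f"# c_vtg_pre,{'' if spec.c_vtg_pre is None else spec.c_vtg_pre}",
        f"# c_vtg_exposure,{spec.c_vtg_exposure}",
        f"# simulation_days,{result.simulation_days}",
        "recruit_day,batch_size,spawn_day,interval_days",
    ]
    previous = None
    for batch in result.batches:
        interval = "" if previous is None else f"{batch.recruit_time - previous:.6f}"
        spawn = (
            f"{batch.spawn_time:.6f}"
            if batch.status is BatchStatus.SPAWNED
            else "UNSPAWNED"
        )
        lines.append(f"{batch.recruit_time:.6f},{batch.n_oogonia},{spawn},{interval}")
        previous = batch.recruit_time
    path.write_text("\n".join(lines) + "\n")
    return path


def read_results_summary(path: str | Path) -> pd.DataFrame:
    """Parse a ResultsSummary file back into a batch table (round-trip check)."""
    rows = []
    meta: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition(",")
            meta[key] = value
            continue
        if line.startswith("recruit_day"):
            continue
        recruit, size, spawn, interval = line.split(",")
        rows.append(
            {
                "recruit_day": float(recruit),
                "batch_size": int(size),
                "spawn_day": math.nan if spawn == "UNSPAWNED" else float(spawn),
                "interval_days": math.nan if interval == "" else float(interval),
            }
        )
    frame = pd.DataFrame(rows, columns=["recruit_day", "batch_size", "spawn_day", "interval_days"])
    frame.attrs.update(meta)
    return frame


def _day_index(results: list[SimulationResult]) -> range:
    ranges = {(-r.startup_days, r.simulation_days) for r in results}
    if len(ranges) > 1:
        raise ValueError(f"results span mismatched day ranges: {sorted(ranges)}")
    start, end = next(iter(ranges))
    return range(start, end)


def write_clutch_size_summary(results: list[SimulationResult], path: str | Path) -> Path:
    """Tab-delimited day x fish matrix of eggs spawned (0 where none)."""
    if not results:
        raise ValueError("no results to write")
    days = _day_index(results)
    path = Path(path)
    eggs: dict[str, dict[int, int]] = {}
    for r in results:
        per_day: dict[int, int] = {}
        for e in r.events:
            per_day[e.study_day] = per_day.get(e.study_day, 0) + e.clutch_size
        eggs[r.fish_id] = per_day
    header = "day\t" + "\t".join(r.fish_id for r in results)
    lines = [header]
    for day in days:
        lines.append(
            f"{day}\t" + "\t".join(str(eggs[r.fish_id].get(day, 0)) for r in results)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_spawning_summary(results: list[SimulationResult], path: str | Path) -> Path:
    """Per-fish totals: spawns and eggs for the full period and the exposure window."""
    path = Path(path)
    lines = ["fish_id\tspawns_full\teggs_full\tspawns_exposure\teggs_exposure"]
    for r in results:
        lines.append(
            f"{r.fish_id}\t{r.spawns_full}\t{r.eggs_full}\t{r.spawns_exposure}\t{r.eggs_exposure}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
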