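"""Life-history data model and wide-format table I/O.

A *life history* is one mother cell followed from its first observed G1
until death: at each replicative age k = 1..K (the unbudded G1 directly
preceding the k-th budding event) we record the cross-sectional area in
μm², the elapsed time in hours since the first G1, and optionally the
background-corrected average fluorescence intensity of a tagged reporter
(arbitrary units).  The replicative lifespan (RLS) of the cell is K, the
number of budding events observed; the frame of death itself carries no
measurement.

Tables are *wide*: one row per cell (id column ``cell``), one column per
replicative age (``1``..``N``), with trailing blanks for ages beyond the
cell's death.  Interior gaps are invalid — curated life histories are
contiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellLifeHistory",
    "LifeHistoryDataset",
    "LifeHistoryError",
    "read_life_history_tables",
    "read_s1_workbook",
    "compute_rls",
    "dataset_summary",
    "write_dataset",
    "read_dataset_dir",
    "dataset_to_json",
    "dataset_from_json",
]


class LifeHistoryError(ValueError):
    """Validation failure in a life-history table or record.

    Always names the offending cell where one exists so bad rows can be
    traced back to the source table.
    """


@dataclass
class CellLifeHistory:
    """Per-age measurements of one mother cell.

    Parameters
    ----------
    cell_id
        Unique identifier within a dataset (row id of the source table).
    experiment_id
        Provenance label (microfluidic experiment / strain batch).
    sizes
        Cross-sectional area in μm² at each recorded age 1..K.
    times
        Hours since the first observed G1; ``times[0] == 0``.
    avg_fluor
        Optional background-corrected average fluorescence (AU), same
        length as ``sizes``.
    death_observed
        False for censored cells (washed out before death).  Curated
        microfluidic datasets typically contain only death-observed
        cells; the flag exists for synthetic or censored cohorts.
    """

    cell_id: str
    experiment_id: str = ""
    sizes: np.ndarray = field(default_factory=lambda: np.empty(0))
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    avg_fluor: np.ndarray | None = None
    death_observed: bool = True

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.avg_fluor is not None:
            self.avg_fluor = np.asarray(self.avg_fluor, dtype=float)
        self.validate()

    def validate(self) -> None:
        cid = self.cell_id
        if self.sizes.ndim != 1 or self.times.ndim != 1:
            raise LifeHistoryError(f"cell {cid!r}: series must be 1-D")
        k = len(self.sizes)
        if k < 1:
            raise LifeHistoryError(f"cell {cid!r}: empty life history")
        if len(self.times) != k:
            raise LifeHistoryError(
                f"cell {cid!r}: {k} size entries but {len(self.times)} time entries"
            )
        if not np.all(np.isfinite(self.sizes)) or not np.all(np.isfinite(self.times)):
            raise LifeHistoryError(f"cell {cid!r}: non-finite measurement")
        if np.any(self.sizes <= 0):
            raise LifeHistoryError(f"cell {cid!r}: non-positive cell size")
        if k > 1 and np.any(np.diff(self.times) <= 0):
            raise LifeHistoryError(f"cell {cid!r}: times not strictly increasing")
        if self.avg_fluor is not None:
            if len(self.avg_fluor) != k:
                raise LifeHistoryError(
                    f"cell {cid!r}: fluorescence length {len(self.avg_fluor)} != {k}"
                )
            if not np.all(np.isfinite(self.avg_fluor)) or np.any(self.avg_fluor < 0):
                raise LifeHistoryError(f"cell {cid!r}: invalid fluorescence value")

    @property
    def rls(self) -> int:
        """Replicative lifespan: number of recorded pre-budding G1 entries."""
        return len(self.sizes)

    @property
    def has_fluor(self) -> bool:
        return self.avg_fluor is not None


@dataclass
class LifeHistoryDataset:
    """A cohort of mother-cell life histories with unique ids."""

    cells: list[CellLifeHistory]
    name: str = "dataset"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.cells:
            raise LifeHistoryError("dataset must contain at least one cell")
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LifeHistoryError(f"duplicate cell ids: {dupes}")

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def __getitem__(self, cell_id: str) -> CellLifeHistory:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    @property
    def has_fluor(self) -> bool:
        return all(c.has_fluor for c in self.cells)

    def lifespans(self) -> np.ndarray:
        return np.array([c.rls for c in self.cells], dtype=int)

    def events(self) -> np.ndarray:
        return np.array([c.death_observed for c in self.cells], dtype=bool)


# ---------------------------------------------------------------------------
# Parsing


def _load_wide(table, sheet: str | None = None) -> pd.DataFrame:
    """Load a wide table from a DataFrame, CSV path, or XLSX path."""
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        path = Path(table)
        if path.suffix.lower() in {".xlsx", ".xlsm", ".xls"}:
            df = pd.read_excel(path, sheet_name=sheet or 0)
        else:
            df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [str(c).strip() for c in df.columns]
    id_col = df.columns[0]
    if id_col.lower() in {"cell", "cell_id", "id"}:
        df = df.rename(columns={id_col: "cell"})
    else:
        # tolerate an unnamed first column of row ids
        df = df.rename(columns={id_col: "cell"})
    df["cell"] = df["cell"].astype(str).str.strip()
    return df


def _row_series(row: pd.Series) -> np.ndarray:
    """Extract the trailing-truncated numeric series of one wide row."""
    vals = pd.to_numeric(row, errors="coerce").to_numpy(dtype=float)
    notna = np.flatnonzero(~np.isnan(vals))
    if notna.size == 0:
        return np.empty(0)
    last = notna[-1]
    return vals[: last + 1]


def read_life_history_tables(
    size_table,
    time_table,
    fluor_table=None,
    *,
    name: str = "dataset",
    source: str | None = None,
    experiment_ids: Mapping[str, str] | None = None,
    time_unit: str = "hours",
) -> LifeHistoryDataset:
    """Assemble a dataset from wide size/time (and optional fluorescence) tables.

    Each argument may be a :class:`pandas.DataFrame` or a path to a CSV/XLSX
    file with a ``cell`` id column and one column per replicative age.  Rows
    are truncated at the last non-missing entry; interior gaps, id
    mismatches between tables, length mismatches, non-increasing times and
    non-positive sizes each raise :class:`LifeHistoryError` naming the cell.

    ``time_unit`` may be ``"hours"``, ``"minutes"`` or ``"frames"`` (one
    frame = 20 minutes of imaging); values are converted to hours.  Times
    are re-zeroed to the first entry if the table does not start at 0.
    """
    scale = {"hours": 1.0, "minutes": 1 / 60.0, "frames": 1 / 3.0}
    if time_unit not in scale:
        raise LifeHistoryError(f"unknown time unit {time_unit!r}")

    sizes_df = _load_wide(size_table)
    times_df = _load_wide(time_table)
    fluor_df = _load_wide(fluor_table) if fluor_table is not None else None

    if list(sizes_df["cell"]) != list(times_df["cell"]):
        raise LifeHistoryError(
            "size and time tables have mismatched row ids: "
            f"{sorted(set(sizes_df['cell']) ^ set(times_df['cell']))[:5]}"
        )
    if fluor_df is not None and list(sizes_df["cell"]) != list(fluor_df["cell"]):
        raise LifeHistoryError("fluorescence table row ids do not match size table")

    cells: list[CellLifeHistory] = []
    for i in range(len(sizes_df)):
        cid = sizes_df["cell"].iloc[i]
        s = _row_series(sizes_df.iloc[i].drop("cell"))
        t = _row_series(times_df.iloc[i].drop("cell"))
        if s.size == 0:
            raise LifeHistoryError(f"cell {cid!r}: no size entries")
        if s.size != t.size:
            raise LifeHistoryError(
                f"cell {cid!r}: {s.size} size entries but {t.size} time entries"
            )
        # interior gaps: row_series truncates at the last non-missing value,
        # so any NaN remaining inside the kept window is an interior hole
        raw_s = pd.to_numeric(sizes_df.iloc[i].drop("cell"), errors="coerce").to_numpy()
        if np.isnan(raw_s[: s.size]).any():
            raise LifeHistoryError(f"cell {cid!r}: interior gap in size series")
        raw_t = pd.to_numeric(times_df.iloc[i].drop("cell"), errors="coerce").to_numpy()
        if np.isnan(raw_t[: t.size]).any():
            raise LifeHistoryError(f"cell {cid!r}: interior gap in time series")
        t = (t - t[0]) * scale[time_unit]
        fl = None
        if fluor_df is not None:
            fl = _row_series(fluor_df.iloc[i].drop("cell"))
            if fl.size != s.size:
                raise LifeHistoryError(
                    f"cell {cid!r}: {fl.size} fluorescence entries but {s.size} sizes"
                )
        exp = experiment_ids.get(cid, "") if experiment_ids else ""
        cells.append(
            CellLifeHistory(cell_id=cid, experiment_id=exp, sizes=s, times=t, avg_fluor=fl)
        )

    if source is None:
        source = str(size_table) if not isinstance(size_table, pd.DataFrame) else "memory"
    return LifeHistoryDataset(cells=cells, name=name, source=source)


def _match_sheet(sheet_names: Sequence[str], letter: str) -> str:
    """Find the workbook sheet for table letter 'a'..'e', tolerantly."""
    letter = letter.lower()
    for s in sheet_names:
        t = s.strip().lower()
        if t in (f"table {letter}", f"table_{letter}", f"table{letter}", letter):
            return s
    for s in sheet_names:
        if s.strip().lower().endswith(f" {letter}") or s.strip().lower() == letter:
            return s
    raise LifeHistoryError(
        f"no sheet matching table {letter!r} among {list(sheet_names)}"
    )


def read_s1_workbook(path, dataset: int = 1, name: str | None = None) -> LifeHistoryDataset:
    """Read a supplementary-style XLSX workbook of wide life-history tables.

    ``dataset=1`` uses sheets for tables a (sizes) and b (times);
    ``dataset=2`` uses tables c (sizes), d (times) and e (average
    fluorescence).  Sheet names are matched tolerantly on the letter.
    """
    xls = pd.ExcelFile(path)
    if dataset == 1:
        sizes = pd.read_excel(xls, _match_sheet(xls.sheet_names, "a"))
        times = pd.read_excel(xls, _match_sheet(xls.sheet_names, "b"))
        fluor = None
    elif dataset == 2:
        sizes = pd.read_excel(xls, _match_sheet(xls.sheet_names, "c"))
        times = pd.read_excel(xls, _match_sheet(xls.sheet_names, "d"))
        fluor = pd.read_excel(xls, _match_sheet(xls.sheet_names, "e"))
    else:
        raise LifeHistoryError("dataset must be 1 or 2")
    return read_life_history_tables(
        sizes, times, fluor, name=name or f"dataset{dataset}", source=str(path)
    )


# ---------------------------------------------------------------------------
# Summaries


def compute_rls(cell: CellLifeHistory) -> int:
    """Replicative lifespan: the number of recorded pre-budding G1 entries.

    Each entry immediately precedes one budding event, so K entries mean K
    completed divisions; the death frame is never recorded.
    """
    return cell.rls


def dataset_summary(dataset: LifeHistoryDataset) -> dict:
    """Cohort summary: cell/entry counts, lifespan quartiles, starting size."""
    rls = dataset.lifespans()
    starts = np.array([c.sizes[0] for c in dataset.cells])
    return {
        "name": dataset.name,
        "n_cells": len(dataset),
        "n_entries": int(sum(c.rls for c in dataset.cells)),
        "rls_median": float(np.median(rls)),
        "rls_min": int(rls.min()),
        "rls_max": int(rls.max()),
        "start_size_median": float(np.median(starts)),
        "has_fluor": dataset.has_fluor,
        "n_censored": int((~dataset.events()).sum()),
    }


# ---------------------------------------------------------------------------
# Writing / round-trip


def _to_wide(dataset: LifeHistoryDataset, attr: str) -> pd.DataFrame:
    kmax = max(c.rls for c in dataset.cells)
    rows = {}
    for c in dataset.cells:
        v = getattr(c, attr)
        rows[c.cell_id] = np.concatenate([v, np.full(kmax - len(v), np.nan)])
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[str(a) for a in range(1, kmax + 1)])
    df.index.name = "cell"
    return df.reset_index()


def write_dataset(dataset: LifeHistoryDataset, destination) -> dict[str, Path]:
    """Write a dataset as wide CSV tables (sizes, times[, fluor]) plus metadata.

    The layout round-trips through :func:`read_dataset_dir` bit-identically:
    floats are written in shortest round-trip representation and re-parsed
    with the exact (round-trip) CSV float parser.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths = {}
    for attr, fname in (("sizes", "sizes.csv"), ("times", "times.csv")):
        p = dest / fname
        _to_wide(dataset, attr).to_csv(p, index=False)
        paths[attr] = p
    if dataset.has_fluor:
        p = dest / "fluor.csv"
        _to_wide(dataset, "avg_fluor").to_csv(p, index=False)
        paths["fluor"] = p
    meta = {
        "name": dataset.name,
        "source": dataset.source,
        "experiment_ids": {c.cell_id: c.experiment_id for c in dataset.cells},
        "death_observed": {c.cell_id: bool(c.death_observed) for c in dataset.cells},
    }
    mp = dest / "meta.json"
    mp.write_text(json.dumps(meta, indent=1))
    paths["meta"] = mp
    return paths


def read_dataset_dir(directory) -> LifeHistoryDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    d = Path(directory)
    if not (d / "sizes.csv").exists():
        raise LifeHistoryError(f"no sizes.csv in {d}")
    meta = {}
    if (d / "meta.json").exists():
        meta = json.loads((d / "meta.json").read_text())
    ds = read_life_history_tables(
        d / "sizes.csv",
        d / "times.csv",
        d / "fluor.csv" if (d / "fluor.csv").exists() else None,
        name=meta.get("name", d.name),
        source=str(d),
        experiment_ids=meta.get("experiment_ids"),
    )
    for c in ds.cells:
        c.death_observed = bool(meta.get("death_observed", {}).get(c.cell_id, True))
    return ds


# ---------------------------------------------------------------------------
# JSON (single-file) serialization, used by the CLI


def dataset_to_json(dataset: LifeHistoryDataset) -> dict:
    return {
        "name": dataset.name,
        "source": dataset.source,
        "cells": [
            {
                "cell_id": c.cell_id,
                "experiment_id": c.experiment_id,
                "sizes": c.sizes.tolist(),
                "times": c.times.tolist(),
                "avg_fluor": None if c.avg_fluor is None else c.avg_fluor.tolist(),
                "death_observed": bool(c.death_observed),
            }
            for c in dataset.cells
        ],
    }


def dataset_from_json(obj: dict | str | Path) -> LifeHistoryDataset:
    if not isinstance(obj, dict):
        obj = json.loads(Path(obj).read_text())
    cells = [
        CellLifeHistory(
            cell_id=c["cell_id"],
            experiment_id=c.get("experiment_id", ""),
            sizes=np.array(c["sizes"], dtype=float),
            times=np.array(c["times"], dtype=float),
            avg_fluor=None if c.get("avg_fluor") is None else np.array(c["avg_fluor"], dtype=float),
            death_observed=bool(c.get("death_observed", True)),
        )
        for c in obj["cells"]
    ]
    return LifeHistoryDataset(cells=cells, name=obj.get("name", "dataset"), source=obj.get("source", ""))
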