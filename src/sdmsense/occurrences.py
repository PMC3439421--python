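"""Occurrence records and the pre-modeling treatments applied to them.

Presence-only occurrence data from public portals is typically clumped:
well-birded areas contribute thousands of records, remote areas a handful.
The treatments here are the standard countermeasures — restriction to a
breeding season and year window, spatial thinning to one record per grid
cell (turning a "biased" set into an "unbiased" one), and a random
train/test partition for evaluation.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .environment import GridSpec
from .exceptions import PartitionError, SdmError

__all__ = [
    "OccurrenceRecord",
    "OccurrenceSet",
    "filter_season",
    "thin_occurrences",
    "split_train_test",
    "read_occurrences",
    "write_occurrences",
]


@dataclass(frozen=True)
class OccurrenceRecord:
    """One presence record: where a species was seen, and optionally when."""

    species: str
    x: float
    y: float
    date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("occurrence coordinates must be finite")


@dataclass
class OccurrenceSet:
    """Point records for one species plus their treatment history.

    ``treatment_label`` is ``"raw"`` for untreated data, ``"biased"`` for a
    set used as-is despite known spatial clumping, and ``"unbiased"`` after
    spatial thinning; a thinned set stores the thinning grid so the one-
    record-per-cell invariant can be re-checked.
    """

    species: str
    records: list[OccurrenceRecord]
    provenance: str = ""
    treatment_label: str = "raw"
    thinning_grid: GridSpec | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.species != self.species:
                raise ValueError(
                    f"record species {rec.species!r} does not match set species {self.species!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def coords(self) -> np.ndarray:
        """(n, 2) array of (x, y) coordinates in record order."""
        return np.array([(r.x, r.y) for r in self.records], dtype=float).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.species for r in self.records],
                "longitude": [r.x for r in self.records],
                "latitude": [r.y for r in self.records],
                "date": [r.date.isoformat() if r.date else "" for r in self.records],
                "treatment_label": self.treatment_label,
            }
        )


def filter_season(
    occ: OccurrenceSet,
    months,
    year_min: int,
    year_max: int,
    keep_undated: bool = False,
) -> OccurrenceSet:
    """Keep records whose month is in ``months`` and year in [year_min, year_max].

    Record order is preserved.  Undated records are an error unless
    ``keep_undated`` is set, in which case they pass through untouched.
    """
    months = set(int(m) for m in months)
    kept = []
    for rec in occ.records:
        if rec.date is None:
            if not keep_undated:
                raise SdmError(
                    "record without a date encountered; pass keep_undated=True to retain"
                )
            kept.append(rec)
        elif rec.date.month in months and year_min <= rec.date.year <= year_max:
            kept.append(rec)
    return replace(occ, records=kept)


def thin_occurrences(occ: OccurrenceSet, thinning_grid: GridSpec, seed: int) -> OccurrenceSet:
    """Spatially thin to one record per occupied thinning cell.

    Within each occupied cell one record is retained uniformly at random
    (deterministic given ``seed``); records at identical coordinates are
    genuine duplicates and compete in the same lottery.  The output count
    equals the number of occupied cells and the result is labeled
    ``"unbiased"``.
    """
    if len(occ) == 0:
        raise SdmError("cannot thin an empty occurrence set")
    pts = occ.coords()
    row, col = thinning_grid.cell_of(pts[:, 0], pts[:, 1])
    cells: dict[tuple[int, int], list[int]] = {}
    for i, key in enumerate(zip(row.tolist(), col.tolist())):
        cells.setdefault(key, []).append(i)
    rng = np.random.default_rng(seed)
    chosen = sorted(
        members[rng.integers(len(members))] for members in cells.values()
    )
    return replace(
        occ,
        records=[occ.records[i] for i in chosen],
        treatment_label="unbiased",
        thinning_grid=thinning_grid,
    )


def split_train_test(
    occ: OccurrenceSet, test_fraction: float, seed: int
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Randomly partition into training and held-out test sets.

    The test size is ``round(test_fraction · N)`` with round-half-up,
    clamped so both parts keep at least one record.  The partition is
    disjoint, exhaustive, and deterministic given ``seed``.
    """
    n = len(occ)
    if n < 2:
        raise PartitionError("need at least 2 records to split")
    if not 0.0 < test_fraction < 1.0:
        raise PartitionError("test_fraction must lie strictly between 0 and 1")
    n_test = int(math.floor(test_fraction * n + 0.5))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [occ.records[i] for i in range(n) if i not in test_idx]
    test = [occ.records[i] for i in range(n) if i in test_idx]
    return replace(occ, records=train), replace(occ, records=test)


# ---------------------------------------------------------------------------
# Delimited-text I/O


def read_occurrences(path, species: str | None = None) -> OccurrenceSet:
    """Read a ``species,longitude,latitude,date`` CSV into one OccurrenceSet."""
    df = pd.read_csv(path, dtype={"species": str, "date": str}, keep_default_na=False)
    required = {"species", "longitude", "latitude"}
    if not required.issubset(df.columns):
        raise SdmError(f"occurrence file must have columns {sorted(required)}")
    if species is not None:
        df = df[df["species"] == species]
    if df.empty:
        raise SdmError("no occurrence rows to read")
    names = df["species"].unique()
    if len(names) > 1:
        raise SdmError(f"file mixes species {sorted(names)}; pass species= to select one")
    records = []
    for rowt in df.itertuples(index=False):
        raw = getattr(rowt, "date", "")
        date = _dt.date.fromisoformat(raw) if raw else None
        records.append(
            OccurrenceRecord(
                species=rowt.species,
                x=float(rowt.longitude),
                y=float(rowt.latitude),
                date=date,
            )
        )
    label = df["treatment_label"].iloc[0] if "treatment_label" in df.columns else "raw"
    return OccurrenceSet(
        species=str(names[0]), records=records, provenance=str(path), treatment_label=label
    )


def write_occurrences(occ: OccurrenceSet, path) -> None:
    """Write the set in the same dialect, with its treatment label."""
    occ.to_frame().to_csv(path, index=False)
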