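"""Fossil occurrence records, timescales and range-through presence.

The fossil record enters every downstream analysis through three containers:

* :class:`OccurrenceRecord` -- one dated fossil find whose age is only known
  to lie inside an interval ``[min_age, max_age]`` (Ma);
* :class:`SpeciesRange` -- a species' first (``ts``) and last (``te``)
  appearance ages, with ``te = 0`` encoding an extant species;
* :class:`PresenceMatrix` -- a species-by-interval boolean table on a
  :class:`TimeScale`, built with the range-through (Lazarus) rule so that a
  species' presence forms a single contiguous block of intervals.

Binning convention: intervals are half-open in Ma with the boundary age
assigned to the *older* interval.  The convention is applied uniformly by
:meth:`TimeScale.bin_index`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceRecord",
    "TimeScale",
    "SpeciesRange",
    "PresenceMatrix",
    "DEFAULT_TIMESCALE_EDGES",
    "read_occurrences",
    "randomize_ages",
    "build_species_ranges",
    "presence_matrix",
    "label_slices",
    "extinction_frequency",
]

#: Interval edges (Ma, oldest first) subdividing the past 40 My into 18
#: unequal NALMA-scale intervals; the 17 interior edges are the survivor-victim
#: slice ages.  Fully overridable -- pass any :class:`TimeScale` instead.
DEFAULT_TIMESCALE_EDGES = (
    40.0, 32.2, 30.0, 27.9, 23.8, 19.5, 18.8, 17.5, 15.9, 14.8,
    12.5, 10.75, 9.0, 6.7, 4.7, 1.7, 0.45, 0.01, 0.0,
)

#: Default occurrence CSV column names; override via the ``dialect`` mapping.
DEFAULT_DIALECT = {
    "taxon": "taxon",
    "min_age": "min_ma",
    "max_age": "max_ma",
    "locality": "locality",
    "subfamily": "subfamily",
}


class ValidationError(ValueError):
    """An input row or container violates a domain invariant."""


class ConfigurationError(ValueError):
    """A required column or configuration entry is missing."""


@dataclass(frozen=True)
class OccurrenceRecord:
    """A single fossil occurrence with an interval-censored age (Ma)."""

    taxon: str
    min_age: float
    max_age: float
    locality: str | None = None
    subfamily: str | None = None
    row: int | None = None  # source row number, for error reporting

    def __post_init__(self) -> None:
        where = f" (row {self.row})" if self.row is not None else ""
        if not self.taxon:
            raise ValidationError(f"empty taxon name{where}")
        if not (0 <= self.min_age <= self.max_age):
            raise ValidationError(
                f"invalid age interval for {self.taxon!r}{where}: "
                f"min_age={self.min_age}, max_age={self.max_age} "
                "(need 0 <= min_age <= max_age)"
            )


@dataclass(frozen=True)
class TimeScale:
    """Ordered interval edges in Ma, oldest first, strictly decreasing."""

    edges: tuple[float, ...] = DEFAULT_TIMESCALE_EDGES
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        if len(edges) < 2:
            raise ValidationError("a timescale needs at least 2 edges")
        if any(e < 0 for e in edges):
            raise ValidationError("timescale edges must be >= 0 Ma")
        if any(a >= b for a, b in zip(edges[1:], edges[:-1])):
            raise ValidationError("timescale edges must be strictly decreasing")
        if self.names is not None and len(self.names) != len(edges) - 1:
            raise ValidationError("need one name per interval (n_edges - 1)")

    @property
    def n_intervals(self) -> int:
        return len(self.edges) - 1

    @property
    def span(self) -> tuple[float, float]:
        """(oldest, youngest) edge in Ma."""
        return self.edges[0], self.edges[-1]

    def interval_bounds(self, i: int) -> tuple[float, float]:
        """(older, younger) edge of interval ``i`` (0 = oldest)."""
        return self.edges[i], self.edges[i + 1]

    def midpoints(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0

    def bin_index(self, ages) -> np.ndarray:
        """Interval index for each age; boundary ages go to the older interval.

        Raises :class:`ValidationError` for ages outside the timescale span.
        """
        a = np.atleast_1d(np.asarray(ages, dtype=float))
        e = np.asarray(self.edges)
        if np.any(a > e[0]) or np.any(a < e[-1]):
            bad = a[(a > e[0]) | (a < e[-1])][0]
            raise ValidationError(
                f"age {bad} Ma outside timescale span [{e[-1]}, {e[0]}]"
            )
        # edges descend; flip sign for searchsorted.  side='left' puts an age
        # exactly on an edge into the older interval; the oldest edge itself
        # belongs to interval 0.
        idx = np.searchsorted(-e, -a, side="left") - 1
        idx = np.clip(idx, 0, self.n_intervals - 1)
        return idx if np.ndim(ages) else idx  # always an array

    @classmethod
    def from_csv(cls, path: str | Path, edge_col: str = "edge_ma",
                 name_col: str = "name") -> "TimeScale":
        df = pd.read_csv(path)
        if edge_col not in df.columns:
            raise ConfigurationError(f"timescale file lacks column {edge_col!r}")
        names = None
        if name_col in df.columns and df[name_col].notna().any():
            names = tuple(str(n) for n in df[name_col].iloc[:-1])
        return cls(edges=tuple(df[edge_col].astype(float)), names=names)

    def to_frame(self) -> pd.DataFrame:
        names = list(self.names) + [""] if self.names else [""] * len(self.edges)
        return pd.DataFrame({"edge_ma": self.edges, "name": names})


@dataclass(frozen=True)
class SpeciesRange:
    """First/last appearance ages of one species; ``te = 0`` means extant."""

    taxon: str
    ts: float
    te: float
    occurrence_count: int = 1

    def __post_init__(self) -> None:
        if not (self.ts >= self.te >= 0):
            raise ValidationError(
                f"{self.taxon!r}: need ts >= te >= 0, got ts={self.ts}, te={self.te}"
            )
        if self.occurrence_count < 1:
            raise ValidationError(f"{self.taxon!r}: occurrence_count must be >= 1")

    @property
    def extant(self) -> bool:
        return self.te == 0.0

    @property
    def duration(self) -> float:
        return self.ts - self.te


# ---------------------------------------------------------------------------
# Occurrence I/O and age randomization
# ---------------------------------------------------------------------------

def read_occurrences(path: str | Path,
                     dialect: Mapping[str, str] | None = None,
                     ) -> list[OccurrenceRecord]:
    """Read an occurrence CSV into validated :class:`OccurrenceRecord`\\ s.

    ``dialect`` maps the logical fields (taxon, min_age, max_age, locality,
    subfamily) to the file's column names; unmapped optional columns are
    simply absent from the records.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path)
    for key in ("taxon", "min_age", "max_age"):
        if cols[key] not in df.columns:
            raise ConfigurationError(
                f"occurrence file {path} lacks required column {cols[key]!r} "
                f"(mapped from {key!r}); available: {list(df.columns)}"
            )
    records = []
    has_loc = cols.get("locality") in df.columns
    has_sub = cols.get("subfamily") in df.columns
    for i, r in enumerate(df.itertuples(index=False)):
        row = df.iloc[i]
        records.append(OccurrenceRecord(
            taxon=str(row[cols["taxon"]]),
            min_age=float(row[cols["min_age"]]),
            max_age=float(row[cols["max_age"]]),
            locality=(str(row[cols["locality"]]) if has_loc and pd.notna(row[cols["locality"]]) else None),
            subfamily=(str(row[cols["subfamily"]]) if has_sub and pd.notna(row[cols["subfamily"]]) else None),
            row=i + 2,  # 1-based with header line
        ))
    return records


def occurrences_to_frame(records: Iterable[OccurrenceRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "taxon": [r.taxon for r in records],
        "min_ma": [r.min_age for r in records],
        "max_ma": [r.max_age for r in records],
        "locality": [r.locality for r in records],
        "subfamily": [r.subfamily for r in records],
    })


def randomize_ages(records: Sequence[OccurrenceRecord],
                   n_replicates: int = 100,
                   seed: int | None = None) -> list[pd.DataFrame]:
    """Draw a point age uniformly inside each occurrence's age interval.

    Returns ``n_replicates`` age-resolved tables; the whole set is
    reproducible bit-for-bit from ``seed``.  The default of 100 replicates
    matches standard practice for propagating fossil dating uncertainty.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    base = occurrences_to_frame(records)
    lo = base["min_ma"].to_numpy()
    hi = base["max_ma"].to_numpy()
    out = []
    for _ in range(n_replicates):
        df = base.copy()
        df["age"] = lo + rng.random(len(base)) * (hi - lo)
        out.append(df)
    return out


def build_species_ranges(table: pd.DataFrame,
                         extant_taxa: Iterable[str] | None = None,
                         ) -> list[SpeciesRange]:
    """Collapse an age-resolved occurrence table to per-species ranges.

    ``ts`` is the oldest and ``te`` the youngest point age of each taxon;
    taxa in ``extant_taxa`` get ``te = 0`` regardless of their youngest
    occurrence (extant status is never inferred from a young fossil).
    """
    if len(table) == 0:
        raise ValidationError("empty occurrence table")
    if "age" not in table.columns:
        raise ConfigurationError("table lacks an 'age' column (run randomize_ages first)")
    extant = set(extant_taxa) if extant_taxa else set()
    g = table.groupby("taxon")["age"].agg(["max", "min", "count"])
    ranges = []
    for taxon, row in g.sort_index().iterrows():
        te = 0.0 if taxon in extant else float(row["min"])
        ranges.append(SpeciesRange(taxon=str(taxon), ts=float(row["max"]),
                                   te=te, occurrence_count=int(row["count"])))
    return ranges


# ---------------------------------------------------------------------------
# Presence matrix, survivor/victim labels, extinction frequency
# ---------------------------------------------------------------------------

@dataclass
class PresenceMatrix:
    """Species-by-interval boolean presence under the range-through rule."""

    taxa: list[str]
    scale: TimeScale
    matrix: np.ndarray  # (n_species, n_intervals) bool

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        self.matrix = m
        if m.shape != (len(self.taxa), self.scale.n_intervals):
            raise ValidationError("matrix shape does not match taxa x intervals")
        if not m.any(axis=1).all():
            raise ValidationError("every species must be present in >= 1 interval")
        # range-through: presence must form one contiguous block per species
        for t, row in zip(self.taxa, m):
            idx = np.flatnonzero(row)
            if idx[-1] - idx[0] + 1 != len(idx):
                raise ValidationError(f"presence of {t!r} is not contiguous")

    @property
    def n_species(self) -> int:
        return len(self.taxa)

    def first_last(self) -> tuple[np.ndarray, np.ndarray]:
        """(first, last) occupied interval index per species."""
        first = self.matrix.argmax(axis=1)
        last = self.matrix.shape[1] - 1 - self.matrix[:, ::-1].argmax(axis=1)
        return first, last

    def implied_ranges(self) -> list[SpeciesRange]:
        """Ranges placed at the midpoints of each species' first/last interval."""
        mids = self.scale.midpoints()
        first, last = self.first_last()
        return [SpeciesRange(t, ts=float(mids[f]), te=float(mids[l]))
                for t, f, l in zip(self.taxa, first, last)]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{a:g}-{b:g}" for a, b in
                zip(self.scale.edges[:-1], self.scale.edges[1:])]
        return pd.DataFrame(self.matrix, index=self.taxa, columns=cols)


def presence_matrix(ranges: Sequence[SpeciesRange], scale: TimeScale) -> PresenceMatrix:
    """Mark each species present in every interval overlapped by ``[te, ts]``.

    Because presence is filled from the interval containing ``ts`` through
    the interval containing ``te``, gaps (Lazarus intervals) are closed by
    construction.
    """
    oldest, youngest = scale.span
    n = len(ranges)
    mat = np.zeros((n, scale.n_intervals), dtype=bool)
    for k, r in enumerate(ranges):
        if r.ts < youngest or r.te > oldest or r.ts > oldest:
            raise ValidationError(
                f"range of {r.taxon!r} ([{r.te}, {r.ts}] Ma) falls outside the "
                f"timescale span [{youngest}, {oldest}]"
            )
        i0 = int(scale.bin_index(r.ts)[0])
        i1 = int(scale.bin_index(max(r.te, youngest))[0])
        mat[k, i0:i1 + 1] = True
    return PresenceMatrix(taxa=[r.taxon for r in ranges], scale=scale, matrix=mat)


def label_slices(matrix: PresenceMatrix) -> pd.DataFrame:
    """Survivor/victim labels for every slice between consecutive intervals.

    For the slice between intervals ``i`` and ``i+1`` the test set is every
    species present in ``i``; a species also present in ``i+1`` is a
    survivor, otherwise a victim.  Species first appearing in ``i+1`` are not
    part of that slice.  Returns one row per (slice, species) with columns
    ``slice_index``, ``slice_ma`` (the boundary age), ``taxon``, ``survivor``.
    """
    if matrix.scale.n_intervals < 2:
        raise ValidationError("need >= 2 intervals to form a slice")
    rows = []
    m = matrix.matrix
    for i in range(matrix.scale.n_intervals - 1):
        present = np.flatnonzero(m[:, i])
        for k in present:
            rows.append((i, matrix.scale.edges[i + 1], matrix.taxa[k],
                         bool(m[k, i + 1])))
    return pd.DataFrame(rows, columns=["slice_index", "slice_ma", "taxon", "survivor"])


def extinction_frequency(matrix: PresenceMatrix) -> pd.DataFrame:
    """Per-interval proportion of species absent from the next interval.

    The youngest interval has no subsequent interval and is reported as NaN,
    as is any interval containing zero species.
    """
    if matrix.n_species == 0:
        raise ValidationError("empty presence matrix")
    m = matrix.matrix
    n_int = matrix.scale.n_intervals
    present = m.sum(axis=0)
    victims = np.zeros(n_int)
    freq = np.full(n_int, np.nan)
    for i in range(n_int - 1):
        victims[i] = int(np.sum(m[:, i] & ~m[:, i + 1]))
        if present[i] > 0:
            freq[i] = victims[i] / present[i]
    victims[-1] = np.nan
    return pd.DataFrame({
        "older_ma": matrix.scale.edges[:-1],
        "younger_ma": matrix.scale.edges[1:],
        "n_present": present,
        "n_victims": victims,
        "extinction_frequency": freq,
    })
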