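"""Data model and I/O for collecting-event and occurrence data.

The sampling unit throughout the package is the *collecting event*: one
deployment/collection episode (e.g. a pitfall trap open for a week at one
site). The analysis unit is the *occurrence*: appearance of a species in one
event, counted once regardless of the number of individuals. Abundance counts
are carried along for I/O completeness but every downstream statistic is
occurrence-based, which suits the nest-centred ecology of ants (local
abundance reflects nest proximity more than landscape abundance).
"""

from __future__ import annotations

import re
import unicodedata
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

METHODS = frozenset(
    {"pitfall", "malaise", "bait", "bee-bowl", "hand", "litter-sift",
     "light-trap", "net", "other"}
)
HABITATS = frozenset({"open", "shrub", "forest", "unknown"})

#: Default sampling window: ISO weeks 18-44, early May through late October.
DEFAULT_WEEK_WINDOW = (18, 44)

_EVENT_KEY_COLS = ("island", "site", "year", "week", "method")


def normalize_species(name: str) -> str:
    """Whitespace-normalize and case-fold a species name (no synonymy)."""
    name = unicodedata.normalize("NFKC", name)
    return re.sub(r"\s+", " ", name.strip()).casefold()


@dataclass(frozen=True)
class SamplingEvent:
    """One collecting event and the species occurrence counts it produced.

    ``counts`` maps species name -> individuals collected; a species with a
    zero count is simply absent from the mapping.
    """

    event_id: str
    island: str
    site: str
    year: int
    week: int
    method: str
    counts: Mapping[str, int] = field(default_factory=dict)
    habitat: str = "unknown"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r} in event {self.event_id}")
        if self.habitat not in HABITATS:
            raise ValidationError(f"unknown habitat {self.habitat!r} in event {self.event_id}")
        for sp, n in self.counts.items():
            if not sp:
                raise ValidationError(f"empty species name in event {self.event_id}")
            if n <= 0:
                raise ValidationError(
                    f"count for {sp!r} in event {self.event_id} must be positive, got {n}"
                )

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.counts)

    @property
    def richness(self) -> int:
        return len(self.counts)


class EventTable:
    """Ordered collection of :class:`SamplingEvent` with a derived species pool."""

    def __init__(
        self,
        events: Iterable[SamplingEvent],
        week_window: tuple[int, int] = DEFAULT_WEEK_WINDOW,
    ) -> None:
        self.events: list[SamplingEvent] = list(events)
        self.week_window = week_window
        lo, hi = week_window
        seen: set[str] = set()
        for ev in self.events:
            if ev.event_id in seen:
                raise ValidationError(f"duplicate event_id {ev.event_id!r}")
            seen.add(ev.event_id)
            if not lo <= ev.week <= hi:
                raise ValidationError(
                    f"event {ev.event_id}: week {ev.week} outside sampling window {week_window}"
                )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def species_pool(self) -> frozenset[str]:
        pool: set[str] = set()
        for ev in self.events:
            pool |= ev.species
        return frozenset(pool)

    @property
    def islands(self) -> list[str]:
        return sorted({ev.island for ev in self.events})

    @property
    def weeks(self) -> list[int]:
        return sorted({ev.week for ev in self.events})

    def subset(self, predicate) -> "EventTable":
        return EventTable([ev for ev in self.events if predicate(ev)], self.week_window)

    def by_island(self) -> dict[str, "EventTable"]:
        return {isl: self.subset(lambda e, isl=isl: e.island == isl) for isl in self.islands}

    def by_week(self) -> dict[int, "EventTable"]:
        """Pool events by week-of-year across years."""
        return {w: self.subset(lambda e, w=w: e.week == w) for w in self.weeks}


@dataclass(frozen=True)
class IslandGeo:
    """Island geography: terrestrial area above high tide and distance to mainland."""

    island: str
    area_km2: float
    isolation_km: float

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ValidationError(f"{self.island}: area_km2 must be > 0")
        if self.isolation_km < 0:
            raise ValidationError(f"{self.island}: isolation_km must be >= 0")


class OccurrenceMatrix:
    """Species x group occurrence counts (number of events containing the species)."""

    def __init__(self, data: pd.DataFrame) -> None:
        if data.index.has_duplicates or data.columns.has_duplicates:
            raise ValidationError("duplicate species or group names in occurrence matrix")
        if (data.values < 0).any():
            raise ValidationError("occurrence counts must be non-negative")
        self.data = data.astype(int)

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> list[str]:
        return list(self.data.columns)

    @property
    def total(self) -> int:
        return int(self.data.values.sum())

    def observed_species(self) -> pd.Series:
        """Number of species with at least one occurrence per group."""
        return (self.data > 0).sum(axis=0)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path) -> "OccurrenceMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def _event_id(island: str, site: str, year: int, week: int, method: str) -> str:
    return f"{island}|{site}|{year}|W{week:02d}|{method}"


def load_events(
    path,
    dialect: str = "tsv",
    week_window: tuple[int, int] = DEFAULT_WEEK_WINDOW,
) -> EventTable:
    """Read a delimited event table (one row per (event, species)).

    Rows sharing an event key (island, site, year, week, method) are grouped
    into one :class:`SamplingEvent`; duplicate species rows within an event
    have their counts summed. The ``count`` column defaults to 1 when absent;
    an empty ``species`` field marks an event that collected nothing.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ParameterError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    df = pd.read_csv(path, sep=sep, dtype={"site": str, "species": str}, keep_default_na=False)
    required = ["island", "site", "year", "week", "method", "species"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    if "count" not in df.columns:
        df["count"] = 1
    if "habitat" not in df.columns:
        df["habitat"] = "unknown"

    events: dict[str, dict] = {}
    cols = ["island", "site", "year", "week", "method", "habitat", "species", "count"]
    for i, (island, site, year, week, method, habitat, species, count) in enumerate(
        zip(*(df[c].tolist() for c in cols))
    ):
        count = int(count)
        if count < 0:
            raise ValidationError(f"negative count {count} at data row {i + 1}")
        key = _event_id(island, site, int(year), int(week), method)
        rec = events.setdefault(
            key,
            {
                "island": island,
                "site": site,
                "year": int(year),
                "week": int(week),
                "method": method,
                "habitat": habitat,
                "counts": {},
            },
        )
        sp = normalize_species(str(species)) if str(species) else ""
        if sp and count > 0:
            rec["counts"][sp] = rec["counts"].get(sp, 0) + count
    return EventTable(
        [SamplingEvent(event_id=k, **rec) for k, rec in events.items()],
        week_window=week_window,
    )


def write_events(table: EventTable, path, dialect: str = "tsv") -> None:
    """Write an event table, one row per (event, species).

    Events that collected nothing are written as a single row with an empty
    species field and count 0, so a load/write round trip is lossless.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    rows = []
    for ev in table:
        base = {
            "island": ev.island, "site": ev.site, "year": ev.year,
            "week": ev.week, "method": ev.method, "habitat": ev.habitat,
        }
        if ev.counts:
            for sp in sorted(ev.counts):
                rows.append({**base, "species": sp, "count": ev.counts[sp]})
        else:
            rows.append({**base, "species": "", "count": 0})
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def aggregate_occurrences(events: EventTable, by: str = "island") -> OccurrenceMatrix:
    """Tabulate occurrences: cell (g, s) = number of events in group g containing s."""
    valid = {"island", "method", "habitat", "site", "week", "year"}
    if by not in valid:
        raise FormatError(f"cannot group occurrences by {by!r}")
    cells: dict[tuple, int] = {}
    groups: list = []
    species: list[str] = []
    for ev in events:
        g = getattr(ev, by)
        if g not in groups:
            groups.append(g)
        for sp in ev.species:
            if sp not in species:
                species.append(sp)
            cells[(sp, g)] = cells.get((sp, g), 0) + 1
    df = pd.DataFrame(0, index=sorted(species), columns=sorted(groups, key=str))
    for (sp, g), n in cells.items():
        df.loc[sp, g] = n
    return OccurrenceMatrix(df)


class PrintedTables(NamedTuple):
    """Verbatim transcriptions of the published inventory's printed tables."""

    occurrences: OccurrenceMatrix
    geography: tuple[IslandGeo, ...]
    sampling: pd.DataFrame  # per-island samples, observed species, abundance
    summary: pd.DataFrame   # observed/estimated S, alpha, turnover per island


def load_printed_fixtures() -> PrintedTables:
    """Load the packaged printed tables from the 2005-2009 island ant inventory."""
    root = resources.files("antbiogeo.data")
    with resources.as_file(root / "island_occurrences.tsv") as p:
        occ = OccurrenceMatrix.from_tsv(p)
    with resources.as_file(root / "island_geography.tsv") as p:
        geo_df = pd.read_csv(p, sep="\t")
    with resources.as_file(root / "diversity_summary.tsv") as p:
        summary = pd.read_csv(p, sep="\t", index_col=0)
    geos = tuple(
        IslandGeo(r.island, float(r.area_km2), float(r.isolation_km))
        for r in geo_df.itertuples(index=False)
    )
    return PrintedTables(occ, geos, geo_df.set_index("island"), summary)
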