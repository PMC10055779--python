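"""Trophic-guild assignment for fungal taxa and potential-pathogen scoring.

A small bundled lookup table (genus/family -> trophic mode, guild,
confidence) stands in for a full guild database; the TSV format lets a
larger database be dropped in unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .io_tables import CountTable, TableFormatError, TaxonomyMap

__all__ = [
    "GuildEntry",
    "GuildTable",
    "GuildAssignment",
    "CONFIDENCE_ORDER",
    "PATHOGEN_GUILDS",
    "load_guild_table",
    "bundled_guild_table",
    "assign_guilds",
    "pathogen_abundance",
    "percent_decrease",
]

CONFIDENCE_ORDER = ("Possible", "Probable", "Highly Probable")
PATHOGEN_GUILDS = frozenset({"Plant Pathogen", "Animal Pathogen"})
_RANKS = ("genus", "family")  # most specific first


@dataclass(frozen=True)
class GuildEntry:
    name: str
    rank: str  # genus or family
    trophic_mode: str
    guild: str
    confidence: str


@dataclass
class GuildTable:
    entries: list[GuildEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("guild table is empty")
        self._lookup: dict[tuple[str, str], GuildEntry] = {}
        for entry in self.entries:
            if entry.rank not in _RANKS:
                raise TableFormatError(f"bad rank {entry.rank!r} for {entry.name!r}")
            if entry.confidence not in CONFIDENCE_ORDER:
                raise TableFormatError(
                    f"bad confidence {entry.confidence!r} for {entry.name!r}"
                )
            key = (entry.rank, entry.name)
            if key in self._lookup:
                raise TableFormatError(f"duplicate guild entry {key}")
            self._lookup[key] = entry

    def get(self, rank: str, name: str) -> GuildEntry | None:
        return self._lookup.get((rank, name))


@dataclass(frozen=True)
class GuildAssignment:
    """Per-taxon guild assignment; unmatched taxa carry ``None`` entries."""

    assignments: dict[str, GuildEntry | None]

    def __getitem__(self, taxon: str) -> GuildEntry | None:
        return self.assignments[taxon]


def load_guild_table(path: str | Path) -> GuildTable:
    rows = [line.split("\t") for line in Path(path).read_text().splitlines() if line.strip()]
    header = [h.strip() for h in rows[0]]
    expected = ["name", "rank", "trophic_mode", "guild", "confidence"]
    if header != expected:
        raise TableFormatError(f"guild table header must be {expected}")
    entries = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != 5:
            raise TableFormatError(f"guild table line {r}: expected 5 fields")
        entries.append(GuildEntry(*(c.strip() for c in row)))
    return GuildTable(entries)


def bundled_guild_table() -> GuildTable:
    ref = resources.files("soilnet").joinpath("data/guilds.tsv")
    with resources.as_file(ref) as path:
        return load_guild_table(path)


def _strip_marker(name: str | None) -> str | None:
    """Reduce marker names like ``unclassified_f__Nectriaceae`` to the
    referenced clean name for lookup purposes."""
    if name is None:
        return None
    import re

    m = re.match(r"^(?:unclassified_|norank_)+[dkpcofg]__(.+)$", name)
    return m.group(1) if m else name


def assign_guilds(tax: TaxonomyMap, guilds: GuildTable,
                  taxa=None) -> GuildAssignment:
    """Match each taxon at the most specific rank available (genus wins over
    family); taxa with no match are left unassigned (None)."""
    taxa = list(tax.lineages) if taxa is None else list(taxa)
    out: dict[str, GuildEntry | None] = {}
    for taxon in taxa:
        entry = None
        for rank in _RANKS:
            name = _strip_marker(tax.rank(taxon, rank)) if taxon in tax else None
            if name is None:
                continue
            entry = guilds.get(rank, name)
            if entry is not None:
                break
        out[taxon] = entry
    return GuildAssignment(out)


def pathogen_abundance(table: CountTable, assignment: GuildAssignment,
                       guild_filter=PATHOGEN_GUILDS,
                       min_confidence: str = "Probable") -> dict[str, float]:
    """Per-sample summed relative abundance of taxa assigned to a pathogen
    guild at or above ``min_confidence``."""
    if min_confidence not in CONFIDENCE_ORDER:
        raise ValueError(f"unknown confidence level {min_confidence!r}")
    floor = CONFIDENCE_ORDER.index(min_confidence)
    rel = table.relative_abundance()
    mask = np.zeros(table.n_taxa, dtype=bool)
    for i, taxon in enumerate(table.taxa):
        entry = assignment.assignments.get(taxon)
        if entry is None:
            continue
        if "Pathotroph" not in entry.trophic_mode:
            continue
        if entry.guild not in guild_filter:
            continue
        if CONFIDENCE_ORDER.index(entry.confidence) < floor:
            continue
        mask[i] = True
    sums = rel[mask].sum(axis=0) if mask.any() else np.zeros(table.n_samples)
    return dict(zip(table.samples, (float(v) for v in sums)))


def percent_decrease(a: float, b: float) -> float:
    """100*(b-a)/b, reported to 2 decimals."""
    if b <= 0:
        raise ValueError("reference value must be positive")
    return round(100.0 * (b - a) / b, 2)
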