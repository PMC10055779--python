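"""Tabular input/output and the core domain types.

Every other module consumes :class:`CountTable`, :class:`TaxonomyMap` and
:class:`SampleDesign` defined here.  All tables are plain TSV with a mandatory
header; taxon and sample identifiers are opaque whitespace-free strings.
Networks are exported as GraphML (lossless attributes) with an optional
edge-list TSV.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CountTable",
    "TaxonomyMap",
    "SampleInfo",
    "SampleDesign",
    "TableFormatError",
    "RANKS",
    "ISMB_LEVELS",
    "FERTILIZERS",
    "HABITATS",
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_design",
    "write_design",
    "write_network_graphml",
    "read_network_graphml",
    "write_network_edgelist",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
_RANK_BY_PREFIX = {
    "d": "domain",
    "k": "domain",  # kingdom-style lineages map onto the top rank
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
}

ISMB_LEVELS = ("L", "M", "H")
FERTILIZERS = ("N", "C", "O")
HABITATS = ("SB", "SR")
NATIVE = "native"


class TableFormatError(ValueError):
    """Raised when an input table violates the format contract."""


def _check_identifiers(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for ident in ids:
        if not ident or re.search(r"\s", ident):
            raise TableFormatError(f"invalid {what} identifier: {ident!r}")
        if ident in seen:
            raise TableFormatError(f"duplicate {what} identifier: {ident!r}")
        seen.add(ident)


@dataclass
class CountTable:
    """Taxa x samples matrix of non-negative integer read counts."""

    taxa: list[str]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        self.samples = list(self.samples)
        self.counts = np.asarray(self.counts)
        _check_identifiers(self.taxa, "taxon")
        _check_identifiers(self.samples, "sample")
        if self.counts.shape != (len(self.taxa), len(self.samples)):
            raise TableFormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if len(self.taxa) < 1 or len(self.samples) < 2:
            raise TableFormatError("need at least 1 taxon and 2 samples")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise TableFormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise TableFormatError("counts must be non-negative")
        sizes = self.counts.sum(axis=0)
        if np.any(sizes <= 0):
            bad = self.samples[int(np.argmin(sizes))]
            raise TableFormatError(f"sample {bad!r} has zero library size")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample (column) relative abundances, computed on demand."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def mean_relative_abundance(self) -> np.ndarray:
        """Mean of per-sample relative abundance for each taxon."""
        return self.relative_abundance().mean(axis=1)

    def taxon_index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None

    def subset_taxa(self, taxa: Iterable[str]) -> "CountTable":
        keep = [self.taxon_index(t) for t in taxa]
        return CountTable([self.taxa[i] for i in keep], list(self.samples), self.counts[keep])

    def subset_samples(self, samples: Iterable[str]) -> "CountTable":
        idx = {s: i for i, s in enumerate(self.samples)}
        keep = [idx[s] for s in samples]
        return CountTable(list(self.taxa), [self.samples[i] for i in keep], self.counts[:, keep])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.samples == other.samples
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class TaxonomyMap:
    """Taxon identifier -> ranked lineage (domain..genus).

    Unknown ranks are stored as ``None``.  Names keep ``unclassified_`` and
    ``norank_`` prefixes verbatim.
    """

    lineages: dict[str, dict[str, str | None]]

    def __post_init__(self) -> None:
        clean: dict[str, dict[str, str | None]] = {}
        for taxon, lineage in self.lineages.items():
            entry: dict[str, str | None] = {r: None for r in RANKS}
            for rank, name in lineage.items():
                if rank not in entry:
                    raise TableFormatError(f"unknown rank {rank!r} for taxon {taxon!r}")
                entry[rank] = name
            clean[taxon] = entry
        self.lineages = clean

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)

    def rank(self, taxon: str, rank: str) -> str | None:
        return self.lineages[taxon][rank]

    def lineage_string(self, taxon: str) -> str:
        parts = []
        for rank in RANKS:
            name = self.lineages[taxon][rank]
            prefix = "d" if rank == "domain" else rank[0]
            parts.append(f"{prefix}__{name}" if name is not None else f"{prefix}__")
        return ";".join(parts)

    def check_covers(self, table: CountTable) -> None:
        missing = [t for t in table.taxa if t not in self.lineages]
        if missing:
            raise TableFormatError(f"taxa without taxonomy entries: {missing[:5]}")


_MARKER = re.compile(r"^(?:unclassified_|norank_)+")


def parse_lineage(lineage: str) -> dict[str, str | None]:
    """Parse a ``;``-separated lineage string with rank prefixes.

    ``g__Fusarium`` -> genus ``Fusarium``; a component such as
    ``unclassified_f__Nectriaceae`` (with or without an outer ``g__`` prefix)
    keeps its full marker-bearing name at the rank implied by the innermost
    prefix (family here) unless an outer prefix overrides it.
    """
    entry: dict[str, str | None] = {r: None for r in RANKS}
    for component in lineage.strip().split(";"):
        component = component.strip()
        if not component:
            continue
        m = re.match(r"^([dkpcofg])__(.*)$", component)
        if m:
            rank = _RANK_BY_PREFIX[m.group(1)]
            name = m.group(2) or None
        else:
            # marker-prefixed component, e.g. unclassified_f__Nectriaceae
            core = _MARKER.sub("", component)
            m2 = re.match(r"^([dkpcofg])__(.*)$", core)
            if not m2:
                raise TableFormatError(f"cannot parse lineage component {component!r}")
            rank = _RANK_BY_PREFIX[m2.group(1)]
            name = component  # preserved verbatim
        entry[rank] = name
    return entry


@dataclass(frozen=True)
class SampleInfo:
    """Treatment factors and covariates for a single sample."""

    sample: str
    ismb: str
    fertilizer: str
    habitat: str
    replicate: int
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.is_native:
            if not (self.ismb == self.fertilizer == self.habitat == NATIVE):
                raise TableFormatError(
                    f"sample {self.sample!r}: native samples must be native in all factors"
                )
        else:
            if self.ismb not in ISMB_LEVELS:
                raise TableFormatError(f"sample {self.sample!r}: bad ismb {self.ismb!r}")
            if self.fertilizer not in FERTILIZERS:
                raise TableFormatError(
                    f"sample {self.sample!r}: bad fertilizer {self.fertilizer!r}"
                )
            if self.habitat not in HABITATS:
                raise TableFormatError(f"sample {self.sample!r}: bad habitat {self.habitat!r}")
        for name, value in self.covariates.items():
            if not math.isfinite(value):
                raise TableFormatError(
                    f"sample {self.sample!r}: covariate {name!r} is not finite"
                )

    @property
    def is_native(self) -> bool:
        return NATIVE in (self.ismb, self.fertilizer, self.habitat)

    @property
    def treatment(self) -> str:
        """Treatment code, e.g. ``OH_SR``; native samples -> ``native``."""
        if self.is_native:
            return NATIVE
        return f"{self.fertilizer}{self.ismb}_{self.habitat}"


@dataclass
class SampleDesign:
    """Per-sample treatment factors plus physicochemical/yield covariates."""

    infos: list[SampleInfo]

    def __post_init__(self) -> None:
        _check_identifiers([s.sample for s in self.infos], "sample")
        self._by_sample = {s.sample: s for s in self.infos}

    @property
    def samples(self) -> list[str]:
        return [s.sample for s in self.infos]

    def __getitem__(self, sample: str) -> SampleInfo:
        return self._by_sample[sample]

    def __len__(self) -> int:
        return len(self.infos)

    def factor(self, name: str, samples: Sequence[str] | None = None) -> list[str]:
        samples = self.samples if samples is None else list(samples)
        if name == "treatment":
            return [self._by_sample[s].treatment for s in samples]
        return [getattr(self._by_sample[s], name) for s in samples]

    def covariate(self, name: str, samples: Sequence[str] | None = None) -> np.ndarray:
        samples = self.samples if samples is None else list(samples)
        return np.array([self._by_sample[s].covariates[name] for s in samples], dtype=float)

    def covariate_names(self) -> list[str]:
        names: list[str] = []
        for info in self.infos:
            for name in info.covariates:
                if name not in names:
                    names.append(name)
        return names

    def non_native_samples(self) -> list[str]:
        return [s.sample for s in self.infos if not s.is_native]


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _read_rows(path: str | Path) -> list[list[str]]:
    text = Path(path).read_text()
    rows = [line.split("\t") for line in text.splitlines() if line.strip()]
    if not rows:
        raise TableFormatError(f"{path}: empty file")
    return rows


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table: header of sample ids, first column taxon ids."""
    rows = _read_rows(path)
    header = rows[0]
    if len(header) < 3:
        raise TableFormatError(f"{path}: need at least 2 sample columns")
    samples = [h.strip() for h in header[1:]]
    taxa: list[str] = []
    counts: list[list[int]] = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise TableFormatError(f"{path}:{r}: expected {len(header)} fields, got {len(row)}")
        taxa.append(row[0].strip())
        parsed: list[int] = []
        for c, cell in enumerate(row[1:], start=2):
            try:
                value = int(cell)
            except ValueError:
                raise TableFormatError(
                    f"{path}:{r}: non-integer count {cell!r} in column {c} "
                    f"(sample {samples[c - 2]!r})"
                ) from None
            if value < 0:
                raise TableFormatError(
                    f"{path}:{r}: negative count in column {c} (sample {samples[c - 2]!r})"
                )
            parsed.append(value)
        counts.append(parsed)
    return CountTable(taxa, samples, np.array(counts, dtype=np.int64))


def write_count_table(table: CountTable, path: str | Path) -> None:
    lines = ["taxon\t" + "\t".join(table.samples)]
    for i, taxon in enumerate(table.taxa):
        lines.append(taxon + "\t" + "\t".join(str(int(v)) for v in table.counts[i]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV of taxon identifier and lineage string."""
    rows = _read_rows(path)
    start = 1 if rows[0][0].lower() in {"taxon", "#taxon", "otu"} else 0
    lineages: dict[str, dict[str, str | None]] = {}
    for r, row in enumerate(rows[start:], start=start + 1):
        if len(row) < 2 or not row[1].strip():
            raise TableFormatError(f"{path}:{r}: missing lineage column")
        taxon = row[0].strip()
        if taxon in lineages:
            raise TableFormatError(f"{path}:{r}: duplicate taxon {taxon!r}")
        lineages[taxon] = parse_lineage(row[1])
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    lines = ["taxon\tlineage"]
    for taxon in tax.lineages:
        lines.append(f"{taxon}\t{tax.lineage_string(taxon)}")
    Path(path).write_text("\n".join(lines) + "\n")


_DESIGN_COLS = ("sample", "ismb", "fertilizer", "habitat", "replicate")


def read_design(path: str | Path) -> SampleDesign:
    rows = _read_rows(path)
    header = [h.strip() for h in rows[0]]
    if tuple(header[:5]) != _DESIGN_COLS:
        raise TableFormatError(
            f"{path}: design header must start with {'/'.join(_DESIGN_COLS)}"
        )
    cov_names = header[5:]
    infos: list[SampleInfo] = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise TableFormatError(f"{path}:{r}: expected {len(header)} fields")
        covs: dict[str, float] = {}
        for name, cell in zip(cov_names, row[5:]):
            cell = cell.strip()
            if cell:
                try:
                    covs[name] = float(cell)
                except ValueError:
                    raise TableFormatError(
                        f"{path}:{r}: non-numeric covariate {name}={cell!r}"
                    ) from None
        try:
            rep = int(row[4])
        except ValueError:
            raise TableFormatError(f"{path}:{r}: non-integer replicate {row[4]!r}") from None
        infos.append(
            SampleInfo(row[0].strip(), row[1].strip(), row[2].strip(), row[3].strip(), rep, covs)
        )
    return SampleDesign(infos)


def write_design(design: SampleDesign, path: str | Path) -> None:
    cov_names = design.covariate_names()
    lines = ["\t".join(_DESIGN_COLS + tuple(cov_names))]
    for info in design.infos:
        cells = [info.sample, info.ismb, info.fertilizer, info.habitat, str(info.replicate)]
        for name in cov_names:
            value = info.covariates.get(name)
            cells.append("" if value is None else repr(float(value)))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def write_network_graphml(network, path: str | Path) -> None:
    """Export a co-occurrence network to GraphML (losslessly re-importable)."""
    import networkx as nx

    graph = network.to_networkx()
    nx.write_graphml(graph, str(path))


def read_network_graphml(path: str | Path):
    import networkx as nx

    from .conet import CoNetwork, Edge

    graph = nx.read_graphml(str(path))
    nodes = {str(n): float(d.get("abundance", 0.0)) for n, d in graph.nodes(data=True)}
    hubs = frozenset(str(n) for n, d in graph.nodes(data=True) if d.get("hub"))
    edges = [
        Edge(str(u), str(v), int(d["sign"]), float(d["brown_p"]), float(d["spearman"]))
        for u, v, d in graph.edges(data=True)
    ]
    return CoNetwork(nodes, edges, hubs=hubs)


def write_network_edgelist(network, path: str | Path) -> None:
    lines = ["source\ttarget\tsign\tbrown_p\tspearman"]
    for edge in network.edges:
        lines.append(
            f"{edge.a}\t{edge.b}\t{edge.sign:+d}\t{edge.brown_p!r}\t{edge.spearman!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
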