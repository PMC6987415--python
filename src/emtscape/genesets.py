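"""Named gene sets and the signature collections that drive enrichment scoring.

Epithelial (E) and mesenchymal (M) program signatures, TGF-beta EMT response
signatures (TES_UP / TES_DOWN) and phenotypic gene sets are all represented as
plain named sets of gene symbols.  Two on-disk dialects are supported: GMT
(tab-separated ``name<TAB>description<TAB>gene...``) and one-column-per-set
delimited text whose header row carries the set names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "OverlapReport",
    "read_gene_sets",
    "write_gmt",
    "overlap_report",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (symbols).

    Identifiers are matched case-sensitively by default; callers wanting
    case-insensitive matching should use :meth:`upper` explicitly, because
    silent case folding can create false overlaps between signatures.
    """

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        genes = frozenset(self.genes)
        if len(genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if any((not isinstance(g, str)) or g == "" for g in genes):
            raise ValueError(f"gene set {self.name!r} contains empty identifiers")
        object.__setattr__(self, "genes", genes)

    @property
    def size(self) -> int:
        return len(self.genes)

    def upper(self) -> "GeneSet":
        """Return a copy with uppercase-normalized identifiers."""
        return GeneSet(self.name, frozenset(g.upper() for g in self.genes), self.description)

    def __len__(self) -> int:
        return self.size

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class GeneSetCollection:
    """Ordered mapping of unique set names to :class:`GeneSet` records."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    @classmethod
    def from_sets(cls, sets: Iterable[GeneSet]) -> "GeneSetCollection":
        coll = cls()
        for gs in sets:
            coll.add(gs)
        return coll

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValueError(f"duplicate gene set name {gs.name!r}")
        self.sets[gs.name] = gs

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: gs.size for name, gs in self.sets.items()}

    def upper(self) -> "GeneSetCollection":
        return GeneSetCollection.from_sets(gs.upper() for gs in self)


@dataclass(frozen=True)
class OverlapReport:
    """Intersection counts between two gene sets.

    ``fraction`` is asymmetric: the share of ``a`` contained in ``b``.
    """

    name_a: str
    name_b: str
    count: int
    size_a: int
    size_b: int

    @property
    def fraction(self) -> float:
        return self.count / self.size_a


def overlap_report(a: GeneSet, b: GeneSet) -> OverlapReport:
    """Count shared identifiers between ``a`` and ``b``.

    Used e.g. to check that phenotypic scoring sets are not redundant with the
    E/M signatures (the redundancy screen demands < 20% overlap).
    """
    return OverlapReport(a.name, b.name, len(a.genes & b.genes), a.size, b.size)


def _read_gmt(path: Path, sep: str = "\t") -> Iterator[GeneSet]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: GMT record needs name, description and >= 1 gene"
                )
            name, desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            yield GeneSet(name, frozenset(genes), desc)


def _read_columns(path: Path, sep: str | None = None) -> Iterator[GeneSet]:
    import csv

    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        if sep is None:
            sep = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.reader(fh, delimiter=sep)
        rows = [row for row in reader if any(cell.strip() for cell in row)]
    if not rows:
        raise ValueError(f"{path}: no content")
    header = [h.strip() for h in rows[0]]
    columns: dict[str, list[str]] = {}
    for j, name in enumerate(header):
        if not name:
            raise ValueError(f"{path}: column {j} has an empty header (set name)")
        genes = [row[j].strip() for row in rows[1:] if j < len(row) and row[j].strip()]
        if not genes:
            raise ValueError(f"{path}: gene set {name!r} is empty")
        columns[name] = genes
    for name, genes in columns.items():
        yield GeneSet(name, frozenset(genes))


def read_gene_sets(path: str | Path, format: str = "gmt") -> GeneSetCollection:
    """Read a gene-set collection from ``path``.

    Parameters
    ----------
    path
        File to read.
    format
        ``"gmt"`` for tab-separated GMT records, ``"columns"`` for
        one-column-per-set delimited text with set names in the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gmt":
        sets = _read_gmt(path)
    elif format in ("columns", "one-column-per-set"):
        sets = _read_columns(path)
    else:
        raise ValueError(f"unknown gene-set format {format!r}")
    coll = GeneSetCollection.from_sets(sets)
    logger.info("read %d gene sets from %s: %s", len(coll), path, coll.sizes())
    return coll


def write_gmt(collection: GeneSetCollection | Mapping[str, GeneSet], path: str | Path) -> None:
    """Write a collection as GMT (genes in sorted order for reproducibility)."""
    sets = collection if isinstance(collection, GeneSetCollection) else collection.values()
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")
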