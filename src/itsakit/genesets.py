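"""Gene-set collections (GMT) and plain-text gene lists.

Symbols are upper-cased on ingest throughout the package: the disease
databases (GeneCards, DrugBank, OMIM, PharmGKB) and GO/KEGG exports mix
case conventions, and set operations on targets are symbol-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


class GMTFormatError(ValueError):
    pass


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, name: str, description: str, members: Iterable[str]) -> None:
        self.sets[name] = GeneSet(name, description, frozenset(normalize_symbol(m) for m in members))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """One gene set per tab-separated line: name, description, members...

    Duplicate members collapse; symbols are upper-cased.
    """
    path = Path(path)
    coll = GeneSetCollection()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GMTFormatError(f"{path.name}:{lineno}: expected >= 2 tab-separated columns")
            coll.add(parts[0], parts[1], parts[2:])
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Newline-delimited symbols; blank lines ignored, case-normalized."""
    with Path(path).open(encoding="utf-8") as fh:
        return frozenset(normalize_symbol(l) for l in fh if l.strip())


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for g in sorted(normalize_symbol(x) for x in genes):
            fh.write(g + "\n")
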