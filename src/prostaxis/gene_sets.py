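"""Named gene-set collections with GMT-format input/output."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt"]


@dataclass
class GeneSetCollection:
    """Mapping of unique set names to member gene identifiers.

    ``provenance`` is a free-text tag (e.g. "hallmark" or "curated").
    """

    sets: dict[str, list[str]]
    provenance: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def filter_to_universe(
        self, universe: Iterable[str], min_size: int = 5, max_size: int | None = None
    ) -> "GeneSetCollection":
        """Intersect every set with a gene universe.

        Sets falling below ``min_size`` members after the intersection are an
        error (they would produce unstable enrichment walks); sets above
        ``max_size`` are dropped silently.
        """
        uni = set(universe)
        out: dict[str, list[str]] = {}
        too_small: list[str] = []
        for name, genes in self.sets.items():
            kept = [g for g in genes if g in uni]
            if len(kept) < min_size:
                too_small.append(name)
            elif max_size is None or len(kept) <= max_size:
                out[name] = kept
        if too_small:
            raise ValueError(
                f"gene sets below min_size={min_size} after intersection "
                f"with the expression universe: {too_small}"
            )
        return GeneSetCollection(out, self.provenance, dict(self.descriptions))


def read_gmt(path: str | Path, provenance: str = "") -> GeneSetCollection:
    """Read a GMT file (set name, description, then tab-separated genes)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        sets[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(sets, provenance, descriptions)


def write_gmt(gs: GeneSetCollection | Mapping[str, list[str]], path: str | Path) -> None:
    """Write a collection to GMT format."""
    if not isinstance(gs, GeneSetCollection):
        gs = GeneSetCollection(dict(gs))
    lines = []
    for name, genes in gs.sets.items():
        desc = gs.descriptions.get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")
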