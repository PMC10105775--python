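"""Cross-link identification tables as canonical residue-pair restraint sets.

A cross-link is an unordered pair of residue positions on (possibly
identical) protein accessions.  Tables exported by XlinkX- or
xiView-style search pipelines are read with a configurable column map,
canonicalised (pair order normalised, duplicates collapsed, self-links
dropped) and merged across datasets by set union.  Identification scores
are carried through but never used for filtering: FDR control happened
upstream in the search engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import CrossLinkFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "CrossLink",
    "CrossLinkSet",
    "ColumnMap",
    "COLUMN_PRESETS",
    "read_crosslinks",
    "write_crosslinks",
    "filter_intramolecular",
    "merge_datasets",
    "top_n_proteins",
]


@dataclass(frozen=True)
class CrossLink:
    """An unordered residue pair; always stored in canonical order.

    Canonical order: ``(protein_a, residue_a) <= (protein_b, residue_b)``
    lexicographically, so the same physical link always hashes equal.
    """

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    score: float | None = None
    source: str = ""

    @classmethod
    def create(
        cls,
        protein_a: str,
        residue_a: int,
        protein_b: str,
        residue_b: int,
        score: float | None = None,
        source: str = "",
    ) -> "CrossLink":
        """Build a link in canonical pair order.

        Raises ValueError for a self-link (same protein, same residue);
        callers reading tables drop those rows instead.
        """
        a = (protein_a, int(residue_a))
        b = (protein_b, int(residue_b))
        if a == b:
            raise ValueError(f"self-link {a} is not a distance restraint")
        if a > b:
            a, b = b, a
        return cls(a[0], a[1], b[0], b[1], score=score, source=source)

    @property
    def key(self) -> tuple[str, int, str, int]:
        return (self.protein_a, self.residue_a, self.protein_b, self.residue_b)

    @property
    def is_intramolecular(self) -> bool:
        return self.protein_a == self.protein_b


class CrossLinkSet:
    """A deduplicated collection of canonical cross-links."""

    def __init__(self, links: Iterable[CrossLink] = ()) -> None:
        self._links: dict[tuple, CrossLink] = {}
        for link in links:
            self.add(link)

    def add(self, link: CrossLink) -> None:
        """Insert a link; on a duplicate pair keep the maximum score and
        accumulate source tags."""
        old = self._links.get(link.key)
        if old is None:
            self._links[link.key] = link
            return
        sources = [s for s in old.source.split(";") if s]
        if link.source and link.source not in sources:
            sources.append(link.source)
        scores = [s for s in (old.score, link.score) if s is not None]
        self._links[link.key] = replace(
            old,
            score=max(scores) if scores else None,
            source=";".join(sources),
        )

    def __len__(self) -> int:
        return len(self._links)

    def __iter__(self) -> Iterator[CrossLink]:
        return iter(self._links.values())

    def __contains__(self, link: CrossLink) -> bool:
        return link.key in self._links

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CrossLinkSet):
            return NotImplemented
        return set(self._links) == set(other._links)

    @property
    def links(self) -> list[CrossLink]:
        return list(self._links.values())

    def protein_counts(self, intramolecular_only: bool = True) -> dict[str, int]:
        """Accession -> number of links; intramolecular counts by default."""
        counts: dict[str, int] = {}
        for link in self:
            if intramolecular_only:
                if link.is_intramolecular:
                    counts[link.protein_a] = counts.get(link.protein_a, 0) + 1
            else:
                for acc in {link.protein_a, link.protein_b}:
                    counts[acc] = counts.get(acc, 0) + 1
        return counts

    def for_protein(self, accession: str) -> "CrossLinkSet":
        """The intramolecular links of one accession."""
        return CrossLinkSet(
            l for l in self if l.is_intramolecular and l.protein_a == accession
        )


@dataclass(frozen=True)
class ColumnMap:
    """Names of the mandatory (and optional score) columns in an export."""

    protein_a: str = "protein_a"
    residue_a: str = "residue_a"
    protein_b: str = "protein_b"
    residue_b: str = "residue_b"
    score: str | None = "score"


COLUMN_PRESETS: dict[str, ColumnMap] = {
    "generic": ColumnMap(),
    "xlinkx": ColumnMap(
        protein_a="Protein Accession A",
        residue_a="Leading Protein Position A",
        protein_b="Protein Accession B",
        residue_b="Leading Protein Position B",
        score="Max. XlinkX Score",
    ),
    "xiview": ColumnMap(
        protein_a="Protein1",
        residue_a="LinkPos1",
        protein_b="Protein2",
        residue_b="LinkPos2",
        score="Score",
    ),
}


def read_crosslinks(
    path: str | Path,
    columns: ColumnMap | str = "generic",
    sep: str | None = None,
    source: str | None = None,
) -> CrossLinkSet:
    """Read a delimited cross-link table into a canonical set.

    Rows are canonicalised; duplicate pairs (including swapped order)
    collapse to one link; self-links are dropped and counted in the log.
    ``sep=None`` sniffs the delimiter (covers CSV and TSV exports).
    """
    path = Path(path)
    if isinstance(columns, str):
        try:
            columns = COLUMN_PRESETS[columns]
        except KeyError:
            raise CrossLinkFormatError(
                f"unknown column preset {columns!r}; "
                f"available: {sorted(COLUMN_PRESETS)}"
            ) from None
    try:
        df = pd.read_csv(path, sep=sep, engine="python")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise CrossLinkFormatError(f"cannot read {path}: {exc}") from exc

    mandatory = [columns.protein_a, columns.residue_a, columns.protein_b, columns.residue_b]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise CrossLinkFormatError(
            f"{path}: missing mandatory columns {missing}; found {list(df.columns)}"
        )
    has_score = columns.score is not None and columns.score in df.columns
    tag = source if source is not None else path.stem

    links = CrossLinkSet()
    n_self = 0
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        rowd = dict(zip(df.columns, row))
        try:
            ra = int(rowd[columns.residue_a])
            rb = int(rowd[columns.residue_b])
        except (TypeError, ValueError):
            raise CrossLinkFormatError(
                f"{path} line {pos}: non-integer residue position"
            ) from None
        if ra < 1 or rb < 1:
            raise CrossLinkFormatError(f"{path} line {pos}: residue positions must be >= 1")
        score = float(rowd[columns.score]) if has_score and pd.notna(rowd[columns.score]) else None
        try:
            link = CrossLink.create(
                str(rowd[columns.protein_a]), ra, str(rowd[columns.protein_b]), rb,
                score=score, source=tag,
            )
        except ValueError:
            n_self += 1
            continue
        links.add(link)
    if n_self:
        logger.info("%s: dropped %d self-links", path, n_self)
    return links


def write_crosslinks(links: CrossLinkSet, path: str | Path) -> None:
    """Write the canonical TSV (protein_a, residue_a, protein_b, residue_b, score, source)."""
    rows = [
        {
            "protein_a": l.protein_a,
            "residue_a": l.residue_a,
            "protein_b": l.protein_b,
            "residue_b": l.residue_b,
            "score": l.score,
            "source": l.source,
        }
        for l in sorted(links, key=lambda l: l.key)
    ]
    pd.DataFrame(
        rows, columns=["protein_a", "residue_a", "protein_b", "residue_b", "score", "source"]
    ).to_csv(path, sep="\t", index=False)


def filter_intramolecular(links: CrossLinkSet) -> CrossLinkSet:
    """Keep only links whose two residues lie on the same accession."""
    return CrossLinkSet(l for l in links if l.is_intramolecular)


def merge_datasets(a: CrossLinkSet, b: CrossLinkSet) -> CrossLinkSet:
    """Set union on canonical pairs; idempotent, commutative, associative."""
    merged = CrossLinkSet(a)
    for link in b:
        merged.add(link)
    return merged


def top_n_proteins(links: CrossLinkSet, n: int) -> list[str]:
    """Accessions ranked by decreasing intramolecular link count.

    Ties are broken by accession text ascending, so the ranking is
    deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = links.protein_counts(intramolecular_only=True)
    ranked = sorted(counts, key=lambda acc: (-counts[acc], acc))
    return ranked[:n]
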