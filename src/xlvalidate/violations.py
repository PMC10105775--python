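"""Cross-link violation analysis on C-alpha structures.

A DSSO (or DSS/BS3-class) cross-link implies the two linked lysine
C-alpha atoms lie within roughly 30 A.  Each intramolecular link is
therefore measured as a Euclidean C-alpha distance on the structure and
classified as satisfied (distance <= threshold, boundary inclusive),
violated, or unmapped when either residue is absent from the model.
Unmapped links are reported but excluded from agreement denominators.

For homo-oligomeric assemblies, an apparently intramolecular link can be
satisfied between two copies of the protein even when the monomer
distance is large; ``assembly_min_distance`` takes the minimum over all
chain-copy pairings to account for this rescue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .crosslinks import CrossLink, CrossLinkSet
from .errors import UndefinedValueError
from .structure_io import Structure, mean_plddt

__all__ = [
    "Assessment",
    "ProteinSummary",
    "ca_distance",
    "assess",
    "agreement_fraction",
    "assembly_min_distance",
    "apply_assembly_rescue",
    "summarize_protein",
    "write_assessments",
    "write_protein_summaries",
    "write_pseudobonds",
]

SATISFIED = "satisfied"
VIOLATED = "violated"
UNMAPPED = "unmapped"

DEFAULT_THRESHOLD = 30.0  # A; recommended maximum for DSS/BS3-class linkers


@dataclass(frozen=True)
class Assessment:
    """One cross-link measured against one structure."""

    link: CrossLink
    distance: float | None
    status: str
    threshold: float
    min_assembly_distance: float | None = None
    pae_value: float | None = None
    location_class: str | None = None

    @property
    def mapped(self) -> bool:
        return self.distance is not None

    @property
    def rescued(self) -> bool:
        """Violated on the monomer but satisfied between assembly copies."""
        return (
            self.status == VIOLATED
            and self.min_assembly_distance is not None
            and self.min_assembly_distance <= self.threshold
        )


@dataclass(frozen=True)
class ProteinSummary:
    """Per-protein violation bookkeeping for one structure."""

    accession: str
    n_links: int
    n_mapped: int
    n_violations: int
    agreement: float | None
    mean_plddt: float | None
    distances: tuple[float, ...]


def ca_distance(
    structure: Structure, chain_id: str, i: int, j: int
) -> float | None:
    """Euclidean C-alpha distance between residues i and j of a chain.

    Returns None (the unmapped signal) when either residue has no
    C-alpha record; that is not an error.
    """
    ri = structure.residue(chain_id, i)
    rj = structure.residue(chain_id, j)
    if ri is None or rj is None:
        return None
    return math.dist(ri.ca_xyz, rj.ca_xyz)


def _status(distance: float | None, threshold: float) -> str:
    if distance is None:
        return UNMAPPED
    return SATISFIED if distance <= threshold else VIOLATED


def assess(
    structure: Structure,
    links: CrossLinkSet | Iterable[CrossLink],
    threshold: float = DEFAULT_THRESHOLD,
    chain_id: str | None = None,
    pae=None,
    segmentation=None,
) -> list[Assessment]:
    """Measure and classify every link on the structure.

    The links are expected to be intramolecular for this structure's
    protein; distances are measured on one chain (the first by default).
    Optionally annotates each assessment with its symmetrized PAE value
    and its within/between/outside domain class.
    """
    from .calibration import link_pae  # local import to avoid a cycle
    from .pae_domains import classify_link_location, symmetrize

    if chain_id is None:
        chain_id = structure.chain_ids[0]
    if pae is not None and not pae.symmetric:
        pae = symmetrize(pae)

    out: list[Assessment] = []
    for link in links:
        d = ca_distance(structure, chain_id, link.residue_a, link.residue_b)
        pae_value = None
        if pae is not None and link.residue_a <= pae.n and link.residue_b <= pae.n:
            pae_value = link_pae(pae, link)
        location = None
        if segmentation is not None and link.residue_b <= len(segmentation.labels):
            location = classify_link_location(segmentation, link)
        out.append(
            Assessment(
                link=link,
                distance=d,
                status=_status(d, threshold),
                threshold=threshold,
                pae_value=pae_value,
                location_class=location,
            )
        )
    return out


def agreement_fraction(assessments: Sequence[Assessment]) -> float:
    """Fraction of mapped links that are satisfied.

    Unmapped links never enter the denominator.  Raises when no link is
    mapped (the fraction is undefined).
    """
    mapped = [a for a in assessments if a.mapped]
    if not mapped:
        raise UndefinedValueError("agreement is undefined with zero mapped links")
    n_sat = sum(a.status == SATISFIED for a in mapped)
    return n_sat / len(mapped)


def assembly_min_distance(
    assembly: Structure,
    link: CrossLink,
    chain_map: Mapping[str, Sequence[str]] | None = None,
) -> float | None:
    """Minimum C-alpha distance over all chain-copy pairings of a link.

    For an intramolecular link on a protein with several copies in the
    assembly, enumerates every ordered pairing (residue_a in copy p,
    residue_b in copy q), including p == q, and returns the minimum.  By
    construction this is <= the intra-copy distance.  ``chain_map`` maps
    accession -> chain ids; by default every chain is a candidate copy.
    """
    if chain_map is None:
        chains_a = chains_b = list(assembly.chain_ids)
    else:
        chains_a = list(chain_map.get(link.protein_a, []))
        chains_b = list(chain_map.get(link.protein_b, []))
        if not chains_a or not chains_b:
            raise KeyError(f"no chains mapped for {link.protein_a}/{link.protein_b}")
    best: float | None = None
    for ca in chains_a:
        ra = assembly.residue(ca, link.residue_a)
        if ra is None:
            continue
        for cb in chains_b:
            rb = assembly.residue(cb, link.residue_b)
            if rb is None:
                continue
            d = math.dist(ra.ca_xyz, rb.ca_xyz)
            if best is None or d < best:
                best = d
    return best


def apply_assembly_rescue(
    assessments: Sequence[Assessment],
    assembly: Structure,
    chain_map: Mapping[str, Sequence[str]] | None = None,
) -> list[Assessment]:
    """Annotate assessments with the minimum assembly distance.

    The monomer status is kept; ``Assessment.rescued`` flags violations
    that an assembly pairing accommodates within the threshold.
    """
    out = []
    for a in assessments:
        d = assembly_min_distance(assembly, a.link, chain_map)
        out.append(replace(a, min_assembly_distance=d))
    return out


def summarize_protein(
    structure: Structure,
    assessments: Sequence[Assessment],
    accession: str | None = None,
) -> ProteinSummary:
    """Counts, agreement, mean pLDDT and the mapped distance list."""
    mapped = [a for a in assessments if a.mapped]
    n_viol = sum(a.status == VIOLATED for a in mapped)
    try:
        plddt = mean_plddt(structure)
    except Exception:
        plddt = None
    return ProteinSummary(
        accession=accession if accession is not None else structure.name,
        n_links=len(assessments),
        n_mapped=len(mapped),
        n_violations=n_viol,
        agreement=(len(mapped) - n_viol) / len(mapped) if mapped else None,
        mean_plddt=plddt,
        distances=tuple(a.distance for a in mapped),
    )


def write_assessments(
    assessments: Sequence[Assessment], path: str | Path
) -> None:
    """Per-link TSV: identity, distance, status, assembly minimum, PAE, class."""
    rows = []
    for a in assessments:
        l = a.link
        rows.append(
            {
                "protein": l.protein_a,
                "residue_a": l.residue_a,
                "residue_b": l.residue_b,
                "distance": None if a.distance is None else round(a.distance, 3),
                "status": a.status,
                "threshold": a.threshold,
                "min_assembly_distance": None
                if a.min_assembly_distance is None
                else round(a.min_assembly_distance, 3),
                "pae": None if a.pae_value is None else round(a.pae_value, 3),
                "location_class": a.location_class,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_protein_summaries(
    summaries: Sequence[ProteinSummary], path: str | Path
) -> None:
    rows = [
        {
            "accession": s.accession,
            "n_links": s.n_links,
            "n_mapped": s.n_mapped,
            "n_violations": s.n_violations,
            "agreement": None if s.agreement is None else round(s.agreement, 4),
            "mean_plddt": None if s.mean_plddt is None else round(s.mean_plddt, 2),
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pseudobonds(
    assessments: Sequence[Assessment],
    path: str | Path,
    chain_id: str = "A",
    satisfied_color: str = "cornflower blue",
    violated_color: str = "red",
) -> None:
    """ChimeraX pseudobond file connecting linked C-alpha atoms.

    One line per mapped link, coloured by status, for visual checks of
    the violation analysis on the displayed model.
    """
    lines = ["; cross-link pseudobonds"]
    for a in assessments:
        if not a.mapped:
            continue
        color = satisfied_color if a.status == SATISFIED else violated_color
        lines.append(
            f"/{chain_id}:{a.link.residue_a}@CA /{chain_id}:{a.link.residue_b}@CA {color}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
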