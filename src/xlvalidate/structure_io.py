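"""Chain-aware C-alpha structure model and AF2 PAE matrix I/O.

Structures are reduced to one record per residue holding the C-alpha
coordinate, the author residue number and (for predicted models) the
per-residue pLDDT confidence stored in the B-factor column.  Cross-link
distance restraints are defined between C-alpha atoms, so nothing beyond
the C-alpha trace is retained.

PAE (predicted aligned error) matrices are read from the two JSON layouts
in circulation: the modern full-matrix layout and the legacy triplet-list
layout (``residue1``/``residue2``/``distance`` arrays).  Entry ``(x, y)``
is the expected error, in angstroms, of residue ``x``'s position when the
prediction is aligned on residue ``y``; the matrix is asymmetric as read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

from .errors import EmptyStructureError, PAEFormatError, StructureFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueRecord",
    "Structure",
    "PAEMatrix",
    "read_structure",
    "write_structure",
    "read_pae",
    "write_pae",
    "mean_plddt",
]


@dataclass(frozen=True)
class ResidueRecord:
    """One residue reduced to its C-alpha atom.

    ``residue_index`` is the author numbering from the file; for AF2
    output it runs contiguously 1..n and matches PAE matrix rows.
    """

    chain_id: str
    residue_index: int
    aa_code: str
    ca_xyz: tuple[float, float, float]
    plddt: float | None = None

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.ca_xyz)):
            raise StructureFormatError(
                f"non-finite C-alpha coordinate for {self.chain_id}/{self.residue_index}"
            )


@dataclass
class Structure:
    """An ordered collection of chains of C-alpha records.

    A single-chain structure is a monomer; multi-chain is an assembly.
    """

    name: str
    chains: dict[str, list[ResidueRecord]]
    source_format: str = "pdb"
    _index: dict[tuple[str, int], ResidueRecord] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not self.chains:
            raise EmptyStructureError(f"structure {self.name!r} has no chains")
        for chain_id, records in self.chains.items():
            indices = [r.residue_index for r in records]
            if any(b <= a for a, b in zip(indices, indices[1:])):
                raise StructureFormatError(
                    f"chain {chain_id}: residue indices not strictly increasing"
                )
            for rec in records:
                self._index[(chain_id, rec.residue_index)] = rec

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    @property
    def is_assembly(self) -> bool:
        return len(self.chains) > 1

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    def residue(self, chain_id: str, residue_index: int) -> ResidueRecord | None:
        """The record at (chain, author index), or None if absent."""
        return self._index.get((chain_id, residue_index))

    def residues(self) -> Iterator[ResidueRecord]:
        for records in self.chains.values():
            yield from records

    def ca_array(self, chain_id: str | None = None) -> np.ndarray:
        """C-alpha coordinates as an (m, 3) array, one chain or all."""
        if chain_id is None:
            recs: Sequence[ResidueRecord] = list(self.residues())
        else:
            recs = self.chains[chain_id]
        return np.array([r.ca_xyz for r in recs], dtype=float)


@dataclass
class PAEMatrix:
    """n x n predicted-aligned-error grid in angstroms.

    ``symmetric`` is False for matrices as read from AF2 output; the
    symmetrized view (average with the transpose) is derived downstream.
    """

    values: np.ndarray
    symmetric: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise PAEFormatError(f"PAE matrix must be square, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise PAEFormatError("PAE matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise PAEFormatError("PAE matrix contains negative entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]


_FORMAT_MAP = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in _FORMAT_MAP:
            raise ValueError(f"format must be auto/pdb/mmcif, got {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    return "pdb"


def _pick_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy C-alpha; occupancy ties broken by altloc order."""
    cas = [
        a
        for a in residue
        if a.name == "CA" and a.element.name == "C"
    ]
    if not cas:
        return None
    return min(cas, key=lambda a: (-a.occ, a.altloc))


def read_structure(
    path: str | Path,
    format: str = "auto",
    read_as_af2: bool = False,
    residue_offset: int = 0,
    name: str | None = None,
) -> Structure:
    """Read a PDB or mmCIF file into a C-alpha Structure.

    Parameters
    ----------
    path:
        Structure file.  ``.cif``/``.mmcif`` suffixes select mmCIF when
        ``format`` is ``auto``.
    read_as_af2:
        Interpret the B-factor column as per-residue pLDDT (AF2 models
        store confidence there).
    residue_offset:
        Added to every author residue number; AF2 output is 1..n and
        needs none, non-AF2 structures can be shifted onto a reference
        numbering.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    try:
        st = gemmi.read_structure(str(path), format=_FORMAT_MAP[fmt])
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureFormatError(f"cannot read {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")

    model = st[0]
    chains: dict[str, list[ResidueRecord]] = {}
    n_skipped = 0
    for chain in model:
        records: list[ResidueRecord] = []
        seen: set[int] = set()
        for residue in chain:
            if residue.is_water():
                continue
            ca = _pick_ca(residue)
            if ca is None:
                n_skipped += 1
                continue
            idx = residue.seqid.num + residue_offset
            if idx in seen:
                raise StructureFormatError(
                    f"{path}: duplicate residue {chain.name}/{idx}"
                )
            seen.add(idx)
            info = gemmi.find_tabulated_residue(residue.name)
            aa = info.one_letter_code.upper() if info else "X"
            records.append(
                ResidueRecord(
                    chain_id=chain.name,
                    residue_index=idx,
                    aa_code=aa if aa.isalpha() else "X",
                    ca_xyz=(ca.pos.x, ca.pos.y, ca.pos.z),
                    plddt=float(ca.b_iso) if read_as_af2 else None,
                )
            )
        if records:
            records.sort(key=lambda r: r.residue_index)
            if chain.name in chains:
                raise StructureFormatError(f"{path}: duplicate chain id {chain.name}")
            chains[chain.name] = records
    if n_skipped:
        logger.warning("%s: skipped %d residues without a C-alpha atom", path, n_skipped)
    if not chains:
        raise EmptyStructureError(f"{path}: no residues with C-alpha atoms")
    return Structure(
        name=name if name is not None else path.stem,
        chains=chains,
        source_format=fmt,
    )


def write_structure(structure: Structure, path: str | Path, format: str = "auto") -> None:
    """Write the C-alpha trace as PDB or mmCIF (pLDDT into B-factors)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    st = gemmi.Structure()
    st.name = structure.name
    model = gemmi.Model("1")
    for chain_id, records in structure.chains.items():
        chain = gemmi.Chain(chain_id)
        for rec in records:
            res = gemmi.Residue()
            res.name = _ONE_TO_THREE.get(rec.aa_code, "ALA")
            res.seqid = gemmi.SeqId(rec.residue_index, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*rec.ca_xyz)
            atom.occ = 1.0
            atom.b_iso = rec.plddt if rec.plddt is not None else 0.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


def read_pae(path: str | Path) -> PAEMatrix:
    """Read a PAE JSON file in either AFDB dialect.

    Accepts the full-matrix layout (``predicted_aligned_error`` or
    ``pae`` holding an n x n array) and the legacy triplet layout
    (flat ``residue1``/``residue2``/``distance`` arrays covering all
    ordered pairs).  Both yield the same asymmetric matrix.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise PAEFormatError(f"{path}: not valid JSON ({exc})") from exc
    if isinstance(data, list):
        if not data:
            raise PAEFormatError(f"{path}: empty JSON list")
        data = data[0]
    if not isinstance(data, dict):
        raise PAEFormatError(f"{path}: expected a JSON object")

    matrix = None
    for key in ("predicted_aligned_error", "pae"):
        if key in data:
            matrix = data[key]
            break
    if matrix is not None:
        rows = list(matrix)
        n = len(rows)
        if n == 0 or any(len(row) != n for row in rows):
            raise PAEFormatError(f"{path}: PAE matrix is ragged or non-square")
        values = np.asarray(rows, dtype=float)
    elif {"residue1", "residue2", "distance"} <= set(data):
        r1 = np.asarray(data["residue1"], dtype=int)
        r2 = np.asarray(data["residue2"], dtype=int)
        d = np.asarray(data["distance"], dtype=float)
        if not (len(r1) == len(r2) == len(d)) or len(r1) == 0:
            raise PAEFormatError(f"{path}: triplet arrays are empty or mismatched")
        n = int(max(r1.max(), r2.max()))
        if len(r1) != n * n:
            raise PAEFormatError(
                f"{path}: triplet list has {len(r1)} entries, expected {n * n}"
            )
        values = np.zeros((n, n), dtype=float)
        values[r1 - 1, r2 - 1] = d
    else:
        raise PAEFormatError(f"{path}: no PAE payload recognised in keys {sorted(data)}")
    return PAEMatrix(values=values, symmetric=False)


def write_pae(pae: PAEMatrix, path: str | Path, dialect: str = "matrix") -> None:
    """Write a PAE matrix as JSON in the matrix or triplet dialect."""
    path = Path(path)
    if dialect == "matrix":
        payload: object = {
            "predicted_aligned_error": pae.values.tolist(),
            "max_predicted_aligned_error": float(pae.values.max()) if pae.n else 0.0,
        }
    elif dialect == "triplets":
        n = pae.n
        r1, r2 = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
        payload = [
            {
                "residue1": r1.ravel().tolist(),
                "residue2": r2.ravel().tolist(),
                "distance": pae.values.ravel().tolist(),
                "max_predicted_aligned_error": float(pae.values.max()),
            }
        ]
    else:
        raise ValueError(f"dialect must be 'matrix' or 'triplets', got {dialect!r}")
    with open(path, "w") as fh:
        json.dump(payload, fh)


def mean_plddt(structure: Structure) -> float:
    """Arithmetic mean pLDDT over all residues of all chains."""
    missing = [
        (r.chain_id, r.residue_index) for r in structure.residues() if r.plddt is None
    ]
    if missing:
        shown = ", ".join(f"{c}/{i}" for c, i in missing[:5])
        more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
        raise StructureFormatError(f"residues missing pLDDT: {shown}{more}")
    vals = [r.plddt for r in structure.residues()]
    return float(np.mean(vals))
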