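"""Synthetic structures, PAE matrices, cross-link sets and assemblies.

Every pipeline stage is exercised on generated data with known ground
truth: multi-domain C-alpha traces with known domain ranges, asymmetric
PAE matrices with low within-domain / high between-domain blocks plus
noise, cross-link sets with known satisfied/violated labels, and
two-copy assemblies in which some "intramolecular" links are satisfied
only between copies.

Geometry model: consecutive C-alpha atoms are spaced 3.8 A (the C-alpha
virtual bond); each domain is grown as a compact self-avoiding walk
confined to a ball of radius ~ 3 * m**(1/3) A (m residues), which
reproduces globular-domain packing densities; linkers are extended walks
that carry the chain between domain balls.  Designated "lysine"
positions (a pseudo-random subset at ``lysine_fraction``) stand in for
the amine-reactive sites of DSSO-class chemistry; no sequence realism is
attempted.

Ground-truth labels are guard-banded: satisfied links are drawn from
pairs at most 28 A apart and violated links from pairs beyond 32 A, so a
30 A threshold classifies them deterministically.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .crosslinks import CrossLink, CrossLinkSet
from .errors import SyntheticDataError
from .structure_io import PAEMatrix, ResidueRecord, Structure

__all__ = [
    "SyntheticSpec",
    "make_structure",
    "scramble_domains",
    "make_pae",
    "sample_crosslinks",
    "make_assembly",
    "make_rescue_scenario",
    "sample_calibration_assessments",
]

CA_BOND = 3.8  # A between consecutive C-alpha atoms
MIN_SEPARATION = 3.5  # A self-avoidance radius
SATISFIED_MAX = 28.0  # A; guard band below the 30 A threshold
VIOLATED_MIN = 32.0  # A; guard band above the 30 A threshold
PAE_CEILING = 31.75  # A; AF2 reports PAE clipped at this value


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic protein scenario."""

    n_residues: int
    domain_ranges: tuple[tuple[int, int], ...]
    lysine_fraction: float = 0.07
    seed: int = 0
    pae_within_mean: float = 3.0
    pae_within_sd: float = 1.0
    pae_between_mean: float = 20.0
    pae_between_sd: float = 3.0
    n_links: int = 30
    violated_fraction: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "domain_ranges", tuple(tuple(r) for r in self.domain_ranges)
        )
        prev_end = 0
        for start, end in self.domain_ranges:
            if not (1 <= start <= end <= self.n_residues):
                raise ValueError(f"domain ({start}, {end}) outside 1..{self.n_residues}")
            if start <= prev_end:
                raise ValueError("domain ranges must be disjoint and ordered")
            prev_end = end
        if not 0 < self.lysine_fraction <= 1:
            raise ValueError("lysine_fraction must be in (0, 1]")
        if not 0 <= self.violated_fraction <= 1:
            raise ValueError("violated_fraction must be in [0, 1]")


def _domain_radius(m: int) -> float:
    return 3.0 * m ** (1.0 / 3.0)


def _grow_chain(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding C-alpha trace: compact domain balls, extended linkers."""
    membership = np.full(spec.n_residues, -1, dtype=int)
    for k, (start, end) in enumerate(spec.domain_ranges):
        membership[start - 1 : end] = k

    max_restarts = 30
    for _ in range(max_restarts):
        coords = _try_grow(spec, membership, rng)
        if coords is not None:
            return coords
    raise SyntheticDataError(
        f"could not pack {spec.n_residues} residues into "
        f"{len(spec.domain_ranges)} domains after {max_restarts} restarts"
    )


def _try_grow(
    spec: SyntheticSpec, membership: np.ndarray, rng: np.random.Generator
) -> np.ndarray | None:
    coords = np.zeros((spec.n_residues, 3))
    centers: dict[int, np.ndarray] = {}
    backtracks_left = 200

    i = 0
    while i < spec.n_residues:
        dom = membership[i]
        if i == 0:
            coords[0] = 0.0
            if dom >= 0:
                start, end = spec.domain_ranges[dom]
                centers[dom] = coords[0] + np.array(
                    [0.8 * _domain_radius(end - start + 1), 0.0, 0.0]
                )
            i = 1
            continue
        if dom >= 0 and dom not in centers:
            start, end = spec.domain_ranges[dom]
            centers[dom] = coords[i - 1] + np.array(
                [0.8 * _domain_radius(end - start + 1), 0.0, 0.0]
            )

        placed = False
        for _attempt in range(300):
            if dom >= 0:
                step = rng.normal(size=3)
                step /= np.linalg.norm(step)
                candidate = coords[i - 1] + CA_BOND * step
                start, end = spec.domain_ranges[dom]
                if np.linalg.norm(candidate - centers[dom]) > _domain_radius(end - start + 1):
                    continue
            else:
                # Extended linker: mostly +x with transverse jitter.
                step = np.array([1.0, 0.0, 0.0]) + 0.3 * rng.normal(size=3)
                step /= np.linalg.norm(step)
                candidate = coords[i - 1] + CA_BOND * step
            if i >= 2:
                d = np.linalg.norm(coords[: i - 1] - candidate, axis=1)
                if d.min() < MIN_SEPARATION:
                    continue
            coords[i] = candidate
            placed = True
            break
        if placed:
            i += 1
            continue
        # Dead end: step back a stretch and regrow it along a new path.
        if backtracks_left == 0:
            return None
        backtracks_left -= 1
        back = min(10, i - 1)
        i -= back
        if i < 1:
            i = 1
        # Forget centers of domains we fully backed out of.
        for d_idx, (start, _end) in enumerate(spec.domain_ranges):
            if start > i:
                centers.pop(d_idx, None)
    return coords


def make_structure(spec: SyntheticSpec, name: str | None = None) -> Structure:
    """A single-chain C-alpha trace with the spec's domain architecture.

    Residues inside domains carry high synthetic pLDDT (~90), linker
    residues low (~55); designated lysines get aa_code "K".
    """
    rng = np.random.default_rng(spec.seed)
    coords = _grow_chain(spec, rng)

    n_lys = max(2, int(round(spec.lysine_fraction * spec.n_residues)))
    lysines = set(rng.choice(spec.n_residues, size=n_lys, replace=False) + 1)

    in_domain = np.zeros(spec.n_residues, dtype=bool)
    for start, end in spec.domain_ranges:
        in_domain[start - 1 : end] = True

    records = []
    for i in range(spec.n_residues):
        plddt = rng.normal(90.0, 3.0) if in_domain[i] else rng.normal(55.0, 5.0)
        records.append(
            ResidueRecord(
                chain_id="A",
                residue_index=i + 1,
                aa_code="K" if (i + 1) in lysines else "A",
                ca_xyz=tuple(coords[i]),
                plddt=float(np.clip(plddt, 0.0, 100.0)),
            )
        )
    return Structure(
        name=name if name is not None else f"SYN{spec.seed:04d}",
        chains={"A": records},
        source_format="pdb",
    )


def scramble_domains(
    structure: Structure,
    ranges: Sequence[tuple[int, int]],
    seed: int,
    translation_range: tuple[float, float] = (20.0, 60.0),
) -> Structure:
    """Randomly re-place every domain after the first as a rigid unit.

    Each body after the first receives a uniform random rotation about
    its centroid plus a translation of uniform random length in
    ``translation_range`` A; internal geometry is preserved exactly.
    Emulates a confidently predicted multi-domain structure whose
    inter-domain placement is wrong.
    """
    rng = np.random.default_rng(seed)
    chain_id = structure.chain_ids[0]
    records = list(structure.chains[chain_id])
    coords = np.array([r.ca_xyz for r in records])
    index_of = {r.residue_index: k for k, r in enumerate(records)}

    for start, end in sorted(ranges)[1:]:
        rows = [index_of[i] for i in range(start, end + 1) if i in index_of]
        body = coords[rows]
        centroid = body.mean(axis=0)
        R = Rotation.random(rng=rng).as_matrix()
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        t = rng.uniform(*translation_range) * direction
        coords[rows] = (body - centroid) @ R.T + centroid + t

    new_records = [
        replace(rec, ca_xyz=tuple(coords[k])) for k, rec in enumerate(records)
    ]
    return Structure(
        name=structure.name + "_scrambled",
        chains={chain_id: new_records},
        source_format=structure.source_format,
    )


def make_pae(spec: SyntheticSpec) -> PAEMatrix:
    """An asymmetric block-structured PAE matrix.

    Residue pairs inside the same domain draw |N(within_mean, sd)|,
    all other pairs |N(between_mean, sd)|, independently per direction
    (the matrix is asymmetric, like raw AF2 output); the diagonal is
    0.2 A and everything is clipped to [0, 31.75].
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    membership = np.full(n, -1, dtype=int)
    for k, (start, end) in enumerate(spec.domain_ranges):
        membership[start - 1 : end] = k

    same = (membership[:, None] == membership[None, :]) & (membership[:, None] >= 0)
    values = np.abs(rng.normal(spec.pae_between_mean, spec.pae_between_sd, size=(n, n)))
    within = np.abs(rng.normal(spec.pae_within_mean, spec.pae_within_sd, size=(n, n)))
    values[same] = within[same]
    np.fill_diagonal(values, 0.2)
    np.clip(values, 0.0, PAE_CEILING, out=values)
    return PAEMatrix(values=values, symmetric=False)


def _lysine_pairs(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    chain_id = structure.chain_ids[0]
    records = structure.chains[chain_id]
    lys = [r for r in records if r.aa_code == "K"]
    if len(lys) < 2:
        raise SyntheticDataError("structure has fewer than 2 designated lysines")
    positions = np.array([r.residue_index for r in lys])
    coords = np.array([r.ca_xyz for r in lys])
    return positions, squareform(pdist(coords))


def sample_crosslinks(
    structure: Structure, spec: SyntheticSpec
) -> tuple[CrossLinkSet, dict[tuple, bool]]:
    """Draw links between designated lysines with known truth labels.

    Satisfied links come from lysine pairs at most 28 A apart, violated
    links from pairs beyond 32 A; the 28-32 A guard band keeps the
    ground truth deterministic at a 30 A threshold.  Returns the set and
    a map link.key -> violated?.
    """
    rng = np.random.default_rng(spec.seed + 1)
    positions, dmat = _lysine_pairs(structure)
    iu = np.triu_indices(len(positions), k=1)
    dists = dmat[iu]
    sat_pool = [
        (int(positions[i]), int(positions[j]))
        for i, j, d in zip(iu[0], iu[1], dists)
        if d <= SATISFIED_MAX
    ]
    vio_pool = [
        (int(positions[i]), int(positions[j]))
        for i, j, d in zip(iu[0], iu[1], dists)
        if d > VIOLATED_MIN
    ]
    n_vio = int(round(spec.n_links * spec.violated_fraction))
    n_sat = spec.n_links - n_vio
    if n_sat > len(sat_pool) or n_vio > len(vio_pool):
        raise SyntheticDataError(
            f"requested {n_sat} satisfied / {n_vio} violated links but pools "
            f"hold {len(sat_pool)} / {len(vio_pool)} lysine pairs"
        )
    chosen_sat = [sat_pool[k] for k in rng.choice(len(sat_pool), n_sat, replace=False)]
    chosen_vio = [vio_pool[k] for k in rng.choice(len(vio_pool), n_vio, replace=False)]

    links = CrossLinkSet()
    truth: dict[tuple, bool] = {}
    for pairs, violated in ((chosen_sat, False), (chosen_vio, True)):
        for i, j in pairs:
            link = CrossLink.create(
                structure.name, i, structure.name, j, source="synthetic"
            )
            links.add(link)
            truth[link.key] = violated
    return links, truth


def make_assembly(
    structure: Structure,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | Sequence[float] = (0.0, 0.0, 0.0),
) -> Structure:
    """Two-copy assembly: chain A is the input, chain B a rigid copy.

    Chain B = rotation @ A + translation (rotation defaults to the
    identity).  Supports constructing links whose intra-copy distance
    exceeds the threshold while a cross-copy pairing satisfies it.
    """
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    chain_id = structure.chain_ids[0]
    records_a = [replace(r, chain_id="A") for r in structure.chains[chain_id]]
    records_b = [
        replace(r, chain_id="B", ca_xyz=tuple(R @ np.asarray(r.ca_xyz) + t))
        for r in structure.chains[chain_id]
    ]
    return Structure(
        name=structure.name + "_dimer",
        chains={"A": records_a, "B": records_b},
        source_format=structure.source_format,
    )


def make_rescue_scenario(
    seed: int, n_rescued: int = 4, n_satisfied: int = 8
) -> tuple[Structure, Structure, CrossLinkSet, set[tuple]]:
    """A two-copy assembly in which known links are rescued across copies.

    Builds a two-domain monomer, pulls the second domain far away (so
    inter-domain links violate on the monomer), then forms a dimer whose
    copy B is translated so that B's second domain sits where A's first
    domain is.  Inter-domain links then find a cross-copy pairing within
    28 A while remaining violated intra-copy.

    Returns (monomer, assembly, links, keys_of_rescued_links).
    """
    spec = SyntheticSpec(
        n_residues=220,
        domain_ranges=((1, 100), (121, 220)),
        lysine_fraction=0.25,
        seed=seed,
        n_links=n_satisfied,
        violated_fraction=0.0,
    )
    base = make_structure(spec)
    # Separate the two domains by a large rigid shift of domain 2.
    rng = np.random.default_rng(seed + 7)
    chain = base.chains["A"]
    coords = np.array([r.ca_xyz for r in chain])
    shift = np.array([300.0, 0.0, 0.0])
    rows2 = [k for k, r in enumerate(chain) if 121 <= r.residue_index <= 220]
    coords[rows2] += shift
    monomer = Structure(
        name=base.name,
        chains={"A": [replace(r, ca_xyz=tuple(coords[k])) for k, r in enumerate(chain)]},
    )

    # Within-domain satisfied links (unaffected by the shift).
    links, _ = sample_crosslinks(monomer, spec)

    # Inter-domain links: violated intra-copy (>= 300 A apart), rescued
    # across copies once B's domain 2 is brought next to A's domain 1.
    lys1 = [r.residue_index for r in monomer.chains["A"] if r.aa_code == "K" and r.residue_index <= 100]
    lys2 = [r.residue_index for r in monomer.chains["A"] if r.aa_code == "K" and r.residue_index >= 121]
    if len(lys1) < 1 or len(lys2) < 1:
        raise SyntheticDataError("rescue scenario needs lysines in both domains")

    # Translate copy B so its domain 2 centroid lands on A's domain 1
    # centroid: inter-domain links then have a short cross-copy pairing.
    rows1 = [k for k, r in enumerate(chain) if r.residue_index <= 100]
    c1 = coords[rows1].mean(axis=0)
    c2 = coords[rows2].mean(axis=0)
    translation = c1 - c2
    assembly = make_assembly(monomer, translation=translation)

    rescued: set[tuple] = set()
    candidates = [(i, j) for i in lys1 for j in lys2]
    rng.shuffle(candidates)
    for i, j in candidates:
        if len(rescued) >= n_rescued:
            break
        ra = monomer.residue("A", i)
        rb = monomer.residue("A", j)
        d_intra = np.linalg.norm(np.subtract(ra.ca_xyz, rb.ca_xyz))
        d_cross = np.linalg.norm(
            np.subtract(ra.ca_xyz, np.asarray(rb.ca_xyz) + translation)
        )
        if d_intra > VIOLATED_MIN and d_cross <= SATISFIED_MAX:
            link = CrossLink.create(monomer.name, i, monomer.name, j, source="synthetic")
            if link not in links:
                links.add(link)
                rescued.add(link.key)
    if len(rescued) < n_rescued:
        raise SyntheticDataError(
            f"only {len(rescued)} rescuable lysine pairs available, wanted {n_rescued}"
        )
    return monomer, assembly, links, rescued


def make_modeling_scenario(
    seed: int,
    n_links: int = 25,
    domain_ranges: tuple[tuple[int, int], ...] = ((8, 195), (201, 296), (311, 498)),
    n_residues: int = 500,
) -> tuple[Structure, Structure, tuple[tuple[int, int], ...], CrossLinkSet]:
    """A rigid-body recovery problem with a known zero-violation answer.

    Generates a compact multi-domain native structure, draws ``n_links``
    cross-links between domain-resident lysines that the native
    arrangement satisfies (<= 28 A), then scrambles the domain placement.
    An arrangement satisfying every link exists by construction (the
    native one), so a restrained rigid-body search can be scored against
    it.  Returns (native, scrambled, body_ranges, links).
    """
    spec = SyntheticSpec(
        n_residues=n_residues,
        domain_ranges=domain_ranges,
        lysine_fraction=0.2,
        seed=seed,
        n_links=n_links,
        violated_fraction=0.0,
    )
    native = make_structure(spec)
    rng = np.random.default_rng(seed + 3)

    in_domain = np.zeros(n_residues + 1, dtype=bool)
    for start, end in domain_ranges:
        in_domain[start : end + 1] = True
    positions, dmat = _lysine_pairs(native)
    iu = np.triu_indices(len(positions), k=1)
    pool = [
        (int(positions[i]), int(positions[j]))
        for i, j in zip(*iu)
        if dmat[i, j] <= SATISFIED_MAX
        and in_domain[positions[i]]
        and in_domain[positions[j]]
    ]
    # Prefer inter-domain links: they are the ones that constrain the
    # arrangement; keep a few intra-domain ones as decoys.
    dom_of = np.full(n_residues + 1, -1)
    for k, (start, end) in enumerate(domain_ranges):
        dom_of[start : end + 1] = k
    inter = [p for p in pool if dom_of[p[0]] != dom_of[p[1]]]
    intra = [p for p in pool if dom_of[p[0]] == dom_of[p[1]]]
    n_inter = min(len(inter), max(n_links // 2, n_links - len(intra)))
    if n_inter + len(intra) < n_links:
        raise SyntheticDataError(
            f"only {len(pool)} satisfiable domain-resident lysine pairs, "
            f"need {n_links}"
        )
    chosen = [inter[k] for k in rng.choice(len(inter), n_inter, replace=False)]
    chosen += [
        intra[k] for k in rng.choice(len(intra), n_links - n_inter, replace=False)
    ]
    links = CrossLinkSet(
        CrossLink.create(native.name, i, native.name, j, source="synthetic")
        for i, j in chosen
    )
    scrambled = scramble_domains(native, domain_ranges, seed=seed + 11)
    return native, scrambled, domain_ranges, links


def sample_calibration_assessments(
    n: int, seed: int, accession: str = "SYNCAL"
):
    """Assessments whose violation probability increases with PAE.

    PAE values are uniform on [0.5, 30]; the violation probability rises
    linearly from 0 at PAE 3.5 to 0.6 at the PAE ceiling, so links below
    3.5 A PAE are never violated.  Distances are bookkeeping values
    (25 A satisfied / 45 A violated).  Used to exercise the calibration
    curve against a known monotone relationship.
    """
    from .violations import Assessment, SATISFIED, VIOLATED

    rng = np.random.default_rng(seed)
    out = []
    seen: set[tuple[int, int]] = set()
    while len(out) < n:
        i, j = sorted(int(v) for v in rng.integers(1, 10 * n, size=2))
        if i == j or (i, j) in seen:
            continue
        seen.add((i, j))
        pae = float(rng.uniform(0.5, 30.0))
        p_violate = 0.6 * max(0.0, (pae - 3.5) / (30.0 - 3.5))
        violated = bool(rng.random() < p_violate)
        link = CrossLink.create(accession, i, accession, j, source="synthetic")
        out.append(
            Assessment(
                link=link,
                distance=45.0 if violated else 25.0,
                status=VIOLATED if violated else SATISFIED,
                threshold=30.0,
                pae_value=pae,
            )
        )
    return out
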