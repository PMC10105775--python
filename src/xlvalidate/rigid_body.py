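"""Cross-link-restrained rigid-body re-arrangement by simulated annealing.

Well-predicted regions of a structure are treated as rigid bodies (their
internal C-alpha geometry is frozen); the bodies are then re-positioned
by Metropolis Monte Carlo under three restraint terms:

* cross-link: flat-bottom harmonic on each restrained C-alpha pair,
  zero up to the linker threshold, ``k_xl * (d - threshold)**2`` beyond;
* connectivity: flat-bottom harmonic keeping consecutive bodies within
  reach of their linker, with 3.8 A of slack per linker residue plus one
  (the C-alpha virtual bond length);
* excluded volume: soft-sphere repulsion between C-alpha atoms of
  different bodies below 3.5 A separation.

Each frame proposes a random rotation about one body's centroid plus a
random translation, accepted with probability ``min(1, exp(-dE/T))``
under a geometric cooling schedule.  An ensemble runs several
independent annealings from random initial conditions with seeds derived
from the base seed by fixed offsets, so every result is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .crosslinks import CrossLink
from .structure_io import ResidueRecord, Structure

__all__ = [
    "RigidBody",
    "SamplerConfig",
    "EnergyTerms",
    "AnnealResult",
    "EnsembleResult",
    "bodies_from_structure",
    "score_state",
    "count_satisfied",
    "anneal",
    "run_ensemble",
    "model_to_structure",
    "write_energy_log",
]


@dataclass(frozen=True)
class RigidBody:
    """A contiguous residue range with fixed internal C-alpha geometry."""

    body_id: int
    residue_range: tuple[int, int]
    coords: np.ndarray  # (m, 3) C-alpha positions for residues start..end

    def __post_init__(self) -> None:
        start, end = self.residue_range
        m = end - start + 1
        if self.coords.shape != (m, 3):
            raise ValueError(
                f"body {self.body_id}: {self.coords.shape[0]} coordinates "
                f"for residue range {start}-{end} ({m} residues)"
            )

    @property
    def start(self) -> int:
        return self.residue_range[0]

    @property
    def end(self) -> int:
        return self.residue_range[1]

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SamplerConfig:
    """Sampler and restraint parameters.

    ``n_frames``/``n_runs`` default to 20,000 frames from 10 random
    initial conditions.  Restraint weights and the temperature schedule
    are exposed because reasonable values depend on system size.
    """

    n_frames: int = 20_000
    n_runs: int = 10
    seed: int = 0
    threshold: float = 30.0  # A, cross-link flat bottom
    k_xl: float = 1.0
    k_conn: float = 1.0
    k_ev: float = 0.1
    t_start: float = 5.0
    t_end: float = 0.1
    max_rotation: float = 0.2  # rad per move
    max_translation: float = 2.0  # A per move
    linker_bond: float = 3.8  # A of connectivity slack per linker residue + 1
    ev_distance: float = 3.5  # A minimum inter-body C-alpha separation
    init_scale: float = 10.0  # initial placement uses move sizes x this

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_runs < 1:
            raise ValueError("n_frames and n_runs must be >= 1")
        if not self.t_start >= self.t_end > 0:
            raise ValueError("need t_start >= t_end > 0")


class EnergyTerms(NamedTuple):
    crosslink: float
    connectivity: float
    excluded_volume: float

    @property
    def total(self) -> float:
        return self.crosslink + self.connectivity + self.excluded_volume


def bodies_from_structure(
    structure: Structure,
    ranges: Sequence[tuple[int, int]],
    chain_id: str | None = None,
) -> list[RigidBody]:
    """Cut rigid bodies out of a chain at the given residue ranges.

    Every residue of every range must be present with a C-alpha; ranges
    are sorted by start.  Residues between ranges become implicit
    flexible linkers (they only contribute connectivity slack).
    """
    if chain_id is None:
        chain_id = structure.chain_ids[0]
    bodies = []
    for k, (start, end) in enumerate(sorted(ranges)):
        rows = []
        for idx in range(start, end + 1):
            rec = structure.residue(chain_id, idx)
            if rec is None:
                raise ValueError(f"residue {idx} of body {start}-{end} missing from chain {chain_id}")
            rows.append(rec.ca_xyz)
        bodies.append(RigidBody(body_id=k, residue_range=(start, end), coords=np.array(rows)))
    for a, b in zip(bodies, bodies[1:]):
        if b.start <= a.end:
            raise ValueError("rigid-body ranges overlap")
    return bodies


def _locate(bodies: Sequence[RigidBody], residue: int) -> tuple[int, int]:
    for k, body in enumerate(bodies):
        if body.start <= residue <= body.end:
            return k, residue - body.start
    raise ValueError(
        f"restrained residue {residue} falls in no rigid body; "
        "linker residues are not modelled as beads"
    )


def _link_indices(
    bodies: Sequence[RigidBody], links: Iterable[CrossLink]
) -> np.ndarray:
    """(n_links, 4) array of body/row indices for both link endpoints."""
    rows = []
    for link in links:
        ba, ia = _locate(bodies, link.residue_a)
        bb, ib = _locate(bodies, link.residue_b)
        rows.append((ba, ia, bb, ib))
    return np.array(rows, dtype=int).reshape(-1, 4)


def _xl_energy(coords: Sequence[np.ndarray], idx: np.ndarray, cfg: SamplerConfig) -> float:
    if len(idx) == 0:
        return 0.0
    pa = np.array([coords[b][i] for b, i in zip(idx[:, 0], idx[:, 1])])
    pb = np.array([coords[b][i] for b, i in zip(idx[:, 2], idx[:, 3])])
    d = np.linalg.norm(pa - pb, axis=1)
    excess = np.maximum(0.0, d - cfg.threshold)
    return float(cfg.k_xl * np.sum(excess**2))


def _conn_energy_pair(
    coords: Sequence[np.ndarray],
    bodies: Sequence[RigidBody],
    p: int,
    cfg: SamplerConfig,
) -> float:
    """Connectivity term between consecutive bodies p and p+1."""
    gap = bodies[p + 1].start - bodies[p].end - 1
    slack = cfg.linker_bond * (gap + 1)
    d = float(np.linalg.norm(coords[p + 1][0] - coords[p][-1]))
    return cfg.k_conn * max(0.0, d - slack) ** 2


def _ev_energy_pair(
    coords: Sequence[np.ndarray], p: int, q: int, cfg: SamplerConfig
) -> float:
    d = cdist(coords[p], coords[q])
    overlap = cfg.ev_distance - d
    np.clip(overlap, 0.0, None, out=overlap)
    return float(cfg.k_ev * np.sum(overlap**2))


def score_state(
    bodies: Sequence[RigidBody],
    coords: Sequence[np.ndarray],
    links: Iterable[CrossLink],
    config: SamplerConfig | None = None,
) -> EnergyTerms:
    """Full restraint energy of a placement (deterministic).

    ``coords`` holds one (m, 3) world-coordinate array per body, in body
    order.  Used directly by tests and reporting; the sampler keeps
    incremental caches but must agree with this function exactly.
    """
    cfg = config if config is not None else SamplerConfig()
    idx = _link_indices(bodies, links)
    e_xl = _xl_energy(coords, idx, cfg)
    e_conn = sum(
        _conn_energy_pair(coords, bodies, p, cfg) for p in range(len(bodies) - 1)
    )
    e_ev = sum(
        _ev_energy_pair(coords, p, q, cfg)
        for p in range(len(bodies))
        for q in range(p + 1, len(bodies))
    )
    return EnergyTerms(crosslink=e_xl, connectivity=float(e_conn), excluded_volume=e_ev)


def count_satisfied(
    bodies: Sequence[RigidBody],
    coords: Sequence[np.ndarray],
    links: Iterable[CrossLink],
    threshold: float = 30.0,
) -> int:
    """Restraints whose current C-alpha distance is within the threshold."""
    idx = _link_indices(bodies, links)
    if len(idx) == 0:
        return 0
    pa = np.array([coords[b][i] for b, i in zip(idx[:, 0], idx[:, 1])])
    pb = np.array([coords[b][i] for b, i in zip(idx[:, 2], idx[:, 3])])
    d = np.linalg.norm(pa - pb, axis=1)
    return int(np.sum(d <= threshold))


def _random_rotation(rng: np.random.Generator, max_angle: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle)
    return Rotation.from_rotvec(axis * angle).as_matrix()


def _random_translation(rng: np.random.Generator, max_radius: float) -> np.ndarray:
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = max_radius * rng.uniform() ** (1.0 / 3.0)
    return radius * direction


@dataclass
class AnnealResult:
    """Best state of one annealing run."""

    run_seed: int
    best_coords: list[np.ndarray]
    best_energy: float
    best_terms: EnergyTerms
    satisfied_links: int
    n_links: int
    acceptance_rate: float
    trace: list[tuple[int, float, float]] = field(default_factory=list)
    # trace rows: (frame, current_energy, best_energy)


def anneal(
    bodies: Sequence[RigidBody],
    links: Sequence[CrossLink],
    config: SamplerConfig,
    run_seed: int,
    log_every: int = 500,
) -> AnnealResult:
    """One Metropolis Monte Carlo annealing run, reproducible from run_seed.

    Per frame one body is chosen uniformly and given a random rotation
    about its centroid (axis uniform on the sphere, angle uniform in
    [0, max_rotation]) plus a random translation uniform in a ball of
    radius max_translation; the move is accepted with probability
    min(1, exp(-dE/T)) under geometric cooling from t_start to t_end.
    The minimum-energy state seen is returned.
    """
    rng = np.random.default_rng(run_seed)
    cfg = config
    n_bodies = len(bodies)
    if n_bodies < 2:
        raise ValueError("annealing needs at least 2 rigid bodies")
    idx = _link_indices(bodies, links)

    # Random initial condition: proposal distribution scaled up.
    coords: list[np.ndarray] = []
    for body in bodies:
        R = _random_rotation(rng, min(math.pi, cfg.init_scale * cfg.max_rotation))
        t = _random_translation(rng, cfg.init_scale * cfg.max_translation)
        c = body.coords.mean(axis=0)
        coords.append((body.coords - c) @ R.T + c + t)

    # Incremental energy caches, one entry per interaction group.
    per_link = np.zeros(len(idx))
    for k, (ba, ia, bb, ib) in enumerate(idx):
        d = float(np.linalg.norm(coords[ba][ia] - coords[bb][ib]))
        per_link[k] = cfg.k_xl * max(0.0, d - cfg.threshold) ** 2
    links_of_body: list[np.ndarray] = [
        np.flatnonzero((idx[:, 0] == b) | (idx[:, 2] == b)) for b in range(n_bodies)
    ]
    conn = np.array(
        [_conn_energy_pair(coords, bodies, p, cfg) for p in range(n_bodies - 1)]
    )
    ev = {
        (p, q): _ev_energy_pair(coords, p, q, cfg)
        for p in range(n_bodies)
        for q in range(p + 1, n_bodies)
    }

    def total() -> float:
        return float(per_link.sum() + conn.sum() + sum(ev.values()))

    current = total()
    best = current
    best_coords = [c.copy() for c in coords]
    n_accept = 0
    trace: list[tuple[int, float, float]] = [(0, current, best)]

    cooling = (
        (cfg.t_end / cfg.t_start) ** (1.0 / max(1, cfg.n_frames - 1))
        if cfg.n_frames > 1
        else 1.0
    )
    temperature = cfg.t_start

    for frame in range(1, cfg.n_frames + 1):
        b = int(rng.integers(n_bodies))
        R = _random_rotation(rng, cfg.max_rotation)
        t = _random_translation(rng, cfg.max_translation)
        c = coords[b].mean(axis=0)
        new_b = (coords[b] - c) @ R.T + c + t

        trial = list(coords)
        trial[b] = new_b
        delta = 0.0
        new_links = {}
        for k in links_of_body[b]:
            ba, ia, bb, ib = idx[k]
            d = float(np.linalg.norm(trial[ba][ia] - trial[bb][ib]))
            e = cfg.k_xl * max(0.0, d - cfg.threshold) ** 2
            new_links[k] = e
            delta += e - per_link[k]
        new_conn = {}
        for p in (b - 1, b):
            if 0 <= p < n_bodies - 1:
                e = _conn_energy_pair(trial, bodies, p, cfg)
                new_conn[p] = e
                delta += e - conn[p]
        new_ev = {}
        for other in range(n_bodies):
            if other == b:
                continue
            key = (min(b, other), max(b, other))
            e = _ev_energy_pair(trial, key[0], key[1], cfg)
            new_ev[key] = e
            delta += e - ev[key]

        if delta <= 0.0 or rng.random() < math.exp(-delta / temperature):
            coords[b] = new_b
            for k, e in new_links.items():
                per_link[k] = e
            for p, e in new_conn.items():
                conn[p] = e
            ev.update(new_ev)
            current += delta
            n_accept += 1
            if current < best:
                best = current
                best_coords = [c_.copy() for c_ in coords]
        temperature *= cooling
        if frame % log_every == 0 or frame == cfg.n_frames:
            trace.append((frame, current, best))

    best_terms = score_state(bodies, best_coords, links, cfg)
    return AnnealResult(
        run_seed=run_seed,
        best_coords=best_coords,
        best_energy=best_terms.total,
        best_terms=best_terms,
        satisfied_links=count_satisfied(bodies, best_coords, links, cfg.threshold),
        n_links=len(idx),
        acceptance_rate=n_accept / cfg.n_frames,
        trace=trace,
    )


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimising ||(P @ R.T + t) - Q||."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cq - cp @ R.T


@dataclass
class EnsembleResult:
    """Summary over independent annealing runs."""

    runs: list[AnnealResult]
    best: AnnealResult  # minimum-energy run
    best_satisfied: int  # maximum satisfied count over runs
    precision_proxy: float | None  # mean pairwise RMSD after superposition

    @property
    def per_run_energies(self) -> list[float]:
        return [r.best_energy for r in self.runs]


def run_ensemble(
    bodies: Sequence[RigidBody],
    links: Sequence[CrossLink],
    config: SamplerConfig,
) -> EnsembleResult:
    """n_runs independent annealings with seeds config.seed + 1..n_runs.

    The precision proxy superposes every run-best model on the largest
    body of the minimum-energy run and reports the mean pairwise
    all-C-alpha RMSD, a rough analogue of ensemble cluster precision.
    """
    runs = [
        anneal(bodies, links, config, run_seed=config.seed + k)
        for k in range(1, config.n_runs + 1)
    ]
    best = min(runs, key=lambda r: r.best_energy)
    largest = int(np.argmax([b.size for b in bodies]))

    precision = None
    if len(runs) > 1:
        ref = best.best_coords
        aligned = []
        for r in runs:
            R, t = _kabsch(r.best_coords[largest], ref[largest])
            aligned.append(np.vstack([c @ R.T + t for c in r.best_coords]))
        rmsds = []
        for i in range(len(aligned)):
            for j in range(i + 1, len(aligned)):
                diff = aligned[i] - aligned[j]
                rmsds.append(float(np.sqrt(np.mean(np.sum(diff**2, axis=1)))))
        precision = float(np.mean(rmsds))

    return EnsembleResult(
        runs=runs,
        best=best,
        best_satisfied=max(r.satisfied_links for r in runs),
        precision_proxy=precision,
    )


def model_to_structure(
    bodies: Sequence[RigidBody],
    coords: Sequence[np.ndarray],
    name: str = "model",
    chain_id: str = "A",
) -> Structure:
    """A single-chain C-alpha Structure of a placement, original numbering.

    Linker residues are not modelled and therefore absent from the
    output (chain numbering keeps the gaps).
    """
    records = []
    for body, xyz in zip(bodies, coords):
        for offset, pos in enumerate(xyz):
            records.append(
                ResidueRecord(
                    chain_id=chain_id,
                    residue_index=body.start + offset,
                    aa_code="A",
                    ca_xyz=tuple(float(v) for v in pos),
                )
            )
    records.sort(key=lambda r: r.residue_index)
    return Structure(name=name, chains={chain_id: records})


def write_energy_log(runs: Sequence[AnnealResult], path: str | Path) -> None:
    """Per-run energy trace CSV (run_seed, frame, energy, best_energy)."""
    rows = []
    for r in runs:
        for frame, current, best in r.trace:
            rows.append(
                {
                    "run_seed": r.run_seed,
                    "frame": frame,
                    "energy": round(current, 6),
                    "best_energy": round(best, 6),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
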