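"""Synthetic structures and ensembles with known ground truth.

Four generators cover the inputs the analysis needs:

* :func:`make_linked_rings` — two closed discrete curves with an exact,
  construction-set linking number (torus-winding geometry), used to validate
  the discrete Gauss sum against a topological invariant.
* :func:`make_helix_wrap` — a single open chain containing one contact-closed
  loop wound a known signed number of turns around a straight thread placed
  on a requested side (N or C). The expected per-loop score is ≈ the winding
  number; handedness sets the sign.
* :func:`make_random_backbone` — compact self-avoiding fixed-bond random
  walks confined to a sphere, a protein-like decoy stand-in.
* :func:`make_planted_sequence_ensemble` — sequence-labeled ensembles whose
  entangled-loop-closing contacts are enriched in chosen amino-acid pairs by
  a known factor, so the inferred enrichment score has the closed-form ground
  truth −τ log(factor).

Synthetic traces carry Cα-only heavy-atom proxies: loop-closing contacts are
engineered directly at Cα distance ≤ 4.5 Å, which is all the Gauss-sum
geometry depends on.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .structure_io import AMINO_ACIDS, ChainTrace
from .gaussian import M0, LoopRecord, scan_loops

BOND_LENGTH = 3.8  # Å, consecutive Cα spacing


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic construction, serializable to JSON."""

    kind: str  # linked_rings | helix_wrap | random_backbone | planted_sequence_ensemble
    turns: int = 1
    side: str = "N"
    n_points: int = 64
    bond_length: float = BOND_LENGTH
    enrichment: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        return cls(**json.loads(text))


def _ca_only_trace(points: np.ndarray, trace_id: str,
                   residues: list[str] | None = None) -> ChainTrace:
    points = np.asarray(points, dtype=float)
    n = len(points)
    return ChainTrace(
        id=trace_id,
        calpha=points,
        residues=residues if residues is not None else ["G"] * n,
        heavy_atoms=[points[i:i + 1] for i in range(n)],
        sidechain_atoms=[points[i:i + 1] for i in range(n)],
    )


def make_linked_rings(
    turns: int, n_points: int = 64,
    radius: float = 20.0, tube_radius: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two closed polylines with exact linking number ``turns``.

    Ring A is a circle of ``radius`` in the xy-plane. Ring B runs once around
    the torus whose core is ring A while winding ``turns`` times poloidally,
    so each poloidal turn pierces the disk spanned by A exactly once; the
    linking number is therefore ``turns`` (sign from handedness). For
    ``turns = 0`` the rings are placed far apart and are unlinked.
    """
    if n_points < 16:
        raise ValueError("need at least 16 points per ring")
    if tube_radius <= 0 or tube_radius >= radius:
        raise ValueError("tube_radius must be in (0, radius)")
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    ring_a = np.column_stack(
        [radius * np.cos(t), radius * np.sin(t), np.zeros_like(t)]
    )
    if turns == 0:
        offset = np.array([5.0 * radius, 0.0, 0.0])
        ring_b = ring_a + offset
        return ring_a, ring_b
    # poloidal angle runs clockwise so that positive turns give a positive
    # Gauss linking sign under the right-hand convention
    rho = radius + tube_radius * np.cos(turns * t)
    ring_b = np.column_stack(
        [rho * np.cos(t), rho * np.sin(t), -tube_radius * np.sin(turns * t)]
    )
    return ring_a, ring_b


def _resample(path: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arclength spacing.

    The first and last vertices are preserved; the number of segments is
    rounded so the actual spacing stays within a few percent of the target.
    """
    path = np.asarray(path, dtype=float)
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    n_seg = max(1, int(round(total / spacing)))
    targets = np.linspace(0.0, total, n_seg + 1)
    out = np.empty((n_seg + 1, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, arclen, path[:, k])
    return out


def make_helix_wrap(
    turns: int,
    side: str = "N",
    bond_length: float = BOND_LENGTH,
    loop_radius: float = 8.0,
    pitch: float = 6.5,
    thread_half_length: float = 40.0,
    contact_distance: float = 4.0,
) -> ChainTrace:
    """Open chain with a contact-closed loop wound ``turns`` times around a
    straight thread on the requested ``side``.

    The loop is a helix of |turns| turns at ``loop_radius`` around the thread
    axis, closed by a wide rectangular return path at constant azimuth (which
    adds no net winding); its endpoints are brought to ``contact_distance``
    (≤ 4.5 Å) of each other, and that closure is the only contact at sequence
    separation ≥ 10 in the chain. For ``side="N"`` the chain runs thread →
    connector → loop; the ``side="C"`` chain is the same geometry traversed
    in reverse order, which leaves the Gauss score unchanged (both subchain
    orientations flip) while swapping which terminus precedes the loop.

    Expected per-loop score: ≈ ``turns`` (within a few percent, the deficit
    being the finite thread length); the sign follows the handedness of the
    winding.
    """
    if turns == 0:
        raise ValueError("turns must be nonzero")
    if side not in ("N", "C"):
        raise ValueError("side must be 'N' or 'C'")
    h = abs(turns) * pitch / 2.0
    rho0, rho1 = loop_radius, loop_radius + 14.0
    dense = 400  # dense parametric sampling before resampling to bond length

    # thread: straight segment along z, traversed upward
    thread = np.column_stack([
        np.zeros(2), np.zeros(2), np.array([-thread_half_length, thread_half_length])
    ])

    # connector: descends far outside the loop, then feeds the loop start
    # from the side the helix initially winds toward, where its final bonds
    # run nearly perpendicular to the loop's local field and pick up almost
    # no spurious winding (~1% in practice)
    sgn = 1.0 if turns > 0 else -1.0
    conn = np.array([
        [0.0, 0.0, thread_half_length],
        [rho1 + 10.0, 0.0, thread_half_length],
        [rho1 + 10.0, 0.0, -h],
        [rho1 + 10.0, sgn * 20.0, -h],
        [rho0, sgn * 20.0, -h],
        # stop 6.5 Å short of the loop start: close enough for chain
        # continuity, far enough that the feed cannot double the loop's
        # closing contact at Cα-proxy cutoffs up to ~6 Å
        [rho0, sgn * 6.5, -h],
    ])

    # loop: helix up (winding) + out + down + back in at constant azimuth
    s = np.linspace(0.0, 1.0, dense)
    phi = 2.0 * np.pi * turns * s
    helix = np.column_stack([
        rho0 * np.cos(phi), rho0 * np.sin(phi), -h + 2.0 * h * s
    ])
    ret = np.array([
        [rho0, 0.0, h],
        [rho1, 0.0, h],
        [rho1, 0.0, -h],
        [rho0 + contact_distance, 0.0, -h],
    ])
    loop_path = np.vstack([helix, ret[1:]])

    points = np.vstack([
        _resample(thread, bond_length),
        _resample(conn, bond_length)[1:],
        _resample(loop_path, bond_length),
    ])
    if side == "C":
        points = points[::-1].copy()
    return _ca_only_trace(points, f"helix_wrap_t{turns:+d}_{side}")


def make_random_backbone(
    n: int,
    bond: float = BOND_LENGTH,
    confinement_radius: float | None = None,
    seed: int = 0,
    min_distance: float = 4.0,
    max_restarts: int = 2000,
) -> ChainTrace:
    """Compact self-avoiding random walk with fixed Cα–Cα bonds.

    Successive points are placed at distance ``bond`` in a uniformly random
    direction, rejected if they leave the confinement sphere or come within
    ``min_distance`` of any non-adjacent previous point. Dead ends backtrack
    a few steps before retrying; a backtrack budget exhausted triggers a full
    restart. Generation is deterministic under ``seed``.
    """
    if n < 12:
        raise ValueError("n must be at least 12")
    if confinement_radius is None:
        confinement_radius = 3.1 * n ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)
    for _attempt in range(max_restarts):
        pts = np.empty((n, 3))
        pts[0] = rng.normal(size=3)
        pts[0] *= 0.3 * confinement_radius * rng.random() / np.linalg.norm(pts[0])
        i = 1
        backtracks = 50 * n
        while 0 < i < n:
            placed = False
            for _try in range(40):
                v = rng.normal(size=3)
                cand = pts[i - 1] + bond * v / np.linalg.norm(v)
                if np.linalg.norm(cand) > confinement_radius:
                    continue
                if i >= 2:
                    d = np.linalg.norm(pts[: i - 1] - cand, axis=1)
                    if d.min() < min_distance:
                        continue
                pts[i] = cand
                placed = True
                break
            if placed:
                i += 1
            else:
                backtracks -= 1
                if backtracks <= 0:
                    break
                i = max(1, i - int(rng.integers(1, 6)))
        if i == n:
            return _ca_only_trace(pts, f"rw_n{n}_s{seed}")
    raise RuntimeError(
        f"could not grow a self-avoiding walk (n={n}, "
        f"radius={confinement_radius:.1f}, seed={seed})"
    )


def make_backbone_pool(
    n_structures: int,
    n: int = 60,
    confinement_radius: float | None = None,
    seed: int = 0,
) -> list[ChainTrace]:
    """Ensemble of compact random backbones with distinct derived seeds."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_structures)
    return [
        make_random_backbone(n, confinement_radius=confinement_radius, seed=int(s))
        for s in seeds
    ]


def _pair_probability_matrix(base: np.ndarray) -> np.ndarray:
    """Ordered-pair label distribution for independently drawn labels."""
    return np.outer(base, base)


def make_wrap_pool(
    pool_size: int = 60, seed: int = 0,
    max_turns: int = 3,
) -> list[ChainTrace]:
    """Pool of helix-wrap geometries with varied winding, side and shape."""
    rng = np.random.default_rng(seed)
    pool = []
    combos = [
        (sign * t, s)
        for t in range(1, max_turns + 1)
        for sign in (1, -1)
        for s in ("N", "C")
    ]
    for k in range(pool_size):
        t, side = combos[k % len(combos)]
        trace = make_helix_wrap(
            turns=t, side=side,
            loop_radius=7.0 + 2.0 * rng.random(),
            pitch=6.3 + 0.7 * rng.random(),
            thread_half_length=35.0 + 10.0 * rng.random(),
        )
        trace.id = f"wrap_pool{k}"
        pool.append(trace)
    return pool


def make_planted_sequence_ensemble(
    n_structures: int,
    enrichment: dict[tuple[str, str] | str, float] | None = None,
    base_frequencies: np.ndarray | None = None,
    pool: list[ChainTrace] | None = None,
    pool_loops: list[list[LoopRecord]] | None = None,
    seed: int = 0,
    cutoff: float = 6.0,
    m0: int = M0,
    wrap_fraction: float = 0.5,
    pool_size: int = 96,
    backbone_n: int = 60,
) -> tuple[list[ChainTrace], list[list[LoopRecord]]]:
    """Sequence-labeled ensemble with planted entangled-contact enrichment.

    Geometry is drawn cyclically from a pool mixing helix-wrap structures
    (each carrying exactly one entangled loop with a clean closing contact)
    with loose random backbones that contribute the bulk of the normal
    contacts; each structure receives fresh labels. Labels are first drawn
    i.i.d. from ``base_frequencies`` (uniform by default), so generic pairs
    and normal contacts follow the independent-pair distribution. The residue
    pair closing each *entangled* loop — identified by running the
    entanglement scan on the geometry — is then redrawn jointly from that
    distribution with the requested ``enrichment`` factors applied.

    Because entangled contacts are a subset of the contacts entering the
    normal-contact frequencies, a planted factor φ would be diluted by its
    own contribution to f_c. The draw distribution is therefore corrected to
    q' = φ·p·(1−ε)/(1−φ·ε), with ε the entangled fraction of contacts in the
    geometry pool, so the *measured* frequency ratio between entangled and
    normal contacts is exactly φ in expectation and the ground-truth
    enrichment score is −τ log φ. Non-planted pairs absorb the leftover mass.

    ``cutoff`` defaults to 6.0 Å: synthetic traces carry Cα-only atom
    proxies, for which a Cα–Cα distance of ~6 Å plays the role that a 4.5 Å
    heavy-atom distance plays in full-atom structures.

    Returns the labeled traces together with per-structure loop records, so
    downstream counting need not rescan shared geometry.
    """
    rng = np.random.default_rng(seed)
    if base_frequencies is None:
        base = np.full(20, 1.0 / 20.0)
    else:
        base = np.asarray(base_frequencies, dtype=float)
        base = base / base.sum()
    if pool is None:
        n_wrap = int(round(pool_size * wrap_fraction))
        wraps = make_wrap_pool(n_wrap, seed=int(rng.integers(2**31 - 1)))
        backbones = make_backbone_pool(
            pool_size - n_wrap, n=backbone_n,
            confinement_radius=3.55 * backbone_n ** (1.0 / 3.0),
            seed=int(rng.integers(2**31 - 1)),
        )
        # interleave so any ensemble-size prefix mixes both kinds
        pool = [t for pair in zip(wraps, backbones) for t in pair]
        pool += wraps[len(backbones):] + backbones[len(wraps):]
    if pool_loops is None:
        pool_loops = [scan_loops(t, cutoff=cutoff, m0=m0) for t in pool]

    # entangled fraction of the contact universe, for the dilution correction
    usage = np.bincount(np.arange(n_structures) % len(pool), minlength=len(pool))
    n_contacts = n_entangled = 0
    from .gaussian import compute_contacts, enumerate_loops
    for geom, loops, u in zip(pool, pool_loops, usage):
        cmap = compute_contacts(geom, cutoff=cutoff, mode="sidechain_heavy")
        n_contacts += u * len(enumerate_loops(cmap, m0=m0))
        n_entangled += u * sum(r.entangled for r in loops)
    eps = n_entangled / max(1, n_contacts)

    pair_p = _pair_probability_matrix(base)  # ordered pairs
    factors = np.ones((20, 20))
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for key, phi in (enrichment or {}).items():
        if phi <= 0:
            raise ValueError("enrichment factors must be positive")
        a, b = (key[0], key[1]) if isinstance(key, str) else key
        factors[idx[a], idx[b]] = phi
        factors[idx[b], idx[a]] = phi
    planted_mask = factors != 1.0
    corrected = np.ones_like(factors)
    if planted_mask.any():
        if np.any(factors[planted_mask] * eps >= 1.0):
            raise ValueError(
                f"entangled contact fraction eps={eps:.2f} too large for the "
                "requested factors; add more normal-contact structures")
        corrected[planted_mask] = (
            factors[planted_mask] * (1.0 - eps)
            / (1.0 - factors[planted_mask] * eps)
        )
    enriched = pair_p * corrected
    planted_mass = enriched[planted_mask].sum()
    if planted_mass >= 1.0:
        raise ValueError("planted pair mass ≥ 1; reduce factors or base freqs")
    # leftover mass goes to the non-planted pairs
    rest_scale = (1.0 - planted_mass) / pair_p[~planted_mask].sum()
    enriched[~planted_mask] = pair_p[~planted_mask] * rest_scale
    flat_q = enriched.ravel() / enriched.sum()

    traces: list[ChainTrace] = []
    loops_out: list[list[LoopRecord]] = []
    aa = np.array(list(AMINO_ACIDS))
    for k in range(n_structures):
        geom = pool[k % len(pool)]
        loops = pool_loops[k % len(pool)]
        labels = rng.choice(20, size=geom.n, p=base)
        for rec in loops:
            if rec.entangled:
                pair = int(rng.choice(400, p=flat_q))
                labels[rec.i1], labels[rec.i2] = pair // 20, pair % 20
        trace = ChainTrace(
            id=f"{geom.id}_seq{k}",
            calpha=geom.calpha,
            residues=[str(x) for x in aa[labels]],
            heavy_atoms=geom.heavy_atoms,
            sidechain_atoms=geom.sidechain_atoms,
        )
        traces.append(trace)
        relabeled = [
            LoopRecord(i1=r.i1, i2=r.i2, g=r.g, j1=r.j1, j2=r.j2,
                       side=r.side, weight=r.weight, protein_id=trace.id)
            for r in loops
        ]
        loops_out.append(relabeled)
    return traces, loops_out


def make_side_planted_ensemble(
    n_structures: int,
    frac_n: float = 0.7,
    turns_choices: tuple[int, ...] = (1, -1, 2, -2),
    seed: int = 0,
) -> list[ChainTrace]:
    """Helix-wrap ensemble whose thread side is N with probability ``frac_n``."""
    rng = np.random.default_rng(seed)
    traces = []
    for k in range(n_structures):
        side = "N" if rng.random() < frac_n else "C"
        t = int(rng.choice(turns_choices))
        trace = make_helix_wrap(turns=t, side=side)
        trace.id = f"wrap{k}_{side}"
        traces.append(trace)
    return traces
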