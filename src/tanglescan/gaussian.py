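"""Gaussian entanglement of open subchains.

The mutual winding of two subchains of a Cα trace is measured by the
discretized Gauss double integral

    G'(γ_i, γ_j) = (1/4π) Σ_i Σ_j (R_i − R_j)/|R_i − R_j|³ · (ΔR_i × ΔR_j)

where R_i = (r_i + r_{i+1})/2 are bond midpoints and ΔR_i = r_{i+1} − r_i
bond vectors. For two closed curves this sum approximates the integer
linking number; on open subchains it is a real-valued entanglement score.

A *loop* is a subchain whose end residues form a heavy-atom contact
(distance ≤ 4.5 Å) at sequence separation ≥ m0 = 10. A *thread* is any
contiguous subchain of length ≥ m0, entirely on the N- or C-terminal side of
the loop and non-overlapping with it. Maximizing |G'| over threads gives the
per-loop score G'_c(i); the extremal (largest-modulus, sign kept) per-loop
score is the per-protein Gaussian entanglement G'_c, and the same extremum
restricted to pairs of contact-closed loops is the linking entanglement L'.

The O(n²) pairwise kernel is computed once per trace and turned into a 2D
prefix-sum table, after which the score of any subchain pair is an O(1)
rectangle sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ChainTrace

#: Heavy-atom contact cutoff (Å) closing a loop.
CONTACT_CUTOFF = 4.5
#: Minimum loop and thread length in residues.
M0 = 10
#: Minimum loop–thread sequence separation in residues.
S_MIN = 1
#: A loop is entangled when its best-thread score reaches this modulus.
ENTANGLED_THRESHOLD = 1.0


@dataclass
class BondGeometry:
    """Midpoints and bond vectors of a Cα trace."""

    midpoints: np.ndarray  # (n-1, 3)
    bond_vectors: np.ndarray  # (n-1, 3)

    @property
    def count(self) -> int:
        return len(self.midpoints)

    @classmethod
    def from_points(cls, points: np.ndarray) -> "BondGeometry":
        points = np.asarray(points, dtype=float)
        return cls(
            midpoints=0.5 * (points[:-1] + points[1:]),
            bond_vectors=np.diff(points, axis=0),
        )


def _pair_contributions(geo_a: BondGeometry, geo_b: BondGeometry) -> np.ndarray:
    """Matrix of Gauss-sum terms between two bond sets.

    Entry (i, j) is (1/4π)(R_i − R_j)/|R_i − R_j|³ · (ΔR_i × ΔR_j); pairs
    with coincident midpoints contribute 0.
    """
    diff = geo_a.midpoints[:, None, :] - geo_b.midpoints[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    cross = np.cross(
        geo_a.bond_vectors[:, None, :], geo_b.bond_vectors[None, :, :]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.einsum("ijk,ijk->ij", diff, cross) / dist**3
    terms[~np.isfinite(terms)] = 0.0
    return terms / (4.0 * np.pi)


@dataclass
class GaussKernel:
    """Pairwise Gauss-sum terms of one trace plus their 2D prefix table.

    ``prefix`` is padded: ``prefix[a, b]`` is the sum of ``pair_contributions``
    over rows < a and columns < b, so the score of residue ranges
    [i1, i2] × [j1, j2] (bonds i1..i2−1 and j1..j2−1) is the rectangle sum
    ``prefix[i2, j2] − prefix[i1, j2] − prefix[i2, j1] + prefix[i1, j1]``.
    """

    pair_contributions: np.ndarray
    prefix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        k = self.pair_contributions
        self.prefix = np.zeros((k.shape[0] + 1, k.shape[1] + 1))
        np.cumsum(np.cumsum(k, axis=0), axis=1, out=self.prefix[1:, 1:])

    @property
    def n_bonds(self) -> int:
        return self.pair_contributions.shape[0]

    def range_score(self, loop: tuple[int, int], other: tuple[int, int]) -> float:
        """Gauss score of residue ranges ``loop`` = (i1, i2) vs (j1, j2)."""
        (i1, i2), (j1, j2) = loop, other
        p = self.prefix
        return float(p[i2, j2] - p[i1, j2] - p[i2, j1] + p[i1, j1])


def build_kernel(trace: ChainTrace | np.ndarray) -> GaussKernel:
    """Precompute the Gauss kernel of a trace (O(n²) once per structure)."""
    points = trace.calpha if isinstance(trace, ChainTrace) else np.asarray(trace)
    geo = BondGeometry.from_points(points)
    terms = _pair_contributions(geo, geo)
    np.fill_diagonal(terms, 0.0)
    return GaussKernel(terms)


def gauss_pair_score(
    trace: ChainTrace | np.ndarray,
    loop: tuple[int, int],
    other: tuple[int, int],
    kernel: GaussKernel | None = None,
) -> float:
    """Gauss double sum between residue ranges ``loop`` and ``other``.

    A residue range [a, b] contributes bonds a..b−1. The two ranges must not
    overlap. Antisymmetric under reversing the orientation of one subchain,
    invariant under rigid motions, sign-flipping under mirror reflection.
    """
    (i1, i2), (j1, j2) = loop, other
    if not (i1 < i2 and j1 < j2):
        raise ValueError("each range must span at least one bond")
    if not (i2 <= j1 or j2 <= i1):
        raise ValueError(f"overlapping ranges {loop} and {other}")
    if kernel is None:
        kernel = build_kernel(trace)
    return kernel.range_score(loop, other)


def gauss_linking_closed(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Discrete Gauss sum between two *closed* polylines.

    The closing bond of each curve (last → first vertex) is included, so for
    well-resolved closed curves the result approximates the integer linking
    number.
    """

    def closed_geometry(curve: np.ndarray) -> BondGeometry:
        pts = np.vstack([np.asarray(curve, dtype=float), curve[0]])
        return BondGeometry.from_points(pts)

    terms = _pair_contributions(closed_geometry(curve_a), closed_geometry(curve_b))
    return float(terms.sum())


@dataclass
class ContactMap:
    """Residue pairs in spatial contact under a distance criterion."""

    contacts: list[tuple[int, int]]  # (i1, i2) with i1 < i2
    mode: str
    cutoff: float


def compute_contacts(
    trace: ChainTrace,
    cutoff: float = CONTACT_CUTOFF,
    mode: str = "any_heavy",
) -> ContactMap:
    """All residue pairs (i1 < i2) with atoms within ``cutoff`` Å.

    ``mode="any_heavy"`` uses every non-hydrogen atom (loop closure);
    ``mode="sidechain_heavy"`` uses side-chain heavy atoms only, falling back
    to all heavy atoms for residues without side-chain atoms (glycine).
    Sequence-separation thresholds are applied downstream.
    """
    if mode == "any_heavy":
        atom_sets: Sequence[np.ndarray] = trace.heavy_atoms
    elif mode == "sidechain_heavy":
        atom_sets = [
            s if len(s) else h
            for s, h in zip(trace.sidechain_atoms, trace.heavy_atoms)
        ]
    else:
        raise ValueError(f"unknown contact mode {mode!r}")
    coords = np.vstack(atom_sets)
    owner = np.repeat(np.arange(trace.n), [len(a) for a in atom_sets])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        ri, rj = owner[pairs[:, 0]], owner[pairs[:, 1]]
        lo, hi = np.minimum(ri, rj), np.maximum(ri, rj)
        keep = hi - lo >= 1
        contacts = sorted(set(zip(lo[keep].tolist(), hi[keep].tolist())))
    else:
        contacts = []
    return ContactMap(contacts=contacts, mode=mode, cutoff=cutoff)


def enumerate_loops(cmap: ContactMap, m0: int = M0) -> list[tuple[int, int]]:
    """Contact pairs at sequence separation ≥ m0, sorted by (i1, i2)."""
    return sorted((i1, i2) for i1, i2 in cmap.contacts if i2 - i1 >= m0)


@dataclass
class LoopRecord:
    """A contact-closed loop with its best (maximal |G'|) thread."""

    i1: int
    i2: int
    g: float = float("nan")
    j1: int | None = None
    j2: int | None = None
    side: str | None = None  # "N" or "C"
    weight: float = 1.0
    protein_id: str = ""

    @property
    def m(self) -> int:
        """Loop length in residues."""
        return self.i2 - self.i1

    @property
    def s(self) -> int | None:
        """Loop–thread sequence separation."""
        if self.side == "N":
            return self.i1 - self.j2
        if self.side == "C":
            return self.j1 - self.i2
        return None

    @property
    def has_thread(self) -> bool:
        return self.j1 is not None

    @property
    def entangled(self) -> bool:
        return self.has_thread and abs(self.g) >= ENTANGLED_THRESHOLD


def _side_candidates(lo: int, hi: int, m0: int) -> tuple[np.ndarray, np.ndarray]:
    """All (j1, j2) with lo ≤ j1, j2 ≤ hi, j2 − j1 ≥ m0, in lexicographic order."""
    if hi - lo < m0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    j1, j2 = np.triu_indices(hi - lo + 1, k=m0)
    return j1 + lo, j2 + lo


def best_thread(
    kernel: GaussKernel,
    loop: tuple[int, int],
    n: int,
    m0: int = M0,
    s_min: int = S_MIN,
) -> LoopRecord:
    """Scan every admissible thread of a loop and keep the extremal score.

    Threads are contiguous residue ranges (j1, j2) with j2 − j1 ≥ m0 lying
    entirely on one side of the loop at separation ≥ s_min. Ties are broken
    deterministically: N-side candidates are scanned before C-side ones, each
    side in lexicographic (j1, j2) order, and the first extremum wins.
    """
    i1, i2 = loop
    # cumulative column sums of the kernel strip spanned by the loop's bonds
    strip_cum = kernel.prefix[i2] - kernel.prefix[i1]  # length n_bonds + 1

    best: tuple[float, int, int, str] | None = None
    for side, lo, hi in (("N", 0, i1 - s_min), ("C", i2 + s_min, n - 1)):
        j1, j2 = _side_candidates(lo, hi, m0)
        if len(j1) == 0:
            continue
        scores = strip_cum[j2] - strip_cum[j1]
        k = int(np.argmax(np.abs(scores)))
        if best is None or abs(scores[k]) > abs(best[0]):
            best = (float(scores[k]), int(j1[k]), int(j2[k]), side)
    if best is None:
        return LoopRecord(i1=i1, i2=i2)
    g, j1b, j2b, side = best
    return LoopRecord(i1=i1, i2=i2, g=g, j1=j1b, j2=j2b, side=side)


@dataclass
class EntanglementResult:
    """Per-protein Gaussian entanglement G'_c and linking entanglement L'."""

    protein_ge: float = 0.0
    protein_le: float = 0.0
    argmax_loop: tuple[int, int] | None = None
    argmax_thread: tuple[int, int] | None = None
    argmax_loop_pair: tuple[tuple[int, int], tuple[int, int]] | None = None
    loops: list[LoopRecord] = field(default_factory=list)
    empty: bool = False


def scan_loops(
    trace: ChainTrace,
    cutoff: float = CONTACT_CUTOFF,
    m0: int = M0,
    s_min: int = S_MIN,
    contact_mode: str = "any_heavy",
    kernel: GaussKernel | None = None,
) -> list[LoopRecord]:
    """Per-loop best-thread records for one trace."""
    if kernel is None:
        kernel = build_kernel(trace)
    cmap = compute_contacts(trace, cutoff=cutoff, mode=contact_mode)
    records = []
    for i1, i2 in enumerate_loops(cmap, m0=m0):
        rec = best_thread(kernel, (i1, i2), trace.n, m0=m0, s_min=s_min)
        rec.protein_id = trace.id
        records.append(rec)
    return records


def protein_entanglement(
    trace: ChainTrace,
    cutoff: float = CONTACT_CUTOFF,
    m0: int = M0,
    s_min: int = S_MIN,
    contact_mode: str = "any_heavy",
) -> EntanglementResult:
    """Protein-level G'_c and L' with their argmax subchain pairs.

    G'_c is the extremal (largest modulus, sign kept) per-loop score; L' is
    the extremal Gauss score over unordered pairs of non-overlapping
    contact-closed loops, each of length ≥ m0. |L'| ≤ |G'_c| always, because
    a closing loop is in particular an admissible subchain of the wider
    thread maximization whenever it is admissible for L'.
    """
    kernel = build_kernel(trace)
    records = scan_loops(
        trace, cutoff=cutoff, m0=m0, s_min=s_min,
        contact_mode=contact_mode, kernel=kernel,
    )
    result = EntanglementResult(loops=records)
    scored = [r for r in records if r.has_thread]
    if not scored:
        result.empty = True
        return result
    top = max(scored, key=lambda r: abs(r.g))
    result.protein_ge = top.g
    result.argmax_loop = (top.i1, top.i2)
    result.argmax_thread = (top.j1, top.j2)

    loops = [(r.i1, r.i2) for r in records]
    best_le = 0.0
    best_pair = None
    for a in range(len(loops)):
        for b in range(a + 1, len(loops)):
            la, lb = loops[a], loops[b]
            # loops are sorted by (i1, i2), so lb can only follow la
            if lb[0] < la[1] + s_min:
                continue
            g = kernel.range_score(la, lb)
            if abs(g) > abs(best_le):
                best_le, best_pair = g, (la, lb)
    result.protein_le = best_le
    result.argmax_loop_pair = best_pair
    return result
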