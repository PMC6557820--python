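"""Reading protein structures into Cα-trace objects.

A :class:`ChainTrace` is the in-memory unit of the whole pipeline: the ordered
Cα coordinates of one chain (or domain), together with per-residue heavy-atom
and side-chain heavy-atom coordinate sets and one-letter amino-acid labels.
Structures with a gap larger than 10 Å between consecutive Cα atoms are
rejected by :func:`passes_continuity_filter`, because a chain break bridged by
a straight virtual bond can create entanglement that is an artifact of missing
coordinates rather than a feature of the fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

logger = logging.getLogger("tanglescan")

#: Default maximum allowed distance between consecutive Cα atoms (Å).
GAP_THRESHOLD = 10.0

#: Canonical one-letter codes in the fixed alphabetical order used by the
#: 20x20 potential matrices.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

# Common modified residues mapped to their parent amino acid; anything else
# non-standard is labeled "X" (kept in the geometric trace, excluded from
# sequence statistics).
_MODIFIED_PARENT = {
    "MSE": "M", "SEC": "C", "PYL": "K", "CSO": "C", "SEP": "S",
    "TPO": "T", "PTR": "Y", "HYP": "P", "MLY": "K", "KCX": "K",
    "CME": "C", "CSD": "C", "OCS": "C", "LLP": "K", "M3L": "K",
}

_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class StructureError(ValueError):
    """Raised for unreadable or empty structure files."""


@dataclass
class ChainTrace:
    """Cα trace of a single protein chain or domain.

    Parameters
    ----------
    id : str
        Identifier (e.g. a CATH domain name such as ``2bjuA02``).
    calpha : (n, 3) ndarray
        Ordered Cα coordinates in Å.
    residues : list of str
        One-letter amino-acid labels, ``"X"`` for unknowns.
    heavy_atoms : list of (k_i, 3) ndarray
        Per-residue coordinates of all non-hydrogen atoms.
    sidechain_atoms : list of (k_i, 3) ndarray
        Per-residue coordinates of side-chain non-hydrogen atoms. May be
        empty for glycine; consumers fall back to ``heavy_atoms`` then.
    author_numbers : list of str, optional
        Original author residue numbering (with insertion codes), kept only
        for reports.
    """

    id: str
    calpha: np.ndarray
    residues: list[str]
    heavy_atoms: list[np.ndarray]
    sidechain_atoms: list[np.ndarray]
    author_numbers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calpha = np.asarray(self.calpha, dtype=float)
        if self.calpha.ndim != 2 or self.calpha.shape[1] != 3:
            raise ValueError("calpha must be an (n, 3) array")
        n = len(self.calpha)
        if n < 2:
            raise ValueError("a ChainTrace needs at least 2 residues")
        if len(self.residues) != n or len(self.heavy_atoms) != n:
            raise ValueError("residues/heavy_atoms length mismatch with calpha")

    @property
    def n(self) -> int:
        return len(self.calpha)

    def bond_lengths(self) -> np.ndarray:
        """Distances between consecutive Cα atoms (Å), length ``n - 1``."""
        return np.linalg.norm(np.diff(self.calpha, axis=0), axis=1)

    def mirrored(self) -> "ChainTrace":
        """Mirror image (reflection through the xy-plane)."""
        flip = np.array([1.0, 1.0, -1.0])
        return ChainTrace(
            id=self.id + "_mirror",
            calpha=self.calpha * flip,
            residues=list(self.residues),
            heavy_atoms=[h * flip for h in self.heavy_atoms],
            sidechain_atoms=[s * flip for s in self.sidechain_atoms],
            author_numbers=list(self.author_numbers),
        )

    def reversed(self) -> "ChainTrace":
        """Trace with the chain direction reversed (N and C termini swapped)."""
        return ChainTrace(
            id=self.id + "_rev",
            calpha=self.calpha[::-1].copy(),
            residues=list(self.residues[::-1]),
            heavy_atoms=list(self.heavy_atoms[::-1]),
            sidechain_atoms=list(self.sidechain_atoms[::-1]),
            author_numbers=list(self.author_numbers[::-1]),
        )


def _residue_label(name: str) -> str:
    name = name.upper().strip()
    if name in _THREE_TO_ONE:
        return _THREE_TO_ONE[name]
    return _MODIFIED_PARENT.get(name, "X")


def read_structure(
    path: str | Path,
    format: str | None = None,
    chain: str | None = None,
    id: str | None = None,
) -> ChainTrace:
    """Parse a PDB or mmCIF file into a :class:`ChainTrace`.

    The first model is used; when alternate locations are present, the first
    one encountered per atom name is kept. Hydrogens (and deuteriums) are
    excluded from the heavy-atom sets. Residues lacking a Cα are dropped; the
    continuity filter then guards against the induced gap.

    Parameters
    ----------
    path : path to a structure file.
    format : "pdb" or "mmcif"; inferred from the file name when omitted.
    chain : chain identifier to select; required for multi-chain files.
    id : identifier for the trace; defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model = st[0]
    chains = [ch for ch in model]
    if chain is not None:
        chains = [ch for ch in chains if ch.name == chain]
        if not chains:
            raise StructureError(f"chain {chain!r} not found in {path}")
    elif len(chains) > 1:
        raise StructureError(
            f"{path} has {len(chains)} chains; pass an explicit chain selector"
        )
    if not chains:
        raise StructureError(f"no chains in {path}")

    calpha: list[np.ndarray] = []
    residues: list[str] = []
    heavy: list[np.ndarray] = []
    side: list[np.ndarray] = []
    numbers: list[str] = []
    for res in chains[0]:
        if res.is_water():
            continue
        seen: set[str] = set()
        ca = None
        h_coords: list[list[float]] = []
        s_coords: list[list[float]] = []
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            if atom.name in seen:  # keep first altloc only
                continue
            seen.add(atom.name)
            xyz = [atom.pos.x, atom.pos.y, atom.pos.z]
            h_coords.append(xyz)
            if atom.name == "CA":
                ca = np.array(xyz)
            elif atom.name not in _BACKBONE_ATOMS:
                s_coords.append(xyz)
        if ca is None:
            if h_coords:
                logger.debug("%s: residue %s has no CA, dropped", path, res.seqid)
            continue
        calpha.append(ca)
        residues.append(_residue_label(res.name))
        heavy.append(np.array(h_coords))
        side.append(np.array(s_coords).reshape(-1, 3))
        numbers.append(str(res.seqid))
    if len(calpha) == 0:
        raise StructureError(f"no Cα atoms found in {path}")
    if len(calpha) < 2:
        raise StructureError(f"fewer than 2 residues with Cα in {path}")
    return ChainTrace(
        id=id or path.stem,
        calpha=np.array(calpha),
        residues=residues,
        heavy_atoms=heavy,
        sidechain_atoms=side,
        author_numbers=numbers,
    )


def passes_continuity_filter(
    trace: ChainTrace, gap_threshold: float = GAP_THRESHOLD
) -> bool:
    """True iff no consecutive Cα–Cα distance exceeds ``gap_threshold`` (Å)."""
    return bool(np.all(trace.bond_lengths() <= gap_threshold))


def load_ensemble(
    source: str | Path | Iterable[str | Path],
    format: str | None = None,
    gap_threshold: float = GAP_THRESHOLD,
    chain: str | None = None,
) -> Iterator[ChainTrace]:
    """Stream filtered :class:`ChainTrace` objects from a directory, a list
    file (one path per line), or an iterable of paths.

    Unreadable files and traces failing the continuity filter are skipped
    with a logged warning.
    """
    paths: list[Path]
    if isinstance(source, (str, Path)):
        src = Path(source)
        if src.is_dir():
            exts = (".pdb", ".ent", ".cif", ".mmcif")
            paths = sorted(p for p in src.iterdir() if p.suffix.lower() in exts)
        elif src.is_file():
            paths = [Path(line.strip()) for line in src.read_text().splitlines()
                     if line.strip()]
        else:
            warnings.warn(f"ensemble source {src} not found; empty stream")
            return
    else:
        paths = [Path(p) for p in source]
    if not paths:
        warnings.warn("empty ensemble source")
        return
    for p in paths:
        try:
            trace = read_structure(p, format=format, chain=chain)
        except StructureError as exc:
            logger.warning("skipping %s: %s", p, exc)
            continue
        if not passes_continuity_filter(trace, gap_threshold):
            logger.warning("skipping %s: Cα gap > %.1f Å", p, gap_threshold)
            continue
        yield trace


def write_trace_pdb(trace: ChainTrace, path: str | Path) -> None:
    """Write a normalized, Cα-only PDB file for a trace (test fixtures).

    Only the Cα record of each residue is written; coordinates are rounded to
    the 1e-3 Å precision of the PDB format.
    """
    lines = []
    for i, (xyz, aa) in enumerate(zip(trace.calpha, trace.residues)):
        res3 = next((k for k, v in _THREE_TO_ONE.items() if v == aa), "UNK")
        lines.append(
            f"ATOM  {i + 1:5d}  CA  {res3} A{i + 1:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
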