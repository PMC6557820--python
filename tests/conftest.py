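"""Shared fixtures: hand-written PDB snippets and cached synthetic pools."""

from __future__ import annotations

import pytest

from tanglescan.gaussian import scan_loops
from tanglescan.synthetic import make_backbone_pool, make_wrap_pool


def format_pdb(residues) -> str:
    """Build PDB text from a list of (resname, [(atom, altloc, x, y, z), ...])."""
    lines = []
    serial = 1
    for resseq, (resname, atoms) in enumerate(residues, start=1):
        for name, altloc, x, y, z in atoms:
            elem = name.strip()[0]
            lines.append(
                f"ATOM  {serial:5d} {name:>4s}{altloc:1s}{resname:>3s} A"
                f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {elem:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def ca_residue(resname: str, x: float, y: float = 0.0, z: float = 0.0):
    return (resname, [(" CA ", " ", x, y, z)])


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Minimal 3-residue Cα-only chain with 3.8 Å bonds."""
    text = format_pdb([
        ca_residue("ALA", 0.0), ca_residue("GLY", 3.8), ca_residue("LYS", 7.6),
    ])
    path = tmp_path / "three.pdb"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def tight_backbones():
    """Compact random backbones that occasionally host entangled loops."""
    return make_backbone_pool(30, n=60, confinement_radius=11.0, seed=101)


@pytest.fixture(scope="session")
def loose_backbones():
    return make_backbone_pool(30, n=60, confinement_radius=13.9, seed=102)


@pytest.fixture(scope="session")
def sequence_pool():
    """Mixed wrap/backbone geometry pool with precomputed loop scans,
    shared by the sequence-statistics tests."""
    wraps = make_wrap_pool(48, seed=11)
    backbones = make_backbone_pool(
        48, n=60, confinement_radius=3.55 * 60 ** (1.0 / 3.0), seed=12)
    pool = wraps + backbones
    pool_loops = [scan_loops(t, cutoff=6.0) for t in pool]
    return pool, pool_loops
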