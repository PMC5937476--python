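import numpy as np
import pytest

from enzyvox.structure_io import BackboneTrace
from enzyvox.synthetic_fixtures import FixtureSpec, generate_trace
from enzyvox.voxelizer import VoxelizerConfig


def pdb_atom_line(serial, name, resname, chain, resseq, x, y, z,
                  altloc=" ", record="ATOM"):
    """Format one fixed-column PDB ATOM/HETATM record."""
    return (f"{record:<6s}{serial:5d} {name:^4s}{altloc}{resname:>3s} "
            f"{chain}{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"  1.00  0.00          {name.strip()[0]:>2s}")


def make_pdb(atoms, hetatms=(), tail=("END",)):
    """Assemble PDB text from (serial, name, resname, chain, resseq, xyz)."""
    lines = [pdb_atom_line(*a) for a in atoms]
    lines += [pdb_atom_line(*h, record="HETATM") for h in hetatms]
    return "\n".join(lines + list(tail)) + "\n"


@pytest.fixture
def three_residue_pdb(tmp_path):
    """3 residues x 4 backbone atoms, plus 2 HETATM waters and a CB atom."""
    atoms = []
    serial = 0
    for r in range(1, 4):
        for name, dx in (("N", 0.0), ("CA", 0.5), ("C", 1.0), ("O", 1.5)):
            serial += 1
            atoms.append((serial, name, "ALA", "A", r, 3.0 * r + dx, 1.0, 2.0))
        serial += 1
        atoms.append((serial, "CB", "ALA", "A", r, 3.0 * r, 2.5, 2.0))
    het = [(90, "O", "HOH", "A", 101, 20.0, 20.0, 20.0),
           (91, "O", "HOH", "A", 102, 21.0, 21.0, 21.0)]
    path = tmp_path / "abc1.pdb"
    path.write_text(make_pdb(atoms, het))
    return path


@pytest.fixture
def helix_trace() -> BackboneTrace:
    return generate_trace(FixtureSpec("helix", n_residues=50, seed=7))


@pytest.fixture
def vox_cfg() -> VoxelizerConfig:
    return VoxelizerConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
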