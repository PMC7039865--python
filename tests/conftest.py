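import numpy as np
import pytest

from porekit import pore_profile as pp
from porekit import synthetic_data as sd

def _pdb_line(record, serial, name, altloc, resname, chain, resseq,
              x, y, z, occ, element):
    name_f = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:5d} {name_f:<4s}{altloc:1s}{resname:<4s}"
        f"{chain:1s}{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
        f"{0.0:6.2f}          {element:>2s}\n"
    )


TOY_PDB = (
    "CRYST1   80.000   80.000  160.000  90.00  90.00  90.00 P 1           1\n"
    + _pdb_line("ATOM", 1, "CA", " ", "ALA", "A", 1, 10, 10, 10, 1.0, "C")
    + _pdb_line("HETATM", 2, "P", " ", "POPC", "L", 101, 20, 20, 60, 1.0, "P")
    + _pdb_line("HETATM", 3, "CL", " ", "CL", "I", 201, 30, 30, 80, 1.0, "CL")
    + "END\n"
)

ALTLOC_PDB = (
    _pdb_line("ATOM", 1, "CA", "A", "ALA", "A", 1, 10.0, 10, 10, 0.40, "C")
    + _pdb_line("ATOM", 2, "CA", "B", "ALA", "A", 1, 10.5, 10, 10, 0.60, "C")
    + _pdb_line("ATOM", 3, "CB", " ", "ALA", "A", 1, 11.0, 11, 11, 1.00, "C")
    + _pdb_line("ATOM", 4, "N", "A", "GLY", "A", 2, 12.0, 12, 12, 0.50, "N")
    + _pdb_line("ATOM", 5, "N", "B", "GLY", "A", 2, 12.5, 12, 12, 0.50, "N")
    + "END\n"
)


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


@pytest.fixture(scope="session")
def constant_channel():
    """30-slice channel of constant 3.0 Å pore radius, one frame."""
    spec = sd.ChannelSpec(radius_profile=sd.constant_profile(3.0), n_slices=30)
    return sd.make_channel_trajectory(spec, 1)


@pytest.fixture(scope="session")
def breathing_channel():
    """Constant-in-z pore of radius 1.7 Å on even frames, 2.2 Å on odd."""
    spec = sd.ChannelSpec(
        radius_profile=sd.alternating_profile(lambda z: 0.0, 1.7, 2.2),
        n_slices=30,
    )
    return sd.make_channel_trajectory(spec, 12)


@pytest.fixture(scope="session")
def channel_slab():
    """Slab well inside the 30-slice channel (z 50..79)."""
    return pp.MembraneSlab(55.0, 75.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
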