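import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cirperm.structure import Structure, structure_from_ca

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                  resseq: int, xyz, altloc: str = " ", occ: float = 1.0,
                  record: str = "ATOM") -> str:
    pad = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record:<6s}{serial:5d} {pad}{altloc}{resname:>3s} {chain}"
            f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {name[0]:>2s}")


@pytest.fixture
def three_residue_pdb() -> str:
    lines = [
        pdb_atom_line(1, "CA", "MET", "A", 1, (0.0, 0.0, 0.0)),
        pdb_atom_line(2, "CA", "LYS", "A", 2, (3.8, 0.0, 0.0)),
        pdb_atom_line(3, "CA", "VAL", "A", 3, (7.6, 0.0, 0.0)),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def messy_pdb() -> str:
    """Chain A with a HOH HETATM, an altloc pair, MSE, and author numbering
    starting at 5 with a gap."""
    lines = [
        pdb_atom_line(1, "CA", "GLY", "A", 5, (0.0, 0.0, 0.0)),
        pdb_atom_line(2, "CA", "ALA", "A", 6, (1.0, 0.0, 0.0), altloc="A",
                      occ=0.6),
        pdb_atom_line(3, "CA", "ALA", "A", 6, (2.0, 0.0, 0.0), altloc="B",
                      occ=0.4),
        pdb_atom_line(4, "CA", "MSE", "A", 8, (7.6, 0.0, 0.0)),
        pdb_atom_line(5, "O", "HOH", "A", 101, (9.0, 9.0, 9.0),
                      record="HETATM"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def pentamer() -> Structure:
    coords = np.array([[3.8 * i, 0.0, 0.0] for i in range(5)])
    return structure_from_ca("MKVLA", coords)
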