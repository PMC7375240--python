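import pytest
from hypothesis import settings

from cyslock import fixtures, structures

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_pocket():
    """Parameterized toy pocket with the anchor cysteine at A:107."""
    pdb = fixtures.make_toy_pocket(seed=1)
    struct = structures.read_structure(pdb, source_id="toy")
    anchor = structures.find_anchor(struct, "A", 107)
    pocket = structures.extract_pocket(struct, anchor)
    return structures.parameterize(pocket)


def atom_line(serial, name, resname, chain, resnum, x, y, z, element=None):
    """Hand-rolled PDB ATOM line for constructing edge-case inputs."""
    nm = name if len(name) == 4 else f" {name:<3s}"
    el = element if element is not None else name[0]
    return (
        f"ATOM  {serial:>5d} {nm} {resname:>3s} {chain}{resnum:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {el:>2s}"
    )
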