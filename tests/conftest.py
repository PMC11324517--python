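import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bindsight.structio import AtomRecord, Structure


def random_rotation(seed: int) -> np.ndarray:
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


def make_atom(
    serial,
    name,
    resname,
    chain,
    resseq,
    pos,
    element="C",
    altloc="",
):
    return AtomRecord(
        serial=serial,
        name=name,
        altloc=altloc,
        resname=resname,
        chain=chain,
        resseq=resseq,
        icode="",
        position=tuple(float(x) for x in pos),
        element=element,
    )


def hexagon(center, normal_tilt_deg=0.0, radius=1.4, resname="PHE", chain="A",
            resseq=1, start_serial=1):
    """Planar six-ring with standard aromatic atom names, tilted about x."""
    names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    a = np.radians(normal_tilt_deg)
    rot = np.array(
        [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
    )
    atoms = []
    for i, name in enumerate(names):
        th = np.radians(60.0 * i)
        local = np.array([radius * np.cos(th), radius * np.sin(th), 0.0])
        pos = rot @ local + np.asarray(center, dtype=float)
        atoms.append(make_atom(start_serial + i, name, resname, chain, resseq, pos))
    return atoms


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
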