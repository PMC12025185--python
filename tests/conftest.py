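import math

import numpy as np
import pytest

from modlys import synthetic_data as synth


def pdb_atom_line(
    serial,
    name,
    resname,
    chain,
    resnum,
    x,
    y,
    z,
    occ=1.00,
    altloc=" ",
    element="",
):
    name_field = f" {name:<3}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5} {name_field:<4}{altloc}{resname:>3} "
        f"{chain}{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


@pytest.fixture
def bridge_structure():
    """One Lys-Asp pair with NZ-OD1 at exactly 3.2 Å."""
    spec = synth.StructureSpec(
        placements=[
            synth.Placement("LYS", 1, "A", (0.0, 0.0, 0.0)),
            synth.Placement("ASP", 2, "A", (3.2, 0.0, 0.0)),
        ]
    )
    return synth.make_structure(spec)


def ring_of_lysines(n, radius=30.0, bridged=(), chain="A", start_number=1):
    """n lysines on a circle; indices in ``bridged`` get an Asp 3.0 Å below NZ."""
    placements = []
    number = start_number
    for i in range(n):
        theta = 2.0 * math.pi * i / n
        nz = (radius * math.cos(theta), radius * math.sin(theta), 0.0)
        placements.append(synth.Placement("LYS", number, chain, nz))
        number += 1
    for i in bridged:
        theta = 2.0 * math.pi * i / n
        od1 = (radius * math.cos(theta), radius * math.sin(theta), -3.0)
        placements.append(synth.Placement("ASP", number, chain, od1))
        number += 1
    return synth.StructureSpec(placements=placements)


@pytest.fixture
def eight_lys_structure():
    """8 well-separated (exposed) lysines, 4 of them salt-bridged to Asp."""
    return synth.make_structure(ring_of_lysines(8, bridged=(0, 1, 2, 3)))


@pytest.fixture
def noiseless_decay():
    def factory(kd, times=(0.0, 30.0, 60.0, 120.0, 180.0), a0=100.0):
        return synth.simulate_decay(
            synth.DecaySpec(kd_true=kd, A0=a0, times=np.asarray(times))
        )

    return factory
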