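import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from aquabridge.models import AtomRecord, ComplexStructure, Model


def make_atom(serial, xyz, name="CA", resname="ALA", chain="A", resseq=1, element="C"):
    return AtomRecord(
        serial=serial, name=name, resname=resname, chain=chain, resseq=resseq,
        icode="", x=xyz[0], y=xyz[1], z=xyz[2], element=element,
    )


def make_water(serial, xyz, resseq=None):
    return make_atom(
        serial, xyz, name="O", resname="HOH", chain="W",
        resseq=serial if resseq is None else resseq, element="O",
    )


@pytest.fixture
def random_complex():
    """A random two-chain model with waters scattered around it (seeded)."""

    def build(n_waters=200, n_res_per_chain=20, seed=0, spread=25.0):
        rng = np.random.default_rng(seed)
        m = Model()
        serial = 0
        for chain, z in (("A", 4.0), ("B", -4.0)):
            for i in range(n_res_per_chain):
                for name in ("CA", "CB"):
                    serial += 1
                    m.protein.append(
                        make_atom(
                            serial,
                            rng.uniform(-2, 2, 3) + [3.8 * i, 0.0, z],
                            name=name,
                            resname="ALA",
                            chain=chain,
                            resseq=i + 1,
                        )
                    )
        for k in range(n_waters):
            serial += 1
            m.waters.append(make_water(serial, rng.uniform(-spread, spread, 3) + [35.0, 0, 0]))
        return ComplexStructure(models=[m], source=f"random(seed={seed})")

    return build
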