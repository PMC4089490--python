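"""Shared fixtures: synthetic structures are generated once per session."""

import numpy as np
import pytest

from pyrinswitch.structure_model import Atom, Chain, Residue, Structure, select
from pyrinswitch.synthetic_structures import (
    BundleSpec,
    make_closed_bundle,
    make_open_dimer,
)


@pytest.fixture(scope="session")
def closed_bundle_R():
    """Closed six-helix bundle with the relay reconstituted (Arg at 84)."""
    return make_closed_bundle(BundleSpec(state="closed", central="R"))


@pytest.fixture(scope="session")
def closed_bundle_L():
    """Closed bundle with the wild-type-like broken relay (Leu at 84)."""
    return make_closed_bundle(BundleSpec(state="closed", central="L"))


@pytest.fixture(scope="session")
def open_dimer():
    """Open stem-helix C2 dimer, wild-type-like anchors (L84, D86)."""
    return make_open_dimer(BundleSpec(state="open-dimer"))


@pytest.fixture(scope="session")
def open_dimer_V86():
    """Open dimer with the acidic anchor removed (D86V)."""
    return make_open_dimer(BundleSpec(state="open-dimer", res86="V"))


def selection_from_coords(coords, elements=None):
    """Ad-hoc AtomSelection over bare coordinates (default: all carbon)."""
    coords = np.asarray(coords, dtype=float)
    elements = elements or ["C"] * len(coords)
    res = Residue(chain_id="A", number=1, name="ALA")
    for i, (c, el) in enumerate(zip(coords, elements)):
        res.atoms.append(Atom(serial=i + 1, name=f"{el}{i}", element=el, coords=c))
    s = Structure(id="adhoc", chains=[Chain("A", [res])])
    return select(s)
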