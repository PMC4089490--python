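"""Salt bridges, charge relay, core burial, switching elements, dimer axis."""

import copy
import itertools

import numpy as np
import pytest

from pyrinswitch.structure_model import Atom, Chain, Residue, Structure
from pyrinswitch.surface_geometry import buried_interface_area
from pyrinswitch.interaction_analysis import (
    ACIDIC_SIDECHAIN_ATOMS,
    BASIC_SIDECHAIN_ATOMS,
    detect_charge_relay,
    dimer_symmetry_axis,
    find_salt_bridges,
    hydrophobic_core,
    interface_charge_summary,
    switching_elements,
)
from pyrinswitch.synthetic_structures import (
    BundleSpec,
    make_closed_bundle,
    make_extended_chain,
    make_open_dimer,
)


def residue_with_atoms(chain_id, number, name, named_coords):
    res = Residue(chain_id, number, name)
    for i, (atom_name, coords) in enumerate(named_coords):
        res.atoms.append(
            Atom(i + 1, atom_name, atom_name[0], np.array(coords, float))
        )
    return res


def arg_glu_pair(no_distance):
    """Minimal Arg/Glu pair whose closest N-O distance is ``no_distance``."""
    arg = residue_with_atoms(
        "A", 1, "ARG",
        [("CA", [0, 0, 0]), ("NE", [1, 0, 0]), ("NH1", [0.5, 1, 0]), ("NH2", [0.5, -1, 0])],
    )
    glu = residue_with_atoms(
        "A", 2, "GLU",
        [("CA", [8, 0, 0]), ("OE1", [1 + no_distance, 0, 0]), ("OE2", [3 + no_distance, 1, 0])],
    )
    return Structure(id="pair", chains=[Chain("A", [arg, glu])])


def test_salt_bridge_detected_at_three_angstroms():
    bridges = find_salt_bridges(arg_glu_pair(3.0), cutoff=4.0)
    assert len(bridges) == 1
    b = bridges[0]
    assert b.basic_name == "ARG" and b.acidic_name == "GLU"
    assert b.min_distance == pytest.approx(3.0, abs=1e-9)
    assert not b.interchain


def test_salt_bridge_respects_cutoff():
    assert find_salt_bridges(arg_glu_pair(5.0), cutoff=4.0) == []


def test_salt_bridges_match_brute_force_enumeration(closed_bundle_R):
    s, _ = closed_bundle_R
    bridges = find_salt_bridges(s, cutoff=4.0)
    expected = set()
    residues = list(s.iter_residues())
    for basic, acidic in itertools.product(residues, residues):
        bnames = BASIC_SIDECHAIN_ATOMS.get(basic.name)
        anames = ACIDIC_SIDECHAIN_ATOMS.get(acidic.name)
        if not bnames or not anames:
            continue
        dmin = min(
            (
                float(np.linalg.norm(ab.coords - aa.coords))
                for ab in basic.atoms if ab.name in bnames
                for aa in acidic.atoms if aa.name in anames
            ),
            default=np.inf,
        )
        if dmin <= 4.0:
            expected.add((basic.key, acidic.key, round(dmin, 6)))
    got = {(b.basic_residue, b.acidic_residue, round(b.min_distance, 6)) for b in bridges}
    assert got == expected and len(got) > 0


def test_salt_bridges_rigid_motion_invariant(closed_bundle_R):
    from scipy.spatial.transform import Rotation

    s, _ = closed_bundle_R
    ref = {(b.basic_residue, b.acidic_residue) for b in find_salt_bridges(s)}
    moved = copy.deepcopy(s)
    rot = Rotation.from_euler("xyz", [33, -71, 12], degrees=True).as_matrix()
    for _, atom in moved.iter_atoms():
        atom.coords = rot @ atom.coords + np.array([-4.0, 9.0, 1.0])
    assert {(b.basic_residue, b.acidic_residue) for b in find_salt_bridges(moved)} == ref


def test_charge_relay_intact_broken_absent(closed_bundle_R, closed_bundle_L):
    intact_s, _ = closed_bundle_R
    call = detect_charge_relay(intact_s, "A")
    assert call.status == "intact"
    assert call.d_E_central <= 4.0 and call.d_central_D <= 4.0

    broken_s, _ = closed_bundle_L
    call = detect_charge_relay(broken_s, "A")
    assert call.status == "broken"
    assert call.d_E_central is None and call.d_central_D is None

    v86_s, _ = make_closed_bundle(BundleSpec(state="closed", central="R", res86="V"))
    assert detect_charge_relay(v86_s, "A").status == "broken"

    # anchor missing from the model -> absent, not an exception
    s = copy.deepcopy(intact_s)
    chain = s.chain("A")
    chain.residues = [r for r in chain.residues if r.number != 26]
    assert detect_charge_relay(s, "A").status == "absent"


def test_charge_relay_robust_to_noise():
    for seed in range(10):
        intact_s, _ = make_closed_bundle(
            BundleSpec(state="closed", central="R", noise_sigma=0.2, seed=seed)
        )
        assert detect_charge_relay(intact_s, "A").status == "intact"
        broken_s, _ = make_closed_bundle(
            BundleSpec(state="closed", central="L", noise_sigma=0.2, seed=seed)
        )
        assert detect_charge_relay(broken_s, "A").status == "broken"


def test_extended_chain_has_no_burial():
    s = make_extended_chain(30)
    result = hydrophobic_core(s, "A", list(range(5, 26)), n_points=240)
    assert all(f < 0.2 for f in result.burial_fraction.values())


def test_core_more_buried_than_surface(closed_bundle_R):
    s, _ = closed_bundle_R
    core = hydrophobic_core(s, "A", n_points=240)
    surface = [n for n in range(10, 96)
               if n not in core.core_residues and s.chain("A").residue(n)][:20]
    surf = hydrophobic_core(s, "A", surface, n_points=240)
    assert np.mean(list(core.burial_fraction.values())) > np.mean(
        list(surf.burial_fraction.values())
    )


def test_core_contact_larger_in_closed_than_open(closed_bundle_L, open_dimer):
    closed, _ = closed_bundle_L
    opened, _ = open_dimer
    closed_area = hydrophobic_core(closed, "A").core_contact_area
    open_area = hydrophobic_core(opened, "A").core_contact_area
    assert closed_area > open_area


def test_empty_core_list_rejected(closed_bundle_R):
    s, _ = closed_bundle_R
    with pytest.raises(ValueError):
        hydrophobic_core(s, "A", [])


def test_switching_elements_dual_engagement(closed_bundle_L, open_dimer):
    closed, _ = closed_bundle_L
    opened, labels = open_dimer
    report = switching_elements(closed, "A", opened, ("A", "B"))
    for num in labels["switch_residues"]:
        assert report.closed_verdict[num] == "core-engaged"
        assert report.open_verdict[num] == "dimer-engaged"
        assert report.closed_core_area[num] > 1.0
        assert report.open_interface_area[num] > 1.0


def test_switching_far_surface_residue_is_neither(closed_bundle_L, open_dimer):
    closed, _ = closed_bundle_L
    opened, _ = open_dimer
    # residue 30 sits in the alpha1-4 bundle, far from the dimer interface
    report = switching_elements(closed, "A", opened, ("A", "B"), residues=[30])
    assert report.open_verdict[30] == "neither"


def test_switching_missing_residue_reported_absent(closed_bundle_L, open_dimer):
    closed, _ = closed_bundle_L
    opened, _ = open_dimer
    report = switching_elements(closed, "A", opened, ("A", "B"), residues=[72, 999])
    assert report.closed_verdict[999] == "absent"
    assert report.open_verdict[999] == "absent"


def test_dimer_axis_recovers_planted_c2(open_dimer):
    s, labels = open_dimer
    result = dimer_symmetry_axis(s, "A", "B")
    assert result.is_twofold
    assert result.rotation_angle == pytest.approx(180.0, abs=0.1)
    planted = np.array(labels["c2_axis_direction"])
    cosang = abs(float(result.axis_direction @ planted))
    assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 1.0


def test_duplicated_monomer_warns_not_twofold(closed_bundle_R):
    s, _ = closed_bundle_R
    dup = copy.deepcopy(s)
    chain_b = copy.deepcopy(dup.chains[0])
    chain_b.chain_id = "B"
    for res in chain_b.residues:
        res.chain_id = "B"
        for atom in res.atoms:
            atom.coords = atom.coords + np.array([50.0, 0, 0])
    dup.chains.append(chain_b)
    with pytest.warns(UserWarning, match="not twofold"):
        result = dimer_symmetry_axis(dup, "A", "B")
    assert not result.is_twofold
    assert result.rotation_angle == pytest.approx(0.0, abs=1.0)


def test_interface_charge_summary_counts(open_dimer, open_dimer_V86):
    sD, _ = open_dimer
    sV, _ = open_dimer_V86
    ifD = buried_interface_area(sD, "A", "B")
    ifV = buried_interface_area(sV, "A", "B")
    cD = interface_charge_summary(sD, ifD)
    cV = interface_charge_summary(sV, ifV)
    # one acidic anchor per chain at the dyad: D86V removes exactly two
    assert cD["total"]["acidic"] - cV["total"]["acidic"] == 2
    assert cD["per_side"]["A"]["acidic"] - cV["per_side"]["A"]["acidic"] == 1
    # net charge counts acidic as -1
    assert cV["total"]["net_charge"] - cD["total"]["net_charge"] == 2


def test_interface_charge_summary_empty_interface(open_dimer):
    sD, _ = open_dimer
    far = copy.deepcopy(sD)
    for res in far.chain("B").residues:
        for atom in res.atoms:
            atom.coords = atom.coords + np.array([200.0, 0, 0])
    iface = buried_interface_area(far, "A", "B", n_points=240)
    summary = interface_charge_summary(far, iface)
    assert summary["total"] == {
        "acidic": 0, "basic": 0, "hydrophobic": 0, "polar": 0, "net_charge": 0
    }
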