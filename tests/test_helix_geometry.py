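"""Helix assignment, axis fitting, conformational calls and superposition."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pyrinswitch.structure_model import Atom, Chain, Residue, Structure
from pyrinswitch.helix_geometry import (
    HelixSegment,
    assign_helices,
    call_conformation,
    fit_helix_axis,
    interhelix_angle,
    superpose,
)
from pyrinswitch.synthetic_structures import BundleSpec, make_closed_bundle, make_ideal_helix, make_open_dimer


def chain_from_ca(ca_coords, start_resnum=1, chain_id="A"):
    residues = []
    for i, c in enumerate(ca_coords):
        residues.append(
            Residue(chain_id, start_resnum + i, "ALA",
                    atoms=[Atom(i + 1, "CA", "C", np.array(c, float))])
        )
    return Structure(id="test", chains=[Chain(chain_id, residues)])


def test_ideal_helix_yields_one_segment_covering_interior():
    ca = make_ideal_helix(20)["CA"]
    segments = assign_helices(chain_from_ca(ca), "A")
    assert len(segments) == 1
    seg = segments[0]
    assert seg.start_res <= 2 and seg.end_res >= 19
    assert seg.rise_per_residue == pytest.approx(1.5, abs=0.02)


def test_helix_linker_helix_yields_two_segments():
    h1 = make_ideal_helix(12)["CA"]
    # 4-residue extended linker then a second helix offset in x
    linker = np.array([h1[-1] + [3.8 * (i + 1), 0, 0] for i in range(4)])
    h2 = make_ideal_helix(12, origin=linker[-1] + [6.0, 0, -5.0])["CA"]
    s = chain_from_ca(np.vstack([h1, linker, h2]))
    segments = assign_helices(s, "A")
    assert len(segments) == 2


def test_numbering_gap_breaks_runs():
    ca = make_ideal_helix(24)["CA"]
    s = chain_from_ca(ca)
    # delete residue 12 -> two shorter helices
    chain = s.chain("A")
    chain.residues = [r for r in chain.residues if r.number != 12]
    segments = assign_helices(s, "A")
    assert len(segments) == 2


def test_axis_fit_direction_rise_and_equivariance():
    h = make_ideal_helix(20, direction=(1, 0, 0))["CA"]
    _, direction, rise, rms = fit_helix_axis(h)
    assert np.degrees(np.arccos(abs(direction @ np.array([1.0, 0, 0])))) < 1.0
    assert direction[0] > 0  # oriented N->C
    assert rise == pytest.approx(1.5, abs=0.02)
    # 4-CA window centers of an ideal helix ride a residual ~0.26 A helix
    assert rms < 0.5
    rot = Rotation.from_euler("zyx", [40, -25, 110], degrees=True).as_matrix()
    _, d2, _, _ = fit_helix_axis(h @ rot.T)
    expected = rot @ direction
    assert np.degrees(np.arccos(np.clip(d2 @ expected, -1, 1))) < 1.0


def test_axis_fit_robust_to_noise():
    base = make_ideal_helix(20)["CA"]
    for seed in range(20):
        rng = np.random.default_rng(seed)
        _, d, _, _ = fit_helix_axis(base + rng.normal(0, 0.3, base.shape))
        assert np.degrees(np.arccos(np.clip(abs(d[2]), -1, 1))) < 5.0


def test_axis_fit_requires_five_cas_and_nondegenerate():
    with pytest.raises(ValueError):
        fit_helix_axis(make_ideal_helix(4)["CA"])
    with pytest.raises(ValueError, match="degenerate"):
        fit_helix_axis(np.tile([[1.0, 2.0, 3.0]], (8, 1)))


def _segment_along(direction, flip=False):
    d = np.array(direction, float)
    d /= np.linalg.norm(d)
    if flip:
        d = -d
    return HelixSegment("A", 1, 10, np.zeros(3), d, 1.5, 0.0)


def test_interhelix_angle_cases():
    a = _segment_along([0, 0, 1])
    assert interhelix_angle(a, a) == pytest.approx(0.0, abs=1e-9)
    assert interhelix_angle(a, _segment_along([0, 0, 1], flip=True)) == pytest.approx(
        180.0, abs=3.0
    )
    assert interhelix_angle(a, _segment_along([0, 1, 0])) == pytest.approx(90.0, abs=3.0)


def test_helix_assignment_rigid_motion_invariant(closed_bundle_R):
    import copy

    s, _ = closed_bundle_R
    ref = [(g.start_res, g.end_res) for g in assign_helices(s, "A")]
    moved = copy.deepcopy(s)
    rot = Rotation.from_euler("xyz", [17, -62, 98], degrees=True).as_matrix()
    for _, atom in moved.iter_atoms():
        atom.coords = rot @ atom.coords + np.array([2.0, -7.0, 4.0])
    assert [(g.start_res, g.end_res) for g in assign_helices(moved, "A")] == ref


def test_helix_boundaries_stable_under_small_noise():
    ref_s, _ = make_closed_bundle(BundleSpec(state="closed"))
    ref = assign_helices(ref_s, "A")
    for seed in (1, 2, 3):
        s, _ = make_closed_bundle(BundleSpec(state="closed", noise_sigma=0.1, seed=seed))
        segs = assign_helices(s, "A")
        assert len(segs) == len(ref)
        for g, r in zip(segs, ref):
            assert abs(g.start_res - r.start_res) <= 1
            assert abs(g.end_res - r.end_res) <= 1


def test_conformation_calls_match_generator_labels(closed_bundle_R, open_dimer):
    closed, _ = closed_bundle_R
    call = call_conformation(closed, "A")
    assert call.state == "closed"
    assert call.inter_axis_angle >= 70.0
    assert not call.evidence["merged_segment"]
    opened, _ = open_dimer
    for cid in ("A", "B"):
        call = call_conformation(opened, cid)
        assert call.state == "open"
        assert call.junction_helical
        assert call.inter_axis_angle < 35.0
        assert call.evidence["merged_segment"]


def test_conformation_missing_range_rejected(closed_bundle_R):
    s, _ = closed_bundle_R
    with pytest.raises(ValueError, match="absent"):
        call_conformation(s, "A", (300, 320), (330, 350))


# --- Kabsch superposition --------------------------------------------------


def test_superpose_recovers_random_rigid_motions():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(12, 3))
    for _ in range(50):
        rot = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-20, 20, size=3)
        sup = superpose(x, x @ rot.T + t)
        assert sup.rmsd <= 1e-9
        assert np.allclose(sup.rotation, rot, atol=1e-6)
        assert np.allclose(sup.translation, t, atol=1e-6)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)


def test_superpose_identity_and_mirror():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(8, 3))
    sup = superpose(x, x)
    assert sup.rmsd <= 1e-9
    assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)
    mirror = x.copy()
    mirror[:, 2] *= -1
    sup_m = superpose(x, mirror)
    assert np.linalg.det(sup_m.rotation) == pytest.approx(1.0, abs=1e-9)
    assert sup_m.rmsd > 0.1


def test_superpose_degenerate_rejected():
    line = np.outer(np.arange(5.0), [1.0, 0, 0])
    with pytest.raises(ValueError):
        superpose(line, line)
    with pytest.raises(ValueError):
        superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def test_superpose_matches_scipy_align_vectors():
    rng = np.random.default_rng(5)
    for seed in range(5):
        x = rng.normal(size=(5, 3))
        y = rng.normal(size=(5, 3))
        sup = superpose(x, y)
        rot, rssd = Rotation.align_vectors(
            y - y.mean(axis=0), x - x.mean(axis=0)
        )
        assert sup.rmsd == pytest.approx(rssd / math.sqrt(len(x)), abs=1e-6)


def grid_min_rmsd(x, y, step_deg=4.0):
    """Brute-force optimal rmsd over an Euler-angle grid via tr(R H)."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = xc.T @ yc
    base = (np.sum(xc**2) + np.sum(yc**2)) / len(x)
    best = -np.inf
    alphas = np.deg2rad(np.arange(0, 360, step_deg))
    betas = np.deg2rad(np.arange(0, 180 + 1e-9, step_deg))
    gammas = np.deg2rad(np.arange(0, 360, step_deg))
    for beta in betas:
        angles = np.stack(
            np.meshgrid(alphas, [beta], gammas, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        mats = Rotation.from_euler("zyz", angles).as_matrix()
        traces = np.einsum("nij,ji->n", mats, h)
        best = max(best, float(traces.max()))
    return math.sqrt(max(base - 2 * best / len(x), 0.0))


def test_superpose_matches_rotation_grid_oracle():
    rng = np.random.default_rng(9)
    for _ in range(3):
        x = rng.normal(size=(5, 3))
        y = x @ Rotation.random(random_state=rng).as_matrix().T + rng.normal(
            0, 0.3, size=(5, 3)
        )
        opt = superpose(x, y).rmsd
        grid = grid_min_rmsd(x, y, step_deg=4.0)
        assert grid >= opt - 1e-9  # grid can never beat the optimum
        assert grid - opt <= 0.12  # within grid resolution


def test_rmsd_triangle_sanity():
    rng = np.random.default_rng(11)
    a = rng.normal(size=(10, 3))
    b = a + rng.normal(0, 0.2, size=(10, 3))
    c = a + rng.normal(0, 0.4, size=(10, 3))
    ab = superpose(a, b).rmsd
    bc = superpose(b, c).rmsd
    ac = superpose(a, c).rmsd
    assert ac <= ab + bc + 1e-9
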