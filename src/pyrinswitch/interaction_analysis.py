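"""Salt bridges, the Glu-Arg-Asp charge relay, hydrophobic-core burial and
dimer-symmetry summaries.

The charge relay is the triad that locks the closed six-helix pyrin-domain
bundle: an acidic anchor (position 26 in NLRP14 numbering), a central basic
residue (position 84) and a second acidic anchor (position 86).  A relay is
"intact" when the central residue is Arg/Lys and its side-chain nitrogens sit
within a salt-bridge cutoff of both anchors' carboxylate oxygens; substituting
the central residue with a hydrophobic one (Leu84, the NLRP14 wild type) or
removing an anchor charge (D86V) breaks it.

Distance cutoffs: 4.0 A between side-chain N and carboxylate O, the common
structural-biology convention for salt bridges; no cutoff is stated in the
primary literature for this system, so the value is a package decision and is
carried in every result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure_model import Residue, Structure, select
from .surface_geometry import (
    DEFAULT_N_POINTS,
    DEFAULT_PROBE,
    InterfaceResult,
    buried_interface_area,
    group_contact_area,
    sasa,
)
from .helix_geometry import superpose

__all__ = [
    "SaltBridge",
    "ChargeRelayCall",
    "SwitchReport",
    "DimerAxisResult",
    "CoreBurialResult",
    "BASIC_SIDECHAIN_ATOMS",
    "ACIDIC_SIDECHAIN_ATOMS",
    "DEFAULT_CORE_RESIDUES",
    "SWITCH_RESIDUES",
    "SALT_BRIDGE_CUTOFF",
    "find_salt_bridges",
    "detect_charge_relay",
    "hydrophobic_core",
    "switching_elements",
    "dimer_symmetry_axis",
    "interface_charge_summary",
]

SALT_BRIDGE_CUTOFF = 4.0  # A, side-chain N to carboxylate O

BASIC_SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
ACIDIC_SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

# Conserved hydrophobic core of the pyrin-domain six-helix bundle (NLRP14
# numbering): eleven canonical core residues plus the three switching
# residues Trp72/Leu76/Leu87 that alternate between core and dimer interface.
CANONICAL_CORE_RESIDUES = (15, 19, 22, 27, 30, 34, 58, 62, 71, 79, 82)
SWITCH_RESIDUES = (72, 76, 87)
DEFAULT_CORE_RESIDUES = CANONICAL_CORE_RESIDUES + SWITCH_RESIDUES

ACIDIC_RES = {"ASP", "GLU"}
BASIC_RES = {"LYS", "ARG", "HIS"}
HYDROPHOBIC_ONE = set("AVLIMFWPC")


@dataclass
class SaltBridge:
    basic_residue: tuple[str, int, str]  # residue key (chain, number, icode)
    acidic_residue: tuple[str, int, str]
    basic_name: str
    acidic_name: str
    min_distance: float
    interchain: bool


@dataclass
class ChargeRelayCall:
    chain_id: str
    anchor_E: int
    anchor_central: int
    anchor_D: int
    status: str  # intact | broken | absent
    central_name: str | None = None
    d_E_central: float | None = None
    d_central_D: float | None = None
    cutoff: float = SALT_BRIDGE_CUTOFF
    note: str = ""


@dataclass
class SwitchReport:
    residues: list[int]
    closed_core_area: dict[int, float]  # intramolecular contact in closed state
    open_interface_area: dict[int, float]  # per-residue burial in open dimer
    closed_verdict: dict[int, str]  # core-engaged | neither | absent
    open_verdict: dict[int, str]  # dimer-engaged | neither | absent
    engagement_threshold: float = 1.0  # A^2


@dataclass
class DimerAxisResult:
    axis_point: np.ndarray
    axis_direction: np.ndarray  # unit
    rotation_angle: float  # deg
    is_twofold: bool
    rmsd: float
    distances: list[tuple[tuple[str, int, str], float]] = field(default_factory=list)
    # ranked ascending: (residue key, side-chain-centroid distance to axis)

    def closest(self, n: int = 10) -> list[tuple[tuple[str, int, str], float]]:
        return self.distances[:n]


@dataclass
class CoreBurialResult:
    chain_id: str
    core_residues: list[int]
    burial_fraction: dict[int, float]
    core_contact_area: float


def _charged_atoms(res: Residue, table: dict[str, tuple[str, ...]]) -> np.ndarray:
    names = table.get(res.name, ())
    coords = [a.coords for a in res.atoms if a.name in names]
    return np.array(coords) if coords else np.empty((0, 3))


def find_salt_bridges(s: Structure, cutoff: float = SALT_BRIDGE_CUTOFF) -> list[SaltBridge]:
    """All basic/acidic residue pairs with a side-chain N..O contact <= cutoff.

    Pairs are aggregated per residue pair with the minimum N-O distance.
    Residues with missing side-chain atoms simply contribute no bridges.
    """
    basics: list[tuple[Residue, np.ndarray]] = []
    acidics: list[tuple[Residue, np.ndarray]] = []
    for res in s.iter_residues():
        if res.name in BASIC_SIDECHAIN_ATOMS:
            pts = _charged_atoms(res, BASIC_SIDECHAIN_ATOMS)
            if len(pts):
                basics.append((res, pts))
        elif res.name in ACIDIC_SIDECHAIN_ATOMS:
            pts = _charged_atoms(res, ACIDIC_SIDECHAIN_ATOMS)
            if len(pts):
                acidics.append((res, pts))
    bridges = []
    for bres, bpts in basics:
        for ares, apts in acidics:
            d = np.linalg.norm(bpts[:, None, :] - apts[None, :, :], axis=-1)
            dmin = float(d.min())
            if dmin <= cutoff:
                bridges.append(
                    SaltBridge(
                        basic_residue=bres.key,
                        acidic_residue=ares.key,
                        basic_name=bres.name,
                        acidic_name=ares.name,
                        min_distance=dmin,
                        interchain=bres.chain_id != ares.chain_id,
                    )
                )
    bridges.sort(key=lambda b: (b.basic_residue, b.acidic_residue))
    return bridges


def detect_charge_relay(
    s: Structure,
    chain_id: str,
    anchors: dict[str, int] | None = None,
    cutoff: float = SALT_BRIDGE_CUTOFF,
) -> ChargeRelayCall:
    """Structural status of the acidic/basic/acidic charge relay of one chain.

    ``anchors`` maps {"E": .., "central": .., "D": ..} to author residue
    numbers; the default is the NLRP14 numbering 26/84/86.  A missing anchor
    residue yields status "absent" (not an exception); a non-basic central
    residue or an over-cutoff distance yields "broken".
    """
    anchors = anchors or {"E": 26, "central": 84, "D": 86}
    chain = s.chain(chain_id)
    res_E = chain.residue(anchors["E"])
    res_C = chain.residue(anchors["central"])
    res_D = chain.residue(anchors["D"])
    call = ChargeRelayCall(
        chain_id=chain_id,
        anchor_E=anchors["E"],
        anchor_central=anchors["central"],
        anchor_D=anchors["D"],
        status="absent",
        cutoff=cutoff,
    )
    if res_E is None or res_C is None or res_D is None:
        missing = [
            n for n, r in zip(
                (anchors["E"], anchors["central"], anchors["D"]),
                (res_E, res_C, res_D),
            ) if r is None
        ]
        call.note = f"anchor residue(s) missing from model: {missing}"
        return call
    call.central_name = res_C.name
    if res_C.name not in ("ARG", "LYS"):
        call.status = "broken"
        call.note = f"central residue {res_C.name}{res_C.number} is not basic"
        return call
    n_pts = _charged_atoms(res_C, BASIC_SIDECHAIN_ATOMS)
    e_pts = _charged_atoms(res_E, ACIDIC_SIDECHAIN_ATOMS)
    d_pts = _charged_atoms(res_D, ACIDIC_SIDECHAIN_ATOMS)
    if not len(n_pts):
        call.status = "broken"
        call.note = "central residue side-chain nitrogens not modelled"
        return call
    if not len(e_pts) or not len(d_pts):
        call.status = "broken"
        which = []
        if not len(e_pts):
            which.append(f"{res_E.name}{res_E.number}")
        if not len(d_pts):
            which.append(f"{res_D.name}{res_D.number}")
        call.note = f"anchor(s) without carboxylate oxygens: {which}"
        return call
    d_ec = float(np.linalg.norm(n_pts[:, None] - e_pts[None], axis=-1).min())
    d_cd = float(np.linalg.norm(n_pts[:, None] - d_pts[None], axis=-1).min())
    call.d_E_central = d_ec
    call.d_central_D = d_cd
    if d_ec <= cutoff and d_cd <= cutoff:
        call.status = "intact"
    else:
        call.status = "broken"
        call.note = f"relay distance over cutoff (E-central {d_ec:.2f}, central-D {d_cd:.2f})"
    return call


def hydrophobic_core(
    s: Structure,
    chain_id: str,
    core_residues=DEFAULT_CORE_RESIDUES,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> CoreBurialResult:
    """Per-residue burial fractions and total core contact area of one chain.

    Burial fraction of residue i is 1 - SASA(i in chain) / SASA(i in its
    tripeptide context i-1..i+1), so a residue with no tertiary contacts
    scores near zero regardless of its backbone neighbours.  Core contact
    area is the averaged contact between the core side chains and all other
    atoms of the same chain.
    """
    core_residues = list(core_residues)
    if not core_residues:
        raise ValueError("empty core residue list")
    chain = s.chain(chain_id)
    present = {r.number for r in chain.residues}
    missing = [n for n in core_residues if n not in present]
    if missing:
        raise ValueError(f"core residues missing from chain {chain_id}: {missing}")

    whole = sasa(select(s, chains=chain_id), probe, n_points)
    burial: dict[int, float] = {}
    for num in core_residues:
        tri = select(s, chains=chain_id, resnums=[num - 1, num, num + 1])
        ref = sasa(tri, probe, n_points)
        key = next(k for k in ref.per_residue if k[1] == num)
        ref_area = ref.per_residue[key]
        in_chain = whole.per_residue.get(key, 0.0)
        burial[num] = 0.0 if ref_area <= 0 else max(0.0, 1.0 - in_chain / ref_area)

    core_sel = select(s, chains=chain_id, resnums=core_residues, sidechain=True)
    core_atom_ids = {id(a) for a in core_sel.atoms}
    rest = select(s, chains=chain_id)
    rest.pairs = [(r, a) for r, a in rest.pairs if id(a) not in core_atom_ids]
    rest.description = f"chain {chain_id} minus core side chains"
    area = group_contact_area(core_sel, rest, probe, n_points)
    return CoreBurialResult(
        chain_id=chain_id,
        core_residues=core_residues,
        burial_fraction=burial,
        core_contact_area=area,
    )


def switching_elements(
    closed: Structure,
    closed_chain: str,
    open_dimer: Structure,
    open_chains: tuple[str, str],
    residues=SWITCH_RESIDUES,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    threshold: float = 1.0,
) -> SwitchReport:
    """Dual-role accounting for the hydrophobic switching residues.

    For each residue: its side-chain contact area against the rest of the
    monomer in the closed structure (core engagement), and its per-residue
    burial in the open dimer's chain-chain interface (dimer engagement).
    Residue numbering must agree between the two structures.
    """
    residues = list(residues)
    closed_nums = {r.number for r in closed.chain(closed_chain).residues}
    open_nums = {r.number for r in open_dimer.chain(open_chains[0]).residues}

    closed_area: dict[int, float] = {}
    closed_verdict: dict[int, str] = {}
    for num in residues:
        if num not in closed_nums:
            closed_verdict[num] = "absent"
            continue
        sc = select(closed, chains=closed_chain, resnums=[num], sidechain=True)
        if len(sc) == 0:
            closed_verdict[num] = "absent"
            continue
        sc_ids = {id(a) for a in sc.atoms}
        rest = select(closed, chains=closed_chain)
        rest.pairs = [(r, a) for r, a in rest.pairs if id(a) not in sc_ids]
        area = group_contact_area(sc, rest, probe, n_points)
        closed_area[num] = area
        closed_verdict[num] = "core-engaged" if area > threshold else "neither"

    iface = buried_interface_area(
        open_dimer, open_chains[0], open_chains[1], probe, n_points
    )
    open_area: dict[int, float] = {}
    open_verdict: dict[int, str] = {}
    for num in residues:
        if num not in open_nums:
            open_verdict[num] = "absent"
            continue
        burial = iface.buried_per_residue.get((open_chains[0], num, ""), 0.0)
        open_area[num] = burial
        open_verdict[num] = "dimer-engaged" if burial > threshold else "neither"

    return SwitchReport(
        residues=residues,
        closed_core_area=closed_area,
        open_interface_area=open_area,
        closed_verdict=closed_verdict,
        open_verdict=open_verdict,
        engagement_threshold=threshold,
    )


def _sidechain_centroid(res: Residue) -> np.ndarray:
    sc = res.sidechain_atoms()
    atoms = sc if sc else res.atoms
    return np.mean([a.coords for a in atoms], axis=0)


def dimer_symmetry_axis(
    s: Structure, chain_a: str, chain_b: str, angle_tolerance: float = 15.0
) -> DimerAxisResult:
    """Molecular (noncrystallographic) twofold axis of a two-chain dimer.

    Chain A is superposed onto chain B over CA atoms matched by residue
    number; the rotation axis of that transform is the candidate dyad.  If
    the rotation angle is not within ``angle_tolerance`` of 180 deg a warning
    is issued and the result is flagged ``is_twofold=False``.  Distances of
    every residue's side-chain centroid to the axis are returned ranked
    ascending.
    """
    ca_a, ca_b = {}, {}
    for cid, store in ((chain_a, ca_a), (chain_b, ca_b)):
        for res in s.chain(cid).residues:
            ca = res.atom("CA")
            if ca is not None:
                store[res.number] = ca.coords
    common = sorted(set(ca_a) & set(ca_b))
    if len(common) < 3:
        raise ValueError(f"fewer than 3 matched residues between {chain_a} and {chain_b}")
    sup = superpose(
        np.array([ca_a[n] for n in common]), np.array([ca_b[n] for n in common])
    )
    rot, t = sup.rotation, sup.translation
    cos_theta = float(np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cos_theta)))
    is_twofold = abs(angle - 180.0) <= angle_tolerance
    if not is_twofold:
        warnings.warn(
            f"chain pair {chain_a}/{chain_b}: rotation angle {angle:.1f} deg "
            "is not twofold",
            stacklevel=2,
        )
    # axis direction: the rotation's +1 eigenvector
    evals, evecs = np.linalg.eig(rot)
    idx = int(np.argmin(np.abs(evals - 1.0)))
    direction = np.real(evecs[:, idx])
    direction /= np.linalg.norm(direction)
    # a point on the screw axis: minimum-norm solution of (I - R) p = t
    point, *_ = np.linalg.lstsq(np.eye(3) - rot, t, rcond=None)
    distances = []
    for res in s.iter_residues():
        c = _sidechain_centroid(res)
        v = c - point
        perp = v - np.dot(v, direction) * direction
        distances.append((res.key, float(np.linalg.norm(perp))))
    distances.sort(key=lambda kv: kv[1])
    return DimerAxisResult(
        axis_point=point,
        axis_direction=direction,
        rotation_angle=angle,
        is_twofold=is_twofold,
        rmsd=sup.rmsd,
        distances=distances,
    )


def interface_charge_summary(s: Structure, interface: InterfaceResult) -> dict:
    """Residue-class counts and net formal charge of the interface, per chain.

    A residue-level surrogate for a continuum electrostatic map: acidic (D/E),
    basic (K/R/H), hydrophobic (AVLIMFWPC), polar (rest).  Net charge counts
    K/R as +1 and D/E as -1; His is excluded from the net total (ambiguous
    protonation) although it is counted in the basic class.
    """
    by_key = {res.key: res for res in s.iter_residues()}
    sides = {}
    for side_name, chain_set in (("A", interface.chain_set_A), ("B", interface.chain_set_B)):
        counts = {"acidic": 0, "basic": 0, "hydrophobic": 0, "polar": 0}
        net = 0
        for key in interface.interface_residues:
            if key[0] not in chain_set:
                continue
            res = by_key[key]
            if res.name in ACIDIC_RES:
                counts["acidic"] += 1
                net -= 1
            elif res.name in BASIC_RES:
                counts["basic"] += 1
                if res.name != "HIS":
                    net += 1
            elif res.one_letter in HYDROPHOBIC_ONE:
                counts["hydrophobic"] += 1
            else:
                counts["polar"] += 1
        counts["net_charge"] = net
        sides[side_name] = counts
    total = {
        k: sides["A"][k] + sides["B"][k]
        for k in ("acidic", "basic", "hydrophobic", "polar", "net_charge")
    }
    return {"per_side": sides, "total": total}
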