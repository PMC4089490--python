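"""Ground-truth-labelled synthetic pyrin-domain geometries.

The generator emits three kinds of labelled inputs:

* idealized alpha helices (parametric backbone + CB),
* a "closed" six-helix bundle: helices packed antiparallel on a circle with
  ~10 A inter-axis spacing, core side chains pointing inward, and — when the
  central relay position carries Arg — the E/R/D charge-relay tips placed in
  contact,
* an "open" C2 dimer: helices 1-4 as in the bundle but the two C-terminal
  helices fused into one straight stem; two chains related by an exact
  180-degree rotation about a recorded axis, with the switching residues'
  side chains facing the partner stem,

plus planted-anchor family alignments for the sequence classifier.

The packing is schematic — a circular arrangement of ideal helices, not a
physically folded domain — so synthetic areas are meaningful only relative to
each other (closed vs open, bonded vs separated), never as absolute
reproductions of crystallographic interface areas.  Side chains extend to CB
only, except Arg/Lys/Asp/Glu/His which carry their charged-group atoms under
real atom names so that salt-bridge and relay detection exercise the same
code paths as on deposited structures.

All randomness (coordinate noise, family sequences) is driven by mandatory
integer seeds; identical spec + seed reproduces identical output bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cre_sequence import Alignment
from .structure_model import Atom, Chain, ONE_TO_THREE, Residue, Structure

__all__ = [
    "BundleSpec",
    "FIRST_RESNUM",
    "LAST_RESNUM",
    "HELIX_STARTS",
    "DEFAULT_HELIX_LENGTHS",
    "make_ideal_helix",
    "make_closed_bundle",
    "make_open_dimer",
    "make_extended_chain",
    "make_family_alignment",
    "default_sequence",
]

FIRST_RESNUM = 7
LAST_RESNUM = 96
HELIX_STARTS = (10, 24, 44, 55, 70, 84)
DEFAULT_HELIX_LENGTHS = (12, 16, 9, 11, 14, 13)  # spans 10-21, 24-39, 44-52,
# 55-65, 70-83, 84-96 in NLRP14 author numbering

RISE = 1.5  # A per residue
TWIST = 100.0  # deg per residue
HELIX_RADIUS = 2.3  # A, CA radius of an ideal alpha helix
BUNDLE_RADIUS = 10.0  # A, slot circle -> ~10 A neighbour inter-axis distance
STEM_SEPARATION = 10.5  # A between the two stem axes of the open dimer

# circular slot order 1,2,6,5,4,3 so that sequence-adjacent helices are
# spatial neighbours and helix 2 packs against helix 6 (the relay geometry)
SLOT_ANGLE = {1: 0.0, 2: 60.0, 6: 120.0, 5: 180.0, 4: 240.0, 3: 300.0}

CANONICAL_CORE = (15, 19, 22, 27, 30, 34, 58, 62, 71, 79, 82)
SWITCH = (72, 76, 87)
RELAY = {"E": 26, "central": 84, "D": 86}

# residues that define the fold and the relay, NLRP14 numbering
_SPECIALS = {
    10: "F", 15: "L", 19: "L", 21: "E", 22: "L", 24: "K", 26: "E", 27: "L",
    30: "F", 34: "L", 39: "E", 44: "L", 52: "K", 55: "R", 58: "L", 62: "M",
    65: "Y", 70: "K", 71: "A", 72: "W", 76: "L", 79: "F", 82: "M", 83: "N",
    84: "L", 86: "D", 87: "L", 90: "R", 95: "I", 96: "N",
}

# default distance from CA to the lead charged-tip atom, A
_TIP_LENGTH = {"R": 6.3, "K": 5.9, "D": 3.6, "E": 4.8, "H": 4.2}
_RELAY_TIP_GAP = 2.6  # designed lead-tip separation inside an intact relay


def default_sequence(central: str = "L", res86: str = "D") -> str:
    """Default threaded sequence over residues 7..96 (NLRP14-like anchors)."""
    chars = []
    for num in range(FIRST_RESNUM, LAST_RESNUM + 1):
        if num == 84:
            chars.append(central)
        elif num == 86:
            chars.append(res86)
        else:
            chars.append(_SPECIALS.get(num, "A"))
    return "".join(chars)


@dataclass
class BundleSpec:
    helix_lengths: tuple[int, ...] = DEFAULT_HELIX_LENGTHS
    state: str = "closed"  # closed | open-dimer
    central: str = "L"  # residue threaded at relay position 84
    res86: str = "D"  # residue threaded at anchor position 86
    sequence: str | None = None  # full override, indexed from FIRST_RESNUM
    noise_sigma: float = 0.0  # A, iid Gaussian on every coordinate
    seed: int = 0

    def resolved_sequence(self) -> str:
        if self.sequence is not None:
            need = LAST_RESNUM - FIRST_RESNUM + 1
            if len(self.sequence) < need:
                raise ValueError(
                    f"sequence must cover residues {FIRST_RESNUM}..{LAST_RESNUM} "
                    f"({need} residues), got {len(self.sequence)}"
                )
            return self.sequence
        return default_sequence(self.central, self.res86)

    def spans(self) -> list[tuple[int, int]]:
        if len(self.helix_lengths) != 6:
            raise ValueError("helix_lengths must have 6 entries")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        spans = []
        for start, length in zip(HELIX_STARTS, self.helix_lengths):
            if length < 4:
                raise ValueError("helix length must be >= 4")
            spans.append((start, start + length - 1))
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if e0 >= s1:
                raise ValueError(f"helix spans overlap: ..{e0} vs {s1}..")
        if spans[-1][1] > LAST_RESNUM:
            raise ValueError("helix 6 extends past the last residue")
        return spans


def _frame_for(direction: np.ndarray) -> np.ndarray:
    """Deterministic rotation matrix whose third column is ``direction``."""
    w = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("zero direction vector")
    w = w / norm
    # keep the in-plane phase convention fixed for the +-z axes the bundle
    # builder relies on: +z is the identity, -z a flip about x
    if w[2] > 0.999:
        return np.eye(3)
    if w[2] < -0.999:
        return np.diag([1.0, -1.0, -1.0])
    ref = np.array([0.0, 0.0, 1.0])
    u = np.cross(ref, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.column_stack([u, v, w])


def make_ideal_helix(
    n_res: int,
    rise: float = RISE,
    twist: float = TWIST,
    radius: float = HELIX_RADIUS,
    origin=(0.0, 0.0, 0.0),
    direction=(0.0, 0.0, 1.0),
    phase0: float = 0.0,
) -> dict[str, np.ndarray]:
    """Parametric ideal alpha helix: N, CA, C, O backbone plus CB.

    Backbone atoms ride on the smooth helix curve (N and C at +-0.35 residue
    offsets from CA, O radially displaced from C); CB points radially outward
    from the helix axis.  With the defaults, consecutive CA-CA distances are
    ~3.83 A and CA(i)..CA(i+3) distances ~5.05 A.
    """
    if n_res < 4:
        raise ValueError("n_res must be >= 4")
    frame = _frame_for(direction)
    origin = np.asarray(origin, dtype=float)
    omega = math.radians(twist)
    phase = math.radians(phase0)

    def curve(t: float) -> np.ndarray:
        a = phase + t * omega
        return np.array([radius * math.cos(a), radius * math.sin(a), t * rise])

    def radial(t: float) -> np.ndarray:
        a = phase + t * omega
        return np.array([math.cos(a), math.sin(a), 0.0])

    out = {name: np.empty((n_res, 3)) for name in ("N", "CA", "C", "O", "CB")}
    for i in range(n_res):
        ca = curve(i)
        out["N"][i] = curve(i - 0.35)
        out["CA"][i] = ca
        c = curve(i + 0.35)
        out["C"][i] = c
        out["O"][i] = c + 1.23 * radial(i + 0.35)
        out["CB"][i] = ca + 1.53 * radial(i)
    for name in out:
        out[name] = out[name] @ frame.T + origin
    return out


def _perp_unit(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.999:
        ref = np.array([1.0, 0.0, 0.0])
    p = np.cross(u, ref)
    return p / np.linalg.norm(p)


def _charged_sidechain(code: str, ca: np.ndarray, u: np.ndarray, tip: np.ndarray | None):
    """Schematic charged side chain: named atoms from CB out to the tip group.

    ``tip`` pins the lead charged atom exactly (relay construction); otherwise
    the tip sits at the residue type's default reach along ``u``.
    """
    if tip is None:
        tip = ca + _TIP_LENGTH[code] * u
    else:
        u = tip - ca
        u = u / np.linalg.norm(u)
    cb = ca + 1.53 * u
    perp = _perp_unit(u)

    def between(f: float) -> np.ndarray:
        return cb + f * (tip - cb)

    if code == "R":
        return [
            ("CB", cb), ("CG", between(0.3)), ("CD", between(0.55)),
            ("CZ", between(0.85)),
            ("NE", tip), ("NH1", tip + 0.6 * u + 1.0 * perp),
            ("NH2", tip + 0.6 * u - 1.0 * perp),
        ]
    if code == "K":
        return [
            ("CB", cb), ("CG", between(0.3)), ("CD", between(0.55)),
            ("CE", between(0.8)), ("NZ", tip),
        ]
    if code == "D":
        return [
            ("CB", cb), ("CG", between(0.55)),
            ("OD1", tip), ("OD2", tip - 0.7 * u + 1.0 * perp),
        ]
    if code == "E":
        return [
            ("CB", cb), ("CG", between(0.35)), ("CD", between(0.7)),
            ("OE1", tip), ("OE2", tip - 0.7 * u + 1.0 * perp),
        ]
    if code == "H":
        return [
            ("CB", cb), ("CG", between(0.5)),
            ("ND1", tip), ("NE2", tip - 0.8 * u + 0.9 * perp),
        ]
    raise ValueError(f"not a charged residue code: {code}")


def _element_of_name(name: str) -> str:
    return name[0]


def _build_chain(chain_id: str, records: list[tuple[int, str, list[tuple[str, np.ndarray]]]]):
    """records: (resnum, one_letter, [(atom_name, coords), ...]) in order."""
    chain = Chain(chain_id=chain_id)
    for num, letter, atoms in records:
        res = Residue(
            chain_id=chain_id,
            number=num,
            name=ONE_TO_THREE.get(letter, "ALA"),
        )
        for atom_name, coords in atoms:
            res.atoms.append(
                Atom(
                    serial=0,
                    name=atom_name,
                    element=_element_of_name(atom_name),
                    coords=np.array(coords, dtype=float),
                )
            )
        chain.residues.append(res)
    return chain


def _renumber_serials(s: Structure) -> None:
    serial = 0
    for _, atom in s.iter_atoms():
        serial += 1
        atom.serial = serial


def _monomer_records(
    spec: BundleSpec,
    open_state: bool,
    stem_axis_xy: tuple[float, float] = (0.0, 0.0),
) -> tuple[list, dict]:
    """Shared monomer construction for the closed bundle and the open chain.

    Returns (records, info) where info carries CA positions and geometry
    needed by the dimer assembly.
    """
    seq = spec.resolved_sequence()
    spans = spec.spans()

    def letter(num: int) -> str:
        return seq[num - FIRST_RESNUM]

    bundle_center = np.zeros(3)
    if open_state:
        bundle_center = np.array([stem_axis_xy[0] + BUNDLE_RADIUS, stem_axis_xy[1], 0.0])

    # --- CA scaffolds per helix ------------------------------------------
    helix_atoms: dict[int, dict[str, np.ndarray]] = {}
    helix_axis: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    n_helices = 4 if open_state else 6
    for k in range(1, n_helices + 1):
        start, end = spans[k - 1]
        length = end - start + 1
        theta = math.radians(SLOT_ANGLE[k])
        axis_xy = bundle_center[:2] + BUNDLE_RADIUS * np.array(
            [math.cos(theta), math.sin(theta)]
        )
        up = k % 2 == 1
        half = (length - 1) * RISE / 2.0
        if up:
            origin = np.array([axis_xy[0], axis_xy[1], -half])
            direction = (0.0, 0.0, 1.0)
        else:
            origin = np.array([axis_xy[0], axis_xy[1], half])
            direction = (0.0, 0.0, -1.0)
        helix_atoms[k] = make_ideal_helix(
            length, origin=origin, direction=direction, phase0=40.0 * k
        )
        helix_axis[k] = (np.array([axis_xy[0], axis_xy[1], 0.0]), np.array(direction))

    stem_span = None
    if open_state:
        # helices 5+6 fused into one straight stem along +z
        stem_start = spans[4][0]
        stem_end = spans[5][1]
        stem_len = stem_end - stem_start + 1
        # phase chosen so switching residue 72 faces the dimer twofold axis
        phase0 = 150.0 - (72 - stem_start) * TWIST
        origin = np.array([stem_axis_xy[0], stem_axis_xy[1], 0.0])
        helix_atoms[0] = make_ideal_helix(
            stem_len, origin=origin, direction=(0.0, 0.0, 1.0), phase0=phase0
        )
        helix_axis[0] = (origin, np.array([0.0, 0.0, 1.0]))
        stem_span = (stem_start, stem_end)

    def span_of(num: int):
        if stem_span and stem_span[0] <= num <= stem_span[1]:
            return 0, stem_span
        for k in range(1, n_helices + 1):
            s0, e0 = spans[k - 1]
            if s0 <= num <= e0:
                return k, (s0, e0)
        return None, None

    # --- CA positions for every residue (helix + interpolated linkers) ---
    ca_pos: dict[int, np.ndarray] = {}
    for num in range(FIRST_RESNUM, LAST_RESNUM + 1):
        k, sp = span_of(num)
        if k is not None:
            ca_pos[num] = helix_atoms[k]["CA"][num - sp[0]]
    all_nums = list(range(FIRST_RESNUM, LAST_RESNUM + 1))
    helix_nums = sorted(ca_pos)
    for num in all_nums:
        if num in ca_pos:
            continue
        prev = max((n for n in helix_nums if n < num), default=None)
        nxt = min((n for n in helix_nums if n > num), default=None)
        if prev is None:
            # N-terminal tail: extend away from the first helix start
            anchor = ca_pos[nxt]
            after = ca_pos[nxt + 1]
            direction = anchor - after
            direction /= np.linalg.norm(direction)
            ca_pos[num] = anchor + (nxt - num) * 3.8 * direction
        elif nxt is None:
            anchor = ca_pos[prev]
            before = ca_pos[prev - 1]
            direction = anchor - before
            direction /= np.linalg.norm(direction)
            ca_pos[num] = anchor + (num - prev) * 3.8 * direction
        else:
            f = (num - prev) / (nxt - prev)
            ca_pos[num] = ca_pos[prev] + f * (ca_pos[nxt] - ca_pos[prev])

    # --- relay tip targets (closed state only) ----------------------------
    relay_tips: dict[int, np.ndarray] = {}
    if not open_state:
        p = (ca_pos[RELAY["E"]] + ca_pos[RELAY["central"]] + ca_pos[RELAY["D"]]) / 3.0
        relay_tips[RELAY["central"]] = p
        for num in (RELAY["E"], RELAY["D"]):
            away = ca_pos[num] - p
            away /= np.linalg.norm(away)
            relay_tips[num] = p + _RELAY_TIP_GAP * away

    # residues whose side chain faces the dimer partner in the open state
    face_partner = set(SWITCH) | {86} if open_state else set()

    def sidechain_direction(num: int) -> np.ndarray:
        ca = ca_pos[num]
        if open_state and num in face_partner:
            horiz = np.array([ca[0], ca[1], 0.0])
            n = np.linalg.norm(horiz)
            return -horiz / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])
        if num in CANONICAL_CORE or num in SWITCH:
            k, _ = span_of(num)
            # knobs-into-holes: bundle core residues bury their side chain
            # against the nearest OTHER helix of the bundle.  Core residues
            # stranded on the open stem keep the default outward
            # orientation — their exposure IS the open state.
            if not open_state or (k is not None and k >= 1):
                best = None
                for j in range(1, n_helices + 1):
                    if j == k:
                        continue
                    axis_point, _ = helix_axis[j]
                    v = np.array([axis_point[0] - ca[0], axis_point[1] - ca[1], 0.0])
                    dist = np.linalg.norm(v)
                    if best is None or dist < best[0]:
                        best = (dist, v)
                if best is not None and best[0] > 1e-9:
                    return best[1] / best[0]
        k, _ = span_of(num)
        if k is not None:
            axis_point, _ = helix_axis[k]
            out = np.array([ca[0] - axis_point[0], ca[1] - axis_point[1], 0.0])
        else:
            out = np.array([ca[0] - bundle_center[0], ca[1] - bundle_center[1], 0.0])
        n = np.linalg.norm(out)
        return out / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])

    # --- assemble residue records ----------------------------------------
    records = []
    for num in all_nums:
        code = letter(num)
        k, sp = span_of(num)
        atoms: list[tuple[str, np.ndarray]] = []
        if k is not None:
            idx = num - sp[0]
            for name in ("N", "CA", "C", "O"):
                atoms.append((name, helix_atoms[k][name][idx]))
        else:
            atoms.append(("CA", ca_pos[num]))
        if code != "G":
            u = sidechain_direction(num)
            if code in _TIP_LENGTH:
                tip = relay_tips.get(num)
                if tip is None and open_state and num in face_partner:
                    # pin the tip short of the twofold axis so the two
                    # symmetry mates do not collide head-on
                    ca = ca_pos[num]
                    horiz = np.array([ca[0], ca[1], 0.0])
                    rho = np.linalg.norm(horiz)
                    reach = min(_TIP_LENGTH[code], max(rho - 1.6, 2.2))
                    tip = ca + reach * u
                atoms.extend(_charged_sidechain(code, ca_pos[num], u, tip))
            else:
                atoms.append(("CB", ca_pos[num] + 1.53 * u))
        records.append((num, code, atoms))

    info = {"ca_pos": ca_pos, "bundle_center": bundle_center, "spans": spans}
    return records, info


def _apply_noise(s: Structure, sigma: float, seed: int) -> None:
    if sigma <= 0:
        return
    rng = np.random.default_rng(seed)
    for _, atom in s.iter_atoms():
        atom.coords = atom.coords + rng.normal(0.0, sigma, size=3)


def make_closed_bundle(spec: BundleSpec) -> tuple[Structure, dict]:
    """Closed six-helix bundle monomer (chain A) with ground-truth labels."""
    if spec.state != "closed":
        raise ValueError(f"spec.state is {spec.state!r}, expected 'closed'")
    records, info = _monomer_records(spec, open_state=False)
    s = Structure(
        id=f"synthetic-closed-{spec.central}84-{spec.res86}86",
        chains=[_build_chain("A", records)],
        metadata={"generator": "make_closed_bundle", "seed": spec.seed,
                  "noise_sigma": spec.noise_sigma},
    )
    _apply_noise(s, spec.noise_sigma, spec.seed)
    _renumber_serials(s)
    s.validate()
    seq = spec.resolved_sequence()
    labels = {
        "state": "closed",
        "central": seq[84 - FIRST_RESNUM],
        "res86": seq[86 - FIRST_RESNUM],
        "relay": "intact" if (
            seq[26 - FIRST_RESNUM] in "ED"
            and seq[84 - FIRST_RESNUM] in "RK"
            and seq[86 - FIRST_RESNUM] in "ED"
        ) else "broken",
        "core_residues": list(CANONICAL_CORE + SWITCH),
        "switch_residues": list(SWITCH),
        "helix_spans": info["spans"],
    }
    return s, labels


def make_open_dimer(spec: BundleSpec) -> tuple[Structure, dict]:
    """Open stem-helix C2 dimer (chains A and B) with ground-truth labels.

    Chain B is chain A rotated by exactly 180 degrees about the z axis
    through the origin (the recorded dyad); coordinate noise, if any, is
    applied afterwards and independently per chain, so only the noise-free
    dimer is exactly symmetric.
    """
    if spec.state != "open-dimer":
        raise ValueError(f"spec.state is {spec.state!r}, expected 'open-dimer'")
    half = STEM_SEPARATION / 2.0
    records, info = _monomer_records(spec, open_state=True, stem_axis_xy=(half, 0.0))
    chain_a = _build_chain("A", records)
    rot = np.diag([-1.0, -1.0, 1.0])  # Rz(180)
    records_b = [
        (num, code, [(name, rot @ xyz) for name, xyz in atoms])
        for num, code, atoms in records
    ]
    chain_b = _build_chain("B", records_b)
    s = Structure(
        id=f"synthetic-open-dimer-{spec.central}84-{spec.res86}86",
        chains=[chain_a, chain_b],
        metadata={"generator": "make_open_dimer", "seed": spec.seed,
                  "noise_sigma": spec.noise_sigma},
    )
    _apply_noise(s, spec.noise_sigma, spec.seed)
    _renumber_serials(s)
    s.validate()
    seq = spec.resolved_sequence()
    labels = {
        "state": "open",
        "central": seq[84 - FIRST_RESNUM],
        "res86": seq[86 - FIRST_RESNUM],
        "relay": "broken" if seq[84 - FIRST_RESNUM] not in "RK" else "distance-dependent",
        "switch_residues": list(SWITCH),
        "c2_axis_point": [0.0, 0.0, 0.0],
        "c2_axis_direction": [0.0, 0.0, 1.0],
        "helix_spans": info["spans"],
    }
    return s, labels


def make_extended_chain(n_res: int = 30, chain_id: str = "A", start_resnum: int = 1,
                        sequence: str | None = None) -> Structure:
    """Fully extended chain (CA trace + alternating CB); no tertiary contacts."""
    if n_res < 3:
        raise ValueError("n_res must be >= 3")
    records = []
    for i in range(n_res):
        num = start_resnum + i
        code = sequence[i] if sequence else "A"
        ca = np.array([3.8 * i, 0.0, 0.0])
        cb = ca + np.array([0.0, 0.0, 1.53 if i % 2 == 0 else -1.53])
        atoms = [("CA", ca)]
        if code != "G":
            atoms.append(("CB", cb))
        records.append((num, code, atoms))
    s = Structure(id="synthetic-extended", chains=[_build_chain(chain_id, records)])
    _renumber_serials(s)
    return s


# ---------------------------------------------------------------------------
# Family alignments

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NON_BASIC = "ACDEFGILMNPQSTVWY"  # candidate central residues that break the relay
_ANCHOR_POS = {"E": 26, "M": 82, "N": 83, "central": 84, "D": 86}  # 1-based


def make_family_alignment(
    n_rows: int,
    intact_rows=None,
    seed: int = 0,
    n_res: int = 96,
    n_gap_columns: int = 8,
) -> tuple[Alignment, dict[str, str]]:
    """Random family alignment with planted intact/broken relay anchors.

    Row ids are ``NLRP14`` (the ungapped-anchor reference, wild-type broken
    relay unless listed intact) followed by ``PYD02``...  ``intact_rows``
    may hold row indices or row ids; all other rows are planted broken,
    either by a non-basic central residue or by Val at the D anchor.
    Returns the alignment plus an id -> {"intact","broken"} label map.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    if n_res < _ANCHOR_POS["D"]:
        raise ValueError(f"n_res must be >= {_ANCHOR_POS['D']}")
    rng = np.random.default_rng(seed)
    ids = ["NLRP14"] + [f"PYD{i + 1:02d}" for i in range(1, n_rows)]
    intact_ids = set()
    for item in intact_rows or []:
        intact_ids.add(ids[item] if isinstance(item, (int, np.integer)) else str(item))
    unknown = intact_ids - set(ids)
    if unknown:
        raise ValueError(f"intact_rows not in alignment: {sorted(unknown)}")

    labels: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
    for rid in ids:
        seq = list(rng.choice(list(_AA), size=n_res))
        seq[_ANCHOR_POS["E"] - 1] = "E"
        seq[_ANCHOR_POS["M"] - 1] = "M"
        seq[_ANCHOR_POS["N"] - 1] = "N"
        if rid in intact_ids:
            seq[_ANCHOR_POS["central"] - 1] = "R"
            seq[_ANCHOR_POS["D"] - 1] = "D"
            labels[rid] = "intact"
        else:
            if rid == "NLRP14":
                seq[_ANCHOR_POS["central"] - 1] = "L"
                seq[_ANCHOR_POS["D"] - 1] = "D"
            elif rng.random() < 0.3:
                # broken at the second acidic anchor, central still basic
                seq[_ANCHOR_POS["central"] - 1] = "R"
                seq[_ANCHOR_POS["D"] - 1] = "V"
            else:
                seq[_ANCHOR_POS["central"] - 1] = str(rng.choice(list(_NON_BASIC)))
                seq[_ANCHOR_POS["D"] - 1] = "D"
            labels[rid] = "broken"
        rows.append((rid, "".join(seq)))

    # insert gap columns: always a gap in the reference row, so the original
    # (planted) columns of every row stay aligned with the reference's
    # ungapped coordinate system; other rows may carry an insertion there
    for col in sorted(rng.integers(0, n_res + 1, size=n_gap_columns), reverse=True):
        fill = ["-" if (i == 0 or rng.random() < 0.75) else str(rng.choice(list(_AA)))
                for i in range(len(rows))]
        rows = [(rid, seq[:col] + f + seq[col:]) for (rid, seq), f in zip(rows, fill)]

    aln = Alignment(rows=rows)
    aln.validate()
    return aln, labels
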