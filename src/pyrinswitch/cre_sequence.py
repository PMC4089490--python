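"""Sequence-level classification of the conformational regulation element.

Across the NLRP pyrin-domain family the closed six-helix bundle is locked by
a charge relay whose sequence signature sits at four alignment-anchored
positions (NLRP14 numbering): an acidic anchor at 26, the conserved Met at
82, the central relay position at 84 (M82-N-R84 vs M82-N-L84 consensus) and a
second acidic anchor at 86.  A pyrin domain with an intact relay (acidic /
basic / acidic at 26/84/86) is predicted to favour the closed monomeric
bundle; a broken relay predicts open-stem dimerization propensity.

Anchor states use conservative substitution classes: E or D count as acidic,
R or K as basic — the classifier scores chemical capability to form the
bridge, not sequence identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .structure_model import ParseError

__all__ = [
    "Alignment",
    "CREProfile",
    "DEFAULT_ANCHORS",
    "read_alignment",
    "map_anchor_columns",
    "classify_cre",
    "family_report",
]

DEFAULT_ANCHORS = {"E": 26, "M": 82, "central": 84, "D": 86}

ACIDIC = frozenset("ED")
BASIC = frozenset("RK")
GAP = "-"


@dataclass
class Alignment:
    rows: list[tuple[str, str]]  # (id, gapped sequence), input order

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, row_id: str) -> str:
        for rid, seq in self.rows:
            if rid == row_id:
                return seq
        raise KeyError(f"no row {row_id!r} in alignment")

    def validate(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        ids = self.ids
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate row id(s): {dup}")
        ncol = len(self.rows[0][1])
        for rid, seq in self.rows:
            if len(seq) != ncol:
                raise ValueError(
                    f"ragged alignment: row {rid!r} has {len(seq)} columns, expected {ncol}"
                )


@dataclass
class CREProfile:
    sequence_id: str
    residue_at_E_anchor: str
    residue_at_M82: str
    residue_at_central: str
    residue_at_D_anchor: str
    bridge_status: str  # intact | broken
    prediction: str  # closed-propensity | open-propensity
    note: str = ""


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a FASTA or Clustal multiple alignment via Bio.AlignIO."""
    from Bio import AlignIO

    if format not in ("fasta", "clustal"):
        raise ValueError(f"unknown alignment format {format!r}")
    path = Path(path)
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise ParseError(f"cannot parse alignment {path}: {exc}") from exc
    aln = Alignment(rows=[(rec.id, str(rec.seq).upper()) for rec in msa])
    aln.validate()
    return aln


def map_anchor_columns(
    a: Alignment,
    reference_id: str,
    anchor_residue_numbers: dict[str, int] | None = None,
    reference_first_resnum: int = 1,
) -> dict[str, int]:
    """0-based alignment columns of the reference row's anchor residues.

    Anchor residue number k maps to the column holding the
    (k - reference_first_resnum + 1)-th non-gap character of the reference
    row.  The mapping is order-preserving and bijective on the reference's
    ungapped positions.
    """
    anchors = anchor_residue_numbers or DEFAULT_ANCHORS
    ref = a.row(reference_id)
    # column of the n-th (1-based) non-gap character
    nongap_cols = [i for i, ch in enumerate(ref) if ch != GAP]
    out: dict[str, int] = {}
    for name, resnum in anchors.items():
        k = resnum - reference_first_resnum  # 0-based ungapped index
        if k < 0 or k >= len(nongap_cols):
            raise ValueError(
                f"anchor {name}={resnum} beyond ungapped length "
                f"{len(nongap_cols)} of reference {reference_id!r}"
            )
        out[name] = nongap_cols[k]
    return out


def classify_cre(a: Alignment, anchor_columns: dict[str, int]) -> list[CREProfile]:
    """One CREProfile per alignment row from the anchor-column characters.

    Intact iff the E anchor is acidic (E/D), the central position basic (R/K)
    and the D anchor acidic (D/E); a gap at any anchor is broken with a note.
    """
    for name in ("E", "central", "D"):
        if name not in anchor_columns:
            raise ValueError(f"anchor column {name!r} missing")
    ncol = a.n_columns
    if any(c < 0 or c >= ncol for c in anchor_columns.values()):
        raise ValueError("anchor column out of range")
    profiles = []
    for rid, seq in a.rows:
        at = {name: seq[col] for name, col in anchor_columns.items()}
        gaps = [name for name in ("E", "central", "D") if at[name] == GAP]
        if gaps:
            status, note = "broken", f"gap at anchor(s) {gaps}"
        elif at["E"] in ACIDIC and at["central"] in BASIC and at["D"] in ACIDIC:
            status, note = "intact", ""
        else:
            status, note = "broken", ""
        profiles.append(
            CREProfile(
                sequence_id=rid,
                residue_at_E_anchor=at["E"],
                residue_at_M82=at.get("M", GAP),
                residue_at_central=at["central"],
                residue_at_D_anchor=at["D"],
                bridge_status=status,
                prediction="closed-propensity" if status == "intact" else "open-propensity",
                note=note,
            )
        )
    return profiles


def family_report(profiles: list[CREProfile]) -> tuple[pd.DataFrame, dict[str, int]]:
    """Tabulate CRE profiles (input order) and count intact/broken statuses."""
    if not profiles:
        raise ValueError("no profiles to report")
    table = pd.DataFrame(
        {
            "sequence_id": [p.sequence_id for p in profiles],
            "E_anchor": [p.residue_at_E_anchor for p in profiles],
            "M82": [p.residue_at_M82 for p in profiles],
            "central": [p.residue_at_central for p in profiles],
            "D_anchor": [p.residue_at_D_anchor for p in profiles],
            "bridge_status": [p.bridge_status for p in profiles],
            "prediction": [p.prediction for p in profiles],
            "note": [p.note for p in profiles],
        }
    )
    counts = {
        "intact": int((table["bridge_status"] == "intact").sum()),
        "broken": int((table["bridge_status"] == "broken").sum()),
    }
    return table, counts
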