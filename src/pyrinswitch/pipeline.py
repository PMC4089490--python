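"""End-to-end switch analysis pipeline and fixture management.

``run_switch_analysis`` chains the individual stages — interface burial,
conformational calling, charge-relay detection, hydrophobic-core accounting,
switching-element report and interface charge summary — over a closed-state
structure and/or an open-dimer structure, and writes a JSON summary plus TSV
tables.  Every report embeds the exact thresholds used and a hash of the
configuration; two runs with identical config produce byte-identical result
files (timestamps go to the log only).

``fetch_fixtures`` downloads deposited PDB entries into a checksummed local
cache.  It is strictly opt-in: nothing else in the package touches the
network, and analyses of deposited entries simply skip when no cached file
exists.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .structure_model import Structure, read_structure
from .surface_geometry import buried_interface_area
from .helix_geometry import call_conformation
from .interaction_analysis import (
    DEFAULT_CORE_RESIDUES,
    SALT_BRIDGE_CUTOFF,
    SWITCH_RESIDUES,
    detect_charge_relay,
    find_salt_bridges,
    hydrophobic_core,
    interface_charge_summary,
    switching_elements,
)

__all__ = ["RunConfig", "run_switch_analysis", "fetch_fixtures", "DEFAULT_FIXTURE_DIR"]

DEFAULT_FIXTURE_DIR = Path.home() / ".cache" / "pyrinswitch" / "fixtures"


@dataclass
class RunConfig:
    closed_path: str | None = None
    open_path: str | None = None
    closed_chain: str = "A"
    open_chains: tuple[str, str] = ("A", "B")
    alpha5_range: tuple[int, int] = (70, 83)
    alpha6_range: tuple[int, int] = (84, 96)
    relay_anchors: dict = field(default_factory=lambda: {"E": 26, "central": 84, "D": 86})
    core_residues: tuple[int, ...] = DEFAULT_CORE_RESIDUES
    switch_residues: tuple[int, ...] = SWITCH_RESIDUES
    probe_radius: float = 1.4
    n_points: int = 960
    salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF
    seed: int = 0
    out_dir: str = "pyrinswitch_out"

    def validate(self) -> None:
        if self.closed_path is None and self.open_path is None:
            raise ValueError("config needs at least one of closed_path / open_path")
        if not (0.5 <= self.probe_radius <= 3.0):
            raise ValueError("probe_radius outside valid range [0.5, 3.0] A")
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")
        if not (2.0 <= self.salt_bridge_cutoff <= 8.0):
            raise ValueError("salt_bridge_cutoff outside valid range [2, 8] A")

    def config_hash(self) -> str:
        # out_dir is excluded: where a report is written does not change it
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _log(log_lines: list[str], msg: str) -> None:
    stamp = time.strftime("%H:%M:%S")
    log_lines.append(f"[{stamp}] {msg}")
    print(f"[{stamp}] {msg}", file=sys.stderr)


def run_switch_analysis(
    config: RunConfig,
    closed: Structure | None = None,
    open_dimer: Structure | None = None,
) -> dict:
    """Run all applicable analysis stages and write the report bundle.

    Structures may be passed directly (e.g. synthetic ones) or read from the
    configured paths.  Any stage failure raises after flagging partial
    outputs in the summary written so far.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    _log(log_lines, f"pyrinswitch {__version__}, config hash {config.config_hash()}")

    if closed is None and config.closed_path:
        _log(log_lines, f"reading closed structure {config.closed_path}")
        closed = read_structure(config.closed_path)
    if open_dimer is None and config.open_path:
        _log(log_lines, f"reading open dimer {config.open_path}")
        open_dimer = read_structure(config.open_path)
    if closed is None and open_dimer is None:
        raise ValueError("no input structures")

    summary: dict = {
        "tool_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
    }
    tables: dict[str, list[dict]] = {}

    if open_dimer is not None:
        _log(log_lines, "stage: interface burial")
        iface = buried_interface_area(
            open_dimer, config.open_chains[0], config.open_chains[1],
            config.probe_radius, config.n_points,
        )
        summary["interface"] = {
            "chains": list(config.open_chains),
            "buried_area_avg": iface.buried_area,
            "buried_total_A": iface.buried_total_A,
            "buried_total_B": iface.buried_total_B,
            "n_interface_residues": len(iface.interface_residues),
        }
        tables["interface_residues"] = [
            {"chain": k[0], "resnum": k[1], "buried_area": v}
            for k, v in sorted(iface.buried_per_residue.items())
            if v > 0.1
        ]
        _log(log_lines, "stage: interface charge summary")
        summary["interface_charge"] = interface_charge_summary(open_dimer, iface)

        _log(log_lines, "stage: conformation (open candidate)")
        summary["conformation_open"] = {}
        for cid in config.open_chains:
            call = call_conformation(
                open_dimer, cid, config.alpha5_range, config.alpha6_range
            )
            summary["conformation_open"][cid] = {
                "state": call.state,
                "inter_axis_angle": call.inter_axis_angle,
                "junction_helical": call.junction_helical,
            }
        _log(log_lines, "stage: charge relay (open candidate)")
        summary["relay_open"] = {}
        for cid in config.open_chains:
            relay = detect_charge_relay(
                open_dimer, cid, config.relay_anchors, config.salt_bridge_cutoff
            )
            summary["relay_open"][cid] = {
                "status": relay.status,
                "d_E_central": relay.d_E_central,
                "d_central_D": relay.d_central_D,
            }

    if closed is not None:
        _log(log_lines, "stage: conformation (closed candidate)")
        call = call_conformation(
            closed, config.closed_chain, config.alpha5_range, config.alpha6_range
        )
        summary["conformation_closed"] = {
            "state": call.state,
            "inter_axis_angle": call.inter_axis_angle,
            "junction_helical": call.junction_helical,
        }
        _log(log_lines, "stage: charge relay (closed candidate)")
        relay = detect_charge_relay(
            closed, config.closed_chain, config.relay_anchors, config.salt_bridge_cutoff
        )
        summary["relay_closed"] = {
            "status": relay.status,
            "d_E_central": relay.d_E_central,
            "d_central_D": relay.d_central_D,
        }
        _log(log_lines, "stage: hydrophobic core")
        core = hydrophobic_core(
            closed, config.closed_chain, config.core_residues,
            config.probe_radius, config.n_points,
        )
        summary["hydrophobic_core"] = {
            "core_contact_area": core.core_contact_area,
            "mean_burial_fraction": sum(core.burial_fraction.values())
            / len(core.burial_fraction),
        }
        tables["core_burial"] = [
            {"resnum": num, "burial_fraction": frac}
            for num, frac in sorted(core.burial_fraction.items())
        ]
        _log(log_lines, "stage: salt bridges")
        bridges = find_salt_bridges(closed, config.salt_bridge_cutoff)
        tables["salt_bridges"] = [
            {
                "basic": f"{b.basic_name}{b.basic_residue[1]}:{b.basic_residue[0]}",
                "acidic": f"{b.acidic_name}{b.acidic_residue[1]}:{b.acidic_residue[0]}",
                "min_distance": round(b.min_distance, 3),
                "interchain": b.interchain,
            }
            for b in bridges
        ]
        summary["n_salt_bridges"] = len(bridges)

    if closed is not None and open_dimer is not None:
        _log(log_lines, "stage: switching elements")
        report = switching_elements(
            closed, config.closed_chain, open_dimer, tuple(config.open_chains),
            config.switch_residues, config.probe_radius, config.n_points,
        )
        summary["switching_elements"] = {
            str(num): {
                "closed_core_area": report.closed_core_area.get(num),
                "open_interface_area": report.open_interface_area.get(num),
                "closed_verdict": report.closed_verdict.get(num),
                "open_verdict": report.open_verdict.get(num),
            }
            for num in report.residues
        }

    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
    for name, rows in tables.items():
        if not rows:
            continue
        cols = list(rows[0])
        lines = ["\t".join(cols)]
        lines += ["\t".join(str(r[c]) for c in cols) for r in rows]
        (out_dir / f"{name}.tsv").write_text("\n".join(lines) + "\n")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    _log(log_lines, f"report bundle written to {out_dir}")
    return summary


def fetch_fixtures(ids: list[str], dest: str | Path = DEFAULT_FIXTURE_DIR) -> list[Path]:
    """Download deposited PDB entries into a checksummed cache (opt-in only).

    Repeated calls are cache hits and touch no network.  Raises on download
    or checksum-manifest failure with the offending accession named.
    """
    import urllib.request

    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    manifest_path = dest / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    paths = []
    for acc in ids:
        acc = acc.lower()
        if not (len(acc) == 4 and acc[0].isdigit()):
            raise ValueError(f"not a PDB accession: {acc!r}")
        target = dest / f"{acc}.pdb"
        if target.exists() and acc in manifest:
            digest = hashlib.sha256(target.read_bytes()).hexdigest()
            if digest != manifest[acc]:
                raise IOError(f"checksum mismatch for cached {acc}")
            paths.append(target)
            continue
        url = f"https://files.rcsb.org/download/{acc}.pdb"
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                data = resp.read()
        except Exception as exc:
            raise IOError(f"download failed for {acc}: {exc}") from exc
        target.write_bytes(data)
        manifest[acc] = hashlib.sha256(data).hexdigest()
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        paths.append(target)
    return paths


def cached_fixture(acc: str, dest: str | Path = DEFAULT_FIXTURE_DIR) -> Path | None:
    """Path of a cached deposited entry, or None when offline/never fetched."""
    target = Path(dest) / f"{acc.lower()}.pdb"
    return target if target.exists() else None
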