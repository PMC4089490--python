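# pyrinswitch

Geometric analysis of pyrin-domain conformational switching.

Pyrin domains (PYDs) — the N-terminal signalling modules of NLRP
inflammasome receptors — adopt the death-domain fold: six antiparallel
α-helices around a conserved hydrophobic core. NLRP14's PYD breaks this
pattern: its helices α5 and α6 fuse into one extended *stem-helix α5/6*,
producing an "open" conformation that mediates a symmetric homodimer,
while a buried Glu–Arg–Asp *charge relay* (positions 26–84–86 in NLRP14
numbering) is what normally locks the "closed" six-helix bundle. Whether
the relay is intact (acidic/basic/acidic) or broken (NLRP14 carries Leu84;
the physiological D86V variant removes the second acid) predicts whether a
family member stays a closed monomer or can open and dimerize.

`pyrinswitch` makes those arguments quantitative and reproducible. It
computes, for any PDB/mmCIF structure or for labelled synthetic geometries
it generates itself:

* **Surface areas** — Shrake–Rupley SASA on a deterministic golden-spiral
  lattice; buried interface area between chain sets in the PISA averaged
  convention, `[SASA(A) + SASA(B) − SASA(A∪B)] / 2`; group-vs-environment
  contact areas (e.g. the hydrophobic core's contact with the rest of a
  monomer).
* **Helix geometry** — Cα-based helix assignment, axis fitting, inter-axis
  angles, and a three-way open / closed / intermediate call for the α5–α6
  pair; Kabsch least-squares superposition.
* **Interactions** — salt bridges (side-chain N···O ≤ 4.0 Å), charge-relay
  status (intact / broken / absent), hydrophobic-core burial fractions,
  dual-role accounting for the switching residues Trp72/Leu76/Leu87 (core
  burial in the closed state vs interface burial in the open dimer), the
  molecular twofold axis of a dimer with ranked residue distances, and
  residue-level interface charge summaries.
* **Sequence classification** — anchor-column mapping in a family
  alignment and per-sequence relay-motif classification
  (closed-propensity vs open-propensity).
* **Synthetic structures** — ideal helices, closed six-helix bundles, open
  C2 stem-helix dimers and planted-anchor family alignments, all carrying
  machine-readable ground-truth labels and mandatory seeds.

## Worked example

```python
from pyrinswitch import (
    BundleSpec, make_closed_bundle, make_open_dimer,
    buried_interface_area, call_conformation, detect_charge_relay,
    switching_elements,
)

closed, _ = make_closed_bundle(BundleSpec(state="closed", central="R"))
opened, _ = make_open_dimer(BundleSpec(state="open-dimer"))  # wild-type L84

print(call_conformation(closed, "A").state)        # closed
print(call_conformation(opened, "A").state)        # open
print(detect_charge_relay(closed, "A").status)     # intact  (Arg84 bridges)
print(detect_charge_relay(opened, "A").status)     # broken  (Leu84)

iface = buried_interface_area(opened, "A", "B")
print(round(iface.buried_area, 1))                 # 346.5  (A^2, averaged)

report = switching_elements(closed, "A", opened, ("A", "B"))
print(report.closed_verdict[72], report.open_verdict[72])
# core-engaged dimer-engaged
```

The printed interface area is the PISA-style two-side average for the
synthetic dimer; the switching-residue verdicts show the same side chains
stabilising the hydrophobic core in the closed bundle and the dimer
interface in the open state.

The same analyses are available from the shell:

```sh
pyrinswitch simulate dimer --seed 3 --out dimer.pdb
pyrinswitch conformation dimer.pdb --chain A
pyrinswitch relay dimer.pdb --anchors 26,84,86
pyrinswitch interface dimer.pdb --chains-a A --chains-b B
pyrinswitch run-all --closed closed.pdb --open dimer.pdb --out-dir out/
```

Analyses of the deposited crystal structures (4n1j wild type, 4n1k D86V,
4n1l L84R) are supported but strictly opt-in: run
`pyrinswitch fetch-fixtures 4n1j 4n1l` once while online; the related tests
skip when no cached file exists.

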