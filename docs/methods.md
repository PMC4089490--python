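# Methods

This note documents the models, parameters and numerical choices behind
`pyrinswitch`, and what its synthetic-data tests do and do not establish
about real structures.

## Coordinate model

Structures are parsed with gemmi (PDB and mmCIF) into a plain
chain → residue → atom hierarchy that keeps **author residue numbering**
throughout — the pyrin-domain literature names residues that way (Glu26,
Leu84, Asp86) and renumbering would silently break every anchor-based
analysis. Hydrogens are dropped everywhere: 2–3 Å crystal structures do not
resolve them and the synthetic generator never emits them. Waters and
heteroatoms are removed unless requested; for alternate locations exactly
one conformer per atom is kept (highest occupancy by default, ties broken
by altloc character). Every retained atom is assigned a fixed heavy-atom
van der Waals radius at load time — C 1.70, N 1.55, O 1.52, S 1.80 Å
(Bondi-style) — and an unknown element is an error, never a silent default.
The PDB writer emits fixed-width ATOM records; read∘write is the identity
on identifiers and on coordinates to three decimals.

## Solvent-accessible surface area

SASA uses Shrake–Rupley quadrature: each atom is inflated by the probe
radius (default 1.4 Å, water) and sampled with a golden-spiral lattice of
`n_points` directions (default 960); the accessible fraction of lattice
points times the inflated-sphere area is the atom's SASA. The lattice is
deterministic — generated once per `n_points`, no randomness — so results
are bit-stable across runs. 960 points reproduce the isolated-sphere
closed form `4π(r+p)²` to well under 1% and is the default accuracy/speed
trade-off; because the lattice orientation is fixed, areas are exactly
translation-invariant but rotation-invariant only to quadrature error
(≲1% at 240 points, smaller at 960). Neighbour candidates come from a
`scipy.spatial.cKDTree` query with radius `r_i + probe + max(r_j + probe)`;
this is a pure prefilter and provably returns the same result as the
all-pairs computation (tested against an all-pairs reimplementation).
Atoms closer than 10⁻⁶ Å are a degenerate-geometry error.

Two independent oracles validate the quadrature: analytic formulas
(isolated sphere; the two-equal-spheres spherical-cap case
`2πR(R − d/2)` of buried cap area per sphere) and a seeded Monte-Carlo
estimator that samples each inflated sphere uniformly and rejects points
inside any neighbour. The MC estimator shares only the atom model with the
quadrature path.

**Interface burial** is reported in the PISA averaged convention,
`[SASA(A) + SASA(B) − SASA(A∪B)] / 2`, which is the convention behind
published protein-interface areas such as the ~890 Ų pyrin dimer
interface; the unaveraged per-side totals are exposed alongside since the
two conventions differ by exactly 2× for a symmetric dimer. Residues
burying > 0.1 Ų on their own side count as interface residues.
**Hydrophobic-core contact area** is operationalised as the averaged
contact between the core residues' side-chain atoms and all other atoms of
the same monomer; published core areas do not state the exact grouping
used, so reproduction tolerances on deposited entries are set to ±15%.

## Helix geometry and the open/closed call

Secondary structure is assigned from Cα geometry alone (no H-bond/DSSP
criterion — neither deposited nor synthetic inputs carry hydrogens, and
the synthetic side chains are minimal): residue *i* is helical iff
|Cα(i)−Cα(i+3)| ∈ [4.5, 6.0] Å and the virtual torsion
Cα(i−1…i+2) ∈ [35°, 75°] (IUPAC sign; an ideal right-handed α-helix scores
≈ +50°). Maximal runs of ≥ 4 flagged residues become segments; a run
i…j spans the helix i…j+3 because the distance criterion at j already
involves residue j+3. Runs break at numbering gaps and missing Cα.

Helix axes are fitted by SVD of local centers (means of 4 consecutive Cα),
oriented N→C; the rise is the mean projection step. Note the 4-Cα window
centers of even a perfect helix retain a residual ~0.26 Å circular wobble;
fit rms is therefore meaningful only above that floor.

The **conformational call** for the α5–α6 pair (default ranges 70–83 and
84–96, NLRP14 numbering, always overridable) is three-way:

* *open* — the α5+α6 region behaves as one continuous stem: either the
  segmentation merges both ranges into a single segment, or a single-helix
  fit of the combined range is collinear (fit rms < 2 Å and rise
  1.0–2.0 Å/residue); and the two half-range axes subtend < 35°.
* *closed* — the combined range is not collinear and the half-range axes
  subtend ≥ 70° (the folded-back bundle geometry).
* *intermediate* — anything else (half-open states).

The angle thresholds and the collinearity test are package decisions — no
quantitative open/closed criterion exists in the structural literature for
this fold — and every report echoes them. The collinearity fallback exists
because the per-residue helical flags are individually fragile under
coordinate noise (at σ = 0.3 Å each flag fails with ~10% probability, so a
27-residue stem virtually always fragments) while the question the call
answers — is this one straight helix or two packed back on each other — is
robustly decided by the whole-range fit. On noise-free geometry the
segmentation criterion and the collinearity criterion agree.

Superposition is the Kabsch algorithm (SVD with determinant correction; a
proper rotation is always returned, also for mirror-image inputs).
Collinear point sets are rejected. Tests validate it against a brute-force
2° Euler-grid search via the trace identity
rmsd² = (Σ|x|² + Σ|y|² − 2·max tr(R·H))/n and against
`scipy.Rotation.align_vectors`.

## Interactions

* **Salt bridges**: all (basic side-chain N, acidic carboxylate O) pairs
  within 4.0 Å — Arg NE/NH1/NH2, Lys NZ, His ND1/NE2 vs Asp OD1/OD2,
  Glu OE1/OE2 — aggregated per residue pair with the minimum distance.
  4.0 Å is the common structural-biology convention; the pyrin literature
  states no number. His counts as basic for bridge detection but is
  excluded from net-charge totals (ambiguous protonation).
* **Charge relay**: anchors default to 26/84/86. Status is *absent* when an
  anchor residue is missing from the model (not an exception), *broken*
  when the central residue is not Arg/Lys, when an anchor lacks carboxylate
  oxygens (e.g. Val86), or when either minimum N···O distance exceeds the
  cutoff; *intact* otherwise.
* **Core burial**: the default core is the 11 canonical bundle residues
  (15, 19, 22, 27, 30, 34, 58, 62, 71, 79, 82) plus the three switching
  residues (72, 76, 87). A residue's burial fraction is
  1 − SASA(in chain)/SASA(in its i−1…i+1 tripeptide), so a residue without
  tertiary contacts scores ≈ 0 regardless of backbone neighbours.
* **Switching elements**: per residue, the closed-state side-chain contact
  area against the rest of the monomer and the open-dimer per-residue
  interface burial; engagement threshold 1 Ų on either side.
* **Dimer axis**: chain A is superposed onto chain B over number-matched
  Cα; the rotation axis is the candidate dyad, with a warning (not an
  error) when the rotation angle is outside 180° ± 15°. Proximity of
  residues to the axis is reported as a ranked distance table of
  side-chain centroids, not a binary call. The axis computed is the
  molecular (noncrystallographic) dyad.
* **Interface charge**: a residue-level surrogate for a continuum
  electrostatic map — counts of acidic (D/E), basic (K/R/H),
  hydrophobic (AVLIMFWPC) and polar interface residues per chain, and the
  net formal charge (K/R − D/E). Continuum electrostatics is deliberately
  out of scope.

## Sequence-level relay classification

Alignments (FASTA/Clustal via Bio.AlignIO) are anchored on a reference row
(NLRP14 numbering by default, anchors 26/82/84/86): anchor residue *k*
maps to the column of the reference's *k*-th non-gap character. A row is
*intact* iff its E anchor is E/D, its central position R/K and its D anchor
D/E — conservative substitution classes, because the classifier scores the
chemical capability to form the bridge, not sequence identity; intact
predicts closed-monomer propensity, broken predicts open-dimer propensity.
A gap at any anchor is broken with an explanatory note. Real NLRP1–14
sequences are not bundled (avoiding transcription errors); users supply
their own alignment, and tests use planted synthetic families only.

## Synthetic structures: what they emulate and what they do not

The generator builds schematic, fully labelled geometries:

* ideal α-helices (rise 1.5 Å/residue, twist 100°, Cα radius 2.3 Å;
  backbone N/C/O ride the smooth helix curve, CB points radially outward);
* a **closed bundle**: six helices, antiparallel, on a circular arrangement
  with ~10 Å neighbour spacing, slot order chosen so sequence-adjacent
  helices pack side by side and helix 2 packs against helix 6 (the relay
  geometry). Core residues place their CB "knobs into holes" toward the
  nearest other helix; the relay residues (when charged) receive
  full charged-group atoms under real atom names, with lead tip atoms
  pinned ~2.6 Å apart around the triad centroid so that an Arg84 relay is
  intact by construction and survives σ ≤ 0.3 Å noise;
* an **open dimer**: helices 1–4 as in the bundle, α5+α6 fused into one
  straight stem; chain B is chain A rotated exactly 180° about a recorded
  axis; the stem phase puts the switching residues on the interface face
  (inter-chain CB–CB < 6 Å) and Asp86's carboxylate near the dyad — which
  is why a D86V pair changes the interface acidic count by exactly 2;
* **family alignments** with planted intact/broken anchors; inserted gap
  columns are always gaps in the reference row so the reference's ungapped
  coordinate system stays aligned with every row's planted motif.

Residue span defaults (α1 10–21, α2 24–39, α3 44–52, α4 55–65, α5 70–83,
α6 84–96 over a 7–96 chain) and the default threaded sequence carry the
NLRP14-like anchors; `central` (84) and `res86` are the two dials the
study conditions vary (L/R and D/V). Coordinate noise is iid Gaussian per
coordinate with a mandatory seed; identical spec + seed gives identical
bytes.

These geometries are deliberately *not* physical folds: packing is
circular rather than Greek-key, side chains stop at CB except for charged
groups, linkers are interpolated, and mild steric overlap is tolerated.
Consequently synthetic areas are meaningful only **relatively** (closed vs
open, bound vs separated, D vs V); they are never compared against the
published crystallographic Å² values, which are only checked in the
opt-in, network-gated tests on the deposited entries themselves. Passing
the synthetic suite demonstrates that the detectors recover planted
ground truth under noise — not that any particular real PYD is open or
closed.

A note on one generator design point: with CB-only side chains, a 10 Å
circular bundle is hollow, so core CBs aimed at the bundle *centre* would
touch nothing and the closed state would not out-bury the open state. The
knobs-into-holes orientation (CB toward the nearest other helix axis)
restores the intended contrast (~25–30 Ų closed-minus-open for the
default spec) while keeping the spacing at 10 Å.

## Study conditions and problem sizes

The acceptance study (`scripts/acceptance.py`, also mirrored in
`tests/test_acceptance.py`) runs: the isolated-sphere check at 960
quadrature points; 20 random 10–50-atom clusters against the MC oracle at
10⁵ samples each; 50 random rigid motions for superposition recovery; the
conformational/relay sweep over 120 structures (closed-with-Arg84 vs
open-dimer-with-Leu84 × σ ∈ {0.1, 0.2, 0.3} Å × 20 seeds); classifier
recovery over 50 seeded families of 200 rows; and the synthetic-dimer
interface measurements (separation, symmetry, D86V acidic-count change,
closed-vs-open core contact, switching-residue dual engagement). Every
random draw derives from the `--seed` argument.

## Known limitations

* No solvent-excluded (molecular) surface, no surface meshes.
* No DSSP/H-bond secondary structure; the Cα criterion under-calls the
  first helical turn by construction (a 20-residue ideal helix yields a
  segment starting at residue 2).
* The open/closed thresholds (35°/70°, collinearity rms < 2 Å) are
  calibrated on idealized geometry; strongly bent but continuous stems
  land in *intermediate* by design.
* No symmetry-mate generation, assembly building, hydrogen placement, pKa
  prediction, docking or continuum electrostatics.
* mmCIF support rides gemmi's reader; PDB is the reference dialect for
  round-trips.
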