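# Methods

This note documents the models, conventions, and design choices behind
`nbcensus`, and what its synthetic benchmarks do and do not demonstrate.

## Coordinate model and PDB conventions

Structures are parsed with gemmi into a minimal chain/residue/atom model.
One model is materialized per `Structure` (default model 1 for NMR
ensembles).  Alternate locations are resolved to the highest-occupancy
conformer, ties broken by file order.  Waters are dropped; other HETATM
residues are kept in a parallel chain grouping under the same chain id,
except residues that are chemically part of the polypeptide (MSE and
similar), which stay in the polymer.  Author residue numbering is
preserved verbatim; all in-memory spans are 0-based half-open and all
human-facing reports are 1-based inclusive.  Elements missing from the
element column are inferred from atom names by PDB v3 conventions.

## CDR annotation ("IMGT-lite")

Full renumbering schemes (IMGT, Kabat, Chothia) are deliberately out of
scope.  Spans are derived from the conserved anchors every VHH carries:
the two cysteines, the FR2 `W[YVF]RQ` motif, an `RFTIS`-like FR3 motif
(fuzzy, one mismatch), and the FR4 `W-G-x-G` motif.  CDR3 runs from the
residue after the second cysteine to the residue before the FR4
tryptophan.  CDR1 starts four residues after Cys1 and ends at the FR2
tryptophan; CDR2 starts 14 residues after that tryptophan and ends one
before the FR3 anchor.  These offsets are calibrated so that, on the
VUN701 sequence, CDR3 spans residues 96–109 (`RAQQKIGRDTFRDY`) and CDR1
contains residues 28–32 — the residue-class labels used for that system —
without asserting that any published numbering scheme was the source.
Missing anchors raise a classified failure (`missing_cys_anchor`, ...)
and the structure is excluded from a census with that reason, replacing
manual curation with an explicit rule.

## Secondary structure

The Kabsch–Sander electrostatic model is implemented exactly: amide H
placed 1.00 Å from N along the bisector of the N–C(i−1)/N–O(i−1)
directions (no H on chain starts, prolines, or across breaks where
C(i−1)–N(i) ≥ 2.5 Å); energy constant 27.888 kcal·Å/mol; bond cutoff
−0.5 kcal/mol; at most the two lowest-energy acceptors per donor;
distances below 0.5 Å clamp to a −9.9 sentinel and flag clashing input.
Assignment uses the reduced alphabet {H, E, T, C}: H for runs of two or
more consecutive i→i+4 turns, E for bridges (both Kabsch–Sander parallel
and antiparallel patterns) extended into ladders of length ≥ 2, T for
isolated 3/4/5-turns, priority H > E > T > C.  Isolated bridges reduce to
C.  Residues with incomplete backbones are excluded from bonding, labeled
C, and warned about.  Per-residue agreement with any particular DSSP
release is not promised — only ladder-level behavior, which is what the
census consumes.

The hairpin detector returns the longest antiparallel ladder whose two
strands both intersect the window from six residues before the CDR3
start through the last CDR3 residue.  The left extension allows hairpin
stems that begin in FR3 (as in VUN701, strands 91–101/105–109); the right
end deliberately excludes the FR4 anchor strand so that the conserved
framework ladder ending on the FR4 tryptophan is never mistaken for a
CDR3 hairpin.  `n_cross_hbonds` counts mutual (reciprocal) bonds between
the strands.

## Census: superposition, matrix, classification

Framework regions are sequence-aligned region-by-region (FR1–FR4) and the
ungapped columns define the Kabsch fit (SVD, reflection-corrected; at
least 40 matched framework Cα or the comparison is refused).  The
reported distance covers the whole domain by default: framework columns
plus CDR columns paired anchor-symmetrically — position k from each CDR
start and position k from each end, out to half the shorter loop.  This
pairing is sequence-independent, deterministic, and respects the fact
that a loop is anchored at both ends; aligning hypervariable CDR3
sequences by string similarity instead would place gaps arbitrarily and
systematically under-weight tip divergence.  Masked (failed) pairs are
excluded from clustering greedily (most-masked structure first) with
reasons logged.  Structures with identical sequences keep one
representative (lowest label lexicographically); proportions are reported
both over all classified structures and over the non-redundant set.

Clustering is average-linkage agglomerative on the RMSD matrix, cut at
k = 3 — deterministic given input order.

The classifier replaces visual curation with an explicit rule over four
descriptors: CDR3 length; mutual cross-strand bond count from the hairpin
detector; protrusion (maximum CDR3 Cα distance from the framework Cα
centroid minus the 95th percentile of framework distances — roughly "Å
beyond the framework envelope"); and the fraction of CDR3 residues,
excluding the three adjacent to each anchor, with at least one heavy-atom
contact to FR2/CDR2-side framework residues.  Defaults: short iff
length ≤ 7; else extended iff bonds ≥ 2 and protrusion ≥ 5 Å and contact
fraction ≤ 0.3; else folded-back.  All four thresholds are configuration
values, and every decision carries a rationale string.

## Contacts and conservation

A contact is a heavy-atom pair at `d ≤ r_a + r_b + slack` (slack 0.5 Å,
boundary inclusive) between disjoint selections, with element-level
Bondi-style radii (C 1.70, N 1.55, O 1.52, S/P 1.80, halogens standard,
fallback 1.70; user-overridable).  Pairs below 1.9 Å are treated as
covalent cross-links (disulfides), flagged and excluded.  Hydrogens are
stripped first.  Because published contact totals depend on the exact
per-atom radius set of the tool that produced them, totals computed here
carry a ±10% comparability caveat; both atom-pair and residue-pair totals
are reported.  Fingerprints count contacts per receptor position
(optionally merged with a GPCRdb-style numbering map) and partition them
by the ligand CDR making the contact.

Conservation of an alignment column is the modal-residue fraction with
strict identity; gaps never count as modal and are excluded from the
denominator by default (a switch includes them as mismatches).  Columns
above mean + 1 SD are flagged as highly conserved.  "Fully conserved"
requires unanimity with no gaps.  Building the alignment itself is input,
not computed.

## Pharmacology

Dose-response fits fix the Hill slope at 1:
`y = b + (t−b)/(1 + m/x)` rising, `y = b + (t−b)/(1 + x/m)` falling, with
the midpoint fitted on a log₁₀ scale bounded four decades beyond the data
range, initialized by interpolating the half-maximal response, and solved
by trust-region least squares (tolerances 1e−12).  Replicates are
averaged per concentration before fitting.  Fits whose dynamic range is
under three times the residual noise SD are flagged unreliable.
Cheng-Prusoff and pK conversions are exact formulas on molar inputs; pK
values are reported to two decimals.  Schild regression is ordinary least
squares of log₁₀(r−1) on log₁₀[B] over points with r > 1 (at least
three); pA₂ is the x-intercept magnitude; K_B = 10^(−pA₂) is taken from
the regression when |slope − 1| ≤ 0.2 and otherwise from a
slope-constrained refit, with the unconstrained value reported alongside.

## The synthetic-data generators

The generators define the benchmark conditions; their defaults are fixed
and not tuned per run.

**Scaffolds.**  An ideal-geometry strand template (NeRF chain extension;
bonds N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å; angles 111.2 /
116.2 / 121.7°; torsions φ = −138.0°, ψ = 133.4°, ω = 180°) and a frozen
rigid transform place antiparallel strand pairs whose designed mutual
hydrogen bonds score −2.5 to −2.6 kcal/mol in the Kabsch–Sander model.
The torsions and transform were obtained once by deterministic
optimization of those bond energies and are frozen as constants.  The
framework is a two-layer arrangement of such pairs (six paired strands
plus one unpaired FR2 strand) spaced so no bond forms between units,
wired through the published VUN701 framework sequence; CDR3 sequences are
drawn per seed from an alphabet excluding C/W (anchor letters) and G/P
(backbone special cases).  Loops are smooth interpolated coil.  This is
an idealization, not a physical model: sheets are hydrogen-bonded within
pairs only, side chains stop at a virtual Cβ, and loop geometry is not
Ramachandran-valid.  What passing tests show is that the *analysis*
stages are correct on geometry whose ground truth is known exactly —
not that the classifier thresholds are calibrated for experimental
structures.

CDR3 construction per mode is length-invariant in shape, so that
same-class scaffolds of different loop lengths remain mutually close in
the RMSD matrix: *extended* uses fixed six-residue stems (the designed
hairpin pair, three mutual bonds) with the turn absorbing length
variation on a tip arc (lengths below 14 shorten the stems; minimum 10 so
at least two mutual bonds remain); *folded-back* runs a fixed entry, a
head-anchored stretch packed 4.7 Å above the FR2-strand face, and a fixed
exit (minimum length 8); *short* (≤ 7 residues) is a tight off-axis arc
between the anchors.

**Jitter.**  `jitter_sd` (default 0.3 Å) is applied as rigid Gaussian
displacements of whole structural units — strand pairs, the CDR3 unit,
each loop — plus an independent per-atom component of sd/5.  This
emulates the low-frequency, collective coordinate variation observed
between independently determined structures of one fold.  Fully
independent per-atom noise of the same magnitude would be unphysical for
a folded ensemble and, because Kabsch–Sander energies vary by several
kcal/mol per Å, would destroy designed hydrogen bonds that any correctly
folded structure retains; it is therefore deliberately not what
`jitter_sd` means.

**Toy complexes** place planted atom pairs 0.25 Å inside the vdW + slack
cutoff and every other cross-chain pair at least 1.0 Å outside it, so the
contact count is exact by construction.  **Titration families** follow
the Gaddum model (apparent EC50 scaled by 1 + [B]/K_B) with additive
Gaussian noise; defaults: EC50 3.3 nM, K_B 18.2 nM, agonist grid
10 pM–100 µM in half-log steps, eight antagonist concentrations
(10 nM–31.6 µM) plus control, 2% noise, six replicates (duplicates ×
three plates).  **Alignments** draw one modal residue per column and
match it with the profile probability; the reported truth is the
*realized* modal fraction.  Every generator is a pure function of spec
and seed.

## Problem sizes

The bundled analyses and checks run a 30-structure census (10 per class,
the size at which every pairwise comparison and the full clustering are
still exhaustively verifiable), three planted complexes, and one
titration family; together they complete in well under a minute on one
CPU.  The census machinery itself is O(n²) in structure count with ~0.15 s
per structure for annotation + secondary structure, so hundreds of
structures remain practical.

## Known limitations

* The secondary-structure stage targets ladder-level agreement with the
  DSSP family, not per-residue agreement with a specific release; π/3₁₀
  discrimination and solvent accessibility are out of scope.
* Classifier thresholds (7 residues, 5 Å, 0.3, 2 bonds) are defaults
  validated on synthetic scaffolds plus the VUN701 geometry; real census
  work should treat them as starting points.
* Contact totals depend on the radius table; cross-tool comparisons carry
  a ±10% caveat.
* The Schild K_B is meaningful only for surmountable antagonism; the
  slope gate (|slope − 1| ≤ 0.2) is a heuristic, and the constrained
  refit is reported rather than hidden when it fails.
* Scaffold geometry is idealized (see above); it validates algorithms,
  not force-field realism.
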