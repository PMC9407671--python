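# Methods

## Fibril model and screw-symmetry inference

A fibril is one or two protofilaments, each an ordered stack of
identical layers (chains) related by a screw operator: rise Δz (Å) along
the axis plus twist Δφ (degrees) about it. `group_layers` clusters
chains by sequence identity and pairwise backbone superposition
(residual rmsd < 0.5 Å through a rotation < 90°; the ~180° operation
relating two protofilaments of a C2 fibril therefore never joins them),
orders each protofilament by centroid projection on the axis, and
averages the screw parameters over all consecutive layer pairs.

`fit_screw_symmetry` superposes backbone N/CA/C/O atoms (side chains are
excluded: robust to rotamer noise) and decomposes the transform. Three
regimes:

* twist < 0.1°: treated as pure translation; the axis is the translation
  direction (the rotation axis is undefined).
* twist < 5°: the rotation axis of a noisy fitted matrix has error
  ∝ 1/sin(Δφ) and systematically biases the rise low (up to 4% at
  σ = 0.1 Å coordinate noise). Because the perpendicular component of
  the layer-to-layer translation is tiny at cross-β twists, the axis is
  taken from the translation direction and the twist measured by
  projecting the rotation onto it. This estimator is unbiased in
  simulation.
* otherwise: the standard axis-angle extraction.

On noiseless synthetic fibrils the fit recovers rise/twist to < 1e-6;
with σ = 0.1 Å per-coordinate noise the assembly-averaged estimate is
within 0.05 Å / 0.5° per seed (measured ≤ 0.017 Å / 0.031° over 20
seeds); a single-pair fit carries about 3× more variance.

The fibril "plus" end is the layer with the largest centroid projection
on the axis. Fibril polarity is not modeled (growth may in reality be
unidirectional); both ends are exposed as options and the CLI default
targets both.

## Secondary structure

Per-residue H/E/L labels come from rectangular (φ, ψ) basins
(H: φ ∈ (−100°, −30°), ψ ∈ (−80°, −5°); E: φ ∈ (−180°, −90°),
ψ ∈ (90°, 180°] ∪ [−180°, −170°)), smoothed so runs shorter than 4 (H)
or 3 (E) become L. This is deliberately simple and testable; an H-bond
pattern (DSSP-style) assignment is out of scope. Chain-terminal residues
have undefined dihedrals and default to L.

## Scaffolds

Blueprints list (element, length) with one helix (10–14 residues),
two or three strands (5–8), and loops (3–5), total 35–50. Backbones are
built with standard peptide geometry (N–CA 1.458, CA–C 1.525, C–N
1.329, C=O 1.231 Å; trans peptide), ideal helix (−57°, −47°) and strand
(−139°, +135°) dihedrals, and loop dihedrals sampled from three allowed
Ramachandran bins (broad α / broad β / left-handed α, weights
0.35/0.5/0.15). An independently sampled chain is almost never globular,
so each attempt folds the chain: loops are first chosen greedily (12
draws per loop, keeping the draw that most compacts the partial chain),
then refined by stochastic descent on (self-clash pairs, Rg excess),
one loop element re-sampled per proposal. A candidate is accepted when
self-clash-free (no non-bonded heavy-atom pair < 2.0 Å) and compact
(Rg ≤ 3.0·N^0.34 Å). One seeded stream drives everything, so builds are
bit-reproducible; about 7% of (blueprint, seed) pairs fail and raise, in
which case callers reseed.

Initial sequences are burial-based: burial = CA neighbors within 10 Å
(excluding i±2); buried positions (≥ 12 neighbors) draw from
{A,V,L,I,F,M,W}, exposed from {D,E,K,R,N,Q,S,T}; positive-φ loop
positions take glycine; cysteine is never assigned (intracellular
targets; no disulfides).

## Docking by motif graft

Placement is strictly graft-defined — no rigid-body search. All
window-length stretches of the chosen scaffold strand, in both parallel
and antiparallel residue order, are superposed onto the virtual next
layer restricted to the site window; candidates are ordered by
(rmsd, parallel-first, start index) and the first hard-clash-free one
wins. The clash check participates in selection because an ideal strand
is periodic: registrations shifted by one residue superpose equally well
(rmsd ≈ 0) but flip the pleat, and only the clash test against the real
fibril distinguishes them. Hard clash: heavy-atom pair < 2.5 Å; soft:
< 0.8 × (vdW radii sum) (C 1.7, N 1.55, O 1.52, S 1.8 Å). A pose with
hard clashes is flagged and never passed downstream.

## Scoring

**Hydrogen bonds.** Amide hydrogens are rebuilt geometrically (1.01 Å
from N, in-plane bisector anti to the preceding C′; first residues and
prolines donate nothing); this module is the single source of hydrogens
— input-file hydrogens are discarded at parse time. A bond requires
N···O ≤ 3.5 Å and N–H···O ≥ 120°, one best acceptor per donor (shortest
distance, ties by lower residue index).

**Dangling-bond inventory.** The tip-window inventory counts
donors/acceptors that are unsatisfied in the bare fibril *and* satisfied
when the fitted virtual next layer is added. The second condition makes
"dangling" mean "broken by truncation": a strand-terminal carbonyl that
even the next monomer could not reach is not held against a capper.
`hb_satisfied + hb_unsat` equals this inventory for every pose.

**Binding-energy surrogate.** A packaged 20×20 residue contact table
(hydropathy-sum plus charge-product terms, dimensionless, symmetric;
`data/contact_table_v1.csv`, swappable) summed over intermolecular pairs
with Cβ–Cβ ≤ 8 Å (Cα for glycine). The score has rank-ordering intent
only — it is not a physical energy. Known artifact of the Cα-for-glycine
convention: glycine can gain contacts geometrically, so greedy design
sometimes favors it at interface positions.

**Dihedral propensity.** Each residue's (φ, ψ) maps to one of five
coarse bins (αR, β, αL, PPII, other); the score is the mean of
log P(aa | bin) from a packaged propensity table with classic
preferences (β-branched residues favored in β, glycine in αL, proline in
PPII). Terminal residues with undefined dihedrals are skipped; a chain
with no defined dihedrals scores NaN.

**Centroid side chains.** One pseudo-atom per residue at 1.53 Å from CA
along CA→Cβ (the Cβ bond length; size lives in the residue-specific
radius, A 1.7 … R 3.2 … W 3.4 Å). Centroid soft clashes use the same
0.8 factor; the centroid *hard* threshold is 1.2 Å — below native
packing, since cross-β stacking legitimately brings Cβ within ~1.5 Å of
facing carbonyl oxygens. Radius monotonicity makes the steric
negative-control property exact: mutating to a larger residue at a fixed
centroid position can only add soft clashes, and a double mutant's delta
is at least the single's.

**Greedy interface design.** Ascending sweeps over interface positions
(any backbone atom within 5 Å of the fibril); at each position all 19
non-cysteine residues are tried, gated by the centroid hard-clash test,
and the best contact-energy improvement is accepted; sweeps stop at a
fixed point. Contact geometry is constant during design, so candidates
are scored incrementally from a precomputed partner table and the score
is re-anchored on the exact evaluator at every acceptance; the reported
trajectory is monotone non-increasing by construction.

**Ranking.** Filter first (hard clashes = 0; hb_unsat ≤ 2; interface
atoms ≥ 40 — both thresholds configurable, chosen as defaults, not taken
from data), then sort by contact energy ascending, ties by satisfied
H-bonds descending, then design id: a deterministic total order. The
relative weighting of the funnel metrics is an open design choice; the
lexicographic filter-then-sort scheme is this package's.

## Kinetics

ThT traces: 4-parameter logistic by bounded least squares with five
deterministic starts (best SSE kept). Baseline noise = 1.4826 × MAD of
the first quartile of *fit residuals* (residuals, so the estimate stays
a noise scale when the transition begins early in the window); a trace
is non-aggregating when the fitted amplitude is below 3× that noise, in
which case the lag is undefined and ratios return an infinite
"no-aggregation" sentinel (complete abolition outranks any finite
delay). Lag time = t50 − 2/rate (tangent-at-midpoint); the convention is
stated because "lag time" has no universal definition. Saturation
binding: one-site model with positivity bounds and multi-start in K50;
all-zero signals set a failure flag; concentration spans under one
decade set a wide-confidence flag.

## Synthetic fixtures: what they emulate and what they do not

`make_ideal_fibril` builds a layer of ideal strands (default 8 + 7
residues) joined by a fixed 3-residue turn, oriented so the first
strand's carbonyl direction — the β-sheet H-bond direction — is the
stacking axis, then stacks layers with the screw operator (default rise
4.75 Å, twist −1.2°, inside the cross-β regime). The turn dihedrals were
chosen once by geometric screening (strands in-plane and roughly
antiparallel, ~9 Å lateral separation so the two strands of one layer do
not H-bond laterally, clash-free stacking) and frozen. The stack forms a
genuine inter-layer backbone H-bond network under the 3.5 Å/120°
criterion (parallel-sheet pattern, partners offset by one residue).
Residues alternate Ala/Val so sequence-dependent scores are defined.
Two-protofilament fibrils relate the filaments by a C2 rotation about
the axis. Ground truth records the operator, strand windows, and the
noiseless held-out layer beyond each end.

`make_complementary_capper` copies the held-out next layer over the site
window plus one flanking residue per side (edge H-bond partners sit one
residue outside the window in a parallel sheet; the N-side flank may
reach into the preceding turn, the C-side stays in the strand run so the
junction keeps strand geometry) and grows an idealized body — loop,
helix, loop, strand — resampling loop dihedrals from a seeded stream
until the body clears the fibril and itself.

These fixtures are idealized: layers are exact copies, there is no
polymorphism, no side-chain atoms beyond the centroid model, no steric
zipper between sheets, and no real tau/α-synuclein/Aβ sequence. Passing
tests demonstrate the machinery is self-consistent and recovers known
ground truth; they do not demonstrate that a specific designed sequence
would inhibit a real fibril — that remains an experimental question.

Kinetic fixtures are seeded logistic/one-site curves with Gaussian
noise. The recovery conditions used in tests and in the acceptance
script are assay-realistic choices made once: the stated
parameter-recovery trace (t50 20 h, rate 0.5 /h, σ 0.02, 48 h at 30-min
reads); a fourfold-lag pair of 6 h vs 24 h (rate 1 /h, 48 h at 10-min
reads, n = 3 replicates, per-condition lag = replicate mean); a 12-point
dilution series 5 nM–10 µM with triplicate averaging for the 150 nM
half-saturation.

## Problem sizes

The default synthetic fibril is 6 layers × 18 residues (backbone atoms
only); scaffold libraries in tests and the acceptance script are tens to
two hundred seeded builds; recovery statistics use 20–50 seeds. These
sizes give stable statistics while keeping the whole suite fast on a
single core.

## Known limitations

* Backbone-centric: no rotamers, no explicit side-chain packing, no
  solvation or electrostatics beyond the charge term in the contact
  table. Scores rank designs; they do not predict affinities.
* Screw symmetry only: 2₁ packings with flipped layers and non-helical
  polymorph boundaries are not detected.
* The site-enumeration rule is the package's own (every strand window);
  it does not claim to reproduce any particular published site count.
* The builder's compactness criterion (Rg ≤ 3.0·N^0.34) is a proxy for
  foldability; no stability screen (dynamics, ab initio refolding) is
  included.
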