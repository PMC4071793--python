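# Methods

This note records the models, numerical choices and known limitations of
each pipeline stage, and what the synthetic ground-truth generators do and
do not emulate.

## Structure model and crystal content

PDB files are parsed through gemmi into a chain → residue → atom hierarchy
that keeps **author residue numbering** as the only public numbering (the
functional-site literature names residues that way, e.g. Glu272). Alternate
locations are collapsed on reading, by default to the highest-occupancy
conformer (ties go to the first in file); hydrogens stay in the model but
are excluded from surface and cavity atom sets. Residues are partitioned
into polymer / hetero / water (water iff the residue is HOH), so content
counts always sum to the residue total. mmCIF is out of scope; the writer
emits fixed-column PDB and supports a per-residue B-factor override used to
colour structures by conservation.

Crystal content uses the Matthews convention: Vm = V_cell/(Z_total·M) in
Å³/Da, with Z_total the CRYST1 Z value times the number of molecules per
asymmetric unit, and solvent fraction 1 − 1.23/Vm clipped at zero. The
1.23 Å³/Da reciprocal partial specific volume is fixed; with it,
Vm = 2.16 Å³/Da gives 43.1% solvent.

## Geometry

**Superposition** is the closed-form least-squares fit (Kabsch), solved via
`scipy`'s `Rotation.align_vectors`; reflections are disallowed and
collinear point sets are rejected (the rotation would be underdetermined).

**Dihedrals** follow the IUPAC sign convention; φ/ψ are undefined at
termini, at missing backbone atoms, and across chain breaks, where a break
is C(i)–N(i+1) > 2.5 Å (an unmodelled loop leaves a numbering gap with a
long C–N distance).

**SASA** is Shrake–Rupley with a deterministic golden-spiral lattice of
960 points per atom — no random orientation, so results are bit-stable
without seeds. Radii: C 1.70, N 1.55, O 1.52, S 1.80 Å (default 1.70 with
a warning for unknown elements); probe 1.4 Å. Relative SASA divides by the
theoretical Gly-X-Gly maxima of Tien et al. (2013); the 0.2 threshold for
"surface" is the usual convention and is configurable.

**Segment superposition** (for internal repeats) is sequence-independent
and order-preserving: a gapless midpoint-anchored seed correspondence is
alternately refined by Kabsch fitting and order-preserving dynamic
programming on the inter-segment Cα distance matrix with score
max(0, 5 Å − d), until the pair set is stable (≤ 50 iterations).
Order-preserving matching is appropriate because tandem repeats align
colinearly; it will not find circularly permuted equivalences. Published
repeat statistics from multi-structure aligners (e.g. a 53-residue
three-repeat core at 3.71 Å) are method-specific; this implementation is
expected to reproduce the qualitative equivalence (≥ 40 three-way matched
positions at ≤ 4.5 Å), not those exact numbers.

## Conservation

Column conservation is Jensen–Shannon divergence (base-2) between the
column's amino-acid frequency vector and a fixed BLOSUM62-derived
background, normalised by the largest divergence any single-residue column
can reach, so scores lie in [0,1] and an invariant column of the rarest
background residue (Trp) scores exactly 1. The pseudo-count (total mass
20 × 1/20 × 0.05) is applied in frequency space — the frequency vector is
mixed with a small uniform mass — which makes scores independent of
alignment depth: duplicating every row changes nothing. With the gap
penalty on (default), scores are multiplied by (1 − gap fraction); all-gap
columns score 0. This is a deliberate, deterministic replacement for
Bayesian phylogeny-aware rate estimation (ConSurf-style): it ignores
sequence relatedness and will overweight clades of near-duplicates, but it
is dependency-free and adequate for locating conserved patches.

Mapping onto a structure aligns the ungapped alignment row to the chain's
observed sequence globally (match 1, mismatch −1, gap −2); an identity
below 90% over the structure residues aborts, since that indicates the
wrong row or chain rather than a noisy alignment. Patch detection smooths
residue scores over surface neighbours within 8 Å of Cα, keeps residues
above the 80th percentile of smoothed scores, clusters them by Cα
connectivity at the same radius, and ranks patches by mean smoothed score
× size.

## Site inference

**Template matching.** Functional-atom groups: Asp CG/OD1/OD2, Glu
CD/OE1/OE2, with the carboxylate carbon as anchor. Asp ↔ Glu are one
equivalence class, and the two carboxylate oxygens may swap — both are
chemically necessary (convergent sites pair Asp with Glu across folds, and
OD1/OD2 labelling is arbitrary). Candidate tuples are pre-filtered on
anchor pairwise distances (within ±3 Å of the template's own, and below a
15 Å span), then scored by the minimum Kabsch RMSD over member assignments
and oxygen swaps; hits at ≤ 2.5 Å RMSD are kept, deduplicated per residue
set, and sorted. No statistical significance is attached to hits (PINTS-
style p-values are out of scope); the RMSD and the evidence integration
carry the weight.

**Nests.** A residue is labelled R if φ ∈ (−140,−20), L if φ ∈ (20,140),
each requiring |ψ| ≤ 90; a nest is a maximal alternating run of ≥ 2
labelled residues plus the following residue (minimum 3 residues). The
windows operationalise a prose definition from the nest literature and are
configurable; they are wide enough that ideal αR and αL conformations sit
comfortably inside.

**Cavities.** Grid spacing 0.9 Å over the heavy-polymer-atom bounding box
plus a 2 Å margin; a grid point is protein if within vdW+probe of any
atom; a free point is a pocket point if protein encloses it along ≥ 5 of
the 7 fixed scan directions; 26-connected clusters of ≥ 50 Å³ become
cavities ranked by volume (ties by centroid lexicographic order). Waters
and heteroatoms are excluded from the defining atom set so ligand-occupied
cavities are still found. Grid volumes are method-dependent: this scan
reproduces volume *ordering* and lining residues, not the absolute volumes
printed by other cavity programs (SURFNET-class tools differ by tens of
percent on the same site).

**Evidence integration.** The composite score is the weighted sum given in
the README; each term is in [0,1] before weighting, improving any single
term can only raise a cavity's score, and ties break by volume then
centroid order, so rankings are deterministic. The volume term uses
V/Vmax (monotone in volume) rather than an inverse-rank step so that
near-equal cavities score near-equally.

## Phylogenetics

Distances: p = mismatches/usable sites, Poisson correction
d = −ln(1 − p). "Ambiguous" means gap or X; pairwise deletion (the
default, matching the usual MEGA wording) removes ambiguous sites per
sequence pair, complete deletion removes them for all rows. p = 1 leaves
the correction undefined and raises.

Neighbor-joining uses the standard Q criterion; ties break by the smallest
(i, j) index pair, and negative branch lengths are clamped to zero with
the deficit moved to the sister branch so path lengths are preserved
(Kuhner–Felsenstein convention). NJ is exact on additive matrices, which
the tests exploit (Robinson–Foulds 0 against the generating topology,
cross-checked against scikit-bio's NJ on perturbed matrices).

Bootstrap: columns are resampled with replacement per replicate; supports
are the fraction of retained replicates containing each bipartition of the
full-data NJ tree, reported on a 0–1 scale as internal node labels on that
tree (no separate majority-rule consensus topology is built — the
full-data tree with supports is what gets drawn). Replicates whose
resample yields an undefined distance matrix (a saturated pair, p = 1) are
discarded and supports are normalised over the retained replicates; with
500 replicates on real alignments this is a vanishing correction, but it
matters on tiny test alignments. Supports are invariant to taxon order
because bipartitions are encoded as label sets. A given seed fixes the
entire replicate stream.

## Synthetic generators

All generators are deterministic under a fixed seed, and serialised
fixtures are byte-stable.

- `build_helix` extends an N–CA–C backbone by natural-extension (NeRF)
  placement at ideal peptide geometry (N–CA 1.458, CA–C 1.525, C–N
  1.329 Å; angles 111.2/116.2/121.7°; ω = 180°), so measured dihedrals
  reproduce the inputs to within 0.5°. Side chains and carbonyl oxygens
  are not built — these backbones test geometry, not packing.
- `plant_triad` rewrites three spread-out residues of a base structure so
  their functional atoms are a rigidly transformed template copy plus
  isotropic Gaussian noise; the ground truth stores the keys, the exact
  transform and the noisy coordinates, so a direct Kabsch on the known
  correspondence is an independent oracle for the matcher. Because the
  oxygen swap and the Asp↔Asp member exchange are legitimate matching
  freedoms, the oracle evaluates the hit's reported correspondence
  (minimising over oxygen swaps), not the planted labelling, which noise
  can make slightly suboptimal.
- `make_cavity_shell` places pseudo-atoms on two staggered concentric
  golden-spiral lattices so that the probe-inflated free region inside is
  a sphere of the requested radius; generation flood-fills a coarse grid
  and refuses to emit a leaking shell. The lattice spacing default
  (2.2 Å) keeps the geometric free-void bulge between lattice atoms below
  ~5% of the analytic volume so that the grid detector's discretisation
  error dominates and shrinks as the grid is refined; much sparser shells
  leave a static bulge that caps achievable accuracy.
- `simulate_msa` evolves a uniform-random root sequence along a tree:
  per branch of length t each non-invariant site substitutes with
  probability 1 − e^(−rate·t) to one of the 19 other residues uniformly.
  This is exactly the model the Poisson distance correction inverts, so
  simulate → distance → NJ is a closed-loop recovery test. One
  substitution event per branch per site is drawn (no within-branch
  multiple hits), so for quantitative checks the expected observed
  difference is p = 1 − (1−q₁)(1−q₂) − q₁q₂/19 per branch pair rather
  than the textbook saturation curve; the tests use this exact form.
  Planted invariant sites never change. Real alignments differ in every
  inconvenient way — rate heterogeneity, indels, compositional bias —
  so passing these tests shows internal consistency of the estimators,
  not robustness to model violation.

## Problem sizes

The default test battery uses 40-residue bases for planting, shells of
radius 5–8 Å (≈ 600–1500 pseudo-atoms), 200 random additive matrices of up
to 10 taxa, simulated alignments of up to 2000 columns on 8 taxa, and
500-replicate bootstraps on 4-taxon alignments; the whole suite runs in
well under a minute, and the acceptance script in about two.

## Known limitations

- Deposited-structure checks require the user to supply the coordinate
  files (`data/README.md`); they are not bundled.
- Conservation scoring is not phylogeny-aware (see above).
- Cavity volumes are grid- and parameter-dependent; only ordering, lining
  and location are contractual.
- The segment aligner assumes colinear repeats; the nest windows are an
  operationalisation of a prose definition.
- The Poisson simulator draws at most one substitution per branch per
  site; branch lengths above ~1 substitution/site saturate accordingly.
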