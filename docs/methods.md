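# Methods

## Ring geometry and distance classes

A Cn-symmetric homo-oligomer carries one label site per protomer on a ring
of radius *R* about the symmetry axis. The pairwise site distances take the
chord values d_k = 2R·sin(kπ/n), k = 1…⌊n/2⌋, with multiplicity n per class
(n/2 for the diametral class of even n); `distance_classes` computes all
n(n−1)/2 pairwise distances and merges them within a tolerance (0.01 Å for
ideal rings, 1 Å for template-derived assemblies, which are never exactly
symmetric). The default candidate radii — 21.36 Å (trimer), 15.31 Å
(pentamer), 16.0 Å (hexamer) — are chosen so the ideal chords reproduce the
distance sets predicted for an A–B-loop label from the corresponding
trimeric/pentameric/hexameric template structures: a single ~37 Å class,
~18 and ~29 Å, and ~16/~28/~31 Å respectively.

The label site is the CA atom of the labeled residue (point-label
approximation). A nitroxide R1 side chain actually places the unpaired
electron 2–4 Å away from the backbone with rotamer spread; we do not model
rotamer clouds, and instead let the classifier's assignment costs and the
10 Å unmatched penalty absorb the offset. This is the main systematic
approximation of the geometric stage.

Template-based assembly (`assemble_on_template`) superposes the monomer
onto each chain of a multi-chain template with the iterative Kabsch
procedure below and reports per-chain RMSD; the symmetry axis of an
assembled ring, where needed, is the principal axis of the label sites.

## Superposition

`kabsch` solves the least-RMSD rigid superposition in closed form (SVD of
the cross-covariance, determinant-sign correction to exclude reflections).
`superpose_structures` runs up to 5 cycles of full fit followed by
rejection of residue pairs with residuals above mean + 2σ, with an absolute
floor of 0.1 Å on the rejection threshold so that near-perfect fits never
reject pairs on numerical noise. Residue correspondences come from global
Needleman–Wunsch–Gotoh alignment (BLOSUM62, gap open −10, extend −1), the
standard scoring for homologs in the ~30% identity range. The default atom
set is CA, the convention for fold-level comparison; backbone (N, CA, C, O)
is available. Structures are held as biotite `AtomArray`s (float32
coordinates, so "exact" comparisons are meaningful only to ~10⁻⁵ relative).

## DEER forward model

The intramolecular form factor of a spin pair at distance r is the
isotropic orientation average of the secular dipolar oscillation; its
frequency is ν(r) = D/r³ with D = (μ₀/4π)·g²μ_B²/h = 52.04 MHz·nm³
computed from CODATA constants. The kernel is evaluated by its Fresnel
closed form, with K(0, r) = 1 handled analytically. Distributions enter in
the pair-sum approximation F(t) = 1 − λ + λ∫K(t,r)P(r)dr: an n-spin ring is
treated as a weighted sum of pair contributions, not an n-spin product
state. At shallow modulation depth this is standard; it omits multispin
"ghost" peaks, which for a pentamer at λ = 0.3 are small but would bias
very-high-depth data.

Discretization: the kernel's phase varies in r as 3·2πνt/r, which at the
late end of a 2.5 µs trace oscillates with sub-Ångström period — pointwise
column sampling aliases. Kernel matrix columns are therefore bin averages
(5-point Gauss–Legendre per r bin), which makes simulated signals stable
under grid refinement (< 10⁻⁴ change from 0.5 to 0.25 Å spacing).

Default grids: t ∈ [0, 2.5] µs in 8 ns steps (≥ 2 oscillation periods for
the distances of interest); r ∈ [10, 80] Å in 0.5 Å steps. The
reconstruction grid deliberately extends below the 15 Å detection limit: a
density component at the grid edge is truncated and systematically
suppressed by the smoothness penalty, so the basis must be wider than the
window in which peaks are trusted.

Noise is i.i.d. Gaussian with σ = λ/SNR, the convention that SNR refers to
the modulated signal amplitude.

## Inversion

Background correction fits ln V(t) linearly on t ≥ 0.6·t_max, where the
form factor has decayed to its 1 − λ plateau; the slope gives the
background rate k, the intercept gives λ, and the corrected form factor is
rescaled to F(0) = 1. The dipolar signal S = (F − (1−λ))/λ is then inverted
by non-negative Tikhonov regularization: stacked least squares [K; αL] vs
[S; 0] solved with deterministic NNLS, L the second-difference operator
with reflective ends, and the result renormalized to unit area.

Automatic regularization (`alpha="auto"`) uses generalized cross-validation
with the influence-matrix trace computed on the NNLS active set. Because
the GCV profile typically has a long shallow plateau whose low-α end fits
noise, the selected α is the largest one scoring within 5% of the minimum —
the smoothest solution the data cannot distinguish from the best-scoring
one, analogous to the one-standard-error rule in cross-validated model
selection. An L-curve selector (`select_alpha`) is provided as the
noise-agnostic alternative; it locates the corner as the knee of the
min-max-normalized (log‖KP−S‖, log‖LP‖) curve, which on discrete NNLS
L-curves is far more stable than pointwise curvature estimates. On clean
two-component signals the two selectors agree to within a grid step; GCV
resolves closely spaced components (e.g. the hexamer's 27.7/32 Å pair)
better and is the default.

Peaks are local maxima with prominence ≥ 5% of max P and mutual separation
≥ 2 Å. Components closer than ~5 Å merge into one peak at realistic widths
and noise — a physical resolution limit of the experiment, not of the
solver — which is why classification must tolerate merged classes failing
to appear.

## Classification

Each candidate oligomer contributes its predicted distance classes within
the detection window [15, 60] Å; outside it short distances are broadened
beyond recognition and long distances exceed what a 2.5 µs trace
constrains, so both out-of-window predictions and out-of-window observed
peaks are excluded. Observed peaks are assigned to predictions by an exact
minimum-cost one-to-one assignment (rectangular linear sum assignment,
verified against exhaustive enumeration in the tests) with cost
|d_obs − d_pred| per matched pair and a flat 10 Å penalty per unmatched
observed peak or unmatched in-window prediction — larger than any credible
peak-position error, small enough not to drown the match terms. Candidates
are ranked by total cost; ties break toward smaller n (parsimony). With
observed peaks {19, 29} the pentamer wins at cost ≈ 1.1 Å; an empty peak
set selects the monomer at cost 0.

## Structural motifs and oligomerization groups

Three binary features separate the oligomerization classes of light-driven
bacterial pumps. (1) The 3-omega motif: a π-stacked triad of aromatic side
chains, one each from helix A, helix B and the B-C loop; detection searches
all such triples for mutual ring-centroid distances ≤ 7 Å (covering offset
stacking) and reports the minimum-sum triple. (2) B-C loop orientation: the
loop-tip CA is compared radially, about the principal axis of all helix CA
atoms, with helix CA atoms within ±5 Å of the same axial height; "flipped"
means the tip lies ≥ 2 Å outside that local bundle radius. (3) Helix
extension: after CA superposition onto a reference structure, the axial
extent (projection onto the reference bundle axis) of helices A, B and G is
compared with the reference. Helix boundaries are user-supplied
annotations; automatic secondary-structure assignment is out of scope.

Group assignment: no extension → group 1 (trimer formers); extension
without the motif → group 2 (proteorhodopsin-like pentamer/hexamer
formers); extension with motif and flipped loop → group 3 (XR-type
pentamer formers). The motif without extension, or without the flipped
loop, is geometrically contradictory (the triad sits on the extended
helix segments and tethers the loop outward) and returns "unclassified";
this makes the map total over all 8 feature combinations.

## Phylogenetics

Pairwise distances are Poisson-corrected, d = −ln(1 − p), from the
proportion p of differing sites after complete deletion of columns with
gaps or missing data. Trees are built by Saitou–Nei Neighbor-Joining with
two deterministic conventions: Q-criterion ties break toward the
lexicographically smallest active pair, and negative branch estimates are
clamped to zero with the deficit transferred to the sibling branch
(matching common implementations). NJ recovers any additive matrix exactly;
the tests verify this to 10⁻⁹ on 50 random additive trees and check
topology against an exhaustive 15-topology least-squares oracle for 5 taxa
and against an independent NJ implementation. Multiple sequence alignment
itself is an input, not computed here.

## Synthetic data

`make_toy_bundle` builds seven-helix bundles from ideal α-helix CA traces
(2.3 Å helical radius, 100° twist, 1.5 Å rise per residue) on a circle,
with CB stubs, an A-B loop carrying the label residue, a B-C loop whose tip
is placed inward or flipped, optional elongation of helices A/B/G (7
residues ≈ two turns) and an optional planted aromatic triad. Random
sequences avoid aromatics so the planted triad is the only π-stacking
candidate. These bundles exercise every structural detector but do not
emulate side-chain packing, real loop conformations or a membrane —
passing tests show the detectors respond to the intended geometric
features, not that the thresholds are calibrated for real structures.

`make_ring_assembly` replicates a monomer by Cn rotation with the label CA
at a specified radius; jitter displaces each protomer rigidly (isotropic
Gaussian translation), emulating imperfect ring symmetry.

`make_deer_dataset` composes the forward model for a Gaussian-mixture
ground truth. Two widths are used: σ = 1.5 Å for emulating experimental
peaks (label rotamer disorder dominates) and σ = 1.0 Å for ring-derived
ground truths in the discrimination experiment, where the generator's
point labels sit on a rigid assembly.

`evolve_sequences` runs uniform substitution over the 20 amino acids
(Poisson number of events per site per branch, each to a uniformly random
different residue) — exactly the process whose pairwise distances the
Poisson correction inverts, up to the small unobserved-back-substitution
bias (< 1% at d = 0.3).

## Problem sizes and determinism

The discrimination experiment runs trimer/pentamer/hexamer × 20 noise
seeds at SNR 50; tree-recovery runs 20 six-taxon families of 5000 sites;
the inversion grid is 314 time points × 141 distance points with a
19-point α grid. Every stochastic component takes an explicit seed and is
bit-reproducible; no global random state is used.

## Known limitations

* Point labels: absolute predicted distances carry a 2–4 Å systematic
  offset relative to real nitroxide positions; conclusions rest on
  pattern matching (number and spacing of classes), which is robust to a
  common offset, but borderline candidate pairs could flip.
* Pair-sum form factors omit multispin ghost peaks.
* Components separated by less than ~5 Å merge in the recovered
  distribution at realistic noise; the hexamer is identified mainly by
  its 16 Å class plus the merged upper classes resolving at moderate
  regularization.
* The classifier assumes a single homogeneous oligomeric species;
  coexisting states (mixtures) are not deconvolved.
* Superposition RMSD depends on the atom set and outlier-rejection
  protocol; published pairwise RMSD values for homologous structures are
  reproducible only to within protocol differences (a few tenths of an Å).
* The B-C loop classifier depends on a 2 Å radial margin chosen to
  separate the synthetic fixtures robustly; it is a tunable parameter,
  not a calibrated constant.
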