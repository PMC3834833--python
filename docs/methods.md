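# Methods

This note records the models, numerical choices and known limitations of
the package, in the order a pipeline run encounters them.

## Synthetic assembly

The generator emulates the structural features the analysis depends on, not
the protein's atomic detail. A subunit is a serpentine Cα-like trace laid on
a spherical-shell sector (polar angle 12–84°, azimuthal width 90°), with
near-uniform arc spacing chosen by bisection so consecutive residues sit
well inside the 5 Å distortion-filter bond window and the 12 Å
elastic-network cutoff. With the default 160 beads per subunit the spacing
is ≈4.2 Å, close to a real Cα virtual bond. Four rotated copies form the
upper tetramer (exact C4 symmetry about z); the lower tetramer is the exact
two-fold image about x, so the compact assembly carries both symmetry axes
by construction and is hollow (all beads on the 45 Å shell; nothing within
0.4× the outer radius of the center). The opening motion is a rigid ±h/2
translation of the two tetramers along the polar axis — the simplest motion
consistent with a flexible equatorial hinge between the tetramers — so a
hinge opening of h extends the maximum inter-bead distance by ≈h.

What the generator does **not** emulate: side-chain chemistry, the true
subunit fold, interparticle interference, buffer subtraction or
concentration merging (curves are emitted already subtracted, one
concentration). Passing tests therefore demonstrate that the *analysis
machinery* behaves correctly on data with the assumed statistical structure,
not that it would reproduce any particular beamline measurement.

Terminal tails (12 N-terminal + 11 C-terminal residues per subunit, the
His-tag construct) are self-avoiding random walks with a fixed 3.8 Å step,
grown outward from each chain end with a 0.7 direction-persistence weight,
rejecting placements within 3.0 Å of the core or of earlier tail beads
(up to 200 direction attempts per bead, whole-member resampling above
that). Cavity RNA conformers are persistent random walks of the C4′ trace
(steps uniform in 5–7 Å) reflected into the cavity sphere, with phosphate
and base beads placed radially around the backbone.

Simulated curves use σ(s) = level·I(s) + floor with Gaussian noise; the
default level of 1% mimics a well-measured synchrotron curve at mid
angles. The default grid is 201 points on 0.009–0.40 Å⁻¹, matching the
analysis windows (the experimental range extends further on both sides, but
no analysis step uses it).

## SAXS computations

**Debye profile.** Vacuum Debye sum with unit form factors: no hydration
shell and no excluded-volume term, because the inputs are coarse beads and
every downstream check is oracle- or recovery-based rather than
absolute-scale. For more than 500 beads the pair distances are binned at
0.1 Å and the double sum replaced by a histogram sum; an exact-sum test
pins the acceleration error (≤5·10⁻³ relative; the error scales with
s·bin width).

**Guinier fit.** Weighted least squares of ln I on s², iterated so the
window satisfies s_max·Rg ≤ 1.3, then shrunk further while an s⁴ curvature
term is statistically significant (F statistic above 10). The second stage
matters: for a compact particle the curve bends *inside* the conventional
window, and a plain fixed-window fit overestimates Rg by 1–2% — more than
the accuracy the sphere benchmark demands. With noisy data the F test keeps
the window wide, so precision is not sacrificed where the bias is invisible.
Curves that rise at low angle (aggregation-like) are rejected rather than
fitted.

**p(r).** From coordinates: a weighted distance histogram, D_max exact.
From a curve: non-negative least squares for p(r) on [0, d_max] under the
forward transform I(s) = ∫p(r)·sinc(sr)dr, with a second-difference
smoothness penalty (α = 10⁻³ of the norm-matched scale) and clamped
endpoints, on the 0.020–0.30 Å⁻¹ window. This is a standard regularized
indirect transform; noise-free recovery of a smooth p(r) correlates ≥0.99
with truth.

**Porod mass.** Q = ∫s²I ds with the Guinier extrapolation supplying the
[0, s_min] head and *no* high-angle extrapolation beyond the measured
s_max — the simplest defensible estimator. Truncation biases V_p upward by
roughly the tail fraction of the invariant (≈6% at s_max·R ≈ 16), which is
the dominant term of the ≤10% sphere benchmark error. The 1.6 nm³/kDa
conversion is the conventional protein value.

**χ figure of merit.** CRYSOL-style: χ² = (1/(N−1))·Σ((I_exp − c·I_model)/σ)²
with the scale c in closed form, on 0.020–0.40 Å⁻¹; experimental points with
σ = 0 get σ = 1% of I with a warning.

**Subunit counts** divide the measured mass by the 26.8 kDa protomer and
round half-up to one decimal.

## Elastic-network sampling

An anisotropic network model with uniform springs on all bead pairs within
12 Å; one consistent network serves all three samplers (the original
workflow used three external tools with differing internals). The Hessian
is diagonalized densely up to 1500 coordinates and by sparse shift-invert
Lanczos (σ = −10⁻⁴, deterministic start vector, sign-fixed eigenvectors)
above that. Exactly six near-zero modes are expected for a connected
network; disconnection at the cutoff is an error naming the component
sizes.

Amplitudes are mapped to displacements as Δx = (A·r₀/1000)·u with u the
unit eigenvector and r₀ = 100 Å, so the "arbitrary units" of the amplitude
grid have an explicit, logged meaning: A = 1000 moves the whole bead set by
r₀ in the 3N-norm (Cα RMSD = |A|·r₀/(1000·√N)). The grid sampler covers
each of the 5 modes at ±2000 step 100 (singles) and all 10 mode pairs on a
coarser ±2000 step 500 grid (so the census stays desk-scale: 1000
conformers before filtering). The Monte-Carlo sampler draws independent
Gaussian amplitudes; the iterative sampler accumulates uniform random
single-mode steps in Cartesian coordinates (an internal-coordinate
treatment is out of scope). Because displacements are linear, each stored
conformer is exactly reproducible from its per-mode amplitude record.

The distortion filter counts within-chain consecutive-bead pairs stretched
beyond 5 Å and keeps conformers with at most 200; inter-chain gaps never
count.

## Ensemble selection

The inner solver is non-negative least squares on σ-weighted intensities;
the overall scale is absorbed so reported weights sum to 1. The
minimal-ensemble search runs a genetic algorithm per ensemble size
K = 1…5 (size-1 exhaustively) and reports the smallest K whose best χ is
within 5% of the best over all K — the parsimony rule is explicit because
the original selection rule is not published. The large-ensemble search
evolves fixed-size multisets (50 members, repetition allowed, uniform
weights) in 5 independent runs, reporting the best run and aggregated
selection frequencies. GA defaults: population 100, 200 generations,
tournament 3, per-gene mutation 0.05, elitism 1; tests and demos use
smaller, stated configurations because the libraries involved are small.
Populations are classified compact/open by explicit labels or an Rg
threshold on the conformer manifest.

Recovery behaviour (measured by the acceptance script, 20 noise seeds at 1%
noise, 16-curve hinge-sweep library): mean absolute error of the recovered
compact fraction ≈ 0.001 (MES) and ≈ 0.01 (EOM) against a 0.18/0.82
two-state truth.

## ssRNA docking

The dinucleotide docker is an FFT shape-complementarity search: receptor
cells are scored +1 on the one-cell surface layer and −15 in the core;
the rotated ligand's occupied cells, dilated to a 3 Å contact footprint,
are correlated against the surface grid, and any raw-cell overlap with the
core excludes a placement. Optional controls mirror practice in grid
dockers: an explicit rotation set, a per-rotation retention quota, and
non-maximum suppression of translation peaks (without it one deep site
soaks up the entire candidate list). The GU template carries a second
guanine base bead — purines have two rings — which makes it geometrically
directional.

Pose processing follows the published funnel: a 5 Å proximity filter to the
known binding residues, 10 Å single-linkage clustering on the maximum
corresponding-bead distance (best score per cluster), graph chaining of up
to 12 slots where pose i links to pose j with g gaps if their 3′/5′ C4′
anchors are separated by [4.5·(g+1), 8.0·(g+1)] Å (the bond window brackets
single-stranded backbone spacing and is configurable), and clustering of
combinations that share at least 70% of their poses (set-based, i.e. ≥9 of
12, over the longer path's slot count). Path enumeration is capped
(500 000 by default) because all-simple-paths counting is combinatorial.

Threading builds an ideal single-stranded helix (3 beads per nucleotide,
rise 5.9 Å, twist 32.7°/nt, radius 4 Å), superposes it rigidly onto the
anchor C4′ positions, and minimizes a harmonic energy (bond terms and 1–3
distance terms at their ideal-helix values, plus anchor restraints) with
L-BFGS and an analytic gradient. The clash filter counts
receptor-bead/RNA-bead pairs closer than 3.5 Å and keeps models with at
most 150; contacts of anchored nucleotides with binding-site residues are
excluded because they are the docking signal. On the coarse 3-bead scale
one bead stands for 8–11 atoms, so the all-atom threshold of 150 is
generous; pipeline configurations that want an equally strict filter at
bead resolution should scale it down by roughly the bead-to-atom ratio
(≈15–30).

**Known limitation.** On the planted-ring benchmark (12 dinucleotide
pockets around a ball's equator) the funnel reliably recovers poses in ≥9
of the 12 pockets and the planted 12-pose combination threads into a
clash-free model, but a *blind* single pass rarely assembles one chain
visiting 9+ pockets: the shape-only score cannot see strand polarity on a
quasi-cylindrical dinucleotide, so about half the recovered poses are
reversed and break the chain windows. The published procedure was not
shape-only (full atomic potentials) and threaded ~66 000 combinations
before filtering to ~4%, a scale this package reproduces only in spirit.
The end-to-end tests therefore verify the funnel's stages jointly but
assert chain completeness on the planted combination.

## Pipeline demos

`run-free` samples the compact assembly's five lowest modes on a coarsened
amplitude grid (singles step 500, pairs step 1000 → 264 filtered
conformers), attaches 2 tail conformers per model (10 is the
publication-faithful default; 2 keeps the demo inside a coffee break
without changing the averaging semantics), synthesizes the experimental
curve from the reference (18%) plus the three largest-Rg conformers (82%,
split 45.8/23.3/13.3), and re-resolves the equilibrium. Because the opening
modes of a hollow shell change Rg by only ≈1 Å while extending D_max by
tens of Å, the compact/open Rg threshold sits 0.5 Å above the reference Rg
(between the two observed clusters). `run-complex` reuses the four
generating conformers as docking receptors, threads as much of the (GU)₁₂
sequence as each anchor path spans (so the modelled RNA stays in the
cavity instead of dangling), and fits ensembles of complex models. Both
demos are bit-for-bit reproducible for a fixed seed; the sparse
eigensolver uses a deterministic start vector and a sign convention for
exactly this reason.

## Degenerate inputs and tie-breaks

Duplicate (chain, residue, bead-name) keys, non-finite coordinates,
non-positive weights, decreasing s grids and negative σ are rejected at
construction. Ties in pose scores break by lowest pose id; ties in
candidate docking placements break deterministically by rotation index and
translation. Guinier fits require ≥5 usable points; χ fits require ≥3
points in the window and a model grid covering it.
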