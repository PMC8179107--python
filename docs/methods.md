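# Methods

This note documents the models, estimators, defaults and numerical
choices behind `loopmsm`, and what the synthetic validation does and
does not establish about real trajectory data.

## Synthetic generator

The toy system is a 3-D bead chain, one bead per residue at 3.8 Å
spacing along a gentle helix (radius 5 Å, 0.6 rad/residue).  Two
disjoint residue blocks act as mobile loops; each block hops between
`n_conformations` discrete geometries under an independent symmetric
discrete-time Markov chain with per-frame switch probability `p`
(split equally among alternatives).  Conformation 0 lies on the
backbone ("recessed"); conformation 1 is displaced 6 Å radially
outward ("extended"); conformation ≥ 2 (used to plant system-exclusive
states) is displaced axially plus half-radially.  All residues receive
isotropic Gaussian jitter (default σ = 0.3 Å) — the simplest noise
model that keeps the conformations separable (the generator warns when
any two conformations differ by less than 4σ in their distances to
scaffold residues, since selection may then legitimately fail).

Defaults: 40 residues; fast block 8–12 with p = 0.01/frame; slow block
28–33 with p = 0.002/frame; 10 trajectories × 20 000 frames.  The 5×
rate separation is large enough that tIC1/tIC2 and the
implied-timescale gap resolve the two processes, yet both are sampled
in a desk-scale run; 2×10⁵ total frames give ~400 slow-block
transitions, enough to estimate the slow MFPT to ~10 %.  Tests and the
acceptance script use smaller explicit sizes per stage (stated below)
to keep the suite fast; statistically the checks are
scale-invariant — coverage and recovery rates depend on estimator
calibration, not problem size.

Hidden dynamics are discrete-time at the frame interval (per-frame
switch probabilities, not rate matrices), matching how MSMs consume
data.  The product of the two block chains (Kronecker product of their
transition matrices) is the planted macrostate process; its stationary
distribution and the full MFPT matrix (by the linear solve below) are
returned as ground truth.  The fully absorbing identity chain is
accepted by the feature-level generator (the hidden path trivially
stays at its initial draw); any other reducible chain is rejected.

The relaxation generator forward-models R1/R2/NOE through the same
model-free operator used for fitting, plus Gaussian noise with stated
per-observable SD (written into the error columns).  It optionally
plants per-residue exchange terms Rex.

What the generator does *not* emulate: physical force-field geometry,
continuous (non-discrete) conformational diffusion, state-dependent
noise, anisotropic tumbling, field-strength-dependent Rex.  Passing
tests therefore demonstrate estimator correctness and statistical
calibration under the stated model, not robustness to every pathology
of real MD or real spectra.

## Featurization

Distances are Cα–Cα (anchors are reported at residue resolution, and a
Cα-only representation suffices for loop-scale geometry).  Pair
enumeration excludes a configurable number of terminal residues
(default clip 2) at each end.  Pruning removes a feature only when
*all* frames are below 3 Å or all above 10 Å; when two systems are
analysed jointly the rule is evaluated over the union of their frames
so both share one feature set, which the shared-coordinate comparison
requires.  RMSF superposes each trajectory on its mean structure
(Kabsch, iterated from the first frame until the mean converges), then
pools squared deviations across trajectories.

## tICA

Covariances use the symmetric (reversible) estimator: means and C(0)
are averaged over both ends of each lagged pair, C(τ) is symmetrized;
pairs never cross trajectory-segment boundaries.  The generalized
eigenproblem C(τ)v = λC(0)v is solved after adding a ridge
reg_epsilon·tr(C0)/d to C(0)'s diagonal (default 1e-6) — an all-pairs
first pass is rank-deficient by construction; with reg_epsilon = 0 a
singular C(0) raises instead.  Components are C(0)-orthonormalized,
ordered by eigenvalue, and sign-fixed so each component's
largest-magnitude loading is positive.  Projections are plain
eigenvector projections (no kinetic-map scaling): downstream landscapes
are density-based, so the scaling is cosmetic.  Emission noise on top
of a hidden chain multiplies the observed eigenvalue by the
signal-variance fraction, so spectral-recovery checks keep noise small
relative to centroid separation.

## Iterative feature selection

Score = max |Pearson correlation| between the raw feature time series
and the first `n_tics_considered` projected tICs (default 2, one per
planted loop process).  Elimination: drop the lowest-scoring half while
more than 2K features remain, then one at a time down to K (default
24); ties break by lexicographic label;
tICA is refit from scratch each iteration.  Stopping: at K, at
`max_iterations`, when all scores are equal ("stalled"), or — under the
alternative threshold rule — when no feature scores below
`min_correlation`.  The anchor-recovery validation runs at the default
K = 24: the top-3 anchor statistic is count-based, and a very small K
dilutes the larger block's per-residue counts (a block-size artifact,
not a property of the method); some unit tests use K = 10 where they
assert pair membership, which is insensitive to K.
The per-iteration log records feature count, score
range and the slowest timescale, so one can verify that elimination
never destroys the slow processes (the toy tests require the selected
set to retain the full-set slowest timescale within 20 %).

## Microstate MSM

k-means (k-means++ init, fixed seed, 3 restarts) in the space of the
leading tICs; sliding-window transition counts at lag τ that never
cross trajectory boundaries; largest strongly connected component by
total counts.  The reversible maximum-likelihood transition matrix is
found by the standard self-consistent iteration on the flux variables
x_ij = π_i T_ij,

    x_ij ← (C_ij + C_ji) / (c_i/x_i + c_j/x_j),

normalized each sweep, converged when the relative change drops below
1e-10 (the map is homogeneous, so normalization does not move the fixed
point).  π comes from the row sums of x; eigenvalues are obtained from
the π-symmetrized matrix, guaranteeing real spectra.  For 2-state
chains the reversible MLE equals row-normalized counts (every 2-state
chain is reversible) — used as an analytic oracle in the tests.
Implied timescales are tabulated per lag; per-lag failures are recorded
as NaN, not fatal.  The Chapman–Kolmogorov test compares T(τ)^f with a
model re-estimated at fτ on user-defined state groups.  Free-energy
surfaces are F = −kT ln p̂ on a 2-D histogram of (tIC1, tIC2), shifted
to min 0, empty bins masked; optional per-frame weights allow
MSM-reweighted surfaces (plain histogramming is the default).

## Metastable coarse-graining

The macrostate count comes from the implied-timescale gap: n = 1 +
argmax(t_k/t_{k+1}); an explicit override always wins, and a spectrum
with all ratios < 1.5 raises rather than guessing.  PCCA+ (inner-simplex
vertex search on the dominant right eigenvectors, barycentric
memberships, negatives clipped and rows renormalized) initializes a
discrete-output HMM: the membership-projected coarse transition matrix
and emission profile seed Baum–Welch (hmmlearn backend), observed at
stride = lag, converged at log-likelihood gain < 1e-6.  If refinement
produces an invalid or empty macrostate the fit retries once from the
crisp PCCA+ assignment.  Populations are the stationary distribution of
the hidden transition matrix; per-frame macrostate labels come from
argmax membership of the frame's microstate.

Uncertainties: bootstrap over whole trajectories (the natural
independent unit); a single trajectory falls back to a 10-block
contiguous bootstrap with a warning.  Replica macrostates are matched
to the reference by maximal membership overlap (Hungarian assignment)
before SDs are taken — label switching is otherwise undefined.  The
bootstrap SD tracks the between-trajectory spread of the estimator;
with few, slowly mixing trajectories the per-trajectory occupancy
distribution is broad and mildly non-Gaussian, so 2-SD intervals cover
the truth at roughly their nominal ~95 % only when each trajectory
spans ≳10 slow relaxation times — the calibration checks use 20
trajectories × 3000 frames (12 slow timescales each).

Macrostate MFPTs solve m = 1 + Q m on the hidden transition matrix
(target rows zeroed), π-weighted over the source set, scaled by
lag × Δt; SDs come from the bootstrap replica matrices.  MFPTs between
*sets* of macrostates that aggregate the faster process isolate the
slow process exactly (for the product chain, the set-MFPT across the
slow block equals 1/p), which is how the two-system rate-ratio check is
defined.

## Two-system comparison

A single tICA model is fit on the concatenated segment lists of both
systems (covariances never pair frames across systems), so both project
into one coordinate space; per-system transition statistics are never
mixed.  Macrostates are matched greedily by smallest distance between
tIC centroids, ties toward higher population; pairs beyond a threshold
(default: half the median cross-system inter-centroid distance) leave
both states exclusive — a geometric rule chosen because the systems
have disjoint trajectories, making membership-overlap matching
undefined.  Matched pairs yield ΔP = P_B − P_A with bootstrap SDs
propagated in quadrature, and MFPT ratios for every ordered matched
pair; unreachable passages are flagged and omitted.  Reference
single conformations are featurized and projected with the shared
model; a structure missing required residues yields None without
aborting the rest.

## Relaxation analysis

Constants: γH = 2.6752218744e8, γN = −2.7126e7 rad s⁻¹ T⁻¹, r_NH =
1.02 Å, ¹⁵N CSA = −172 ppm.  The spectral density is the standard
two-Lorentzian model-free form; R1, R2, NOE combine J at
{0, ωN, ωH±ωN, ωH} with dipolar and CSA prefactors, Rex adding to R2
only.  Default field: 800 MHz (¹H).

τm estimation: residues with R2/R1 outside mean ± 1 SD or NOE < 0.65
are trimmed (exchange-broadened or mobile positions bias the ratio);
each retained residue's rigid-limit R2/R1(τm) relation is inverted by
Brent's method on τm ∈ [0.5, 60] ns and the median is returned.
Isotropic tumbling only: an axially symmetric diffusion tensor needs
per-residue bond orientations from a structure, which is outside the
present scope.  On data from a mildly non-rigid protein the
rigid-inversion median carries a ~2 % downward bias — acceptable
against the per-residue fit's insensitivity to small τm errors.

Model-free fitting: per residue, weighted least squares (scipy
`least_squares`, bounded: 0 ≤ S² ≤ 1, 0 ≤ τe ≤ min(τm/2, 5 ns),
0 ≤ Rex ≤ 50 s⁻¹, several starts) over three nested models — S² only,
S²+τe, S²+τe+Rex.  The simplest model is kept unless the next one
improves χ² by more than Δχ² = 4.6 (a ~90 % two-parameter heuristic;
configurable).  Failed residues are flagged and skipped, not fatal.

R2/R1 classification: ratio above the ensemble mean + 1 SD → "slow"
(μs–ms exchange); below mean − 1 SD → "fast" (ps–ns flexibility);
otherwise "typical".  Residues missing either rate are excluded and
listed.

## Pipeline

`pipeline.run` chains the stages with a flat config, one global seed
expanded into per-stage seeds by SHA-256, artifacts and a manifest
written per stage.  Stages communicate only through returned
objects/serialized artifacts; a rerun with identical config and inputs
reproduces identical outputs.

## Problem sizes used in validation

Anchor recovery: 20 seeds × (4 × 2500 frames).  HMM coverage: 10 seeds
× (20 × 3000 frames), 25 bootstrap replicas.  Rate-ratio comparison:
3 replicate pairs × (16 × 4000 frames), HMM lag 10.  MFPT oracle:
10⁵ first-passage replicas per chain.  tICA spectral recovery:
2 × 10⁵ frames.  Model-free round trip: 5×5 (S², τe) grid at
τm ∈ {8, 14.7, 20} ns.

## Known limitations

- The HMM stationary distribution tracks the realized occupancy of the
  input data; with slowly mixing inputs its deviation from the true π
  is dominated by the data, not the estimator, and only the trajectory
  bootstrap reflects that.
- Greedy centroid matching can mispair macrostates when two systems'
  landscapes deform strongly rather than gaining/losing states.
- Short-lag HMMs slightly underestimate slow MFPTs when frame
  misassignment opens spurious escape channels; lag 10 on the toy
  system keeps the bias within ~±20 %.
- No Bayesian MSM posterior, TRAM/MBAR, transition-path theory, or
  kernel tICA; no anisotropic diffusion-tensor fitting or CPMG
  dispersion analysis.
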