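# Methods

`pictract` reimplements, at desk scale, a complete probabilistic-tractography
connectivity-profiling analysis: digital fibre phantoms with known
connections, constrained spherical deconvolution (CSD) of the
diffusion-weighted signal, PICo-style Monte-Carlo streamline tracking,
seed-to-target maximum-connectivity matrices, and a two-level
Poisson/consistency group inference.  This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Phantom and forward model

A phantom is a set of tubular fibre bundles rasterised on a voxel grid
(default 40x40x40 voxels at 1 mm isotropic).  Presets: a straight tube, a
single circular arc, two nested non-touching arcs ("two_arcs", a stand-in
for a pair of parallel crescent-shaped association bundles), and two
straight tubes crossing at a controlled angle.  Each in-tube voxel carries
the local tangent; voxels shared by k bundles hold k fibre populations with
fraction 1/k; the first and last 3 mm of each tube are its two endpoint
label regions, and each bundle's endpoint pair is a ground-truth
connection.

The noise-free signal is the standard multi-tensor model,

    S(v, g) = S0 [ sum_j f_j exp(-b g'D_j g) + (1 - sum_j f_j) exp(-b l_iso) ],

with axially symmetric tensors (defaults: lambda_parallel = 1.7e-3,
lambda_perp = 3e-4 mm^2/s — typical deep-white-matter values) and an
isotropic compartment at l_iso = 7e-4 mm^2/s.  Rician noise is applied as
the magnitude of a complex Gaussian perturbation with sigma = S0/SNR
(default SNR 30 at b0, typical of 3 T DWI).  The emulated acquisition is
61 unique gradient directions at b = 1200 s/mm^2 plus one b = 0 volume;
direction sets are generated by electrostatic repulsion with antipodal
symmetrisation (500 fixed iterations), since the original direction table
is not published and any uniform hemisphere set is equivalent for the
model.

Cohorts of N participants (default 13) are simulated with designed
per-participant presence or absence of each connection: absent bundles are
removed from that participant's truth before signal synthesis.  Noise
streams use seeds `master_seed + participant_index`.  Every participant
shares the tracking mask derived from the *full* geometry (fibre mask
dilated by 2 voxels), so absence is not inferable from the mask.

What the generator does **not** emulate: EPI/eddy-current/motion artefacts,
cardiac pulsation, partial-volume gradients at grey/white interfaces,
spatially varying SNR, or inter-subject anatomical variability beyond
connection presence.  Passing tests therefore demonstrate the *procedural*
correctness and statistical behaviour of the pipeline under its own model
assumptions, not performance on real scans.

## Constrained spherical deconvolution

Signals are normalised per voxel by the mean b = 0 signal.  On the real,
orthonormal, even-order spherical-harmonic basis (antipodally symmetric;
scipy's Condon-Shortley convention with `sqrt(2) (-1)^m Re/Im` real
combinations), spherical convolution with the axially symmetric single-fibre
response R is diagonal per degree:

    s_lm = f_lm k_l,   k_l = sqrt(4 pi/(2l+1)) r_l,

with r_l the zonal coefficients of R.  The response is estimated from
ground-truth single-fibre voxels (rotate gradients so the fibre axis is +z,
average, project on zonal harmonics); an analytic tensor-convolution
response is provided as the alternative and agrees to ~2e-4.

The FOD is fit per voxel at lmax = 8 (45 coefficients) by iterative
soft-constrained least squares: amplitudes on a fixed 300-direction set
that fall below tau = 0.1 times the mean amplitude of an initial lmax = 4
fit are penalised towards zero, re-selecting the active set until it
stabilises (at most 50 iterations).

**Constraint weight.**  The penalty weight is the one genuinely open
numerical choice, and it controls a real trade-off.  A band-limited FOD
cannot be exactly non-negative while matching the l = 2, 4 moments a
noise-free fibre signal pins down (only the true delta attains those
moments), so "hard" non-negativity necessarily smooths the FOD — an exact
inequality-constrained QP solve yields ~5% reconvolution residuals and
merges crossings below ~45 degrees.  A data-dominant fit preserves the
band-limit's full angular resolution — crossings down to exactly 30
degrees at lmax = 8 (25-degree pairs merge even for ideal truncated-delta
pairs) — at the cost of residual negative side-lobes of order 10% of the
peak, which every downstream consumer clips at zero.  With noise, however,
deconvolution by a smooth kernel amplifies high-order coefficients by
1/k_l (k_8/k_0 ~ 3e-4 at b = 1200), and an unregularised fit at SNR 30 is
unusable.  The default therefore scales the constraint weight with the
estimated per-voxel noise (30 x the RMS residual of the unconstrained fit,
clamped to [0.01, 1] of the operator-norm scale): noise-free fits stay
data-dominant, realistic-SNR fits are fully regularised.

Peaks are extracted as grid local maxima over a 724-point Fibonacci sphere,
refined by continuous maximisation, with antipodes merged, a 15-degree
minimum separation and a 0.25 relative amplitude floor.

## Tracking

Streamlines propagate bidirectionally from start points uniformly jittered
inside the seed voxel (jitter avoids lattice artefacts; a mid-pathway seed
must be able to reach both ends, which unidirectional tracking cannot).
At each 0.5 mm step a direction is drawn from the trilinearly interpolated
FOD over the 724-direction set, restricted to the hemisphere within 90
degrees of the previous step, with probability proportional to amplitude.
Directions whose amplitude falls below the tracking threshold (default
0.2) carry zero probability: a streamline never steps along sub-threshold
amplitude.  This floor matters: the clipped band-limited delta keeps ~17%
of its mass in wide-angle side-lobe rings, and sampling them randomises
propagation (mid-tube far-end survival drops from ~100% to ~50% at region
level).  The 0.2 default sits above the isotropic-background amplitude
(~0.08) and the single-fibre side-lobe ring (~0.12) and far below
crossing-lobe peaks (~1.3), on the scale where a unit-integral delta peaks
at ~3.3.

Stopping rules: cumulative turning angle within one voxel above 180
degrees (implemented literally as printed — deliberately permissive, no
per-step cap); physical path limit of 500 mm, budgeted across the two
half-tracks (the first half consumes steps first, the remainder goes to
the second, so the cap binds on the concatenated streamline); leaving the
tracking mask; no admissible amplitude above threshold.  Visitation is
binary per streamline per voxel; the seed voxel always counts.

Determinism: per-streamline uniform streams are
`default_rng(SeedSequence(seed).spawn(...)[i])`, so runs are bit-reproducible
and the first k streamlines of a larger run are the same trajectories
(counts are monotone in the streamline count).  A numba kernel and a pure
Python path implement the algorithm draw-for-draw identically and are
cross-checked for exact count equality in the tests.

## Connectivity and group statistics

Seed ROIs are spheres of voxels whose centres lie within the radius
(inclusive boundary — the convention under which a 5 mm sphere on a 1 mm
grid centred on a voxel centre holds exactly 515 voxels), optionally
clipped by a probability mask with a "> 0" retention default.  The
connectivity value for a target region is the **maximum** visitation count
over seed voxels and region voxels, which keeps values in 0..n_initiated
(0..10,000 at the full protocol) regardless of region sizes.

Per participant, the pooled seed-by-target values (zeros included — most
pairs are unconnected) are fit by a Poisson MLE (the mean); the individual
threshold is the smallest integer t with P(X > t | lambda) < .05, and a
connection survives when its value is strictly greater than t.  Across
participants, a connection enters the profile under the strict criterion
when it survives in more than 75% of participants (floor(0.75 N) + 1, i.e.
at least 10 of 13) and under the relaxed criterion at more than 50% (at
least 7 of 13).

Because the phantom has only 4 endpoint regions while the zero-dominated
pooled distribution the Poisson fit assumes comes from a
whole-hemisphere parcellation of ~49 mostly unconnected regions, the label
volume adds small unconnected "background" distractor regions (default 12,
placed deterministically away from any bundle).  Without them the pooled
sample is 8 values dominated by the trivially-full seed-region entries and
the threshold is unstable.

## Problem sizes and defaults in the shipped analysis

The shipped analysis runs the 13-participant two-arcs cohort at 1,000
streamlines per seed voxel with 1 mm seed spheres (7 voxels per seed) — a
deliberate desk-scale operating point for the stochastic recovery runs;
the printed 10,000-streamline protocol remains the package default and is
exercised on a single seed voxel in the tests (where its 0..10,000 range
contract is asserted).  At these sizes a full run completes in about a
minute on one CPU.  The angular-resolution measurement uses a 300-direction
b = 3000 s/mm^2 scheme, the regime in which the narrow-crossing capability
of CSD is defined.

## Known limitations

* Band-limited non-negativity is necessarily approximate (see above);
  negative side-lobes are clipped, not absent.
* The PICo probability distribution is realised as direct FOD-amplitude
  importance sampling; residual-bootstrap PDFs are a possible extension,
  not implemented.
* The curvature rule is per-voxel cumulative and therefore
  voxel-size-dependent; grids much coarser than the step size make it
  stricter in distance terms.
* Region-level connectivity uses nearest-voxel visitation of discrete
  points at 0.5 mm steps; voxels grazed between points are not counted.
* The Poisson null is a pragmatic convention inherited from the method
  being reproduced; pooled connectivity values are zero-inflated and
  over-dispersed, and the threshold should be read as a procedural
  cut-off, not a calibrated error rate.
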