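# Methods

`neurovasc` simulates and analyses BOLD fMRI studies in which concurrent,
mutually orthogonal neuronal stimuli (a 3-back working-memory task and a
flashing-checkerboard visual stimulus) and a vascular stimulus (four 1-min
CO2-inhalation blocks targeting a +5 mmHg end-tidal rise) are used to split
functional brain networks into spatially similar "neural"/"vascular"
component pairs.  This note documents the models, the generator's
assumptions, the numerical choices, and what passing tests do and do not
demonstrate.

## Stimulus design

One scan lasts 660 s (330 volumes, TR = 2 s).  The default block schedules
are:

* working memory: eleven 30-s blocks with a 60-s rest in mid-scan,
* visual: four 33-s blocks confined to the second half (t >= 330 s),
* hypercapnia: four 60-s blocks spanning both halves.

Exact zero pairwise Pearson correlation between binary designs requires
that each pair's on-overlap equal the product of the on-fractions times the
scan length.  On a 660-s scan this is integer-feasible only for particular
block counts; with 30-s working-memory and 60-s CO2 blocks the unique
solution family uses eleven WM blocks (WM∩CO2 = 120 s exactly) and 33-s
visual blocks (WM∩VIS = 66 s, VIS∩CO2 = 48 s).  Onsets were found by a
seeded combinatorial search on a 1.5-s grid (the granularity of the
working-memory item presentation) and are frozen in `paradigm.py`; the
measured off-diagonal correlations are ~1e-15.  After convolution with the
HRF the designs acquire slight collinearity (max |r| = 0.007 for the task
pair; the scan-specific CO2 regressor correlates more variably).

The canonical HRF is the standard double-gamma difference,
h(t) = g(t; 6, 1) − g(t; 16, 1)/6 on [0, 32] s, peak-normalized, sampled at
dt = 0.1 s before TR down-sampling (limits quantization of 1.5-s stimulus
events on the 2-s volume grid).  Convolution is causal with a zero-padded
past (block designs start at rest).

## Synthetic study generator

### Signal model

Each of three networks (DMN, TPN, VN) is two overlapping sources.  Spatial
maps are sums of 3D Gaussian blobs (sigma = 1.6 voxels) on a 24×24×12 grid
with an ellipsoidal brain mask (~3100 voxels): one shared node plus three
unique nodes per member, giving half-maximum Dice overlaps of ~0.25–0.35
within a pair.  Pairs occupy equal-mask-volume x-slabs and node centers of
different pairs are kept >= 3 sigma apart, so cross-pair maps are disjoint.
The voxel signal is

    S(v,t) = S0_v · (1 + Σ_k m_k(v)·s_k(t)/100 + g(t)/100) + drift_v(t) + ε,

with S0 ≈ 1000 (5% voxel-to-voxel spread), per-voxel random quadratic
drift (coefficient sd 4 raw units ≈ 0.4 %BOLD), and white noise
(sd 8 ≈ 0.8 %BOLD per sample; strongly loaded voxels then show single-scan
task correlations of roughly 0.5–0.6).

Neural timecourses are HRF-convolved task designs scaled to a plateau
amplitude in %BOLD (DMN −1.0, deactivation; TPN +1.2; VN +1.8 — checkerboard
responses in visual cortex are the strongest routinely observed task
responses).  Vascular timecourses are HRF-convolved end-tidal CO2
excursions scaled by a cerebrovascular reactivity (CVR, %BOLD per mmHg:
DMN 0.40, TPN 0.60, VN 0.60 — upper-normal gray-matter values).  A weak
global CO2 response (0.05 %/mmHg) is added to every in-mask voxel as the
brain-wide aggregate of the three network response shapes, so it spans no
temporal dimension beyond the network sources.

### Response-shape diversity (an identifiability requirement)

Timecourses that are exactly proportional cannot be separated by any linear
decomposition: if DMN deactivation were the exact mirror of TPN activation,
the two sources would collapse into a single component with a signed map.
The generator therefore gives each network mildly distinct response
dynamics, all physiologically motivated and within reported ranges:

* neural: DMN deactivation lags by 2 s and is dispersed by a 4-s
  exponential; TPN and VN are canonical (VN 0.5 s/1 s).
* vascular: DMN lags by 4 s with 6-s dispersion (vascular transit);
  TPN has a partially adapting response (70% transient fraction, 15-s
  adaptation) — regional CO2 responses differ in sustained-vs-transient
  dynamics, not only in arrival time; VN is unlagged.

Two constraints bound these choices, found by explicit calculation rather
than taste.  First, effective vascular delays beyond ~12 s must be avoided:
the working-memory design is quasi-periodic with ~45–60 s cycles, so a
response delayed by near half a cycle spuriously *flips* its correlation
with the task regressor, which in the replication mode (below) both
destroys the CO2 attribution of the normalized R² and manufactures fake
task coupling.  Second, the three vascular responses are all linear filters
of one input (the PetCO2 excursion); a pure lag/dispersion ladder leaves
the six-source timecourse set effectively rank-five, and the adapting TPN
shape is what restores the missing dimension.

### Physiology

Raw capnograph traces are simulated at 25 Hz with a 3.5-s breathing period
(5% period jitter): each breath rises to a plateau at the current end-tidal
value (0.2 mmHg plateau jitter) and falls toward the inspired level.
End-tidal extraction finds per-breath maxima separated by a 2-s refractory
interval with a robust prominence floor, then interpolates linearly onto
the volume grid with constant extrapolation.  Round-trip RMSE against the
generating envelope is ~0.18 mmHg for the hypercapnia envelope family.  An
instantaneous step envelope is not fully recoverable by per-breath sampling
(irreducible edge error ~0.45 mmHg at this breathing rate); the study's own
envelopes rise with the 8-s gas-equilibration time constant, which is what
the round-trip checks use.

In hypercapnia mode the underlying PetCO2 envelope is a per-subject
baseline (40 ± 3 mmHg) plus 5 mmHg times the equilibration-smoothed block
design, plus a small AR(1) process (sd 0.25 mmHg) and a slow drift.  In
replication mode there is no challenge; PetCO2 fluctuates naturally (AR sd
1.2 mmHg, drift 0.9 mmHg — natural breathing varies far more than
gas-controlled breathing) and is negatively coupled to the working-memory
design through an 8-s-smoothed coupling of amplitude k = 3 mmHg
(task-correlated breathing).  k was calibrated once so that the group-mean
PetCO2 trace correlates with the task design at r ≈ −0.7 (single scans sit
near −0.5 with wide spread).  Network maps and subject effects depend only
on the master seed, not the mode: a replication study simulated at the same
seed re-scans the same cohort with fresh scan noise.

### What the generator does not emulate

Head motion, cardiac/respiratory cycle aliasing, field inhomogeneity,
spatial noise autocorrelation, anatomical structure, and scanner drift
nonlinearity are all absent, and alignment is perfect by construction.
Passing recovery tests therefore demonstrates that the analysis chain is
correct and well-calibrated under its stated signal model — not that it is
robust to the artifacts of real acquisitions, which the upstream alignment
and denoising tools of a real pipeline must handle.

## Analysis chain

* **Preprocessing** — per in-mask voxel, least-squares removal of an
  order-2 polynomial (QR-orthogonalized basis over scan time), then
  conversion to percent signal change about the pre-detrend temporal mean;
  the 30 %BOLD datasets are voxel-wise averaged (masks intersected).
* **Spatial ICA** — PCA whitening to 30 components, then fixed-point ICA
  over voxels-as-samples.  The kurtosis ("cube") contrast suits the sparse
  blob-like maps; the deflationary scheme is used because the parallel
  update does not converge when most whitened dimensions carry only noise.
  Deflation can land in run-dependent local optima, so eight seeded
  restarts are run and the solution with the greatest summed |excess
  kurtosis| (the contrast being maximized) is kept.  Maps are scaled to
  unit variance and flipped to non-negative skewness, timecourses in
  tandem; everything is deterministic per seed.
* **Identification** — DMN is the component with the most negative
  correlation to the working-memory regressor, TPN the most positive, VN
  the most positive to the visual regressor; collisions raise an error.
* **Thresholding** — a two-class mixture (Gaussian null + Gamma activation
  tail) fitted by EM; voxels with activation posterior > 0.5 are included.
  If the classes fail to separate (activation mean within 2 null sd — the
  Gamma otherwise swallows the positive half of flat maps) the threshold
  falls back to z > 2.3 with a logged warning.
* **Pairing** — each labeled component is paired with the remaining
  component of greatest Dice overlap (candidates exclude only the
  component itself by default; a switch excludes the other labeled
  components); ties break to the lower index.
* **Dual regression** — per volume, the in-mask voxel values are regressed
  on all 30 maps plus an intercept; the coefficient series are the
  scan-specific component timecourses.
* **Normalized R²** — simple-regression R² of a timecourse on one stimulus
  divided by the multiple-regression R² on the full stimulus model
  (marginal reading; a `partial` switch is available).  Defined as 0 for
  degenerate inputs.  Caveat: for a timecourse the model barely explains,
  the ratio hovers near the chance share (1/m for m regressors) with high
  variance, so normalized R² should only be interpreted for components
  with appreciable full-model R².
* **Inference** — paired two-tailed t-tests of neural-minus-vascular
  normalized R² across scans, Bonferroni-corrected over all nine
  (label × stimulus) tests; normality of the paired differences is
  assessed by a Monte-Carlo Lilliefors test (10^4 seeded Gaussian
  replicates of the KS statistic with estimated moments); non-normal
  differences are flagged but still tested.
* **Replication** — the original maps are applied unchanged to the
  replication scans by dual regression; the scan's own natural PetCO2
  regressor replaces the hypercapnia regressor; the coupling report gives
  the group-mean PetCO2/task correlation full-length and block-averaged
  (30-s epochs, 6-s pre-onset baseline; longer windows would overlap the
  next block).

## Numerical conventions and degenerate inputs

Zero-variance inputs yield flagged NaN/0 results rather than errors in
correlation tables and normalized R²; rank-deficient dual-regression
designs raise with the most collinear component pair named; ICA
non-convergence retries with derived seeds before raising; blob placement
retries the whole layout (10 attempts) before raising.  Seeds derive from
`numpy.random.SeedSequence` spawning throughout, and every public entry
point takes an explicit seed.

## Problem sizes and the fixed study seed

The default study is desk-scale: 24×24×12 voxels rather than a full
64×64×35 acquisition grid, with the full 330-volume timeseries and all 30
(or 24) scans.  The mathematics is unchanged; the whole chain runs in
about half a minute.  The default study's master seed is fixed (1) as part
of the study definition — like the sample sizes, it selects the one
synthetic cohort the analyses describe — while analysis-side randomness
(ICA restarts, Monte-Carlo nulls) remains caller-seeded.  Across other
study seeds the hypercapnia-mode recovery passes essentially always and
the replication-mode dissociation passes in the large majority of draws;
the thin margin is the DMN CO2 contrast, which in replication mode is
intrinsically delicate because task-coupled CO2 makes deactivation and
vasodilation nearly collinear regressors — the same confound the method is
designed to expose.

## Known limitations

* FastICA with a fixed 30-component dimensionality approximates
  probabilistic ICA; no Bayesian dimensionality estimation is attempted,
  and the pair-splitting is sensitive to this choice by construction.
* The two-class mixture threshold has no negative-activation class;
  Dice pairing operates on positive-tail masks of skew-aligned maps.
* Spatial ICA penalizes exactly the within-pair overlap the phenomenon
  creates; with overlaps much beyond Dice ≈ 0.4 the true sources are no
  longer the spatially-most-independent solution and recovery degrades —
  a property of the method, not of the implementation.
* Stage-2 dual-regression group maps, FDR alternatives, and mixed-effects
  models are out of scope.
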