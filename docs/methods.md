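# Methods

This note documents the models, conventions and numerical choices behind
`tubudyn`, and what the synthetic-data tests do and do not demonstrate.

## Angular observables and the diffusion model

A substrate-anchored tubulin dimer is treated as a rigid body with two
angular coordinates: twist χ about the dimer axis and tilt θ of that axis.
For a freely diffusing angular coordinate α the mean squared displacement is

    MSD(Δt) = ⟨(α(t+Δt) − α(t))²⟩ = 2 D Δt,

and D is estimated as half the slope of a linear fit.  Assumptions: the
angle series is continuous (unwrapped), stationary over the fit range, and
the short-lag regime is diffusive.  The model is fitted with a free
intercept, which absorbs static localisation noise; D is reported from the
slope only.  No anomalous-diffusion exponent is fitted — the model is linear
by construction, and a reduced chi-square much larger than 1 is the signal
that a linear MSD is the wrong model for the data at hand.

**MSD estimator.**  Displacement pairs are pooled over all tracks and all
overlapping start times (maximal data use; the non-overlapping all-pairs
estimator is kept in the test suite as an oracle and the two agree exactly
on small inputs).  Per-spot averaging (equal weight per track rather than
per pair) is available via `averaging="per_track"`; pooled-per-pair is the
default.  Lag 0 is identically zero and not stored.

**Weighted fit.**  The default weights are the per-lag pooled pair counts
(the "chi-square" sense); inverse-variance weighting from the per-lag error
estimate MSD·√(2/n) is available.  The default fit range is the first 8
lags — with 50 ms DXT frames that is 50–400 ms, the window over which
published single-molecule MSD curves remain linear — and is configurable.

**Uncertainties.**  MSD values at different lags share displacement pairs
and are strongly correlated, so the naive WLS covariance understates the
slope error by an order of magnitude.  When per-track information is
available the slope and intercept standard errors are computed by
delete-one-track jackknife (the track is the independent unit), which the
tests show to be consistent with the across-ensemble spread of fitted D and
to shrink as 1/√(number of tracks).  For curves constructed without
per-track data the residual-based WLS formula is used and documented as a
lower bound.

**Combined metric.**  MSD_combined(Δt) = MSD_θ(Δt) + MSD_χ(Δt), for
comparisons between measurements whose anchoring orientation is
indeterminate.  For two i.i.d. components with equal D its slope is 4D.

## Superposition and the twist/tilt extraction

Kabsch superposition is implemented directly (SVD of the 3×3
cross-covariance with the determinant correction, optional weights) and
cross-checked in the tests against the MDAnalysis implementation.  Inputs
with fewer than three points or rank < 2 (collinear) are rejected.

The relative motion of TUBB is isolated by fitting each frame's TUBA-core
Cα set (default residues 1–436) onto frame 0 and reporting TUBB-core
(1–427) quantities without a second fit.  The relative Cα-RMSD is therefore
a measure of inter-domain displacement and is invariant to any global rigid
motion of a frame.  The reference is frame 0 of each run (the shared
initial model).  RMSF is computed per chain about the time-average
structure after fitting each frame on that chain's own core.

The inter-domain rotation R_t (Kabsch, frame-0 TUBB core → frame-t TUBB
core after the TUBA fit) is decomposed as R_t = R_swing ∘ R_twist via the
quaternion projection method: the twist quaternion is the normalised
projection of the rotation quaternion onto the (scalar, axis) plane.  The
decomposition is exact (recomposition reproduces R_t to machine precision,
~1e-15 Frobenius), unique for tilt < 180°, with the degenerate 180°-swing
case mapped to zero twist.  Twist is signed, right-handed about the axis
pointing TUBA → TUBB, unwrapped over time; tilt is the swing magnitude in
[0°, 180°].

**Dimer axis.**  The default axis is the unit vector from the TUBA-core to
the TUBB-core Cα centroid in frame 0 — the geometrically natural stand-in
for the anchored vertical axis, and configurable.  Because this axis is an
estimate, angle recovery against a generator that twists about exactly z
carries a relative error of order (axis error)²; the exactness tests pass
the true axis explicitly, the statistical tests use the default.

## PCA of relative motion

After TUBA-core fitting of all frames of all runs to the first run's frame
0, the TUBB-core Cα coordinates (3N-vectors) are pooled, centred on the
pooled mean, and their covariance is eigendecomposed (`numpy.linalg.eigh`;
scikit-learn PCA is the cross-check in the tests).  Principal axes are
shared across runs so different dimers project onto a common PC1–PC2 plane.
Contribution ratio = eigenvalue / total variance; ratios sum to 1 and the
eigenvalue sum equals the total coordinate variance (trace conservation).
Occupancy maps are 2-D histograms of the projections normalised to
fractions, default 50×50 bins spanning the pooled extrema.  Because the
peak "presence frequency" depends on the bin size, peak values are compared
between ensembles only as orderings, never as absolute numbers.  Mode
vectors are eigenvector components per Cα scaled by √eigenvalue.

## Interface contacts

Contact definition: any heavy-atom pair (one atom per side, hydrogens
silently excluded) strictly closer than the cutoff, default 4.0 Å; a pair
at exactly 4.0 Å is not a contact.  The interface is every residue pair
with one residue per chain role; C-terminal tails are included unless the
selection restricts to cores.  Neighbour search uses `scipy.spatial.cKDTree`
with the boundary handled explicitly (the tree query is inclusive, the
definition strict); a brute-force O(N²) oracle in the tests and acceptance
script verifies exact agreement on random frames.  A residue's contact
frequency counts frames in which it participates in ≥ 1 interface contact
(the per-pair table preserves the full information); the pooled denominator
is the total frame count over all runs, and the pooled value equals the
frame-count-weighted mean of per-run frequencies.  Inputs are assumed
whole-molecule (PBC removed); a validation warns when the inter-chain
centroid separation jumps by more than 20 Å between frames.

## T7-loop two-state classification

Reference distances: Gln245(Cδ)–Gln11(Cδ) ("interface") and
Gln245(Cδ)–Val353(Cα) ("internal"); the atoms are configurable so Cα-only
models can substitute Cα for Cδ.  A frame is state A when the interface
distance is below t_A and the internal distance at least t_B; state B for
the converse; otherwise unassigned — ambiguity is surfaced, not resolved.
The default thresholds t_A = t_B = 8 Å sit midway between the reported
distance modes (~4 Å bound, ~10–12 Å free); since the boundary is a
convention, a built-in sweep over 6–10 Å reports how occupancies depend on
it.  Distance histograms use 0.5 Å bins by default.  No hidden-Markov
segmentation or kinetic rate estimation is attempted.

## Sequence identity

Global alignment (Biopython `PairwiseAligner`) with match +1, mismatch 0
and a linear gap penalty of −1.  Identity is identical aligned positions
divided by the number of aligned columns, reported to two decimals.  The
published tubulin isoform identities are only consistent with a denominator
that excludes terminal-gap columns (e.g. 449/451 = 99.56 for the
alpha pair), so that is the default; the full-alignment-length convention
is exposed as an option, and the convention is stated here precisely so
that deviations from published values can be attributed.

The bundled FASTA carries curated offline copies of the canonical human
TUBA1A, TUBA1B, TUBB3 and TUBB5 sequences (UniProt accessions in the
headers).  Their lengths match the canonical entries and all
literature-anchored residues (TUBA Gln11/Thr73/Tyr224; TUBB
Gln245–Leu246–Asn247, Val353, the 45/239/351 isoform sites, TUBB3
phospho-Ser444) are in place; the alpha-pair identity reproduces the
published 99.56 exactly, while the beta-pair identity computes 92.60
against a published 92.57 — a one-residue-scale discrepancy in the bundled
copies that is documented rather than patched.  Verify against UniProt
where network access exists.

## Synthetic generators: what they emulate, and what they do not

`simulate_rotor` produces Gaussian random-walk angle tracks
(α(t+Δ) = α(t) + N(0, 2DΔ) + drift·Δ, optional i.i.d. measurement noise).
Defaults emulate the DXT measurement geometry: 50 ms frames, 300 frames
(15 s of tracking), 150 spots.  `simulate_dimer` builds a two-domain
Cα-resolution dimer (Fibonacci-sphere domains of 436 and 427 residues,
radius 22 Å, centroids 46 Å apart) in which domain B moves rigidly with a
programmed twist/tilt process, opposed interface atom pairs sit at a 3.4 Å
rest distance, and a T7-style loop toggles between a TUBA-facing and a
TUBB-facing conformation by a telegraph (two-state Markov) process — chosen
over a potential-energy model precisely because its occupancy and switching
rate are then exact ground truth.  The loop assembly sits near the dimer
axis, as the real T7 loop does at the intra-dimer interface; this also
keeps the programmed contact distances in force under the twist motion.
The angular process is Ornstein–Uhlenbeck by default (stationary sd 5°
twist, 2.5° per tilt component, relaxation 500 frames), giving free
diffusion with D = sd²/relaxation at short lags and the bounded excursions
expected of an assembled dimer; a free-diffusion mode exists.  The loop
switch rate (0.1/frame, i.e. mean dwell ~14 frames in A at occupancy 0.7)
is fast enough that a few-thousand-frame run is ergodic, which is what
makes occupancy recovery to ±0.05 a meaningful test.  All randomness flows
through one seeded NumPy PCG64 generator; outputs are bit-reproducible.

`simulate_two_mode_dimer` displaces the B domain along exactly two
orthonormalised rigid displacement patterns (twist-like and tilt-like) with
i.i.d. Gaussian amplitudes of programmed variance ratio — linear modes, so
PCA ground truth is exact rather than small-angle approximate.

**Not emulated:** force fields, solvent, thermostats, correlated
internal-loop dynamics beyond the two-state flip, detector noise structure
beyond i.i.d. jitter, diffraction-image processing, and gold-label
mechanics.  Passing tests therefore demonstrate that the *analysis chain*
recovers programmed statistical structure, not that real tubulin behaves
like the generator.

## Numerical choices and degenerate inputs

* Kabsch: rank check rejects collinear inputs; determinant correction
  enforces a proper rotation; weights must be non-negative with positive
  sum.
* Swing–twist: twist quaternion norm below 1e-12 (exact 180° swing) maps to
  zero twist.
* Twist series are unwrapped in radians and re-expressed in degrees; tilt
  is non-negative by construction.
* MSD requires max_lag < shortest track length; fits need ≥ 3 lag points,
  non-identical lags and a non-zero MSD (a constant track is rejected with
  an explicit error rather than fitted as D = 0).
* Contact boundary: squared distances are compared with `<` against the
  squared cutoff, so the inclusive k-d-tree query is filtered exactly.
* Histograms (occupancy, distances, contact counts) always normalise to
  total mass 1; empty inputs and non-positive bin sizes are rejected.
* CSV floats are written with a pinned `%.9g` format, making rerun outputs
  byte-identical; every summary carries the config hash, seed and package
  version.

## Problem sizes

The recovery checks run at the sizes the study design implies and desk
hardware handles comfortably: 200 tracks × 500 frames for diffusion
recovery, two ensembles of 150 × 500 for the paired ratio, 5 runs × 2,000
frames for loop-state and contact-frequency recovery, 3,000 frames for PCA
recovery, 1,000 random rotations for the decomposition bound, and 100
random 50-atom frames for the contact oracle.  The full test suite runs in
about half a minute; `scripts/acceptance.py` in a few seconds.

## Known limitations

* The tilt angle is a magnitude, so its MSD is not 2DΔt near zero tilt;
  tilting diffusion constants are recovered from rotor tracks (where θ is a
  signed coordinate), and MD-derived tilt series should be interpreted
  accordingly.
* The jackknife slope error requires ≥ 2 tracks; single-run MD-derived
  angle tracks fall back to the (understated) residual-based error.
* Frames whose loop state differs from frame 0 perturb the twist/tilt
  least-squares fit by a few tenths of a degree on the synthetic dimer; on
  real data any large loop rearrangement inside the fitting core has the
  same effect, which is a property of core-based superposition generally.
* Percent identity depends on the stated alignment convention; published
  values computed with other tools (different gap model or denominator) can
  differ in the second decimal.
* The 2-D occupancy peak value depends on bin size; only orderings between
  ensembles on a shared grid are meaningful.
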