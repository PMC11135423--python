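# Methods

## Model and procedure

trackmotion implements the classical single-particle-tracking (SPT)
motion-type analysis for 2-D trajectories sampled at a fixed frame
interval Δt. Each track is treated independently; there is no ensemble
averaging across tracks and no drift correction.

**Time-averaged MSD.** For a track of N frames the estimator at lag
τ = k·Δt averages over all N − k overlapping origin pairs (sliding
origin). Overlapping pairs are the SPT standard: they maximise the pair
count on ~150-frame tracks at the cost of correlated lag estimates,
which the unweighted fit below deliberately ignores. Lags are capped at
k_max = floor(f·(N−1)) with f = 0.25 by default, because time-averaged
MSD values at long lags average too few pairs to be meaningful; at least
lag 1 is always returned.

**Anomalous-diffusion fit.** MSD(τ) = A·τ^α + B is fitted in linear
space, unweighted, by trust-region bounded least squares
(`scipy.optimize.curve_fit`, method `trf`), with A ≥ 0, 0 ≤ α ≤ 3,
B ≥ 0, initialised at α = 1, A = MSD(τ₁)/τ₁, B = 0. B absorbs the
static offset that localization error adds to every lag (≈ 4σ² in 2-D).
The α upper cap of 3 is numerical plumbing chosen so the ballistic value
α = 2 is an interior solution.

Non-identifiable cases are flagged rather than interpreted:

* curves with fewer than 3 lags (too short to constrain 3 parameters);
* flat curves (relative spread ≤ 1e-12), where A and B are exchangeable
  and α means nothing — this covers stationary tracks with MSD ≡ 0;
* fits whose exponent lands on the α cap (within 1e-6). On plateau-like
  curves the least-squares optimum occasionally degenerates to A → 0
  with α running to the cap, the vanishing power term chasing the
  Monte-Carlo noise of the last lags; the exponent carries no
  information there. The α = 0 lower bound is *not* flagged: it is the
  model's physical subdiffusive limit and the correct asymptote for
  strong confinement.

All three produce `converged=False` and the track is classified
ambiguous; such tracks are counted and reported, never dropped silently.

**Exponent classification.** active if α > 1.5, diffusive if
0.9 < α < 1.1, confined if α < 0.5, otherwise ambiguous. The
inequalities are strict, so α exactly on a boundary is ambiguous. The
gaps [0.5, 0.9] and [1.1, 1.5] are genuinely unclassifiable under this
scheme; "ambiguous" is this package's reporting convention for them.

**Displacement classification.** ND = |x_N − x_1| and
LMD = max_t |x(t) − x_1| use only the axial (x) coordinate and are
absolute magnitudes — a retrograde 6-μm run is as directed as an
anterograde one. Directed if ND > 5 μm; else stationary if LMD < 1 μm;
else oscillatory. By this evaluation order the boundary values ND = 5 μm
and LMD = 1 μm fall to oscillatory, the inequalities being strict. For
raw camera-frame data `project_principal_axis` rotates each track onto
its principal axis first; the simulator already emits axial frames.

**Aggregation and statistics.** The statistical unit is the replicate
(culture). Class fractions are computed within each replicate (both
families always sum to 1 over their classes, ambiguous included), then
summarised per group as mean ± SD across replicates. Two-group designs
get a per-class Welch unequal-variance t test on the per-replicate
fractions, two-sided, uncorrected by default (`holm=True` applies Holm
correction within each class family). When both groups have zero
variance the statistic is defined by its limit: t = 0, p = 1 for equal
means, t = ±∞, p = 0 otherwise. Groups with fewer than 2 replicates skip
the comparison with a warning.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| frame_interval | 0.6 | s | acquisition sampling interval |
| duration | 90 | s | acquisition length → 151 frames |
| localization_sigma | 0.02 | μm | SD of additive Gaussian localization error per coordinate |
| velocity | 0.3 | μm/s | ballistic ground-truth speed (27 μm over a full track) |
| diffusion_coefficient | 0.1 | μm²/s | Brownian/confined step variance 2DΔt per coordinate |
| corral_radius | 0.2 | μm | reflecting disc radius for confined motion |
| min_frames_exclusive | 20 | frames | tracks must have strictly more frames |
| max_lag_fraction | 0.25 | — | MSD lag cap as fraction of track duration |
| α windows, ND/LMD cuts | 1.5 / 0.9–1.1 / 0.5; 5 μm / 1 μm | | classification constants |

Thresholds are a frozen dataclass; alternative constants can be passed
to every classifier and to `TrackMotionModel`.

## What the simulator does and does not emulate

The generator reproduces the acquisition geometry (uniform 0.6-s
sampling, 90-s movies), the three idealised motion regimes, and additive
i.i.d. Gaussian localization noise (σ = 0.02 μm, sub-pixel). Per-track
RNG streams are derived from (seed, track_id), so the set of generated
tracks is independent of generation order.

It does **not** emulate: mode switching within a track (real mRNPs pause
and re-engage motors), anisotropic or curved neurite geometry, motion
blur, photobleaching/blinking, detection or linking errors, gaps from
the tracking software, or z-projection artefacts from the three-slice
stacks. Passing the recovery tests therefore shows the estimator and
classifier chain is correct for tracks that are pure realisations of one
regime; it does not certify performance on tracks that switch regimes
mid-movie, which the α classifier can only average over.

Confinement is modelled as a reflecting circular corral (radial fold-in
at the boundary), the simplest mechanism producing the plateaued MSD the
confined class implies. At the defaults the free step SD (0.35 μm)
exceeds the corral radius, so the plateau (≈ R²) is reached within one
lag — "strong" confinement.

## Numerical choices and degenerate inputs

* Reflection at the corral uses the radial fold r → 2R − r (iterated;
  errors if a single step exceeds ~64 folds). In the R → ∞ limit the
  confined simulator reproduces the free-diffusion path bit for bit.
* Track tables are parsed with round-trip float precision so
  write→read is exact to ≤ 1e-9 relative.
* Tracks with interrupted sampling are split at every gap into uniform
  segments (ids suffixed `_s0`, `_s1`, …); 1-frame remainders are
  dropped with a warning. Gap interpolation is deliberately not offered.
* Uniform spacing is enforced to within 1e-9 s.
* Welch zero-variance limits as above; fraction sums are exact up to
  float addition (tested to 1e-9).

## Known limitations

* Single-trajectory α estimates on 151-frame tracks scatter with
  SD ≈ 0.25 even for pure Brownian motion, so the narrow diffusive
  window (0.9, 1.1) captures only ~25–30 % of true-Brownian tracks,
  most of the rest falling in the ambiguous gaps; the *ensemble mean* α
  is nonetheless ≈ 1.0. Per-track motion-class fractions should be read
  with this in mind; validation asserts diagonal dominance of the
  ground-truth confusion among the three named classes, treating
  ambiguous as a no-call.
* ND/LMD polarity (anterograde vs retrograde) is out of scope — the
  track frame does not encode soma orientation.
* Between-group tests assume per-replicate fractions are approximately
  normal; with 3–5 replicates this is an approximation, as in common
  practice.

## Problem sizes used in validation

The test suite and the acceptance script use the study-scale geometry
throughout (151 frames at 0.6 s): 200-track ensembles for the Brownian
and confined exponent-recovery checks, 100 random tracks (N ≤ 50)
against the brute-force MSD oracle, and mixtures of 60–360 labelled
tracks for the end-to-end pipeline checks.
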