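# Methods

## Sequence model

The predictive model is Prediction by Partial Matching (PPM), a
variable-order Markov model over a declared finite alphabet. Training counts
every n-gram of orders 0..`max_order` in the corpus; contexts never cross
sequence boundaries, and position 1 of a sequence is predicted from the
empty context. Prediction blends context levels with an escape mechanism:

* escape A: local mass c/(n+1), escape 1/(n+1);
* escape C (default): local mass c/(n+t), escape t/(n+t);
* escape D: local mass (c−0.5)/n, escape t/(2n),

with n the context's total count and t its number of distinct continuations.
With `exclusion=False` (default) smoothing is interpolated: at every level
the escape mass multiplies the full lower-order distribution, for seen and
unseen symbols alike. This is the standard choice in music-cognition PPM
implementations and guarantees exact normalization, which pure per-symbol
back-off without exclusion does not. With `exclusion=True` classic back-off
with symbol exclusion is used: symbols predicted at a higher order are
removed from all lower-order estimates, and if exclusion ever exhausts the
alphabet the remaining escape mass is renormalized over that level's local
estimates. Both regimes end in a uniform floor over the alphabet, so every
declared symbol — including violation tokens absent from training — has
strictly positive probability and finite information content (IC),
−log₂ p, in bits (base 2 throughout, the convention for surprisal).

Defaults: `max_order=4` (sequences have five events, so no longer context
exists), escape C, exclusion off, and no online adaptation — the model is
frozen after training, because the analysis applies training-set statistics
to new sequences. All of these are configurable and recorded in the model's
JSON serialization (format-versioned, losslessly round-trippable).

## Stimulus design

The generator reproduces the statistics of the experimental design, not its
literal notes (which are not published): 26 five-chord progressions in six
major tonalities (D, E, B♭, A♭, A, E♭; 5+5+4+4+4+4 sequences), each built
from one of eight cadential templates — function/inversion progressions such
as I–vi–IV–V–I or I–IV⁶–ii⁶–V–I, all ending with the authentic cadence
V→I. Chords are voiced in close position on the 27-key keyboard (key 1 =
F3, MIDI 53), with a per-tonality register anchor (lowest or highest
feasible octave for the bass).

The per-tonality template selections and anchors are a frozen design plan,
chosen once so that the published design counts hold by construction:

* 26 base sequences of 5 chords;
* exactly 50 distinct chords (distinct key triples). The arithmetic: the
  plan uses 52 distinct (tonality, function/inversion) tokens, and exactly
  two cross-tonality key-triple coincidences are unavoidable on 27 keys —
  the tonic of E equals the dominant of A, and the tonic of E♭ equals the
  dominant of A♭, because triads rooted between C♯4 and E4 fit the keyboard
  in only one octave. 52 − 2 = 50.
* six standard fingerings: {1-2-3, 1-2-4, 1-2-5, 1-3-4, 1-3-5, 1-4-5}.
  Only three of the study's six are named in print (1-2-4, 1-3-5, 1-2-3);
  the remaining three are thumb-anchored triad fingerings chosen here and
  flagged as implementation choices. The chord-to-finger mapping is
  deliberately flexible: each chord has a span-dependent candidate list
  (span ≤ 7 keys, = 8, ≥ 9), recurrences rotate through it with a
  seed-dependent phase, and final chords take the canonical 1-3-5. At least
  one recurring chord therefore carries three distinct fingerings, mirroring
  the published worked example.

Derived conditions: the irregular ending replaces only the final chord with
the Neapolitan — the minor subdominant with its fifth replaced by the
diminished sixth, voiced from the subdominant root voicing by lowering the
third and raising the fifth one semitone. Its pitch content equals the major
triad a semitone above the tonic, which enforces the Tonic/Neapolitan
pitch-content reuse across the semitone-apart tonality pairs in the set
(D→E♭, A♭→A, A→B♭, E♭→E). Short-context variants keep exactly the last two
events; nonstandard-fingering variants replace only the final fingering with
2-3-5 or 2-4-5, balanced 13/13 across base sequences. The penultimate event
is bit-identical across all six conditions of a base sequence. Mean
black-key counts of regular vs irregular finals differ by ≤ 0.5 (measured
0.12 at the default plan). The Neapolitan's voicing inversion (bass on the
scale's fourth degree, i.e. first inversion of the triad) is a design
choice; the source design does not state one.

The training corpus is 60 sequences — all eight templates plus two repeats
in each of six disjoint tonalities (C, G, B, F, D♭, G♭) — structurally and
motorically correct throughout, encoded with the same machinery, so its
structural tokens are exactly the test alphabet minus the violation token.

`validate_design` re-checks every one of these assertions on any generated
set and never mutates it.

## IC profiles

Profiles are computed per level (structural/motor) × condition over the 26
sequences. Short sequences are scored with a fresh empty context at their
first presented chord: the interposed filler task has no harmonic or
fingering content, so it is represented as a context reset only. Violation
effects are final-position IC differences (Neapolitan − Tonic at the
structural level; nonstandard − standard fingering at the motor level,
averaged over structure levels, which do not enter the motor encoding). The
context effect is the long-context minus short-context structural violation
effect; an order-0 model is context-blind and yields exactly 0.

## Behavioral generator

Each simulated pianist performs every base sequence once per condition
(6 × 26 = 156 trials). Trial RT is log-normal with unit-mean multiplicative
noise (σ_log = 0.15) around baseline + structural sensitivity × structural
IC(final) + motor sensitivity × motor IC(final). Population defaults:
baseline 900 ± 80 ms between subjects; sensitivities 6 ± 1.5 (structural)
and 8 ± 1.5 (motor) ms/bit, truncated at zero — a few milliseconds per bit,
producing interaction effects of tens of ms, the order observed in this
paradigm. Keystroke onsets scatter around the chord onset with SD 45 ms
(centered, so the trial RT is exactly the mean of the three final onsets);
key-error probability is 0.06 + 0.005/bit of structural IC, finger-error
probability 0.06 + 0.005/bit of motor IC, so structural violations inflate
key errors and motor violations inflate finger errors. With these defaults
the exclusion pipeline retains ≈ 69% of trials, matching the reported
retention; the defaults are a calibrated configuration, not a claim about
mechanism.

What the generator does *not* emulate: learning or fatigue across blocks,
sequential dependencies between trials, keystroke velocity/force dynamics,
the video-based finger-scoring process, and any non-IC source of condition
differences. Passing tests therefore show that the analysis chain recovers
the effects this generative structure plants — not that real pianists obey
it.

Exclusion pipeline, in order: (1) penultimate and final chord correct in
keys and fingers; (2) keystroke span of both chords ≤ 150 ms; (3) final RT
strictly below 3000 ms (a 3000-ms trial is excluded); (4) one single pass
per participant removing RTs > 2 SD from that participant's mean across
conditions, with thresholds from the pre-trim sample. A second application
of the pipeline re-triggers none of rules 1–3; the 2-SD trim is defined as
single-pass because any literal 2-SD trim shrinks the SD and would trim
again if iterated. With zero RT spread the trim removes nothing. Error
counts are tallied from the full trial table (errors are a dependent
variable in their own right); RT means use only valid trials, and empty
cells are missing (NaN), never zero.

## Statistics

Repeated-measures ANOVAs operate on per-subject condition means. All factors
have two levels, so each effect is a one-df contrast: with cell signs ±1
(products of factor codes) and per-subject score L_s = mean_c sign(c)·y_sc,
SS_effect = n·m·L̄², SS_error = m·Σ(L_s−L̄)², F(1, n−1) =
SS_effect/(SS_error/(n−1)), partial η² = SS_effect/(SS_effect+SS_error).
Sphericity is moot for two-level factors and no correction is applied. The
implementation is cross-checked in the tests against statsmodels' AnovaRM
and a hand-worked fixture. The signed interaction estimate (difference of
differences) is reported; for the STRUCTURE × CONTEXT table it equals the
subject-mean SP-index, SP = (RT_irr,long − RT_reg,long) − (RT_irr,short −
RT_reg,short), an identity asserted to 1e-9.

Post-hoc paired t tests use Bonferroni correction, adjusted p = min(1, p·m);
two-tailed by default, with one-tailed alternatives selectable and labeled.
Movement cost is mean RT(motor blocks) − mean RT(baseline blocks). Tract-FA
summarization includes a voxel iff FA > 0, it belongs to exactly one tract,
and it was part of that tract in ≥ 50% of participants; empty tracts are
flagged, never silently zero. Multiple regression is OLS on z-scored
variables (both sides standardized on the analyzed sample), reporting
standardized β, per-coefficient t and p (n − p − 1 error df), and adjusted
R²; rank-deficient designs are rejected. The pipeline's FA regression stage
runs on synthetic FA values with a planted standardized association of 0.6
to the SP-index (no diffusion data exists in a simulation run) and is
labeled synthetic in its outputs.

## Cluster-extent Monte Carlo

Null volumes are independent standard-normal fields on the analysis grid
(default 105 × 105 × 68 voxels of 2 mm — the 210-mm square FOV and
37 × 3.68-mm slab resampled to 2 mm — simulated unmasked), smoothed with a
Gaussian kernel (default FWHM 8 mm, converted to voxel units per axis) and
re-standardized to unit variance so the voxel threshold keeps its nominal
level. Per iteration the maximum supra-threshold cluster extent is recorded
(default: one-tailed z = Φ⁻¹(1−0.001) for directional contrasts;
18-connectivity, faces + edges); the corrected threshold is the smallest k
whose exceedance probability under the max-cluster null falls below α =
0.05. Defaults were fixed before any comparison; 6/26-connectivity and
two-tailed modes are selectable, and `convention_sensitivity` re-thresholds
the same simulated volumes under the full convention grid.

Known limitation: at these defaults the estimated threshold is ≈ 90–106
voxels (720–850 mm³) across all connectivity/tailedness conventions and
random seeds, not the ≈ 46 resampled voxels (368 mm³) quoted for this
design in the source analysis. The threshold expressed in mm³ is invariant
to the simulation grid (we verified that simulating at the 70 × 70 × 37
acquisition grid with 3 × 3 × 3.68-mm voxels gives the same volume), so no
grid/connectivity/tailedness convention reconciles the two at 8-mm FWHM on
an unmasked 6.0-L FOV. A smaller effective smoothness or search volume in
the original MATLAB simulation would produce the smaller printed value; the
inputs needed to settle this are not published. The estimator itself is
validated by construction (achieved family-wise p < α), by calibration on
fresh null volumes, and by its monotonicities in FWHM and voxel threshold.

## Problem sizes and numerics

The test suite runs the full design (26 + 60 sequences), 1000-iteration
Monte Carlo batches for the statistical calibration/power checks (n = 26
subjects per simulation), 1000 iterations for the cluster-threshold check,
and small grids (≈ 32 × 32 × 20) for the cluster unit tests — sizes chosen
to keep the whole suite in the ten-minute range on one CPU while leaving
Monte Carlo error well inside the asserted tolerances. Distributions are
required to normalize within 1e-9; oracle comparisons use 1e-10; ties in
the fingering rotation are broken deterministically by the seed-dependent
phase; all randomness flows through `numpy.random.default_rng` seeds, and
every pipeline run is a pure function of its config.
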