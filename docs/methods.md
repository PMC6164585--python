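# Methods

## Geometry and coordinate conventions

The solver works in the plane of a single linear array: the x-axis is the
array axis, the middle solver microphone `S2` sits at the origin, and `S3`
lies on the positive side. From the cosine rule on triangles `P S1 S2` and
`P S2 S3` plus the two range-difference constraints `r1 - r2 = c·t12`,
`r2 - r3 = c·t23`, the range `r2` and axis angle `θ` follow in closed form
(see README). Everything outside the solver uses the signed boresight angle
`φ = 90° - θ`, positive toward the last microphone; the mapping is fixed
here because axis angles in `[0°, 180°]` carry no left/right sign of their
own.

A linear array is cylindrically symmetric about its axis, so the 3-D problem
(array mounted at height *h* over the floor) collapses exactly to 2-D per
array: a floor source reduces to its axial coordinate and the slant radial
distance `sqrt(radial² + h²)`. `ArrayPose` uses this collapse for mic
distances and true bearings; the closed-form solver is therefore exact for
overhead-mounted arrays too, and the mounting height biases only the
*range*, never the bearing sign that area fusion consumes.

Two consequences of linearity are embraced rather than fought: a source and
its mirror image across the array axis are indistinguishable (hence two
orthogonal arrays for quadrant resolution), and a plane-wave (far-field)
source makes the range denominator `4c(a·t23 - b·t12)` vanish. We treat
`|a·t23 - b·t12| < 1e-12 s·m` as far field and return a sentinel instead of
a number; the bearing remains valid. `|cos θ|` may exceed 1 by up to `1e-9`
from floating-point noise and is clamped; beyond that the measurement is
rejected as inconsistent. On-axis sources (both delays saturated at the
spacings) are resolved to 0° or 180° by delay sign.

The default solver triple is mics (1, 2, 4) of the four-microphone array,
giving `a = 0.149 m`, `b = 0.077 m` — the widest aperture available; any
strictly increasing triple is configurable.

## Delay estimation

Per one-second frame, plain normalised cross-correlation (no PHAT
weighting — the design constraint is a cheap real-time loop) restricted to
the physically admissible lag window `spacing/c` plus a one-sample margin.
The integer peak is refined by a three-point parabolic fit, clipped to
±0.5 sample. At 16 kHz one sample is ~21 mm of path over a 149 mm baseline
(≈8° of bearing near boresight), so the sub-sample refinement is
load-bearing; measured estimator error on band-limited fixtures is well
under 0.1 sample at 20 dB SNR.

The frame confidence is the mean of the two pair peak correlations, a
number in [0, 1]; the validity gate requires it to exceed 0.5 *strictly*.
The energy gate for "sound present" defaults to 3× the median RMS of a
session's first ten frames (configurable): a plain noise-floor multiple,
chosen because the deployed system's silence criterion is not otherwise
specified.

## Fusion, gating, Grubbs

The sign pair `(sign φ_A, sign φ_B)` indexes a configurable quadrant→area
table (default: `(+,+)→I, (−,+)→II, (−,−)→III, (+,−)→IV`); zero angles tie
to the positive side so area counts are reproducible. A record is valid iff
both `|φ| ≤ 30°` and fused confidence `> 0.5`; invalid records keep their
measured values for audit, and null records (energy gate failed, or an
unsolvable measurement) stay null. The fused confidence is the mean over
arrays — gating per fused value rather than per array was an open choice;
the mean is symmetric and keeps the 0.5 threshold meaningful.

Gross-error filtering is the iterative two-sided Grubbs test at α = 0.05:
repeatedly remove the single most extreme value while
`G = max|x − mean|/sd` exceeds `G_crit(n, α) = ((n−1)/√n)·√(t²/(n−2+t²))`
with `t = t_{α/(2n), n−2}`. Constant or short (< 3) sequences pass through
untouched. Monte-Carlo checks in the suite confirm the false-removal rate
sits near α on outlier-free normal samples.

## Monitoring statistics

Accuracy is `100·correct/(correct+incorrect)`, displayed to one decimal
with half-up rounding (`decimal.Decimal`, matching how such tables are
printed; binary-float `round()` gets 71.95 → 71.9 wrong). Valid-record
bookkeeping is the identity `valid = non_null − invalid`, checked against
direct status counting. "Vocalisation count" means *valid* one-second
records; non-null counts are exposed separately since sound-presence and
valid localisation are distinct notions and summaries may want either.

## Scene simulator

The simulator defines the study conditions for every test: a 16 kHz
four-channel render per array, sources on the pen floor, free-field
propagation with 1/r spreading, and noise at a scene-wide SNR (default
20 dB white; "mechanical" noise is 4th-order low-passed white noise below
1 kHz, and a mixture model splits power evenly).

The hen call is a continuous-time model, not a stored sample: a harmonic
stack (fundamental drawn in 450–650 Hz, 4–6 partials with 1/k amplitude
decay), slow sinusoidal vibrato (1–4 % depth, 4–8 Hz), and a raised-cosine
syllabic envelope at 2.5–4 Hz, looping every 2.48 s. All parameters derive
from one seed, so renders are bit-identical under a fixed seed. Because the
model is analytic, each microphone channel is produced by evaluating it at
the retarded time `t − r_i/c`: sub-sample delays are exact by construction,
which is what allows the suite to assert estimator errors of 0.1 sample and
render-vs-geometry delay agreement of 0.05 sample. Sampled (array) source
signals are supported through windowed-sinc (Hann, 32-tap half-width)
band-limited interpolation instead; this path trades exactness for
generality and is tested to the same 0.05-sample bound on band-limited
content.

The reference grid is 9 × 7 points at 245 mm × 237 mm pitch centred under
the arrays (covering a ~1.96 m × 1.42 m test floor); with a 1.8 m mounting
height its outer mid-row columns reproduce the ±28° bearing extremes. The
nine-bearing sweep used for angle-error evaluation places the call at 1.8 m
range at bearings −28°…+28° from a single array.

What the simulator does **not** emulate: room reverberation and echo paths,
source directivity (the emitter is a point source), microphone mismatch and
sensor noise colouring, moving sources within a frame, and overlapping
simultaneous callers. Passing simulation tests therefore demonstrates the
correctness of the geometry, estimator and bookkeeping under free-field
conditions — not the field accuracy of a physical deployment, which was
measured on hardware and live birds and is dominated by exactly those
unmodelled effects (published field accuracies sit near 74 %, while the
free-field simulation is near-perfect by comparison).

## Night-sound categoriser

The four night-sound categories are recognised by explicit rules derived
from their qualitative descriptors: band-energy fractions (Welch PSD) and
an active-duration measure (short-time RMS above 10 % of its peak).
Defaults: a category band must hold ≥ 70 % of clip energy; "short" is
< 0.5 s; "≈2 s formant" is 1.5–2.5 s; mechanical noise must additionally be
active for most of the clip; a crow must genuinely span the band (≥ 5 %
below 1 kHz and ≥ 50 % above). First matching rule wins, in the order
mechanical → grunt → pecking → crow; anything else is `unknown`. These
thresholds are this package's own quantification of qualitative
descriptions — no claim is made of matching human labelling, and the STFT
display parameters (32 ms Hann, 50 % overlap) are defaults, not asserted
fidelity.

## Problem sizes and numerical choices

The test suite runs entirely on synthetic scenes: bearing sweeps use 2–3
one-second frames per bearing and the acceptance script uses 10; grid
evaluations use one frame per point. Closed-form/brute-force equivalence is
checked on 200 random sources against a `least_squares` hyperbola
intersection at `xtol=ftol=gtol=1e-15`, agreeing to 1e-6. The Grubbs size
check uses 1000–1200 replicates of n = 30. These sizes give stable
statistics while keeping the whole suite in seconds.

## Known limitations

- Range estimates from a 226 mm aperture degrade quadratically with
  distance and are reported but not gated on; the monitoring logic uses
  bearings only.
- Elevation is not estimated; the 2-D collapse folds mounting height into
  range bias.
- One source per frame: concurrent callers produce a correlation peak for
  the louder one or a confidence drop, not a multi-source fix.
- The quadrant→area mapping of a physical installation must be configured;
  the default is a convention, not a measurement.
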