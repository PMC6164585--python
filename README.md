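# coopssl

Sound-source localisation (SSL) and vocalisation monitoring for poultry pens
instrumented with linear microphone arrays.

Laying hens are nearly silent at night; starvation, machine malfunction or
other stressors make a flock vocalise abnormally, and *where* those sounds
come from (nest side vs feeder side) is diagnostic. `coopssl` implements the
full monitoring chain for a pen watched by two orthogonal four-microphone
linear arrays mounted overhead: time-difference-of-arrival (TDOA)
localisation at one-second intervals, dual-array fusion into floor areas,
validity gating, and the count statistics used to screen a night's activity.
A ground-truthed scene simulator stands in for the physical pen so the whole
pipeline is testable from software alone.

## The method

With three collinear microphones `S1(-a, 0)`, `S2(0, 0)`, `S3(b, 0)` and a
source `P` at distance `r_i` from `S_i`, the arrival-time differences
`t12 = (r1 - r2)/c` and `t23 = (r2 - r3)/c` (sound speed `c = 340 m/s`) give
a closed-form fix via the cosine rule:

    r2       = [2b(c²t12² - a²) + 2a(c²t23² - b²)] / [4c(a·t23 - b·t12)]
    cos θ    = [2t12(b²c - c³t23²) + 2t23(a²c - c³t12²)]
               / [2a(b² - c²t23²) + 2b(a² - c²t12²)]

where `θ` is the angle between the array axis and the line to the source.
The pipeline works with the signed boresight angle `φ = 90° - θ`. Delays are
estimated per one-second frame by normalised cross-correlation with
three-point parabolic peak interpolation; each array's `φ` sign selects a
quadrant, and the sign pair of two orthogonal arrays selects one of four
floor areas. Records are *valid* only when `|φ| ≤ 30°` on both arrays and the
correlation confidence exceeds 0.5; laboratory sessions additionally apply
an iterative two-sided Grubbs test to drop gross angle errors. Vocalisation
counts are the number of valid one-second records per time window.

The default array reproduces a Kinect-style geometry: consecutive microphone
gaps of 149 / 40 / 37 mm at 16 kHz sampling, with the solver using mics
(1, 2, 4), i.e. `a = 149 mm`, `b = 77 mm`.

## Worked example

```python
from coopssl import (MicArrayGeometry, forward_delays, solve_range,
                     solve_angle, axis_to_boresight)

geometry = MicArrayGeometry()           # a = 0.149 m, b = 0.077 m
tdoa = forward_delays(geometry, (0.5, 1.2))   # exact delays for a known source
print(solve_range(tdoa, geometry))      # 1.3000000000000365
print(solve_angle(tdoa, geometry))      # 67.38013505195948
print(axis_to_boresight(67.38013505195948))   # 22.61986494804052
```

The source at `(0.5, 1.2)` m sits 1.3 m from the middle microphone at an
axis angle of 67.38°, i.e. 22.62° to the right of boresight — inside the
±30° monitoring window.

The `examples/` directory holds one narrative script per capability
(closed-form geometry, simulate-and-localise, bearing-error sweep,
monitoring statistics, night-sound categorisation). A typical run of
`examples/03_bearing_sweep_accuracy.py` prints

    overall mean absolute bearing error: 0.088 deg

over the nine reference bearings (−28°…+28°) at 1.8 m range and 20 dB SNR —
the simulated pipeline's angular accuracy under clean free-field conditions.

A thin CLI wraps the same pipeline for shell use:

```sh
coopssl simulate --out-dir scene --duration 8 --seed 1
coopssl localise scene/array_A.wav scene/array_B.wav --out events.csv
coopssl monitor events.csv --flock-size 15
coopssl evaluate --rendered --snr-db 20
```

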