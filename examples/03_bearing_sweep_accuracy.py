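"""Bearing-error sweep over the nine laboratory reference angles.

For each reference bearing (-28 ... +28 degrees) a hen call is rendered at
1.8 m range with 20 dB SNR, and each one-second frame is localised.  The
mean absolute boresight error summarises the simulated pipeline's angular
accuracy; the deployed system's usable window is +/-30 degrees.
"""

import numpy as np

from coopssl import MicArrayGeometry, REFERENCE_BEARINGS_DEG, axis_to_boresight
from coopssl.geometry import solve_angle
from coopssl.simulate import bearing_scene, render_scene
from coopssl.tdoa import AudioFrame, measure_frame

FS = 16_000
geometry = MicArrayGeometry()

errors = []
for i, bearing in enumerate(REFERENCE_BEARINGS_DEG):
    spec = bearing_scene(bearing, seed=100 + i, snr_db=20.0, duration=3.0)
    waves, _ = render_scene(spec)
    per_bearing = []
    for f in range(3):
        frame = AudioFrame(waves["A"][:, f * FS:(f + 1) * FS], FS)
        meas = measure_frame(frame, geometry)
        phi = axis_to_boresight(solve_angle(meas, geometry))
        per_bearing.append(abs(phi - bearing))
    errors.extend(per_bearing)
    print(f"bearing {bearing:+5.0f} deg:  mean |error| = "
          f"{np.mean(per_bearing):.3f} deg")

print(f"\noverall mean absolute bearing error: {np.mean(errors):.3f} deg")
# Sub-sample peak interpolation is what keeps this well under 2 degrees:
# one raw sample at 16 kHz spans ~21 mm of path over a 149 mm baseline.
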