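"""Render a synthetic pen scene and run the full localisation pipeline.

A synthetic hen call plays from one corner of the pen for the first two
seconds of a four-second scene; both overhead arrays record it at 16 kHz
with 20 dB SNR white noise.  The pipeline gates each one-second frame for
sound, estimates the two boresight angles by cross-correlation, fuses them
into an area label and applies the validity gates.
"""

import numpy as np

from coopssl import HenCallModel, SceneSource, SceneSpec, localise_session, render_scene

spec = SceneSpec(
    sources=(
        SceneSource(
            position=(0.4, 0.3),  # pen area I (laying area)
            signal=HenCallModel.from_seed(3),
            schedule=((0.0, 2.0),),
        ),
    ),
    snr_db=20.0,
    duration=4.0,
    seed=9,
)
waves, truth = render_scene(spec)
print("ground truth per second:")
print(truth.to_string(index=False))

threshold = 0.25 * max(float(np.sqrt(np.mean(w**2))) for w in waves.values())
events = localise_session(
    waves["A"], waves["B"], spec.sample_rate, energy_threshold=threshold
)
print("\npipeline output (one event per second):")
for ev in events:
    if ev.status == "null":
        print(f"  t={ev.timestamp:.0f}s  null (no sound)")
    else:
        print(
            f"  t={ev.timestamp:.0f}s  phi_A={ev.phi_A:+6.2f}  "
            f"phi_B={ev.phi_B:+6.2f}  conf={ev.confidence:.2f}  "
            f"area={ev.area}  {ev.status}"
        )
# Valid events land in area I with bearings matching the truth table to a
# fraction of a degree; quiet tail seconds come back null (energy gate) or
# invalid (confidence gate), never as spurious valid localisations.
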