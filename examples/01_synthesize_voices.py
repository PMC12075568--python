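"""Generate synthetic voices and recover their acoustic-quality parameters.

Builds quasi-periodic glottal-pulse recordings with known jitter, shimmer and
harmonics-to-noise ratio, then runs the cycle detector and prints injected
vs. measured values — the round trip that validates the analysis chain.
"""

import numpy as np

from neurovibe import VoiceGenSpec, gen_voice
from neurovibe import feature_extraction as fx

print(f"{'injected jitter':>16} {'measured':>9}")
for target in (0.005, 0.01, 0.02, 0.04):
    rec = gen_voice(VoiceGenSpec(f0=150, jitter_target=target,
                                 shimmer_target=0.0, hnr_target=60, seed=0))
    cycles = fx.estimate_glottal_cycles(rec.samples, rec.rate)
    print(f"{target:16.3%} {fx.jitter(cycles):9.3%}")

print(f"\n{'injected HNR':>16} {'measured':>9}")
for target in (5.0, 10.0, 20.0):
    rec = gen_voice(VoiceGenSpec(f0=150, jitter_target=0.0,
                                 shimmer_target=0.0, hnr_target=target,
                                 seed=0))
    print(f"{target:14.1f}dB {fx.hnr(rec.samples, rec.rate):7.1f}dB")

rec = gen_voice(VoiceGenSpec(f0=220, jitter_target=0.0, shimmer_target=0.0,
                             hnr_target=60, seed=1))
cycles = fx.estimate_glottal_cycles(rec.samples, rec.rate)
print(f"\npitch of a 220 Hz voice: {fx.pitch(cycles):.2f} Hz")
print("Measured values should match the injected targets closely; a large "
      "gap would mean the cycle detector is mis-tracking the pulses.")
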