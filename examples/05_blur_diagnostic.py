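"""Check that the sliding-window blur cancels out of the suppression ratio.

A 1-s analysis window smears amplitude changes over a second of apparent time.
This diagnostic programs a constant amplitude gain into a simulated masked
condition and verifies that the estimated dB ratio is flat at -20*log10(gain)
everywhere — even for windows straddling stimulus onset, where both raw courses
show a 1-s ramp.
"""

import numpy as np

from ssvepdyn.pipeline import blur_cancellation_diagnostic

for gain in (1.0, 0.8, 0.5):
    rep = blur_cancellation_diagnostic(gain=gain)
    print(f"gain {gain:4.2f}: programmed ratio {rep.programmed_db:6.3f} dB, "
          f"max deviation {rep.max_abs_deviation_db:.2e} dB "
          f"over {int(rep.evaluated.sum())} window centers")

rep = blur_cancellation_diagnostic(gain=0.8)
onset = np.argmin(np.abs(rep.times))
print("\nat stimulus onset the raw amplitude course is mid-ramp "
      f"({rep.alone_amplitudes[onset]:.2f} uV of the final 2.00 uV), "
      f"yet the ratio already reads {rep.ratio_db[onset]:.3f} dB")
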