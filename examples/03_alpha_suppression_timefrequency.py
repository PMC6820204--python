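"""Measure stimulus-induced alpha suppression with Morlet wavelets.

Power in the 7-10 Hz band over 0.5-1.2 s after sentence onset, in dB re. the
-0.6 to -0.1 s prestimulus baseline: strongly negative on alHG contacts
(the ongoing alpha oscillation is suppressed), near zero on pmHG.
"""

import numpy as np

from hgalpha import timefreq
from hgalpha.simulate import SimulationParams, simulate_dataset

params = SimulationParams(n_hemispheres=1, n_trials_per_condition=10,
                          n_click_trials_per_rate=2, seed=2)
ds = simulate_dataset(params)
rec = ds.sentence_epochs[0]
contacts = ds.hemisphere_contacts(0)

cfg = timefreq.WaveletConfig()
low = cfg.low_freqs()
alpha_freqs = low[(low >= 7) & (low <= 10 + 1e-9)]
tf = timefreq.morlet_power(rec, cfg, freqs=alpha_freqs)
db = timefreq.baseline_db(tf, cfg.baseline_window)
alpha_db = timefreq.band_window_power(db, (7, 10), (0.5, 1.2))

for zone in ("pmHG", "alHG", "STP_STG_other"):
    m = contacts.zone == zone
    print(f"{zone:>13}: alpha change {alpha_db[m].mean():+6.2f} dB "
          f"(n={m.sum()} contacts)")
offset = timefreq.offset_locked_power(rec, cfg)
print(f"offset-locked alHG alpha (re. post-offset baseline): "
      f"{offset[contacts.zone == 'alHG'].mean():+.2f} dB")
# alHG loses ~6 dB (mixed clear/vocoded trials); the offset-locked value
# shows the suppression persists right up to the end of the sentence.
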