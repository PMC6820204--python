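"""Simulate click-train recordings and localize primary auditory cortex.

Primary (pmHG) contacts phase-lock to 100 Hz click trains and show <20 ms
evoked components; non-primary (alHG) contacts do neither. The classifier
sees only anatomical gyrus membership, never the simulator's labels.
"""

import numpy as np

from hgalpha import localize, phaselock
from hgalpha.simulate import SimulationParams, simulate_dataset

params = SimulationParams(n_hemispheres=1, n_trials_per_condition=4,
                          n_click_trials_per_rate=20, seed=0)
ds = simulate_dataset(params)
clicks = ds.click_epochs[0]
contacts = ds.hemisphere_contacts(0)

at_100 = clicks.select_trials(clicks.conditions.astype(float) == 100.0)
itpc = phaselock.compute_itpc(at_100)
chance = phaselock.surrogate_chance_level(at_100, seed=0)
evoked, times = localize.averaged_evoked_potential(clicks)
report = localize.classify_contacts(itpc, chance, evoked, times,
                                    contacts.on_heschl)
report["itpc_100Hz"] = phaselock.itpc_at_stimulus_rate(itpc, 100.0)

hg = report[report.on_heschl]
acc = (hg["assigned_field"].to_numpy() == contacts.zone[contacts.on_heschl]).mean()
print(hg[["contact_id", "itpc_100Hz", "itpc_significant",
          "evoked_latency", "assigned_field"]].to_string(index=False))
print(f"\nagreement with simulated ground truth: {100 * acc:.0f}%")
# pmHG rows: ITPC near 1 at the 100 Hz bin and latencies near 12 ms;
# alHG rows: ITPC near the ~0.2 chance level and no early component.
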