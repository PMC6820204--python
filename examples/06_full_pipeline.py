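"""Run the complete study end to end on a reduced synthetic dataset.

simulate -> preprocess (notch, 1000 Hz) -> localize fields from click trains
-> wavelet power, offset-locked and spectral analyses -> exact group tests.
A full-size run (8 hemispheres, default trial counts) takes a few minutes;
this example trims sizes so it finishes in well under a minute.
"""

import warnings

from hgalpha.pipeline import RunConfig, run_full_analysis
from hgalpha.simulate import SimulationParams

sim = SimulationParams(n_hemispheres=4, n_trials_per_condition=8,
                       n_click_trials_per_rate=10,
                       n_pmhg=3, n_alhg=3, n_other=5)
config = RunConfig(sim=sim, n_perm=500).with_seed(1)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_full_analysis(config)

print(result.tests[["comparison", "N", "W", "p", "r_e"]]
      .round(3).to_string(index=False))
print("\nper-hemisphere distance-decay slopes (dB/mm):",
      [round(s, 3) for s in result.distance_decay["slope"]])
# At N=4 hemispheres the smallest attainable exact p is 2/16 = 0.125: the
# headline contrasts (alpha lower in alHG, stronger suppression for clear
# speech, positive distance-decay slopes) all land on it.
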