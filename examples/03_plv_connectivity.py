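"""Measure seed-to-target phase-locking for an injected coupling.

A 18 Hz burst with a common random phase per event is added to the
anterior temporal seed and, jittered by vonMises(0, kappa=2), to one
frontal-pole target.  The PLV at the injected time-frequency bin should
approach the population resultant I1(2)/I0(2) ~= 0.698; uncoupled bins
stay near the chance floor ~ sqrt(pi)/2/sqrt(n).
"""

import numpy as np

from ecogplv import AnalysisConfig, CouplingSpec, von_mises_resultant
from ecogplv.plv import pairwise_plv, tf_phase
from ecogplv.preprocess import notch, rereference_connector
from ecogplv.simulate import ScheduleSpec, reduced_session_config, simulate_session

config = AnalysisConfig()
cfg = reduced_session_config(
    session_id="plv-demo", n_slots=100, channels_per_region=8,
    couplings=[CouplingSpec("at00", "fp00", "tone", 18.0, (100.0, 300.0),
                            kappa=2.0, amplitude_uv=40.0)],
)
cfg.schedule = ScheduleSpec(n_slots=100, p_omit=0.0)
bundle, events, _ = simulate_session(cfg, seed=3)

conditioned = notch(rereference_connector(bundle), *config.notch_hz)
seed = tf_phase(conditioned, events, "at00", config)
target = tf_phase(conditioned, events, "fp00", config)
m = pairwise_plv(seed, target, "tone", config.alpha_plv)

fi = np.argmin(np.abs(m.freqs_hz - 18.0))
ti = np.argmin(np.abs(m.times_ms - 200.0))
floor = np.sqrt(np.pi) / 2 / np.sqrt(m.n_trials)
print(f"{m.n_trials} trials; PLV at the injected bin (18 Hz, 200 ms): "
      f"{m.plv[fi, ti]:.3f}  (population value {von_mises_resultant(2.0):.3f})")
print(f"median PLV across all {m.plv.size} bins: {np.median(m.plv):.3f} "
      f"(chance floor ~{floor:.3f})")
print(f"Rayleigh-significant bins after FDR: {m.significant.sum()} "
      f"of {m.significant.size}")
# Expected: injected-bin PLV within a few hundredths of 0.698, the map
# median near the chance floor, and significance concentrated around the
# injected burst.
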