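"""Contrast tone-presentation vs tone-omission phase locking.

An omission-only 18 Hz coupling at 180-220 ms links the anterior
temporal seed to 4 of 16 frontal-pole electrodes.  The contrast
pipeline compares the two conditions' phase-difference samples per
time-frequency bin (circular common-median test, uncorrected p < 0.05),
applies the 20% band rule per frequency band, and summarizes the signed
proportion of significant electrodes over 10 ms windows.

Coupling only a minority of a connector group matters: the group-mean
re-reference subtracts whatever the coupled channels share, so coupling
every channel of a connector would largely cancel the injected burst.
"""

import numpy as np

from ecogplv import AnalysisConfig, CouplingSpec, run_plv
from ecogplv.simulate import reduced_session_config, simulate_session

config = AnalysisConfig()
cfg = reduced_session_config(
    session_id="contrast-demo", n_slots=1000, channels_per_region=16,
    couplings=[CouplingSpec("at00", t, "omission", 18.0, (180.0, 220.0),
                            kappa=5.0, amplitude_uv=20.0)
               for t in ("fp00", "fp01", "fp02", "fp03")],
)
bundle, events, _ = simulate_session(cfg, seed=4)
res = run_plv(bundle, events, config, np.random.default_rng(0))

c = res.contrast_for("at00", "fp00")
fi = np.argmin(np.abs(c.freqs_hz - 18.0))
ti = np.argmin(np.abs(c.times_ms - 200.0))
print(f"{c.n_trials_per_condition} trials per condition")
print(f"injected bin (18 Hz, 200 ms): omission PLV {c.plv_omission[fi, ti]:.3f}"
      f" vs tone PLV {c.plv_tone[fi, ti]:.3f}, contrast p = {c.p[fi, ti]:.3f}")

ratio = res.ratio_maps["at00"]
in_box = config.band_mask("low_beta", c.freqs_hz)[:, None] & (
    (c.times_ms >= 150) & (c.times_ms <= 250))[None, :]
print(f"mean signed ratio over the injected low-beta/200 ms box: "
      f"{ratio[in_box].mean():+.3f} (16 electrodes, 4 coupled)")
print(f"mean signed ratio elsewhere: {ratio[~in_box].mean():+.3f}")

props = res.proportions["at00"]
lb = props[props.band == "low_beta"]
peak = lb.loc[lb.value.idxmax()]
print(f"peak signed low-beta proportion: {peak.value:+.2f} at the "
      f"{peak.window_start_ms:.0f} ms window (positive = omission larger)")
# Expected: omission PLV several-fold above tone PLV at the injected
# bin (absolute values are modest because the 40 ms burst is much
# shorter than the 18 Hz wavelet, which dilutes it with surrounding
# noise), a positive ratio concentrated in the injected box, and the
# low-beta proportion time course peaking near 200 ms.  Individual bins
# are only intermittently significant: the common-median test has
# limited power for pure concentration differences (see
# docs/methods.md).
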