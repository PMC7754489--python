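"""Why the pulsatility index is computed on the averaged normalized curve.

Two estimators of a subject's PI from n noisy perforator curves:
  (a) average the normalized curves, then apply (max-min)/mean once;
  (b) apply (max-min)/mean per curve, then average the per-curve PIs.
The max/min operators rectify noise, so (b) inflates PI badly at realistic
noise levels; averaging first suppresses the noise before the extremes are
taken.
"""

from perfcensor import pi_noise_simulation

table = pi_noise_simulation(
    n_perforators=30, true_pi=0.45, noise_sd=0.3, n_reps=1000, seed=0
)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
best = table.loc[table["bias"].abs().idxmin(), "method"]
print(f"\ntrue PI = 0.45; the less noise-sensitive estimator is: {best}")
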