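"""Predicted size bias of hull-based EV sizing at finite localisation precision.

A vesicle labelled on its membrane rim and imaged with localisation
precision sigma appears broadened: the RMS radial spread of its
localisations is sqrt(R^2 + sigma^2), so the apparent diameter is
2*sqrt(R^2 + sigma^2) and small vesicles are inflated the most.
"""

from evquant import predicted_observed_diameter

print(f"{'true d (nm)':>12} {'sigma (nm)':>11} {'observed d (nm)':>16} {'bias (nm)':>10}")
for true_d in (50, 100, 150, 200):
    for sigma in (15.0, 20.0):
        d_obs, bias = predicted_observed_diameter(true_d / 2, sigma)
        print(f"{true_d:>12} {sigma:>11.0f} {d_obs:>16.1f} {bias:>10.1f}")

print("\nThe bias shrinks with vesicle size: a 50 nm EV gains 8-14 nm of")
print("apparent diameter over the 15-20 nm precision range, a 150 nm EV ~3-5 nm.")
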