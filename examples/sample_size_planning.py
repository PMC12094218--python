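"""How many animals per time point to detect a rhythm with 80% power?

Uses a 6-points-per-day template (every 4 hours) and solves for the
number of replicates per time point at several amplitude-to-noise
ratios.
"""

from cosinorpower import solve_sample_size

print("template: 6 time points per 24 h cycle, alpha = 0.05, target power 0.80")
for snr in (0.5, 0.75, 1.0, 1.5, 2.0):
    reps, res = solve_sample_size(
        n_per_cycle=6, A=snr, sigma=1.0, phi=0.0, alpha=0.05, target_power=0.80
    )
    print(
        f"  A/sigma = {snr:4.2f}: {reps} replicate(s)/time point "
        f"(n = {6 * reps:3d}), delta^2 = {res.delta2:6.2f}, power = {res.power:.3f}"
    )
print()
print("Halving the amplitude-to-noise ratio roughly quadruples the required n,")
print("since the noncentrality parameter scales as n * (A/sigma)^2 / 2 here.")
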