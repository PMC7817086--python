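"""Generate a chaotic one-time-pad keystream and inspect its bit balance.

Two logistic-map orbits (mu, x0 pairs are the secret) are thresholded at
0.5 and XORed.  A healthy stream has ones-frequency near 0.5 and changes
completely under a tiny parameter perturbation.
"""

from dnaotp import LogisticParams, keystream

p0 = LogisticParams(mu=3.78, x0=0.51)
p1 = LogisticParams(mu=3.92, x0=0.44)

k = keystream(p0, p1, n=100_000)
print(f"first 64 bits : {k.to_bitstring()[:64]}")
print(f"ones fraction : {k.bits.mean():.5f}   (ideal 0.5)")

# sensitivity: perturb one initial value in the 12th decimal
p0b = LogisticParams(mu=3.78, x0=0.510000000001)
kb = keystream(p0b, p1, n=100_000)
diff = (k.bits != kb.bits).mean()
print(f"bit change after 1e-12 perturbation of x0: {diff:.3f}  (~0.5 = decorrelated)")
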