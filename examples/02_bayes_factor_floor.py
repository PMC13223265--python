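"""JZS Bayes factors from group t statistics and the evidence floor.

The Bayes factor is minimized at t = 0; with N = 90 and prior scale
sqrt(2)/2 that floor is ~0.12, which is why asymmetric thresholds
(BF > 5 for the alternative, BF < 1/5 for the null) are used.
"""
import numpy as np

from narrative_encoding import classify_voxels, jzs_bf

n, scale = 90, np.sqrt(2) / 2
print(f"BF floor at t=0, N={n}: {jzs_bf(0.0, n, scale):.4f} "
      f"(rounds to {round(jzs_bf(0.0, n, scale), 2)})")
for t in (1.0, 2.0, 3.0, 5.0):
    print(f"  t = {t:.0f} -> BF10 = {jzs_bf(t, n, scale):.3g}")

# classify four illustrative voxels from their two-condition evidence
cmap = classify_voxels(
    bf_social=np.array([20.0, 0.1, 9.0, 2.0]),
    t_social=np.array([4.0, 0.5, 3.5, 1.2]),
    bf_tom=np.array([30.0, 15.0, 0.12, 2.0]),
    t_tom=np.array([5.0, 3.8, 0.4, 1.1]),
)
names = {0: "none", 1: "social_only", 2: "tom_only", 3: "both"}
print("voxel classes:", [names[int(c)] for c in cmap.labels])
# A voxel needs strong evidence FOR one condition and strong evidence for
# the null of the other before it is called condition-specific.
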