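"""Simulate a withering time course and inspect the moisture trajectory.

23 half-hourly time points x 6 replicates; moisture falls from 0.772 to
0.395 with replicate noise of sd 0.01.
"""

import numpy as np

from withervision import WitheringDesign, simulate_withering_series

design = WitheringDesign(seed=1)
series = simulate_withering_series(design)

print(series.head(8).to_string(index=False))
print(f"\nsamples: {len(series)}  (23 time points x 6 replicates)")
print(f"moisture range: {series.moisture.min():.4f} .. {series.moisture.max():.4f}")
r = np.corrcoef(series.time_h, series.moisture)[0, 1]
print(f"corr(time, moisture) = {r:+.4f}")
print("\nThe strong negative correlation reflects steady water loss over "
      "the 11 h course; each row is one replicate leaf sample.")
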