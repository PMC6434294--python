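"""Histogram of the survival data with all fitted densities overlaid.

Writes density_overlay.png next to this script (requires matplotlib).
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import frechetbayes as fb
from frechetbayes.analysis import plot_fit

report = fb.analyze(fb.head_neck_survival())
ax = plot_fit(report)
ax.set_xlabel("survival time (days)")
out = Path(__file__).with_name("density_overlay.png")
plt.savefig(out, dpi=150, bbox_inches="tight")
print(f"wrote {out}")
print("The right-skewed histogram and the five fitted Frechet densities; the")
print("ML curve follows the data closely, consistent with its KS p-value.")
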