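"""Fit the three-parameter Frechet distribution to the bundled survival data.

The 44 head-and-neck-cancer survival times are strongly right-skewed; the
Frechet (extreme value type-II) family handles this with a heavy right tail
and a location parameter that can shift the support left of the smallest
observation.  The script fits all five estimators (ML and the four
Lindley-Bayes variants with default hyperparameters k = a = b = 1) and
quantifies each fit with the Kolmogorov-Smirnov statistic.
"""

import frechetbayes as fb

data = fb.head_neck_survival()
print(f"loaded {data.n} survival times, range [{data.min:g}, {data.values.max():g}] days\n")

report = fb.analyze(data)
print(report.to_text())

print(
    "\nEach row is one estimation method: the fitted shape alpha (tail"
    "\nheaviness), scale lambda (spread, in days) and location eta (support"
    "\nstart).  Small KS distance D with large p means the fitted cdf tracks"
    "\nthe empirical one; the ML fit here is comfortably adequate (p >> 0.05)."
    "\n"
    "\nNote the warnings column: with the fitted scale near 120 days, the"
    "\ndefault loss constant k = 1 is very aggressive (LINEX loss grows like"
    "\nexp(k * error-in-days)), so several Lindley brackets leave their domain"
    "\non this data and those methods fall back to the ML triple, flagged as"
    "\nbracket_failure rather than reported silently.  A loss constant matched"
    "\nto the data scale and the derived-variant brackets behave better:"
)

small_k = fb.analyze(data, config=fb.HyperConfig(k=0.01, variant="derived"))
print("\nWith k = 0.01, derived variant:\n")
print(small_k.to_text())
print(
    "\nEven then the corrections are large — the inverse observed information"
    "\nhas entries of order 10^3 on this small, heavy-tailed sample, so the"
    "\nLindley expansion is stretched; the flags make that visible."
)
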