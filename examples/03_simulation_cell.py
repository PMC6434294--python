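"""One Monte Carlo cell of the estimator-comparison study.

Replicates sampling from Frechet(1, 2, 3) at n = 100, fits all five
estimators to each replicate, and reports the average estimate and the mean
squared error per method and parameter.  R = 500 keeps the run to a few
seconds; the full study uses R = 3000.
"""

import frechetbayes as fb
from frechetbayes.montecarlo import SimulationCell, render_table, run_cell

cell = SimulationCell(
    truth=fb.FrechetParams(1.0, 2.0, 3.0),
    n=100,
    R=500,
    seed=20240926,
)
res = run_cell(cell)
print(render_table({cell.n: res}, cell.truth))

print(
    "\nEach entry is the Monte Carlo average of that method's estimate with"
    "\nits MSE around the true value in parentheses.  With the default"
    "\nhyperparameters the noninformative general-entropy estimator (BGENP)"
    "\ntypically attains the smallest shape-parameter MSE, at the price of a"
    "\nmild downward bias; bracket-failure counts (replicates where the"
    "\napproximation left its domain) are tracked per Bayes method."
)
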