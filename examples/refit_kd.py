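"""Recover a linear Kd from reported Freundlich parameters.

Many batch studies report only the Freundlich fit (Kf, n).  A linear Kd
is re-derived by simulating the batch series: each initial concentration
is propagated through the mass balance Ci - Ce = SLR * Qe(Ce), and a
through-origin line is fitted to the resulting (Ce, Qe) points.
"""

import soilptf as sp
from soilptf.isotherms import BatchConditions

conditions = BatchConditions(Ci_list=(0.5, 1, 2, 5, 10), slr="1:10")

# n = 1: the Freundlich model is already linear, so Kd == Kf exactly
res = sp.refit_kd(Kf=2.67, n=1.0, conditions=conditions)
print(f"n=1.0: Kd = {res.Kd:.4f} L kg^-1 (p = {res.p_value:.2g})")

# n > 1: saturating sorption; the apparent Kd sits below Kf and drops
# further if the concentration series is shifted upward
for grid in [(0.5, 1, 2, 5, 10), (5, 10, 20, 50, 100)]:
    res = sp.refit_kd(Kf=3.35, n=1.20, conditions=BatchConditions(grid, "1:10"))
    tag = "" if res.significant else "  (not significant, would be excluded)"
    print(f"n=1.2, Ci {grid[0]}-{grid[-1]} mg/L: Kd = {res.Kd:.4f} L kg^-1{tag}")
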