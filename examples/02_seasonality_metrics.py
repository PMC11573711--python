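"""The four rainfall-seasonality metrics on contrasting regimes.

A uniform regime, a monsoon regime (rain concentrated in four months) and
a desert-margin regime, evaluated with every metric; higher values mean
drier/more concentrated, except madm where 1 means perfectly uniform.
"""

import numpy as np

from treelim.seasonality import madd, madm, mconc, mddm, MONTH_LENGTHS

regimes = {
    "uniform": np.full(12, 100.0),
    "monsoon": np.array([0, 0, 0, 0, 50, 300, 400, 300, 100, 0, 0, 0], float),
    "arid-margin": np.array([5, 2, 0, 0, 0, 0, 0, 0, 0, 10, 30, 15], float),
}

print(f"{'regime':12s} {'madm':>8s} {'mconc':>8s} {'madd':>8s} {'mddm':>8s}")
for name, pr_m in regimes.items():
    # expand the monthly climatology into a flat daily series for the
    # dry-day metrics (rain spread evenly over each month's days)
    daily = np.concatenate([
        np.full(n, m / n) for m, n in zip(pr_m, MONTH_LENGTHS)
    ]).reshape(-1, 1)
    print(f"{name:12s} {madm(pr_m.reshape(12, 1))[0]:8.3f} "
          f"{mconc(pr_m.reshape(12, 1))[0]:8.3f} "
          f"{madd(daily)[0]:8.3f} {mddm(daily)[0]:8.3f}")

print("\nmadm=1 means perfectly even months; mconc=0 means directions cancel;")
print("madd/mddm are dry-day fractions (threshold 0.1 mm/day).")
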