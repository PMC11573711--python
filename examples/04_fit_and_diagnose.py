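"""Fit the limitation model by MCMC on a small fixture and diagnose it.

Uses a deliberately small grid so the example runs in ~10 seconds; the
test-scale protocol (4 chains x 2000 iterations) and full protocol
(10 x 10000) only change ChainConfig.
"""

import numpy as np

import treelim as tl
from treelim.inference import predictive_coverage
from treelim.synthetic import SyntheticConfig, generate_drivers, simulate_observations

cfg = SyntheticConfig(nlat=16, nlon=16, seed=2)
drivers = generate_drivers(cfg)
spec = tl.default_control_spec()
pred = tl.prepare_predictors(drivers, spec)
obs = simulate_observations(drivers, cfg.true_params, seed=3)

train_idx, val_idx = tl.split_train(obs.n, fraction=0.20, seed=4)
print(f"{obs.n} cells: {train_idx.size} train, {val_idx.size} validation")

ens = tl.sample_posterior(obs.subset(train_idx), pred.subset(train_idx), spec,
                          config=tl.ChainConfig(n_chains=4, n_iter=1000, seed=5))
print(f"posterior ensemble: {len(ens)} members, acceptance {ens.acceptance:.2f}")

diag = tl.rhat(ens)
truth = cfg.true_params.to_dict(spec)
print(f"{'parameter':10s} {'true':>7s} {'5%':>7s} {'95%':>7s} {'R-hat':>6s}")
for name in ("tc_max", "sigma", "p0", "k_stress"):
    i = ens.param_names.index(name)
    lo, hi = np.quantile(ens.chains[:, :, i].ravel(), [0.05, 0.95])
    print(f"{name:10s} {truth[name]:7.3f} {lo:7.3f} {hi:7.3f} {diag[name]:6.2f}")

cov = predictive_coverage(obs.subset(val_idx), pred.subset(val_idx), ens, spec, seed=6)
print(f"held-out 10-90% predictive coverage: {cov:.1%} (expect ~80%)")
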