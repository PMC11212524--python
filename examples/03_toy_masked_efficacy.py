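"""Why the mark matters: efficacy invisible to marginal quantiles.

In the toy model with γ1 = −(2γ0+1), the marginal quantile ratio between
arms equals 1 at every τ — a markless analysis sees nothing — while the
mark-specific efficacy is positive for nearby strains (v < 1/2) and
negative for distant ones.  This script prints both closed forms and then
recovers the mark-specific pattern from simulated data.
"""

import numpy as np

from markqr import build_grid, fit_field, generate_toy

data, oracle = generate_toy(gamma0=0.25, gamma1=-1.5, n=4000, seed=5)

taus = [0.1, 0.2]
print("marginal qve (exactly zero by construction):")
for t in taus:
    print(f"  tau={t}: {oracle.marginal_qve(t):+.3f}")

print("\nmark-specific qve (closed form vs estimate), tau = 0.2:")
grid = build_grid(a=0.2, b=0.8, tau0=0.2, tauU=0.2, n_mark=13, n_tau=1,
                  h=0.15, horizon=float(data.time.max()))
field = fit_field(data, None, grid)
print(" v     true    estimated")
for iv in (0, 3, 6, 9, 12):
    v = grid.mark_points[iv]
    est = np.exp(field.beta[iv, 0, 1]) - 1.0
    print(f"{v:.2f}  {oracle.qve(v, 0.2):+.3f}   {est:+.3f}")
print("\nPositive efficacy below v = 0.5 flips to negative above it — the "
      "signal a marginal analysis integrates away to exactly zero.")
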