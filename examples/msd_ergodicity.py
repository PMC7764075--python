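"""Compare ensemble- and time-averaged MSD: weak ergodicity breaking.

For a drifting Hurst exponent (linear) the ensemble-averaged MSD leaves
the 95% band of per-trajectory time-averaged MSDs over most short lags;
for the oscillating (periodic) Hurst exponent the two averages agree.
"""

from mfbmtest import MfbmModel, eatamsd, preset_linear, preset_periodic, simulate_mfbm

for name, preset in [("linear drift", preset_linear),
                     ("periodic", preset_periodic)]:
    model = MfbmModel(hurst=preset(300.0), n_points=300)
    ens = simulate_mfbm(model, n=300, seed=7, include_origin=True)
    curves = eatamsd(ens, max_lag=75)
    inside = (curves.eamsd >= curves.ci_lo) & (curves.eamsd <= curves.ci_hi)
    print(f"{name:14s} H(t): EAMSD inside the 95% TAMSD band at "
          f"{100 * inside.mean():5.1f}% of lags 1..75")
# A low fraction means the ensemble average systematically departs from
# the time averages — the hallmark of weak ergodicity breaking; near 100%
# means the two kinds of averaging agree.
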