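"""Mean-squared-displacement estimators and ergodicity diagnostics.

Three standard MSD estimators for an ensemble of ``n`` equally spaced
trajectories, each with ``N`` observations:

ensemble-averaged (EAMSD)
    ``EAMSD(tau = m*dt) = (1/n) sum_k (X_k(t1 + tau) - X_k(t1))^2`` — the
    average squared displacement from a common anchor ``t1``.  With the
    deterministic origin ``X(0) = 0`` as anchor (the default) this is the
    empirical variance of ``X(tau)``, which for MFBM should scale as
    ``sigma^2 tau^{2 H(tau)}``.
time-averaged (TAMSD), per trajectory
    ``TAMSD(tau = m*dt, k) = (1/(N-m)) sum_j (X_k(t_{j+m}) - X_k(t_j))^2``.
ensemble-of-time-averaged (EATAMSD)
    the mean of the per-trajectory TAMSDs, with a pointwise 95% empirical
    quantile band across trajectories.

Systematic disagreement between the ensemble average and the (ensemble of)
time averages is the hallmark of weak ergodicity breaking; for MFBM it
appears whenever ``H(t)`` drifts (linear, logistic), while for periodic
``H(t)`` with a short period the two averages stay close.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TrajectoryEnsemble

__all__ = ["MSDCurves", "eamsd", "tamsd", "eatamsd"]


@dataclass(frozen=True)
class MSDCurves:
    """EAMSD / TAMSD / EATAMSD curves on a common lag axis."""

    lags: np.ndarray
    eamsd: np.ndarray | None
    eatamsd: np.ndarray
    tamsd_matrix: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    band: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        data = {"lag": self.lags}
        if self.eamsd is not None:
            data["eamsd"] = self.eamsd
        data.update(
            {"eatamsd": self.eatamsd, "ci_lo": self.ci_lo, "ci_hi": self.ci_hi}
        )
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), index=False)

    def plot(self, ax=None, loglog: bool = True):
        """EAMSD vs EATAMSD with the confidence band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(
            self.lags, self.ci_lo, self.ci_hi, alpha=0.3, color="tab:red",
            label=f"{self.band:.0%} TAMSD band",
        )
        ax.plot(self.lags, self.eatamsd, "--", color="tab:red", label="EATAMSD")
        if self.eamsd is not None:
            ax.plot(self.lags, self.eamsd, color="tab:blue", label="EAMSD")
        if loglog:
            ax.set_xscale("log")
            ax.set_yscale("log")
        ax.set_xlabel("lag")
        ax.set_ylabel("MSD")
        ax.legend()
        return ax


def eamsd(
    ensemble: TrajectoryEnsemble,
    max_lag: int | None = None,
    anchor_origin: bool = True,
) -> np.ndarray:
    """Ensemble-averaged MSD at lags ``m*dt``, ``m = 1..max_lag``.

    With ``anchor_origin`` (default) displacements are measured from the
    deterministic start ``X(0) = 0``, so ``EAMSD(tau)`` is the empirical
    variance of ``X(tau)``; the ensemble must carry the origin column or
    the anchor is taken as the implicit zero at ``t = 0``.  With
    ``anchor_origin=False`` the anchor is the first observed grid point
    ``t1`` and lags run over the remaining points.
    """
    vals = ensemble.values
    if anchor_origin:
        x = vals[:, 1:] if ensemble.origin_included else vals
        # anchor X(0) = 0: displacement is the value itself
        disp = x
    else:
        x = vals[:, 1:] if ensemble.origin_included else vals
        disp = x[:, 1:] - x[:, [0]]
    n_lags = disp.shape[1]
    if max_lag is None:
        max_lag = n_lags
    if not (1 <= max_lag <= n_lags):
        raise ValueError(f"max_lag must be in [1, {n_lags}], got {max_lag}")
    return np.mean(disp[:, :max_lag] ** 2, axis=0)


def tamsd(x: np.ndarray, m: int | np.ndarray) -> float | np.ndarray:
    """Time-averaged MSD of one trajectory at lag(s) ``m`` grid steps.

    ``(1/(N-m)) sum_j (x[j+m] - x[j])^2``; vectorized over ``m``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("tamsd expects a single trajectory vector")
    N = x.size
    ms = np.atleast_1d(np.asarray(m, dtype=int))
    if np.any((ms < 1) | (ms > N - 1)):
        raise ValueError(f"lags must be in [1, {N - 1}], got {m}")
    out = np.array([float(np.mean((x[mi:] - x[: N - mi]) ** 2)) for mi in ms])
    return float(out[0]) if np.isscalar(m) or np.asarray(m).ndim == 0 else out


def eatamsd(
    ensemble: TrajectoryEnsemble,
    max_lag: int | None = None,
    band: float = 0.95,
    include_eamsd: bool = True,
    anchor_origin: bool = True,
) -> MSDCurves:
    """Ensemble-of-time-averaged MSD with a pointwise quantile band.

    Computes per-trajectory TAMSDs for lags ``1..max_lag`` (default
    ``N - 1``), their mean (EATAMSD) and the pointwise empirical
    ``(1-band)/2`` and ``1-(1-band)/2`` quantiles across trajectories.
    The t=0 origin column, if present, is excluded from time averaging
    (it is deterministic, not an observation) but used for the EAMSD
    anchor.
    """
    obs = ensemble.without_origin().values
    n, N = obs.shape
    if max_lag is None:
        max_lag = N - 1
    if not (1 <= max_lag <= N - 1):
        raise ValueError(f"max_lag must be in [1, {N - 1}], got {max_lag}")
    dt = ensemble.dt
    ms = np.arange(1, max_lag + 1)
    tamsd_matrix = np.empty((n, max_lag))
    for mi in ms:
        diff = obs[:, mi:] - obs[:, : N - mi]
        tamsd_matrix[:, mi - 1] = np.mean(diff**2, axis=1)
    mean_curve = tamsd_matrix.mean(axis=0)
    if n >= 2:
        q = (1.0 - band) / 2.0
        ci_lo = np.quantile(tamsd_matrix, q, axis=0)
        ci_hi = np.quantile(tamsd_matrix, 1.0 - q, axis=0)
    else:
        ci_lo = mean_curve.copy()
        ci_hi = mean_curve.copy()
    ea = (
        eamsd(ensemble, max_lag=max_lag, anchor_origin=anchor_origin)
        if include_eamsd
        else None
    )
    return MSDCurves(
        lags=ms * dt,
        eamsd=ea,
        eatamsd=mean_curve,
        tamsd_matrix=tamsd_matrix,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        band=band,
    )
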