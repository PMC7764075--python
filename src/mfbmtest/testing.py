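"""Hypothesis test for MFBM and Monte Carlo power studies.

The null hypothesis is that a trajectory comes from an MFBM with a *given*
Hurst-exponent function ``H(t)`` (and variance level); the alternative is
any other ``H(t)``.  The test statistic is the lag-``tau`` autocovariance
``ACVF_N(tau)`` whose exact null law is the generalized chi-square of
:mod:`mfbmtest.statistic`.  The rejection region is two-sided with equal
tails: accept iff the statistic falls in
``[quantile(alpha/2), quantile(1 - alpha/2)]`` of the null distribution,
and the reported p-value is the matching equal-tail value
``2 * min(F(stat), 1 - F(stat))``.

The default lag is ``tau = 1``; larger lags use fewer products and give a
less informative statistic.

Power surfaces sweep two parameters of an alternative Hurst family,
simulate ``n_reps`` trajectories per grid cell from the alternative model
and record the fraction rejected by the *null* test.  Cells whose Hurst
function leaves ``(0, 1)`` (where MFBM is undefined) are masked and never
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .hurst import HurstFamily, HurstFunction, make_hurst, validate_hurst
from .model import MfbmModel, simulate_mfbm
from .statistic import QuadraticFormSpec, acvf_stat, gchi2_cdf, gchi2_quantile, null_eigenvalues

__all__ = [
    "TestResult",
    "PowerGrid",
    "critical_region",
    "run_test",
    "power_grid",
]

#: Which two parameters each family sweeps in a power study (fixed rest).
GRID_AXES: dict[HurstFamily, tuple[str, str]] = {
    HurstFamily.LINEAR: ("a", "b"),
    HurstFamily.LOGISTIC: ("b", "c"),
    HurstFamily.PERIODIC: ("a", "b"),
}


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single ACVF goodness-of-fit test."""

    statistic: float
    tau: int
    alpha: float
    acceptance_interval: tuple[float, float]
    p_value: float
    reject: bool

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "tau": self.tau,
            "alpha": self.alpha,
            "acceptance_interval": list(self.acceptance_interval),
            "p_value": self.p_value,
            "reject": self.reject,
        }


def critical_region(
    null_model: MfbmModel | QuadraticFormSpec,
    tau: int = 1,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Equal-tail acceptance interval of the null ACVF distribution.

    Returns ``(q_lo, q_hi)`` with ``F(q_lo) = alpha/2`` and
    ``F(q_hi) = 1 - alpha/2`` for the generalized chi-square null law.
    Accepts either a null model or a precomputed eigenvalue spec (so power
    grids can reuse one spectrum across cells).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    spec = (
        null_model
        if isinstance(null_model, QuadraticFormSpec)
        else null_eigenvalues(null_model, tau)
    )
    return gchi2_quantile(spec, alpha / 2.0), gchi2_quantile(spec, 1.0 - alpha / 2.0)


def run_test(
    x: np.ndarray,
    null_model: MfbmModel,
    tau: int = 1,
    alpha: float = 0.05,
    _spec: QuadraticFormSpec | None = None,
    _interval: tuple[float, float] | None = None,
) -> TestResult:
    """Test one trajectory against an MFBM null.

    ``x`` must have the null model's length ``N``.  The decision uses the
    equal-tail acceptance interval; the p-value ``2 min(F, 1 - F)`` is
    clipped to ``[0, 1]`` and coherent with the decision
    (reject iff p < alpha, up to CDF tolerance).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != null_model.n_points:
        raise ValueError(
            f"trajectory length {x.size} does not match null model N="
            f"{null_model.n_points}"
        )
    spec = _spec if _spec is not None else null_eigenvalues(null_model, tau)
    interval = _interval if _interval is not None else critical_region(spec, tau, alpha)
    stat = acvf_stat(x, tau)
    F = gchi2_cdf(spec, stat)
    p_value = float(np.clip(2.0 * min(F, 1.0 - F), 0.0, 1.0))
    reject = not (interval[0] <= stat <= interval[1])
    return TestResult(
        statistic=stat,
        tau=tau,
        alpha=alpha,
        acceptance_interval=(float(interval[0]), float(interval[1])),
        p_value=p_value,
        reject=bool(reject),
    )


@dataclass(frozen=True)
class PowerGrid:
    """Monte Carlo power estimates over a 2-D alternative-parameter grid.

    ``power[i, j]`` is the rejection fraction for the alternative with
    ``axis1_values[i]`` and ``axis2_values[j]``; ``valid_mask`` is False
    (and power NaN) where the alternative Hurst function leaves ``(0, 1)``.
    """

    axis1_name: str
    axis2_name: str
    axis1_values: np.ndarray
    axis2_values: np.ndarray
    power: np.ndarray
    valid_mask: np.ndarray
    n_reps: int
    alpha: float
    tau: int
    seed: int
    null_spec: dict | None = field(default=None, compare=False)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: axis1, axis2, power, valid, n_reps."""
        a1, a2 = np.meshgrid(self.axis1_values, self.axis2_values, indexing="ij")
        return pd.DataFrame(
            {
                self.axis1_name: a1.ravel(),
                self.axis2_name: a2.ravel(),
                "power": self.power.ravel(),
                "valid": self.valid_mask.ravel(),
                "n_reps": self.n_reps,
            }
        )

    def to_csv(self, path: str | Path, manifest: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if manifest:
            meta = {
                "null_model": self.null_spec,
                "alpha": self.alpha,
                "tau": self.tau,
                "seed": self.seed,
                "n_reps": self.n_reps,
                "axes": {
                    self.axis1_name: self.axis1_values.tolist(),
                    self.axis2_name: self.axis2_values.tolist(),
                },
            }
            path.with_suffix(path.suffix + ".manifest.json").write_text(
                json.dumps(meta, indent=2)
            )

    def plot(self, ax=None, **imshow_kwargs):
        """Heat map of the power surface (masked cells blank)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        masked = np.ma.masked_where(~self.valid_mask, self.power)
        extent = [
            self.axis2_values[0],
            self.axis2_values[-1],
            self.axis1_values[0],
            self.axis1_values[-1],
        ]
        im = ax.imshow(
            masked,
            origin="lower",
            aspect="auto",
            extent=extent,
            vmin=0.0,
            vmax=1.0,
            **imshow_kwargs,
        )
        ax.set_xlabel(self.axis2_name)
        ax.set_ylabel(self.axis1_name)
        ax.figure.colorbar(im, ax=ax, label="power")
        return ax


def _alt_params(
    family: HurstFamily,
    axis_names: tuple[str, str],
    v1: float,
    v2: float,
    fixed: dict[str, float],
) -> dict[str, float]:
    params = dict(fixed)
    params[axis_names[0]] = v1
    params[axis_names[1]] = v2
    return params


def power_grid(
    null_model: MfbmModel,
    alt_family: str | HurstFamily,
    axis1_values: np.ndarray,
    axis2_values: np.ndarray,
    n_reps: int = 1000,
    tau: int = 1,
    alpha: float = 0.05,
    seed: int = 0,
    fixed_params: dict[str, float] | None = None,
    progress: bool = False,
) -> PowerGrid:
    """Monte Carlo power surface of the test over a 2-D parameter sweep.

    For each valid cell, ``n_reps`` trajectories are simulated from the
    alternative MFBM (same grid and variance level as the null) and tested
    against the null's acceptance interval; the power is the rejection
    fraction.  The cell at the null's own parameters therefore estimates
    the type-I error.

    Parameters
    ----------
    null_model
        The MFBM under the null hypothesis; its acceptance interval is
        computed once and reused for every cell.
    alt_family
        Alternative Hurst family; the two swept parameters are ``(a, b)``
        for linear/periodic and ``(b, c)`` for logistic.
    axis1_values, axis2_values
        Values of the first/second swept parameter.
    fixed_params
        Remaining family parameters (e.g. logistic ``d`` and ``t0``);
        defaults to the null model's own values when the families match.
    seed
        Master seed; each cell gets a deterministic substream derived from
        ``(seed, cell index)`` so grids are reproducible cell by cell.
    """
    fam = HurstFamily(alt_family)
    if fam not in GRID_AXES:
        raise ValueError(f"power grids support families {list(GRID_AXES)}, got {fam}")
    axis1_values = np.asarray(axis1_values, dtype=float)
    axis2_values = np.asarray(axis2_values, dtype=float)
    if axis1_values.size == 0 or axis2_values.size == 0:
        raise ValueError("axis value vectors must be non-empty")
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    axes = GRID_AXES[fam]
    if fixed_params is None:
        fixed_params = {}
        if null_model.hurst.family is fam:
            fixed_params = {
                k: v for k, v in null_model.hurst.params.items() if k not in axes
            }
    spec = null_eigenvalues(null_model, tau)
    interval = critical_region(spec, tau, alpha)
    horizon = null_model.hurst.horizon
    power = np.full((axis1_values.size, axis2_values.size), np.nan)
    valid = np.zeros(power.shape, dtype=bool)
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(power.size, dtype=np.uint32)
    for i, v1 in enumerate(axis1_values):
        for j, v2 in enumerate(axis2_values):
            params = _alt_params(fam, axes, v1, v2, fixed_params)
            try:
                alt_fn = make_hurst(fam, params, horizon)
            except ValueError:
                continue
            if not validate_hurst(alt_fn, null_model.grid).valid:
                continue
            alt_model = MfbmModel(
                hurst=alt_fn,
                sigma2=null_model.sigma2,
                n_points=null_model.n_points,
                dt=null_model.dt,
            )
            cell_seed = int(cell_seeds[i * axis2_values.size + j])
            ens = simulate_mfbm(alt_model, n=n_reps, seed=cell_seed)
            stats = _acvf_batch(ens.values, tau)
            power[i, j] = float(
                np.mean((stats < interval[0]) | (stats > interval[1]))
            )
            valid[i, j] = True
            if progress:
                print(
                    f"[power] {axes[0]}={v1:g} {axes[1]}={v2:g} "
                    f"power={power[i, j]:.3f}"
                )
    return PowerGrid(
        axis1_name=axes[0],
        axis2_name=axes[1],
        axis1_values=axis1_values,
        axis2_values=axis2_values,
        power=power,
        valid_mask=valid,
        n_reps=n_reps,
        alpha=alpha,
        tau=tau,
        seed=seed,
        null_spec=null_model.to_dict(),
    )


def _acvf_batch(values: np.ndarray, tau: int) -> np.ndarray:
    """ACVF statistic for each row of an (n, N) trajectory matrix."""
    n_pts = values.shape[1]
    if tau == 0:
        return np.einsum("ij,ij->i", values, values) / n_pts
    return (
        np.einsum("ij,ij->i", values[:, tau:], values[:, : n_pts - tau])
        / (n_pts - tau)
    )
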