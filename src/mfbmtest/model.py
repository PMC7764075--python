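"""MFBM covariance kernel, covariance-matrix assembly and exact simulation.

A multifractional Brownian motion (MFBM) is the centred Gaussian process
with covariance

    Cov(B_{H(t)}(t), B_{H(s)}(s))
        = D(H(t), H(s)) * (t^{H(t)+H(s)} + s^{H(t)+H(s)} - |t-s|^{H(t)+H(s)})

where the scale factor is

    D(x, y) = sigma^2 * sqrt(Gamma(2x+1) Gamma(2y+1) sin(pi x) sin(pi y))
              / (2 Gamma(x+y+1) sin(pi (x+y)/2)).

For constant ``H`` this collapses to fractional Brownian motion
(``D(H, H) = sigma^2 / 2``), and for ``H = 1/2`` to Brownian motion.  The
variance scales as ``sigma^2 * t^{2 H(t)}``.

On a finite uniform grid ``t_i = i * dt`` the process is an ``N``-variate
Gaussian, so sample paths are drawn *exactly* by factoring the covariance
matrix (Cholesky, with an eigendecomposition fallback for borderline
floating-point semidefiniteness) and multiplying standard normals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .hurst import HurstFunction, validate_hurst

__all__ = [
    "MfbmModel",
    "TrajectoryEnsemble",
    "scale_factor_D",
    "covariance",
    "build_cov_matrix",
    "simulate_mfbm",
]

#: Relative tolerance on the most negative eigenvalue of a covariance matrix.
EPS_PSD = 1e-10


def scale_factor_D(x, y, sigma2: float = 1.0):
    """Covariance scale factor ``D(x, y)`` of the MFBM kernel.

    Vectorized over ``x`` and ``y`` (broadcasting); both must lie strictly
    in ``(0, 1)``.  Computed via log-gamma for numerical stability:
    ``D = sigma2 * exp(0.5*(lgamma(2x+1) + lgamma(2y+1)) - lgamma(x+y+1))
    * sqrt(sin(pi x) sin(pi y)) / (2 sin(pi (x+y)/2))``.

    ``D(H, H) = sigma2 / 2`` for every ``H`` in ``(0, 1)`` and the function
    is symmetric in ``(x, y)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((x <= 0) | (x >= 1)) or np.any((y <= 0) | (y >= 1)):
        raise ValueError("scale_factor_D requires arguments strictly in (0, 1)")
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    log_num = 0.5 * (
        gammaln(2.0 * x + 1.0)
        + gammaln(2.0 * y + 1.0)
        + np.log(np.sin(np.pi * x))
        + np.log(np.sin(np.pi * y))
    )
    log_den = gammaln(x + y + 1.0) + np.log(2.0 * np.sin(np.pi * (x + y) / 2.0))
    out = sigma2 * np.exp(log_num - log_den)
    return out if out.ndim else float(out)


def covariance(fn: HurstFunction, s, t, sigma2: float = 1.0):
    """MFBM covariance ``Cov(B_{H(t)}(t), B_{H(s)}(s))``; vectorized.

    Zero whenever ``s`` or ``t`` is 0 (the process starts at the origin
    almost surely).  On the diagonal it reduces to the variance law
    ``sigma2 * t^{2 H(t)}``.
    """
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(s < 0) or np.any(t < 0):
        raise ValueError("covariance requires non-negative times")
    s_b, t_b = np.broadcast_arrays(s, t)
    out = np.zeros(s_b.shape, dtype=float)
    pos = (s_b > 0) & (t_b > 0)
    if np.any(pos):
        sp, tp = s_b[pos], t_b[pos]
        hsum = np.asarray(fn(tp)) + np.asarray(fn(sp))
        d = scale_factor_D(np.asarray(fn(tp)), np.asarray(fn(sp)), sigma2)
        out[pos] = d * (tp**hsum + sp**hsum - np.abs(tp - sp) ** hsum)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MfbmModel:
    """An MFBM restricted to a uniform time grid ``t_i = i * dt``, i=1..N.

    ``t = 0`` is excluded from the covariance matrix (its row/column would
    be identically zero, making the matrix singular); simulated ensembles
    may prepend it as a deterministic zero for MSD anchoring.

    Parameters
    ----------
    hurst
        Hurst-exponent function, valid on ``[0, N*dt]``.
    sigma2
        Variance level ``sigma^2 > 0``; the process variance at time ``t``
        is ``sigma2 * t^{2 H(t)}``.  Default 1.
    n_points
        Number of grid points ``N``.
    dt
        Grid spacing (default 1, i.e. ``t = 1, 2, ..., N``).
    """

    hurst: HurstFunction
    sigma2: float = 1.0
    n_points: int = 1000
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")
        if self.n_points < 1:
            raise ValueError(f"n_points must be >= 1, got {self.n_points}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_points * self.dt > self.hurst.horizon * (1 + 1e-12):
            raise ValueError(
                f"grid extends to {self.n_points * self.dt} beyond the Hurst "
                f"function horizon {self.hurst.horizon}"
            )
        report = validate_hurst(self.hurst, self.grid)
        if not report.valid:
            raise ValueError(
                "Hurst function leaves (0, 1); analytic range "
                f"{report.analytic_range}, offending grid times "
                f"{report.offending_times[:5]}"
            )

    @property
    def grid(self) -> np.ndarray:
        """Time grid ``(1..N) * dt``."""
        return np.arange(1, self.n_points + 1, dtype=float) * self.dt

    @cached_property
    def cov(self) -> np.ndarray:
        """The ``N x N`` covariance matrix (symmetric, PSD up to round-off)."""
        return build_cov_matrix(self.hurst, self.grid, self.sigma2)

    @cached_property
    def _factor(self) -> np.ndarray:
        """Lower-triangular-ish factor ``L`` with ``L @ L.T = cov``.

        Cholesky first; if floating-point round-off makes the matrix
        indefinite, retry with jitter ``1e-12 * mean(diag)`` escalating
        tenfold up to ``1e-6 * mean(diag)``; final fallback is a symmetric
        eigendecomposition with negative eigenvalues clipped to zero.
        """
        sigma = self.cov
        try:
            return np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            pass
        scale = float(np.mean(np.diag(sigma)))
        jitter = 1e-12 * scale
        while jitter <= 1e-6 * scale:
            try:
                return np.linalg.cholesky(sigma + jitter * np.eye(sigma.shape[0]))
            except np.linalg.LinAlgError:
                jitter *= 10.0
        w, v = np.linalg.eigh(sigma)
        if w[-1] <= 0:
            raise np.linalg.LinAlgError(
                "covariance factorization failed: no positive eigenvalues"
            )
        return v * np.sqrt(np.clip(w, 0.0, None))

    @cached_property
    def sqrt_matrix(self) -> np.ndarray:
        """Symmetric PSD square root ``S`` of the covariance (``S @ S = cov``).

        Built from the eigendecomposition with negative round-off
        eigenvalues clipped to zero; used for the quadratic-form spectrum.
        """
        w, v = np.linalg.eigh(self.cov)
        return (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T

    def simulate(
        self, n: int, seed: int, include_origin: bool = False
    ) -> "TrajectoryEnsemble":
        """Draw ``n`` exact sample paths; see :func:`simulate_mfbm`."""
        return simulate_mfbm(self, n=n, seed=seed, include_origin=include_origin)

    def to_dict(self) -> dict:
        return {
            "hurst": self.hurst.to_dict(),
            "sigma2": self.sigma2,
            "n_points": self.n_points,
            "dt": self.dt,
        }

    @classmethod
    def from_dict(cls, spec: dict) -> "MfbmModel":
        return cls(
            hurst=HurstFunction.from_dict(spec["hurst"]),
            sigma2=float(spec.get("sigma2", 1.0)),
            n_points=int(spec["n_points"]),
            dt=float(spec.get("dt", 1.0)),
        )


def build_cov_matrix(
    fn: HurstFunction, grid: np.ndarray, sigma2: float = 1.0
) -> np.ndarray:
    """Assemble the MFBM covariance matrix on ``grid`` (all times > 0).

    The result is symmetric with diagonal ``sigma2 * t_i^{2 H(t_i)}`` and
    must be PSD up to a relative round-off tolerance of ``1e-10``; a larger
    violation signals a numerically hostile Hurst function and raises.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("covariance grid times must be strictly positive")
    h = np.asarray(fn(grid), dtype=float)
    hsum = h[:, None] + h[None, :]
    d = scale_factor_D(h[:, None], h[None, :], sigma2)
    t = grid[:, None]
    s = grid[None, :]
    sigma = d * (t**hsum + s**hsum - np.abs(t - s) ** hsum)
    sigma = 0.5 * (sigma + sigma.T)
    w = np.linalg.eigvalsh(sigma)
    if w[0] < -EPS_PSD * max(w[-1], 0.0):
        raise ValueError(
            f"covariance matrix not PSD within tolerance: lambda_min={w[0]:.3e}, "
            f"lambda_max={w[-1]:.3e}"
        )
    return sigma


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """A set of ``n`` equally spaced sample paths on a common grid.

    ``values`` has one row per trajectory; columns align with ``times``.
    If ``origin_included``, the first column is the deterministic anchor
    ``X(0) = 0``.
    """

    values: np.ndarray
    times: np.ndarray
    origin_included: bool = False
    seed: int | None = None
    model_spec: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times", times)
        if values.shape[1] != times.size:
            raise ValueError(
                f"values has {values.shape[1]} columns but grid has {times.size} points"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("trajectory values must be finite")
        if self.origin_included:
            if times[0] != 0.0 or np.any(values[:, 0] != 0.0):
                raise ValueError("origin column must be t=0 with X(0)=0")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 1.0

    def without_origin(self) -> "TrajectoryEnsemble":
        """Drop the t=0 anchor column if present."""
        if not self.origin_included:
            return self
        return TrajectoryEnsemble(
            values=self.values[:, 1:],
            times=self.times[1:],
            origin_included=False,
            seed=self.seed,
            model_spec=self.model_spec,
        )

    # -- delimited-text I/O --------------------------------------------------

    def to_csv(self, path: str | Path, write_sidecar: bool = True) -> None:
        """Write as CSV: first column ``time``, one column per trajectory.

        Metadata (seed, model spec, origin flag) goes to a ``.json``
        sidecar next to the CSV.
        """
        path = Path(path)
        df = pd.DataFrame(
            self.values.T,
            columns=[f"traj_{k}" for k in range(self.n)],
        )
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)
        if write_sidecar:
            meta = {
                "seed": self.seed,
                "origin_included": self.origin_included,
                "model": self.model_spec,
            }
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(meta, indent=2)
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrajectoryEnsemble":
        path = Path(path)
        df = pd.read_csv(path)
        times = df.iloc[:, 0].to_numpy(dtype=float)
        values = df.iloc[:, 1:].to_numpy(dtype=float).T
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        seed = None
        model_spec = None
        origin = bool(times.size and times[0] == 0.0 and np.all(values[:, 0] == 0.0))
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            seed = meta.get("seed")
            model_spec = meta.get("model")
            origin = bool(meta.get("origin_included", origin))
        return cls(
            values=values,
            times=times,
            origin_included=origin,
            seed=seed,
            model_spec=model_spec,
        )


def simulate_mfbm(
    model: MfbmModel, n: int, seed: int, include_origin: bool = False
) -> TrajectoryEnsemble:
    """Draw ``n`` i.i.d. exact MFBM sample paths on the model grid.

    Each path is ``L @ z`` with ``L`` a factor of the covariance matrix
    and ``z`` standard normal, i.e. an exact draw from the finite-
    dimensional law of the process.  Reproducibility contract: a single
    integer ``seed`` fully determines the ensemble, and trajectory ``k``
    is generated from its own deterministic substream (spawned via
    ``numpy`` ``SeedSequence``), so the first ``k`` trajectories do not
    change when ``n`` grows.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    L = model._factor
    N = model.n_points
    z = np.empty((n, N))
    for k, child in enumerate(np.random.SeedSequence(seed).spawn(n)):
        z[k] = np.random.default_rng(child).standard_normal(N)
    values = z @ L.T
    times = model.grid
    if include_origin:
        values = np.hstack([np.zeros((n, 1)), values])
        times = np.concatenate([[0.0], times])
    return TrajectoryEnsemble(
        values=values,
        times=times,
        origin_included=include_origin,
        seed=seed,
        model_spec=model.to_dict(),
    )
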