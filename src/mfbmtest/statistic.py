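"""The ACVF test statistic and its generalized chi-square null distribution.

For a centred Gaussian sample ``X = (X(1), ..., X(N))`` the empirical
autocovariance at lag ``tau`` *without mean subtraction*,

    ACVF_N(tau) = (1 / (N - tau)) * sum_{i=1}^{N-tau} X(i + tau) X(i),

is a quadratic form ``X' A(tau) X`` in a symmetric banded matrix ``A(tau)``
(diagonal ``1/N`` for ``tau = 0``; two subdiagonals with entries
``1 / (2 (N - tau))`` for ``tau >= 1``).  If ``X ~ N(0, Sigma)`` then

    ACVF_N(tau)  =d=  sum_i lambda_i Z_i^2,       Z_i i.i.d. N(0, 1),

where ``lambda_i`` are the eigenvalues of ``Sigma^{1/2} A(tau) Sigma^{1/2}``
— a generalized chi-square law with possibly mixed-sign weights.  This
holds whether or not the process is stationary, which is what makes the
statistic usable for multifractional Brownian motion.

The CDF of the weighted sum is evaluated by Imhof-type numerical inversion
of the characteristic function,

    P(Q <= q) = 1/2 - (1/pi) * int_0^inf sin(theta(u)) / (u rho(u)) du,
    theta(u)  = (1/2) sum_i arctan(lambda_i u) - q u / 2,
    rho(u)    = prod_i (1 + lambda_i^2 u^2)^{1/4},

which handles indefinite weight vectors where positive-weights series
methods do not apply.  When all (retained) weights are equal the law is
exactly a scaled chi-square and the closed form is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize
from scipy.stats import chi2

from .model import MfbmModel

__all__ = [
    "QuadraticFormSpec",
    "acvf_stat",
    "build_lag_matrix",
    "null_eigenvalues",
    "gchi2_cdf",
    "gchi2_quantile",
]

#: Eigenvalues with |lambda| below this fraction of max|lambda| are dropped.
EIGVAL_DROP_REL = 1e-12


def acvf_stat(x: np.ndarray, tau: int) -> float:
    """Empirical autocovariance at lag ``tau``, no mean subtraction.

    ``(1 / (N - tau)) * sum_{i=1}^{N-tau} x[i + tau] * x[i]`` (1-based).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("acvf_stat expects a single trajectory vector")
    n = x.size
    if n < 2:
        raise ValueError(f"need N >= 2, got N={n}")
    if not (0 <= tau <= n - 1):
        raise ValueError(f"tau must be in [0, {n - 1}], got {tau}")
    return float(x[tau:] @ x[: n - tau]) / (n - tau)


def build_lag_matrix(N: int, tau: int) -> np.ndarray:
    """Symmetric matrix ``A(tau)`` with ``x' A(tau) x = acvf_stat(x, tau)``.

    ``tau = 0``: ``(1/N) I``.  ``tau >= 1``: entries ``1 / (2 (N - tau))``
    where ``|i - j| = tau``, zero elsewhere.
    """
    if N < 2:
        raise ValueError(f"need N >= 2, got N={N}")
    if not (0 <= tau <= N - 1):
        raise ValueError(f"tau must be in [0, {N - 1}], got {tau}")
    if tau == 0:
        return np.eye(N) / N
    a = np.zeros((N, N))
    idx = np.arange(N - tau)
    a[idx, idx + tau] = 0.5 / (N - tau)
    a[idx + tau, idx] = 0.5 / (N - tau)
    return a


@dataclass(frozen=True)
class QuadraticFormSpec:
    """Eigenvalue weights defining a generalized chi-square distribution.

    ``eigenvalues`` are those of ``Sigma^{1/2} A(tau) Sigma^{1/2}`` sorted
    descending; they may contain negatives (``A(tau >= 1)`` is indefinite)
    and zeros.
    """

    eigenvalues: np.ndarray
    tau: int
    model_spec: dict | None = None

    def __post_init__(self) -> None:
        lam = np.sort(np.asarray(self.eigenvalues, dtype=float))[::-1]
        if not np.all(np.isfinite(lam)):
            raise ValueError("eigenvalues must be finite")
        object.__setattr__(self, "eigenvalues", lam)

    @property
    def mean(self) -> float:
        """E[Q] = sum of weights (= trace(Sigma A))."""
        return float(self.eigenvalues.sum())

    @property
    def variance(self) -> float:
        """Var[Q] = 2 * sum of squared weights."""
        return float(2.0 * np.sum(self.eigenvalues**2))

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "tau": self.tau,
            "model": self.model_spec,
        }

    @classmethod
    def from_dict(cls, spec: dict) -> "QuadraticFormSpec":
        return cls(
            eigenvalues=np.asarray(spec["eigenvalues"], dtype=float),
            tau=int(spec["tau"]),
            model_spec=spec.get("model"),
        )

    def cdf(self, q) -> float | np.ndarray:
        return gchi2_cdf(self, q)

    def quantile(self, p: float) -> float:
        return gchi2_quantile(self, p)


def null_eigenvalues(
    model: MfbmModel | np.ndarray, tau: int
) -> QuadraticFormSpec:
    """Spectrum of ``S A(tau) S`` with ``S`` the symmetric root of ``Sigma``.

    ``S A S`` shares its spectrum with ``Sigma A`` by similarity but is
    symmetric, so the eigenvalues are guaranteed real in floating point.
    Accepts either a model (whose covariance matrix is used) or a raw
    covariance matrix.
    """
    if isinstance(model, MfbmModel):
        S = model.sqrt_matrix
        spec_dict = model.to_dict()
    else:
        sigma = np.asarray(model, dtype=float)
        w, v = np.linalg.eigh(sigma)
        S = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
        spec_dict = None
    N = S.shape[0]
    A = build_lag_matrix(N, tau)
    M = S @ A @ S
    lam = np.linalg.eigvalsh(0.5 * (M + M.T))
    return QuadraticFormSpec(eigenvalues=lam, tau=tau, model_spec=spec_dict)


# -- generalized chi-square distribution ------------------------------------


def _active_weights(spec: QuadraticFormSpec | np.ndarray) -> np.ndarray:
    lam = (
        spec.eigenvalues
        if isinstance(spec, QuadraticFormSpec)
        else np.asarray(spec, dtype=float)
    )
    amax = np.max(np.abs(lam)) if lam.size else 0.0
    if amax == 0.0:
        return np.empty(0)
    return lam[np.abs(lam) > EIGVAL_DROP_REL * amax]


def _imhof_parts(u: float, lam: np.ndarray, q: float):
    """theta, theta', theta'', g = 1/(u rho) and g'/g at a single point."""
    lu = lam * u
    denom = 1.0 + lu**2
    theta = 0.5 * float(np.sum(np.arctan(lu))) - 0.5 * q * u
    dtheta = 0.5 * float(np.sum(lam / denom)) - 0.5 * q
    d2theta = -float(np.sum(lam**2 * lu / denom**2))
    log_rho = 0.25 * float(np.sum(np.log1p(lu**2)))
    g = np.exp(-log_rho) / u
    dlog_g = -(1.0 / u + 0.5 * float(np.sum(lam**2 * u / denom)))
    return theta, dtheta, d2theta, g, dlog_g


def _imhof_tail_bound(u: float, lam: np.ndarray, q: float, m: int) -> float:
    """Bound on the neglected tail beyond ``u`` after the IBP correction."""
    _, dtheta, _, g, dlog_g = _imhof_parts(u, lam, q)
    envelope = g * u / max(m / 2.0, 1.0)  # int_u^inf |g|, g ~ u^{-m/2-1}
    if abs(dtheta) > 1e-8:
        oscillatory = g * abs(dlog_g) ** 2 / dtheta**2 * u
        return min(envelope, oscillatory)
    return envelope


def _imhof_cutoff(lam: np.ndarray, q: float, epsabs: float) -> float:
    """Upper integration limit with post-correction tail below ``epsabs``."""
    m = lam.size
    u = 1.0 / max(float(np.max(np.abs(lam))), 1e-300)
    for _ in range(400):
        if _imhof_tail_bound(u, lam, q, m) <= epsabs:
            return u
        u *= 1.4
    return u


def _chernoff_tail(lam: np.ndarray, q: float, upper: bool) -> float:
    """Chernoff bound on P(Q >= q) (upper) or P(Q <= q) (lower).

    Uses the exact cumulant generating function
    ``K(t) = -0.5 sum log(1 - 2 lambda_i t)`` minimized over a grid of
    admissible ``t`` (``2 lambda_i t < 1`` for all i).
    """
    if upper:
        lam_edge = np.max(lam)
        if lam_edge <= 0:  # support within (-inf, 0]
            return 0.0 if q > 0 else 1.0
        ts = (1.0 / (2.0 * lam_edge)) * np.linspace(1e-6, 0.9999, 60)
    else:
        lam_edge = np.min(lam)
        if lam_edge >= 0:  # support within [0, inf)
            if q < 0:
                return 0.0
            # t unbounded below; sweep a wide log-spaced range
            ts = -(1.0 / (2.0 * np.max(lam))) * np.geomspace(1e-6, 1e8, 120)
        else:
            ts = (1.0 / (2.0 * lam_edge)) * np.linspace(1e-6, 0.9999, 60)
    best = np.inf
    for t in ts:
        arg = 1.0 - 2.0 * lam * t
        if np.any(arg <= 0):
            continue
        log_bound = -0.5 * float(np.sum(np.log(arg))) - t * q
        best = min(best, log_bound)
    return float(np.exp(best)) if np.isfinite(best) else 1.0


def _imhof_cdf_scalar(lam: np.ndarray, q: float, epsabs: float) -> float:
    # Far tails: skip quadrature (wildly oscillatory there) when a Chernoff
    # bound already pins the CDF to 0 or 1 within tolerance.
    mean = float(lam.sum())
    if q >= mean and _chernoff_tail(lam, q, upper=True) < 0.1 * epsabs:
        return 1.0
    if q <= mean and _chernoff_tail(lam, q, upper=False) < 0.1 * epsabs:
        return 0.0
    upper = _imhof_cutoff(lam, q, epsabs * 0.1)

    def integrand(u: float) -> float:
        lu = lam * u
        theta = 0.5 * float(np.sum(np.arctan(lu))) - 0.5 * q * u
        log_rho = 0.25 * float(np.sum(np.log1p(lu**2)))
        return np.sin(theta) * np.exp(-log_rho) / u

    val, _ = integrate.quad(
        integrand, 0.0, upper, epsabs=epsabs * 0.1, epsrel=1e-10, limit=800
    )
    # Oscillatory tail beyond the cutoff via integration by parts with
    # h = g / theta':  int_U^inf sin(theta) g du
    #   = cos(theta(U)) h(U) - sin(theta(U)) h'(U) / theta'(U) + O(next order).
    theta, dtheta, d2theta, g, dlog_g = _imhof_parts(upper, lam, q)
    if abs(dtheta) > 1e-8:
        h = g / dtheta
        dh = h * (dlog_g - d2theta / dtheta)
        val += np.cos(theta) * h - np.sin(theta) * dh / dtheta
    return float(np.clip(0.5 - val / np.pi, 0.0, 1.0))


def gchi2_cdf(spec: QuadraticFormSpec | np.ndarray, q, epsabs: float = 1e-8):
    """CDF of ``sum_i lambda_i Z_i^2`` at ``q`` (scalar or array).

    Negligible weights (``|lambda| < 1e-12 max|lambda|``) are dropped.  If
    all retained weights are equal the scaled chi-square closed form is
    used; otherwise Imhof characteristic-function inversion to absolute
    tolerance ``epsabs``.  An all-zero weight vector gives the unit step
    at 0.
    """
    lam = _active_weights(spec)
    q_arr = np.asarray(q, dtype=float)
    scalar = q_arr.ndim == 0
    q_arr = np.atleast_1d(q_arr)
    if lam.size == 0:
        out = (q_arr >= 0.0).astype(float)
        return float(out[0]) if scalar else out
    if np.allclose(lam, lam[0], rtol=1e-14, atol=0.0):
        # Q = lambda * chi2_m exactly.
        m = lam.size
        c = lam[0]
        out = chi2.cdf(q_arr / c, m) if c > 0 else chi2.sf(q_arr / c, m)
    else:
        out = np.array([_imhof_cdf_scalar(lam, float(qi), epsabs) for qi in q_arr])
    return float(out[0]) if scalar else out


def gchi2_quantile(
    spec: QuadraticFormSpec | np.ndarray, p: float, epsabs: float = 1e-8
) -> float:
    """Quantile ``q`` with ``gchi2_cdf(q) = p``, by bracketed root search."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    lam = _active_weights(spec)
    if lam.size == 0:
        raise ValueError("degenerate distribution: all weights zero")
    if np.allclose(lam, lam[0], rtol=1e-14, atol=0.0):
        m, c = lam.size, lam[0]
        return float(c * (chi2.ppf(p, m) if c > 0 else chi2.isf(p, m)))
    mean = float(lam.sum())
    sd = float(np.sqrt(2.0 * np.sum(lam**2)))
    lo, hi = mean - 10.0 * sd, mean + 10.0 * sd
    # expand the bracket until the CDF straddles p
    for _ in range(100):
        if gchi2_cdf(lam, lo, epsabs) < p:
            break
        lo -= 10.0 * sd
    for _ in range(100):
        if gchi2_cdf(lam, hi, epsabs) > p:
            break
        hi += 10.0 * sd
    return float(
        optimize.brentq(
            lambda q: gchi2_cdf(lam, q, epsabs) - p, lo, hi, xtol=1e-10 * max(sd, 1.0)
        )
    )
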