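"""Hurst-exponent functions ``H(t)`` for multifractional Brownian motion.

A multifractional Brownian motion (MFBM) replaces the constant Hurst index
of fractional Brownian motion with a continuous function ``H(t)`` taking
values strictly inside ``(0, 1)``.  This module constructs, evaluates and
validates such functions for the families commonly used to model transient
anomalous diffusion:

``linear``
    ``H(t) = a*t + b`` — a steady drift from short- to long-range
    dependence (or vice versa).
``logistic``
    ``H(t) = (c - b) / (1 + exp(-d*(t - t0)/T)) + b`` — a rapid but smooth
    switch between two levels ``b`` (early) and ``c`` (late), centred at
    ``t0`` with steepness ``d``.
``periodic``
    ``H(t) = a*sin(4*pi*t/T) + b`` — gradual, repetitive regime changes
    (two full periods over the horizon).
``constant``
    ``H(t) = H`` — plain fractional Brownian motion.
``tabulated``
    linear interpolation between user-supplied ``(time, value)`` knots,
    which keeps the function continuous.

Validity requires ``H(t)`` to stay *strictly* inside ``(0, 1)``: at 0 or 1
the covariance scale factor degenerates (``sin(pi*H) = 0``), so the open
interval is enforced.  For the named families validation uses analytic
extrema in addition to grid evaluation, so it cannot be fooled by a coarse
grid.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "HurstFamily",
    "HurstFunction",
    "HurstValidity",
    "make_hurst",
    "eval_hurst",
    "validate_hurst",
    "linear_hurst",
    "logistic_hurst",
    "periodic_hurst",
    "constant_hurst",
]


class HurstFamily(str, enum.Enum):
    """Named parameterizations of the Hurst-exponent function."""

    LINEAR = "linear"
    LOGISTIC = "logistic"
    PERIODIC = "periodic"
    CONSTANT = "constant"
    TABULATED = "tabulated"


#: Required parameter names per family.
_REQUIRED_PARAMS: dict[HurstFamily, tuple[str, ...]] = {
    HurstFamily.LINEAR: ("a", "b"),
    HurstFamily.LOGISTIC: ("b", "c", "d", "t0"),
    HurstFamily.PERIODIC: ("a", "b"),
    HurstFamily.CONSTANT: ("H",),
    HurstFamily.TABULATED: ("times", "values"),
}


@dataclass(frozen=True)
class HurstFunction:
    """A time-varying Hurst exponent ``H(t)`` on ``[0, T]``.

    Instances are immutable and callable: ``fn(t)`` evaluates the family
    formula elementwise.  Use :func:`make_hurst` (or the family shortcuts)
    to construct one with parameter checking.

    Attributes
    ----------
    family
        One of :class:`HurstFamily`.
    params
        Named real parameters of the family.  For ``tabulated`` the keys
        are ``times`` and ``values`` (equal-length tuples).
    horizon
        Time horizon ``T > 0``; the function is defined on ``[0, T]``.
    """

    family: HurstFamily
    params: Mapping[str, object] = field(default_factory=dict)
    horizon: float = 1.0

    def __post_init__(self) -> None:
        fam = HurstFamily(self.family)
        object.__setattr__(self, "family", fam)
        if not (np.isfinite(self.horizon) and self.horizon > 0):
            raise ValueError(f"horizon must be finite and positive, got {self.horizon}")
        missing = [p for p in _REQUIRED_PARAMS[fam] if p not in self.params]
        if missing:
            raise ValueError(f"family {fam.value!r} missing parameters: {missing}")
        if fam is HurstFamily.TABULATED:
            t = np.asarray(self.params["times"], dtype=float)
            v = np.asarray(self.params["values"], dtype=float)
            if t.ndim != 1 or t.shape != v.shape or t.size < 2:
                raise ValueError("tabulated family needs >= 2 (time, value) pairs")
            if np.any(np.diff(t) <= 0):
                raise ValueError("tabulated times must be strictly increasing")
            if t[0] > 0 or t[-1] < self.horizon:
                raise ValueError("tabulated knots must cover [0, horizon]")
            # freeze as tuples so the dataclass stays hashable
            object.__setattr__(
                self, "params", {"times": tuple(t.tolist()), "values": tuple(v.tolist())}
            )
        else:
            object.__setattr__(
                self, "params", {k: float(self.params[k]) for k in _REQUIRED_PARAMS[fam]}
            )

    # -- evaluation ---------------------------------------------------------

    def __call__(self, times: float | Sequence[float] | np.ndarray) -> np.ndarray:
        """Evaluate ``H(t)`` elementwise; ``times`` must lie in ``[0, T]``."""
        t = np.asarray(times, dtype=float)
        if np.any(t < 0) or np.any(t > self.horizon):
            bad = t[(t < 0) | (t > self.horizon)]
            raise ValueError(
                f"times outside [0, {self.horizon}]: {np.atleast_1d(bad)[:5]}"
            )
        p = self.params
        T = self.horizon
        if self.family is HurstFamily.LINEAR:
            out = p["a"] * t + p["b"]
        elif self.family is HurstFamily.LOGISTIC:
            out = (p["c"] - p["b"]) / (1.0 + np.exp(-p["d"] * (t - p["t0"]) / T)) + p["b"]
        elif self.family is HurstFamily.PERIODIC:
            out = p["a"] * np.sin(4.0 * np.pi * t / T) + p["b"]
        elif self.family is HurstFamily.CONSTANT:
            out = np.full_like(t, p["H"], dtype=float)
        else:  # tabulated
            out = np.interp(t, np.asarray(p["times"]), np.asarray(p["values"]))
        return out if out.ndim else float(out)

    # -- analytic range -----------------------------------------------------

    def analytic_range(self) -> tuple[float, float]:
        """Bounds ``[lo, hi]`` of ``H`` over ``[0, T]`` from family analytics.

        For ``linear`` these are the endpoint values, for ``periodic``
        ``b -/+ |a|`` (the sine attains both extrema within two periods),
        for ``logistic`` the asymptotic levels ``min(b, c)``/``max(b, c)``
        (a closure bound: the finite-horizon values stay strictly between),
        for ``constant`` the value itself and for ``tabulated`` the knot
        extrema (piecewise-linear interpolation attains them).
        """
        p = self.params
        T = self.horizon
        if self.family is HurstFamily.LINEAR:
            ends = (p["b"], p["a"] * T + p["b"])
            return min(ends), max(ends)
        if self.family is HurstFamily.LOGISTIC:
            return min(p["b"], p["c"]), max(p["b"], p["c"])
        if self.family is HurstFamily.PERIODIC:
            return p["b"] - abs(p["a"]), p["b"] + abs(p["a"])
        if self.family is HurstFamily.CONSTANT:
            return p["H"], p["H"]
        vals = np.asarray(p["values"], dtype=float)
        return float(vals.min()), float(vals.max())

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        """Plain-dict form ``{family, params, horizon}`` for JSON/YAML."""
        params = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in self.params.items()
        }
        return {"family": self.family.value, "params": params, "horizon": self.horizon}

    @classmethod
    def from_dict(cls, spec: Mapping[str, object]) -> "HurstFunction":
        return cls(
            family=HurstFamily(spec["family"]),
            params=dict(spec["params"]),  # type: ignore[arg-type]
            horizon=float(spec["horizon"]),  # type: ignore[arg-type]
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "HurstFunction":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class HurstValidity:
    """Structured validity report from :func:`validate_hurst`."""

    valid: bool
    offending_times: tuple[float, ...] = ()
    analytic_range: tuple[float, float] | None = None

    def __bool__(self) -> bool:
        return self.valid


def make_hurst(
    family: str | HurstFamily,
    params: Mapping[str, object],
    horizon: float,
) -> HurstFunction:
    """Construct a :class:`HurstFunction` with parameter validation.

    Parameters
    ----------
    family
        Family name (``linear``, ``logistic``, ``periodic``, ``constant``
        or ``tabulated``).
    params
        Named parameters; see module docstring for each family's formula.
    horizon
        Time horizon ``T > 0``.
    """
    try:
        fam = HurstFamily(family)
    except ValueError as exc:
        raise ValueError(
            f"unknown Hurst family {family!r}; choose from "
            f"{[f.value for f in HurstFamily]}"
        ) from exc
    return HurstFunction(family=fam, params=params, horizon=horizon)


def eval_hurst(fn: HurstFunction, times: Sequence[float] | np.ndarray) -> np.ndarray:
    """Evaluate ``H(t)`` at ``times`` (all within ``[0, T]``)."""
    return np.asarray(fn(np.asarray(times, dtype=float)))


def validate_hurst(
    fn: HurstFunction,
    grid: Sequence[float] | np.ndarray | None = None,
) -> HurstValidity:
    """Check that ``H(t)`` lies strictly in ``(0, 1)`` over ``[0, T]``.

    Validation combines (a) evaluation on ``grid`` (default: 1001 equally
    spaced points on ``[0, T]``) and (b) the family's analytic extrema, so
    excursions between grid points cannot slip through.  The open interval
    is strict: a function touching 0 or 1 is invalid.

    Returns
    -------
    HurstValidity
        ``valid`` flag, the offending grid times (if any) and the analytic
        range.
    """
    if grid is None:
        grid = np.linspace(0.0, fn.horizon, 1001)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("validation grid must be non-empty")
    vals = np.asarray(fn(grid))
    bad = (vals <= 0.0) | (vals >= 1.0)
    lo, hi = fn.analytic_range()
    valid = (not bool(bad.any())) and lo > 0.0 and hi < 1.0
    return HurstValidity(
        valid=valid,
        offending_times=tuple(np.atleast_1d(grid[bad]).tolist()),
        analytic_range=(lo, hi),
    )


# -- convenience constructors ----------------------------------------------


def linear_hurst(a: float, b: float, horizon: float) -> HurstFunction:
    """``H(t) = a*t + b`` on ``[0, horizon]``."""
    return make_hurst(HurstFamily.LINEAR, {"a": a, "b": b}, horizon)


def logistic_hurst(
    b: float, c: float, d: float, t0: float, horizon: float
) -> HurstFunction:
    """``H(t) = (c-b)/(1+exp(-d*(t-t0)/T)) + b`` on ``[0, horizon]``."""
    return make_hurst(
        HurstFamily.LOGISTIC, {"b": b, "c": c, "d": d, "t0": t0}, horizon
    )


def periodic_hurst(a: float, b: float, horizon: float) -> HurstFunction:
    """``H(t) = a*sin(4*pi*t/T) + b`` on ``[0, horizon]``."""
    return make_hurst(HurstFamily.PERIODIC, {"a": a, "b": b}, horizon)


def constant_hurst(H: float, horizon: float) -> HurstFunction:
    """Constant ``H(t) = H`` (plain fractional Brownian motion)."""
    return make_hurst(HurstFamily.CONSTANT, {"H": H}, horizon)


# -- reference study presets -------------------------------------------------

#: Linear preset: H(t) = 0.0003 t + 0.3 on [0, 1000], drifting from 0.3 to 0.6.
def preset_linear(horizon: float = 1000.0) -> HurstFunction:
    return linear_hurst(a=0.3 / horizon, b=0.3, horizon=horizon)


#: Logistic preset: smooth switch from 0.3 to 0.6 centred at T/2, steepness 100.
def preset_logistic(horizon: float = 1000.0) -> HurstFunction:
    return logistic_hurst(b=0.3, c=0.6, d=100.0, t0=horizon / 2.0, horizon=horizon)


#: Periodic preset: 0.15 sin(4 pi t / T) + 0.45, oscillating between 0.3 and 0.6.
def preset_periodic(horizon: float = 1000.0) -> HurstFunction:
    return periodic_hurst(a=0.15, b=0.45, horizon=horizon)


PRESETS = {
    "linear": preset_linear,
    "logistic": preset_logistic,
    "periodic": preset_periodic,
}
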