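"""Logicle (biexponential) display transform for fluorescence intensities.

The logicle scale is approximately linear around zero — so the
background-subtracted, partly negative intensities of unstained cells remain
visible — and asymptotically logarithmic at large values.  It is
parameterized by the full-scale data value ``T``, the linearization width
``W`` (decades), the number of displayed decades ``M`` and the number of
additional negative decades ``A``.

The transform used here maps data values onto display scale ``x`` in
``[0, 1]`` through the inverse of the biexponential

    S(x) = a·exp(b·x) − c·exp(−d·x) − f

whose five constants are fixed by requiring ``S(1) = T``, ``S(x1) = 0`` at
the zero-point ``x1 = (A + W)/(M + A)``, and a smooth quasi-linear region of
width ``W`` decades around ``x1``.  It is used for histogram display only,
never for metric computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["LogicleTransform", "logicle", "estimate_w"]


@dataclass(frozen=True)
class LogicleTransform:
    """Callable logicle transform with a fixed parameter set.

    Parameters
    ----------
    T:
        Full-scale ("top of scale") data value; must be positive.
    W:
        Width of the quasi-linear region in decades; ``W >= 0``.
    M:
        Total number of displayed decades (default 4.5).
    A:
        Additional negative decades below the quasi-linear region (default 0).
    """

    T: float
    W: float
    M: float = 4.5
    A: float = 0.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.M <= 0:
            raise ValueError("M must be positive")
        if self.W < 0:
            raise ValueError("W must be non-negative")
        if self.A < 0:
            raise ValueError("A must be non-negative")
        if 2 * self.W + self.A > self.M:
            raise ValueError("require 2W + A <= M for a valid scale")
        object.__setattr__(self, "_constants", self._solve_constants())

    def _solve_constants(self) -> tuple[float, float, float, float, float, float]:
        w = self.W / (self.M + self.A)
        x2 = self.A / (self.M + self.A)
        x1 = x2 + w
        x0 = x2 + 2.0 * w
        b = (self.M + self.A) * np.log(10.0)
        if w == 0.0:
            d = b
        else:
            # d is the decay rate of the negative exponential; the quasi-linear
            # width pins it through 2 ln(d/b) + w (d + b) = 0 with 0 < d < b.
            func = lambda d: 2.0 * (np.log(d) - np.log(b)) + w * (d + b)
            d = optimize.brentq(func, 1e-12, b, xtol=1e-14, rtol=1e-15)
        c_a = np.exp(x0 * (b + d))
        f_a = np.exp(b * x1) - c_a / np.exp(d * x1)
        a = self.T / (np.exp(b) - f_a - c_a / np.exp(d))
        c = c_a * a
        f = f_a * a
        return (a, b, c, d, f, x1)

    @property
    def zero_point(self) -> float:
        """Display-scale coordinate mapped to data value 0."""
        return self._constants[5]

    def inverse(self, x) -> np.ndarray:
        """Biexponential: display scale -> data value (closed form)."""
        a, b, c, d, f, _ = self._constants
        x = np.asarray(x, dtype=np.float64)
        return a * np.exp(b * x) - c * np.exp(-d * x) - f

    def _slope(self, x: np.ndarray) -> np.ndarray:
        a, b, c, d, _, _ = self._constants
        return a * b * np.exp(b * x) + c * d * np.exp(-d * x)

    def forward(self, values) -> np.ndarray:
        """Data value -> display scale, by inverting the biexponential.

        Strictly monotone and defined for negative inputs.  Solved with
        bisection-safeguarded Newton iteration to ~1e-12 relative accuracy.
        """
        values = np.atleast_1d(np.asarray(values, dtype=np.float64))
        x1 = self._constants[5]
        # bracket: S is strictly increasing, expand until it contains all values
        lo = np.full(values.shape, x1 - 1.0)
        hi = np.full(values.shape, 1.5)
        for _ in range(200):
            bad = self.inverse(lo) > values
            if not bad.any():
                break
            lo[bad] -= 1.0
        for _ in range(200):
            bad = self.inverse(hi) < values
            if not bad.any():
                break
            hi[bad] += 1.0
        x = 0.5 * (lo + hi)
        for _ in range(100):
            fx = self.inverse(x) - values
            above = fx > 0
            hi = np.where(above, x, hi)
            lo = np.where(above, lo, x)
            step = fx / self._slope(x)
            x_new = x - step
            # fall back to bisection when Newton leaves the bracket
            outside = (x_new <= lo) | (x_new >= hi)
            x_new = np.where(outside, 0.5 * (lo + hi), x_new)
            if np.all(np.abs(x_new - x) < 1e-14):
                x = x_new
                break
            x = x_new
        return x

    def __call__(self, values) -> np.ndarray:
        return self.forward(values)


def logicle(values, T: float, W: float, M: float = 4.5, A: float = 0.0) -> np.ndarray:
    """Apply a logicle transform with the given parameters to ``values``."""
    return LogicleTransform(T=T, W=W, M=M, A=A).forward(values)


def estimate_w(values, T: float, M: float = 4.5, neg_quantile: float = 0.05) -> float:
    """Choose the linearization width from the data's negative tail.

    Uses the common rule ``W = (M − log10(T/|r|)) / 2`` where ``r`` is the
    ``neg_quantile`` quantile of the negative data values, clipped to
    ``[0, M/2]``.  Returns 0 when there are no negative values.
    """
    values = np.asarray(values, dtype=np.float64)
    neg = values[values < 0]
    if neg.size == 0:
        return 0.0
    r = np.quantile(neg, neg_quantile)
    w = (M - np.log10(T / abs(r))) / 2.0
    return float(np.clip(w, 0.0, M / 2.0))
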