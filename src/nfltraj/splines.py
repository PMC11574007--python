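"""Restricted cubic spline (RCS) basis for disease-time (EYO) trajectories.

With three knots the RCS contributes exactly two design columns — the identity
("linear EYO") term and a single nonlinear ("cubic EYO") term — and the fitted
function is linear beyond both boundary knots with continuous value, first and
second derivatives everywhere (Harrell normalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SpecError

__all__ = ["SplineSpec", "choose_knots", "rcs_basis"]


@dataclass(frozen=True)
class SplineSpec:
    """Three strictly increasing knot locations on the EYO axis (years)."""

    knots: tuple[float, float, float]

    def __post_init__(self) -> None:
        k = tuple(float(v) for v in self.knots)
        if len(k) != 3:
            raise SpecError(f"exactly 3 knots required, got {len(k)}")
        if not (k[0] < k[1] < k[2]):
            raise SpecError(f"knots must be strictly increasing, got {k}")
        object.__setattr__(self, "knots", k)


def choose_knots(eyo_values, probs=(0.10, 0.50, 0.90)) -> SplineSpec:
    """Place knots at empirical quantiles of the pooled analysis sample.

    Quantiles use linear interpolation of order statistics. Requires at least
    10 distinct values; an all-equal sample is degenerate.
    """
    x = np.asarray(eyo_values, dtype=float)
    x = x[np.isfinite(x)]
    if np.unique(x).size < 10:
        raise SpecError(
            f"need >= 10 distinct finite EYO values to place knots, got {np.unique(x).size}"
        )
    knots = np.quantile(x, probs, method="linear")
    if not (knots[0] < knots[1] < knots[2]):
        raise SpecError(f"degenerate knot placement {tuple(knots)}; EYO sample too concentrated")
    return SplineSpec(tuple(knots))


def rcs_basis(x, spec: SplineSpec):
    """Return ``(linear_term, cubic_term)`` of the 3-knot restricted cubic spline.

    cubic_term(x) = [(x-t1)^3_+ - (x-t2)^3_+ (t3-t1)/(t3-t2)
                     + (x-t3)^3_+ (t2-t1)/(t3-t2)] / (t3-t1)^2

    where z_+ = max(z, 0). The function is 0 below t1 and linear above t3.
    """
    t1, t2, t3 = spec.knots
    x = np.asarray(x, dtype=float)

    def pp3(v):  # positive part cubed
        return np.where(v > 0.0, v, 0.0) ** 3

    cubic = (
        pp3(x - t1)
        - pp3(x - t2) * (t3 - t1) / (t3 - t2)
        + pp3(x - t3) * (t2 - t1) / (t3 - t2)
    ) / (t3 - t1) ** 2
    return x, cubic
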