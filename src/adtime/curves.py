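"""The shared cognitive-decline curve and its time-shifted prediction.

The group curve is a mixture of linear, quadratic, and exponential
components,

    g(t) = lin * t + quad * t**2 + exp_amp * (exp(exp_rate * t) - 1),

which satisfies g(0) = 0 as baseline anchoring requires. A subject whose
baseline visit sits at latent position ``delta`` on the group timeline is
predicted, ``t`` years after baseline, to show the baseline-anchored value

    predict_shifted(theta, delta, t) = g(delta + t) - g(delta).

This family is exactly closed under time translation: shifting the origin by
``c`` maps (lin, quad, exp_amp, exp_rate) to
(lin + 2*c*quad, quad, exp_amp * exp(exp_rate * c), exp_rate) without
changing any shifted prediction — the identity used to pin the translation
gauge during alternating optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputDataError, ParameterError

__all__ = ["GroupCurveParams", "group_curve_eval", "predict_shifted", "translate_curve"]

# exp arguments are clipped here to keep optimizer excursions finite
_EXP_CLIP = 500.0


@dataclass(frozen=True)
class GroupCurveParams:
    """Parameters of g(t). Units: lin z/yr, quad z/yr^2, exp_amp z, exp_rate 1/yr."""

    lin: float
    quad: float
    exp_amp: float
    exp_rate: float

    def __post_init__(self):
        vals = (self.lin, self.quad, self.exp_amp, self.exp_rate)
        if not all(np.isfinite(vals)):
            raise ParameterError("curve parameters must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.lin, self.quad, self.exp_amp, self.exp_rate])

    def as_dict(self) -> dict:
        return {
            "lin": self.lin,
            "quad": self.quad,
            "exp_amp": self.exp_amp,
            "exp_rate": self.exp_rate,
        }

    @property
    def has_curvature(self) -> bool:
        """Shifts are identifiable only if the curve is not a straight line."""
        return abs(self.quad) > 1e-12 or abs(self.exp_amp) > 1e-12


def group_curve_eval(theta: GroupCurveParams, t) -> np.ndarray:
    """Evaluate g(t); g(0) = 0 by construction."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InputDataError("t must be finite")
    z = np.clip(theta.exp_rate * t, -_EXP_CLIP, _EXP_CLIP)
    return theta.lin * t + theta.quad * t * t + theta.exp_amp * (np.exp(z) - 1.0)


def predict_shifted(theta: GroupCurveParams, delta: float, t) -> np.ndarray:
    """Baseline-anchored prediction g(delta + t) - g(delta)."""
    t = np.asarray(t, dtype=float)
    return group_curve_eval(theta, delta + t) - group_curve_eval(theta, np.asarray(delta, float))


def translate_curve(theta: GroupCurveParams, c: float) -> GroupCurveParams:
    """Reparameterize g so the time origin moves by c.

    For all delta, t: predict_shifted(theta, delta, t) ==
    predict_shifted(translate_curve(theta, c), delta - c, t).
    """
    return GroupCurveParams(
        lin=theta.lin + 2.0 * c * theta.quad,
        quad=theta.quad,
        exp_amp=theta.exp_amp * float(np.exp(np.clip(theta.exp_rate * c, -_EXP_CLIP, _EXP_CLIP))),
        exp_rate=theta.exp_rate,
    )
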