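"""Temporal rate functions for kinetic modeling.

Three nested functional forms describe how a kinetic rate (RNA synthesis,
processing, degradation, or an RNAPII transition rate) evolves along a
treatment time course:

``constant``
    a single value, no temporal change;
``sigmoid``
    a smooth monotone transition ``baseline -> plateau`` centered at ``t50``;
``impulse``
    the product-of-sigmoids impulse model widely used for transcriptional
    time courses: a transition ``baseline -> peak`` at ``t_onset`` followed
    by ``peak -> plateau`` at ``t_offset``, able to describe transient
    over- or undershoots.

All forms are continuous in ``t`` and evaluate vectorized over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RateFunction", "constant", "sigmoid", "impulse"]

_FORMS = ("constant", "sigmoid", "impulse")
_NPARAMS = {"constant": 1, "sigmoid": 4, "impulse": 6}


def _logistic(x):
    # clipped to avoid overflow for extreme slope * time products
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def sigmoid_eval(t, baseline, plateau, t50, slope):
    """Sigmoid transition from ``baseline`` (t << t50) to ``plateau``."""
    return baseline + (plateau - baseline) * _logistic(slope * (np.asarray(t, float) - t50))


def impulse_eval(t, baseline, peak, plateau, t_onset, t_offset, slope):
    """Product-of-sigmoids impulse.

    Tends to ``baseline`` for t << t_onset, ``~peak`` between onset and
    offset, and ``plateau`` for t >> t_offset.  ``peak`` must be nonzero;
    parameters may broadcast (e.g. per-gene parameter arrays against a
    time vector).
    """
    t = np.asarray(t, float)
    rise = baseline + (peak - baseline) * _logistic(slope * (t - t_onset))
    fall = plateau + (peak - plateau) * _logistic(-slope * (t - t_offset))
    return rise * fall / peak


@dataclass(frozen=True)
class RateFunction:
    """A kinetic rate as a function of time (hours).

    Parameters
    ----------
    form : {'constant', 'sigmoid', 'impulse'}
    params : array-like
        ``constant``: (value,); ``sigmoid``: (baseline, plateau, t50, slope);
        ``impulse``: (baseline, peak, plateau, t_onset, t_offset, slope).
    """

    form: str
    params: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ValueError(f"unknown rate form {self.form!r}")
        p = tuple(float(x) for x in np.atleast_1d(np.asarray(self.params, float)))
        if len(p) != _NPARAMS[self.form]:
            raise ValueError(
                f"{self.form} form takes {_NPARAMS[self.form]} parameters, got {len(p)}"
            )
        object.__setattr__(self, "params", p)

    @property
    def n_params(self) -> int:
        return _NPARAMS[self.form]

    @property
    def is_variable(self) -> bool:
        return self.form != "constant"

    def __call__(self, t):
        if self.form == "constant":
            return np.full_like(np.asarray(t, float), self.params[0])
        if self.form == "sigmoid":
            return sigmoid_eval(t, *self.params)
        return impulse_eval(t, *self.params)

    def value_at(self, t: float) -> float:
        return float(self.__call__(np.asarray([t]))[0])


def constant(value: float) -> RateFunction:
    return RateFunction("constant", (value,))


def sigmoid(baseline, plateau, t50, slope) -> RateFunction:
    return RateFunction("sigmoid", (baseline, plateau, t50, slope))


def impulse(baseline, peak, plateau, t_onset, t_offset, slope) -> RateFunction:
    return RateFunction("impulse", (baseline, peak, plateau, t_onset, t_offset, slope))
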