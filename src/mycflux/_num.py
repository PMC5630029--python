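"""Shared numerics: fast solution of chained linear-decay ODEs.

Both the RNA model (pre-mRNA -> mature) and the RNAPII compartment chain
(promoter -> gene body -> TES) are cascades of equations of the form

    dy/dt = source(t) - rate(t) * y

which are solved on a fine grid with an exponential midpoint scheme:
each step uses the exact constant-coefficient propagator with midpoint
rate/source values.  The scheme is exact for constant rates (steady states
are true fixed points) and second-order accurate otherwise, and it
vectorizes over leading axes (e.g. genes).
"""

from __future__ import annotations

import numpy as np

__all__ = ["expstep_solve"]


def expstep_solve(rate, source, y0, t):
    """Integrate ``dy/dt = source - rate * y`` along the last axis of ``t``.

    Parameters
    ----------
    rate, source : arrays broadcastable to (..., len(t)); rate > 0.
    y0 : initial value(s), broadcastable to the leading shape.
    t : strictly increasing 1-D time grid.
    """
    t = np.asarray(t, float)
    dt = np.diff(t)
    rate = np.asarray(rate, float)
    source = np.asarray(source, float)
    rm = 0.5 * (rate[..., 1:] + rate[..., :-1])
    sm = 0.5 * (source[..., 1:] + source[..., :-1])
    x = rm * dt
    # per-step increment: exact propagator with midpoint coefficients
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(x > 1e-12, sm * (-np.expm1(-x)) / np.where(rm > 0, rm, 1.0), sm * dt)
    K = np.clip(np.cumsum(x, axis=-1), None, 500.0)
    pad = np.zeros(K.shape[:-1] + (1,))
    K = np.concatenate([pad, K], axis=-1)
    E = np.exp(K)
    acc = np.concatenate([pad, np.cumsum(b * E[..., 1:], axis=-1)], axis=-1)
    return (np.asarray(y0, float) + acc) / E
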