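"""Sigmoid growth/activity models shared by the simulator and the fitting code.

All three models are parameterised the same way, in the modified
("biologically interpretable") form widely used for microbial growth
curves:

* ``A``      -- signal span between baseline and plateau (amplitude),
* ``mu``     -- maximum slope, in signal units per hour,
* ``lambda_``-- lag time in hours (intercept of the tangent at the
  inflection point with the baseline),
* ``y0``     -- baseline signal,
* ``nu``     -- Richards shape parameter (Richards only); at ``nu = 1``
  the Richards curve reduces exactly to the logistic.

Each function evaluates the noiseless curve on an array of times.
"""

from __future__ import annotations

import numpy as np

__all__ = ["logistic", "gompertz", "richards", "MODELS", "MODEL_NPARAMS"]

_E = np.e


def logistic(t, A, mu, lambda_, y0):
    t = np.asarray(t, dtype=float)
    if A == 0:
        return np.full_like(t, float(y0))
    z = 4.0 * mu / A * (lambda_ - t) + 2.0
    # clip to avoid overflow in exp for extreme lag/slope combinations
    return y0 + A / (1.0 + np.exp(np.clip(z, -700, 700)))


def gompertz(t, A, mu, lambda_, y0):
    t = np.asarray(t, dtype=float)
    if A == 0:
        return np.full_like(t, float(y0))
    z = mu * _E / A * (lambda_ - t) + 1.0
    return y0 + A * np.exp(-np.exp(np.clip(z, -700, 700)))


def richards(t, A, mu, lambda_, y0, nu=1.0):
    t = np.asarray(t, dtype=float)
    if A == 0:
        return np.full_like(t, float(y0))
    if nu <= 0:
        raise ValueError(f"Richards shape parameter nu must be > 0, got {nu}")
    z = mu / A * (1.0 + nu) ** (1.0 + 1.0 / nu) * (lambda_ - t)
    inner = 1.0 + nu * np.exp(1.0 + nu) * np.exp(np.clip(z, -700, 700))
    return y0 + A * inner ** (-1.0 / nu)


MODELS = {"logistic": logistic, "gompertz": gompertz, "richards": richards}

# free parameters per model (A, mu, lambda, y0 [, nu])
MODEL_NPARAMS = {"logistic": 4, "gompertz": 4, "richards": 5}
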