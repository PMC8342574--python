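"""Variance-stabilizing transform for taxa proportions.

The phenotype entering the twin models is ``y = arcsin(sqrt(p))`` where
``p`` is a per-sample relative abundance.  For binomially sampled
proportions this transform approximately stabilizes the variance, which
is why it is the standard choice when Gaussian variance-component models
are fit to compositional abundances.  The inverse map ``p = sin(y)**2``
is used by the cohort simulator to push latent Gaussian phenotypes back
onto the proportion scale.
"""

from __future__ import annotations

import numpy as np

__all__ = ["asin_sqrt", "inv_asin_sqrt", "HALF_PI"]

HALF_PI = np.pi / 2.0

#: proportions this far outside [0, 1] are treated as floating-point
#: slop and clamped; anything further out is a caller error
CLAMP_TOL = 1e-9


def asin_sqrt(p):
    """Arcsine-square-root transform of a proportion.

    Parameters
    ----------
    p : float or array-like
        Proportion(s) in [0, 1].  Values within ``1e-9`` of the
        boundaries are clamped; values further outside raise.

    Returns
    -------
    float or ndarray
        ``arcsin(sqrt(p))`` in radians, in [0, pi/2].
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < -CLAMP_TOL) or np.any(arr > 1.0 + CLAMP_TOL):
        bad = arr[(arr < -CLAMP_TOL) | (arr > 1.0 + CLAMP_TOL)]
        raise ValueError(f"proportion outside [0, 1]: {bad.flat[0]!r}")
    out = np.arcsin(np.sqrt(np.clip(arr, 0.0, 1.0)))
    return out if out.ndim else float(out)


def inv_asin_sqrt(y):
    """Inverse transform: ``sin(y)**2``.

    Values outside [0, pi/2] (possible for simulated latent phenotypes)
    are clamped to the boundary before inversion, so the result is
    always a valid proportion.
    """
    arr = np.clip(np.asarray(y, dtype=float), 0.0, HALF_PI)
    out = np.sin(arr) ** 2
    return out if out.ndim else float(out)
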