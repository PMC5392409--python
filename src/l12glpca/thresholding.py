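"""Half-thresholding: the proximal operator of the entrywise L1/2 quasi-norm.

For the scalar objective

    f(x) = (x - sigma)^2 + lam * |x|^(1/2)

the global minimiser has the closed form (Xu et al.'s half-threshold
operator)

    h_lam(sigma) = (2/3) * sigma * (1 + cos(2*pi/3 - (2/3) * psi_lam(sigma)))

with ``psi_lam(sigma) = arccos((lam/8) * (|sigma|/3)^(-3/2))``, applied when
``|sigma|`` exceeds the threshold ``(54^(1/3)/4) * lam^(2/3)`` and zero
otherwise.  At ``|sigma|`` equal to the threshold the two candidates ``0``
and ``(2/3)*sigma`` attain exactly the same objective value; the operator
returns 0 there, so the output jumps from 0 to ``(2/3)*sigma`` just past
the threshold.

Because the L1/2 quasi-norm of a matrix is entrywise
(``||A||_{1/2}^{1/2} = sum_ij |a_ij|^{1/2}``), the matrix proximal map
decouples and is the scalar operator applied per entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidConfigurationError

__all__ = [
    "HalfThresholdParams",
    "half_threshold",
    "half_threshold_scalar",
    "half_threshold_matrix",
    "threshold_value",
]

#: Multiplier of ``lam**(2/3)`` in the cut value below which the operator is 0.
THRESHOLD_COEF = 54.0 ** (1.0 / 3.0) / 4.0


def threshold_value(lam):
    """Cut value ``(54^(1/3)/4) * lam^(2/3)``; zero iff ``lam`` is zero."""
    if lam < 0:
        raise InvalidConfigurationError("lam must be nonnegative")
    return THRESHOLD_COEF * float(lam) ** (2.0 / 3.0)


@dataclass(frozen=True)
class HalfThresholdParams:
    """Regularisation weight together with its derived cut value."""

    lam: float
    threshold: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "threshold", threshold_value(self.lam))


def half_threshold(sigma, lam):
    """Apply the half-threshold operator elementwise.

    Parameters
    ----------
    sigma : array_like
        Finite input value(s).
    lam : float
        Nonnegative regularisation weight of the ``|x|^(1/2)`` term.

    Returns
    -------
    ndarray
        Array of the same shape; each entry is the global minimiser of
        ``(x - sigma)^2 + lam * |x|^(1/2)``.
    """
    if lam < 0:
        raise InvalidConfigurationError("lam must be nonnegative")
    sigma = np.asarray(sigma, dtype=float)
    if not np.all(np.isfinite(sigma)):
        raise InvalidConfigurationError("sigma contains non-finite entries")
    if lam == 0:
        return sigma.copy()
    out = np.zeros_like(sigma)
    mask = np.abs(sigma) > threshold_value(lam)
    if np.any(mask):
        s = sigma[mask]
        psi = np.arccos((lam / 8.0) * (np.abs(s) / 3.0) ** (-1.5))
        out[mask] = (2.0 / 3.0) * s * (1.0 + np.cos(2.0 * np.pi / 3.0 - (2.0 / 3.0) * psi))
    return out


def half_threshold_scalar(sigma, lam):
    """Scalar form of :func:`half_threshold`."""
    return float(half_threshold(np.asarray([sigma], dtype=float), lam)[0])


def half_threshold_matrix(A, lam):
    """Entrywise half-thresholding of a matrix.

    Minimises ``||X - A||_F^2 + lam * ||X||_{1/2}^{1/2}`` with the entrywise
    quasi-norm; the problem separates over entries.
    """
    return half_threshold(A, lam)
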