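"""Symmetric beta-binomial probability machinery.

The symmetric beta-binomial is a binomial random variable whose success
probability is itself drawn from a Beta(alpha, alpha) distribution.  Its
mean allele fraction is exactly 0.5 and a single dispersion parameter
``alpha`` controls how far allele fractions stray from balance: small
alpha means strong allelic imbalance, large alpha approaches
Binomial(N, 0.5).  The distribution is invariant to which allele is
labelled "A", which is what lets the model accumulate evidence across
samples without phasing.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .datatypes import DataError

__all__ = ["sbb_logpmf", "sbb_pmf"]


def sbb_logpmf(a_count, total_count, alpha: float):
    """Log pmf of the symmetric beta-binomial.

    ``log[ C(N, a) * B(a + alpha, N - a + alpha) / B(alpha, alpha) ]``
    evaluated in log space via log-gamma.  Vectorized over counts.

    Parameters
    ----------
    a_count : int or array
        Reads assigned to the A allele, ``0 <= a_count <= total_count``.
    total_count : int or array
        Total allele-specifically mapped reads, ``>= 1``.
    alpha : float
        Shared shape parameter of the underlying Beta (``alpha = beta``).
    """
    if not np.all(np.asarray(alpha) > 0):
        raise DataError(f"alpha must be > 0, got {alpha}")
    a = np.asarray(a_count, dtype=np.float64)
    n = np.asarray(total_count, dtype=np.float64)
    if np.any(n < 1):
        raise DataError("total_count must be >= 1")
    if np.any((a < 0) | (a > n)):
        raise DataError("a_count must lie in [0, total_count]")
    # terms are grouped so each parenthesis is symmetric in a <-> N - a,
    # making the label symmetry exact in floating point, not just analytic
    out = (
        gammaln(n + 1.0)
        - (gammaln(a + 1.0) + gammaln(n - a + 1.0))
        + (gammaln(a + alpha) + gammaln(n - a + alpha))
        - gammaln(n + 2.0 * alpha)
        - (2.0 * gammaln(alpha) - gammaln(2.0 * alpha))
    )
    if np.isscalar(a_count) and np.isscalar(total_count):
        return float(out)
    return out


def sbb_pmf(a_count, total_count, alpha: float):
    """Pmf of the symmetric beta-binomial (convenience wrapper)."""
    return np.exp(sbb_logpmf(a_count, total_count, alpha))
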