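"""Underflow-safe two-sided p-values.

GWAS consortia publish association p-values far below the smallest positive
double (~5e-324): the strongest lipid association handled here is printed as
8e-373.  All p-value handling in this package therefore works on log10(p).
Parsing keeps the decimal-string exponent intact, comparisons are done in log
space, and the p -> z conversion uses the log-space normal quantile
(:func:`scipy.special.ndtri_exp`) so it stays accurate down to arbitrarily
small p.
"""

from __future__ import annotations

import math
import re

import numpy as np
from scipy import special

__all__ = ["log10_from_string", "log10_from_p", "p_from_log10", "z_from_log10p", "log10p_from_z"]

_SCI_RE = re.compile(
    r"""^\s*(?P<mantissa>[0-9]*\.?[0-9]+)\s*(?:[eE]\s*(?P<exp>[+-]?[0-9]+))?\s*$"""
)

_LN10 = math.log(10.0)


def log10_from_string(text: str) -> float:
    """Parse a decimal p-value string to log10(p) without underflow.

    ``"8e-373"`` parses to ``log10(8) - 373`` even though ``float("8e-373")``
    is 0.0.  Raises ``ValueError`` for malformed strings or p outside (0, 1].
    """
    m = _SCI_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse p-value {text!r}")
    mantissa = float(m.group("mantissa"))
    exponent = int(m.group("exp") or 0)
    if mantissa <= 0.0:
        raise ValueError(f"p-value must be positive, got {text!r}")
    log10p = math.log10(mantissa) + exponent
    if log10p > 0.0:
        raise ValueError(f"p-value must be <= 1, got {text!r}")
    return log10p


def log10_from_p(p: float) -> float:
    """log10 of an ordinary float p-value in (0, 1]."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    return math.log10(p)


def p_from_log10(log10p: float) -> float:
    """Back to a float; underflows to 0.0 below ~1e-308 (display only)."""
    return 10.0 ** log10p


def z_from_log10p(log10p, direction=1.0):
    """Signed z-score from a two-sided log10 p-value.

    |z| is the upper-tail standard-normal quantile at p/2, evaluated in log
    space; the sign is taken from ``direction``.
    """
    log10p = np.asarray(log10p, dtype=float)
    if np.any(log10p > 0.0):
        raise ValueError("log10 p-value above 0 (p > 1)")
    # ln(p/2) = ln(10)*log10(p) - ln(2); ndtri_exp inverts log-CDF
    ln_half_p = log10p * _LN10 - math.log(2.0)
    z = -special.ndtri_exp(ln_half_p)
    out = np.sign(direction) * z
    if out.ndim == 0:
        return float(out)
    return out


def log10p_from_z(z):
    """Two-sided log10 p-value from a z-score, accurate for large |z|."""
    z = np.asarray(z, dtype=float)
    # log p = log 2 + log Phi(-|z|)
    logp = math.log(2.0) + special.log_ndtr(-np.abs(z))
    out = logp / _LN10
    if out.ndim == 0:
        return float(out)
    return out
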