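"""Small reporting helpers shared by the CLI and result tables."""

from __future__ import annotations

import math

from .attribution import proportion_se

__all__ = ["percent", "percent_str", "proportion_summary"]


def percent(k: int, n: int, sig: int = 3) -> float:
    """Fraction k/n as a percentage rounded to ``sig`` significant figures.

    The convention used in summary tables: 31/2132 -> 1.45, 151/395 -> 38.2.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    value = 100.0 * k / n
    if value == 0:
        return 0.0
    return round(value, sig - 1 - math.floor(math.log10(abs(value))))


def percent_str(k: int, n: int, sig: int = 3) -> str:
    v = percent(k, n, sig)
    return f"{v:g}%"


def proportion_summary(k: int, n: int) -> dict[str, float]:
    """Proportion with its standard error and 95% CI, on the percent scale."""
    p = k / n
    se, (lo, hi) = proportion_se(p, n)
    return {
        "percent": percent(k, n),
        "se_percent": 100.0 * se,
        "ci_low_percent": 100.0 * lo,
        "ci_high_percent": 100.0 * hi,
    }
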