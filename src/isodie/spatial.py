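"""Cross-platform concordance of exon inclusion: single-cell vs spatial
long-read data.

Exons carrying alternative donors/acceptors are only comparable when the
vast majority of overlapping reads map to the exact exon; surviving exons'
DeltaPsi values are compared by sign and by Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

__all__ = ["ConcordanceReport", "eligible_exons", "concordance"]


@dataclass
class ConcordanceReport:
    exons: pd.DataFrame  # exon_id, dpsi_sc, dpsi_spatial, same_sign
    n: int
    n_same_sign: int
    fraction_same_sign: float
    pearson_r: float
    r_squared: float
    point_binomial_p: float


def eligible_exons(
    flags: dict[str, bool],
    exact_reads: dict[str, int],
    overlapping_reads: dict[str, int],
    min_fraction: float = 0.9,
) -> list[str]:
    """Exons comparable across platforms.

    ``flags`` marks exons overlapping alternative donor/acceptor variants;
    those pass only when strictly more than ``min_fraction`` of reads
    overlapping the exon map to that exact exon. Unflagged exons always pass.
    """
    out = []
    for eid in sorted(flags):
        if not flags[eid]:
            out.append(eid)
            continue
        total = overlapping_reads.get(eid, 0)
        if total > 0 and exact_reads.get(eid, 0) / total > min_fraction:
            out.append(eid)
    return out


def concordance(
    dpsi_sc: pd.Series, dpsi_spatial: pd.Series, min_abs_dpsi: float = 0.0
) -> ConcordanceReport:
    """Directional agreement of DeltaPsi between two datasets.

    Exons present in both inputs are compared; a pair agrees when the two
    DeltaPsi values have the same strict sign (zero counts as discordant).
    Reports the exact binomial point probability C(n, k) * 0.5^n of the
    same-sign count and the Pearson correlation of the paired values.
    """
    shared = dpsi_sc.index.intersection(dpsi_spatial.index)
    a = dpsi_sc.loc[shared].astype(float)
    b = dpsi_spatial.loc[shared].astype(float)
    keep = (a.abs() >= min_abs_dpsi) | (b.abs() >= min_abs_dpsi)
    keep &= (a != 0) | (b != 0)
    a, b = a[keep], b[keep]
    n = len(a)
    if n == 0:
        raise ValueError("no comparable exons")
    same = np.sign(a.to_numpy()) * np.sign(b.to_numpy()) > 0
    k = int(same.sum())
    if n >= 2 and a.std() > 0 and b.std() > 0:
        r = float(np.corrcoef(a, b)[0, 1])
    else:
        r = float("nan")  # undefined for < 2 points or a constant vector
    df = pd.DataFrame(
        {"dpsi_sc": a, "dpsi_spatial": b, "same_sign": same}
    ).rename_axis("exon_id")
    return ConcordanceReport(
        exons=df,
        n=n,
        n_same_sign=k,
        fraction_same_sign=k / n,
        pearson_r=r,
        r_squared=r * r,
        point_binomial_p=comb(n, k) * 0.5**n,
    )
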