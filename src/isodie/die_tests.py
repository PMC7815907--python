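"""Differential isoform / TSS / polyA / exon usage tests.

The gene-level test compares isoform count distributions between two cell
groups with a Pearson chi-square on an (up to) 11 x 2 table — the ten most
abundant isoforms plus a collapsed remainder. The effect size DeltaPi is the
change in percent isoform summed over at most two isoforms moving in the
same direction. Gene-level families use Benjamini-Hochberg; exon-level 2 x 2
tests are dependent and use Benjamini-Yekutieli. A feature is significant
when adjusted p <= fdr and |DeltaPi| (or |DeltaPsi|) >= 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .isoform_catalog import UsageTable, collapse_top_k

__all__ = [
    "DieResult",
    "chi2_nx2",
    "delta_pi",
    "adjust_bh",
    "adjust_by",
    "test_feature_usage",
    "test_exons",
    "MIN_DEPTH",
    "FDR_THRESHOLD",
    "DPI_THRESHOLD",
]

MIN_DEPTH = 25  # reads per gene per category required for testability
FDR_THRESHOLD = 0.05
DPI_THRESHOLD = 0.1
COLLAPSE_K = 10  # isoforms kept before the remainder row


@dataclass
class DieResult:
    feature_id: str  # gene id (isoform/TSS/polyA kinds) or exon id
    feature_kind: str  # isoform | TSS | polyA | exon
    testable: bool
    reason: str | None = None  # why untestable
    raw_p: float = np.nan
    adjusted_p: float = np.nan
    correction_factor: float = np.nan  # adjusted/raw before clamping at 1
    effect: float = np.nan  # signed DeltaPi or DeltaPsi
    contributors: list[tuple[str, float]] = field(default_factory=list)
    significant: bool = False


def chi2_nx2(counts: np.ndarray) -> float:
    """Raw p of a Pearson chi-square on an n x 2 count table.

    All-zero rows are dropped; no continuity correction; df = n - 1.
    Raises ValueError when a column sums to zero or fewer than two non-empty
    rows remain (untestable table).
    """
    m = np.asarray(counts, dtype=float)
    if m.ndim != 2 or m.shape[1] != 2:
        raise ValueError("expected an n x 2 table")
    m = m[m.sum(axis=1) > 0]
    if m.shape[0] < 2:
        raise ValueError("fewer than two non-empty rows")
    if (m.sum(axis=0) == 0).any():
        raise ValueError("a column sums to zero")
    _, p, _, _ = stats.chi2_contingency(m, correction=False)
    return float(p)


def delta_pi(
    pi_a: pd.Series, pi_b: pd.Series
) -> tuple[float, list[tuple[str, float]]]:
    """Top-two same-direction change in percent isoform between two groups.

    Per-isoform delta = Pi_A - Pi_B. The positive candidate sums the two
    largest positive deltas (or the single one); the negative candidate the
    two most negative. Returns the larger magnitude with its sign, plus the
    contributing isoforms.
    """
    idx = pi_a.index.union(pi_b.index)
    d = pi_a.reindex(idx, fill_value=0.0) - pi_b.reindex(idx, fill_value=0.0)
    d = d.sort_values(kind="mergesort")
    neg = [(i, v) for i, v in d.items() if v < 0][:2]
    pos = [(i, v) for i, v in d.iloc[::-1].items() if v > 0][:2]
    up = sum(v for _, v in pos)
    down = -sum(v for _, v in neg)
    if up == down == 0:
        return 0.0, []
    if up >= down:
        return float(up), pos
    return float(-down), neg


def _step_up(p: np.ndarray, scale: float) -> np.ndarray:
    """Generic FDR step-up: adjusted_(i) = min_{j>=i} p_(j) * scale * m / j,
    returned unclamped in the original order."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * scale * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = adj
    return out


def adjust_bh(pvals) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg; returns (adjusted clamped at 1, correction factors).

    The correction factor is adjusted/raw *before* clamping, matching how
    per-gene correction factors are reported.
    """
    p = np.asarray(pvals, dtype=float)
    pre = _step_up(p, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(p > 0, pre / p, np.inf)
    return np.minimum(pre, 1.0), factor


def adjust_by(pvals) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Yekutieli: BH scaled by c(m) = sum_{i<=m} 1/i (dependent tests)."""
    p = np.asarray(pvals, dtype=float)
    c_m = float(np.sum(1.0 / np.arange(1, len(p) + 1)))
    pre = _step_up(p, c_m)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(p > 0, pre / p, np.inf)
    return np.minimum(pre, 1.0), factor


def _feature_counts(table: UsageTable, kind: str, groups: tuple[str, str]) -> UsageTable:
    """Aggregate the isoform table to TSS or polyA features when asked."""
    if kind == "isoform":
        return table
    part = {"TSS": 1, "polyA": 3}[kind]

    def label(ck: str) -> str:
        if ck in table.keys:
            return (table.keys[ck].tss_peak_id, table.keys[ck].polya_peak_id)[part == 3]
        parts = ck.split("|")
        return parts[part] if len(parts) == 4 else ck

    agg = table.counts.groupby([label(ck) for ck in table.counts.index]).sum()
    agg = agg.loc[sorted(agg.index)]
    return UsageTable(table.gene_id, agg)


def test_feature_usage(
    tables: dict[str, UsageTable],
    groups: tuple[str, str],
    kind: str = "isoform",
    min_depth: int = MIN_DEPTH,
    k: int = COLLAPSE_K,
    fdr: float = FDR_THRESHOLD,
    dpi_threshold: float = DPI_THRESHOLD,
) -> list[DieResult]:
    """Per-gene differential usage of isoforms, TSSs or polyA sites.

    Genes need >= ``min_depth`` reads in each group; the chi-square runs on
    the collapsed table while DeltaPi is computed on the full per-feature Pi
    vectors. BH adjustment spans all testable genes of this comparison.
    """
    if kind not in ("isoform", "TSS", "polyA"):
        raise ValueError(f"unknown feature kind {kind!r}")
    a, b = groups
    results: list[DieResult] = []
    testable: list[DieResult] = []
    for gid in sorted(tables):
        table = tables[gid]
        res = DieResult(gid, kind, testable=False)
        results.append(res)
        missing = [g for g in groups if g not in table.counts.columns]
        if missing or table.group_total(a) < min_depth or table.group_total(b) < min_depth:
            res.reason = "depth"
            continue
        feat = _feature_counts(table, kind, groups)
        mat, _ = collapse_top_k(feat, groups, k)
        mat = mat[mat.sum(axis=1) > 0]
        if mat.shape[0] < 2:
            res.reason = "single_feature"
            continue
        res.raw_p = chi2_nx2(mat)
        res.effect, res.contributors = delta_pi(feat.pi(a), feat.pi(b))
        res.testable = True
        testable.append(res)

    if testable:
        adj, factor = adjust_bh([r.raw_p for r in testable])
        for r, ap, f in zip(testable, adj, factor):
            r.adjusted_p = float(ap)
            r.correction_factor = float(f)
            r.significant = ap <= fdr and abs(r.effect) >= dpi_threshold
    return results


def exon_test_eligible(table: np.ndarray) -> bool:
    """Expected-count screen: min(rowSums) * min(colSums) / total >= 5."""
    m = np.asarray(table, dtype=float)
    total = m.sum()
    if total == 0:
        return False
    return m.sum(axis=1).min() * m.sum(axis=0).min() / total >= 5


def test_exons(
    counts: pd.DataFrame,
    groups: tuple[str, str],
    fdr: float = FDR_THRESHOLD,
    dpsi_threshold: float = DPI_THRESHOLD,
    psi_bounds: tuple[float, float] = (0.1, 0.9),
) -> list[DieResult]:
    """Per-exon 2 x 2 inclusion/exclusion tests between two groups.

    ``counts`` is the long table from :func:`isodie.exon_quant.exon_counts`.
    An exon is skipped as constitutive unless its pooled Psi (both groups
    combined) lies in ``psi_bounds``, and must pass the expected-count screen.
    Adjustment is Benjamini-Yekutieli across all tested exons.
    """
    a, b = groups
    wide = counts.pivot_table(
        index="exon_id",
        columns="group",
        values=["inclusion", "exclusion"],
        aggfunc="sum",
        fill_value=0,
    )
    results: list[DieResult] = []
    tested: list[DieResult] = []
    for eid in sorted(wide.index):
        res = DieResult(eid, "exon", testable=False)
        results.append(res)
        try:
            inc = np.array([wide.at[eid, ("inclusion", a)], wide.at[eid, ("inclusion", b)]])
            exc = np.array([wide.at[eid, ("exclusion", a)], wide.at[eid, ("exclusion", b)]])
        except KeyError:
            res.reason = "depth"
            continue
        pooled = inc.sum() + exc.sum()
        if pooled == 0:
            res.reason = "depth"
            continue
        pooled_psi = inc.sum() / pooled
        if not (psi_bounds[0] <= pooled_psi <= psi_bounds[1]):
            res.reason = "constitutive"
            continue
        table = np.array([inc, exc])  # rows: inclusion/exclusion, cols: groups
        if not exon_test_eligible(table):
            res.reason = "expected_counts"
            continue
        if (table.sum(axis=0) == 0).any():
            res.reason = "depth"
            continue
        res.raw_p = chi2_nx2(table)  # 2x2: rows incl/excl, cols groups
        psi_a = inc[0] / (inc[0] + exc[0]) if inc[0] + exc[0] > 0 else np.nan
        psi_b = inc[1] / (inc[1] + exc[1]) if inc[1] + exc[1] > 0 else np.nan
        res.effect = float(psi_a - psi_b)
        res.testable = True
        tested.append(res)

    if tested:
        adj, factor = adjust_by([r.raw_p for r in tested])
        for r, ap, f in zip(tested, adj, factor):
            r.adjusted_p = float(ap)
            r.correction_factor = float(f)
            r.significant = ap <= fdr and abs(r.effect) >= dpsi_threshold
    return results


def results_frame(results: list[DieResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        c = r.contributors
        rows.append(
            {
                "feature_id": r.feature_id,
                "kind": r.feature_kind,
                "testable": r.testable,
                "reason": r.reason,
                "raw_p": r.raw_p,
                "adjusted_p": r.adjusted_p,
                "correction_factor": r.correction_factor,
                "effect": r.effect,
                "iso1": c[0][0] if len(c) > 0 else "",
                "iso2": c[1][0] if len(c) > 1 else "",
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
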