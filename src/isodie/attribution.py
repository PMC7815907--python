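"""Tracing bulk-level differential isoform expression through a cell-type
hierarchy: DeltaPi ratios, the Single-/Both-/No-Cell-Type model classes,
concurrence enrichment, traceability, and TSS directionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, sqrt

from scipy import stats

__all__ = [
    "AttributionRecord",
    "classify_model",
    "directed_delta_pi",
    "traceability",
    "concurrence_test",
    "tss_directionality",
    "proportion_se",
    "SINGLE",
    "BOTH",
    "NONE",
    "LOW_DEPTH",
]

def directed_delta_pi(pi_a, pi_b, contributors: list[str]) -> float:
    """Child-group DeltaPi projected onto the parent's contributing isoforms.

    For a symmetric top-two swap the sign of an independently estimated
    DeltaPi is arbitrary (the positive and negative directions tie), so
    parent and child scalars cannot be compared directly. Summing the
    child's per-isoform Pi changes over the isoforms that carried the
    *parent's* effect fixes a common direction: the ratio
    DeltaPi_child / DeltaPi_parent and the sign-matching model rules then
    compare like with like. ``pi_a``/``pi_b`` are the child's Pi vectors
    (pandas Series); absent isoforms count as Pi = 0.
    """
    total = 0.0
    for iso in contributors:
        total += float(pi_a.get(iso, 0.0)) - float(pi_b.get(iso, 0.0))
    return total


SINGLE = "Single-Cell-Type"
BOTH = "Both-Cell-Types"
NONE = "No-Cell-Type"
LOW_DEPTH = "insufficient-depth"


@dataclass
class AttributionRecord:
    gene_id: str
    parent: str
    parent_dpi: float
    child_dpi: dict[str, float | None]  # None = untestable child
    ratios: dict[str, float | None] = field(default_factory=dict)
    model: str | None = None
    responsible: list[str] = field(default_factory=list)


def classify_model(
    gene_id: str,
    parent: str,
    parent_dpi: float,
    children: dict[str, float | None],
    dpi_threshold: float = 0.1,
) -> AttributionRecord:
    """Classify which of two child cell groups carries a parent-level signal.

    A child "participates" when it is testable, |DeltaPi_child| >= threshold
    and its sign matches the parent's. Both participating -> Both-Cell-Types;
    exactly one -> Single-Cell-Type; neither, with both testable ->
    No-Cell-Type (abundance/expression shifts only); otherwise insufficient
    depth. Ratios DeltaPi_child / DeltaPi_parent are emitted on magnitudes
    with matched sign, undefined when the parent effect is 0.
    """
    if len(children) != 2:
        raise ValueError("expected exactly two children per hierarchy split")
    rec = AttributionRecord(gene_id, parent, parent_dpi, dict(children))
    sign = 1.0 if parent_dpi >= 0 else -1.0
    for child, dpi in children.items():
        if dpi is None or parent_dpi == 0:
            rec.ratios[child] = None
        else:
            rec.ratios[child] = (dpi * sign) / abs(parent_dpi)
    if abs(parent_dpi) < dpi_threshold:
        return rec  # model defined only for parent-level events

    participating = [
        c
        for c, dpi in children.items()
        if dpi is not None and abs(dpi) >= dpi_threshold and dpi * sign > 0
    ]
    untestable = [c for c, dpi in children.items() if dpi is None]
    if len(participating) == 2:
        rec.model = BOTH
    elif len(participating) == 1:
        rec.model = SINGLE
    elif untestable:
        rec.model = LOW_DEPTH
    else:
        rec.model = NONE
    rec.responsible = sorted(participating)
    return rec


def traceability(
    bulk_dpi: float,
    leaf_dpi: dict[str, float | None],
    ratio_threshold: float = 0.9,
) -> str:
    """Was a bulk-level event carried (ratio >= threshold, same sign) by some leaf?

    Returns 'traced', 'untraced', or 'low-depth' (all leaves untestable).
    """
    testable = {k: v for k, v in leaf_dpi.items() if v is not None}
    if not testable:
        return "low-depth"
    if bulk_dpi == 0:
        return "untraced"
    sign = 1.0 if bulk_dpi > 0 else -1.0
    for v in testable.values():
        if v * sign / abs(bulk_dpi) >= ratio_threshold:
            return "traced"
    return "untraced"


def concurrence_test(
    dpi_child1: dict[str, float],
    dpi_child2: dict[str, float],
    dpi_threshold: float = 0.1,
) -> tuple[float, float, float, list[list[int]]]:
    """Do two sibling cell groups shift isoforms in the same genes more often
    than independence predicts?

    Over genes testable in both children, builds the 2 x 2 table of
    (|DeltaPi_child1| >= threshold) x (|DeltaPi_child2| >= threshold).
    Returns (observed %, expected % under independence = product of the
    marginals, two-sided Fisher exact p, the table).
    """
    genes = sorted(set(dpi_child1) & set(dpi_child2))
    if not genes:
        raise ValueError("no genes testable in both children")
    n = len(genes)
    hit1 = [abs(dpi_child1[g]) >= dpi_threshold for g in genes]
    hit2 = [abs(dpi_child2[g]) >= dpi_threshold for g in genes]
    both = sum(a and b for a, b in zip(hit1, hit2))
    only1 = sum(a and not b for a, b in zip(hit1, hit2))
    only2 = sum(b and not a for a, b in zip(hit1, hit2))
    neither = n - both - only1 - only2
    table = [[both, only1], [only2, neither]]
    observed = 100.0 * both / n
    expected = 100.0 * (sum(hit1) / n) * (sum(hit2) / n)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return observed, expected, float(p), table


def tss_directionality(
    genes: dict[str, tuple[str, int, int]],
) -> tuple[int, int, float, float]:
    """Does a focal cell group favour upstream TSSs for its specific isoforms?

    ``genes`` maps gene_id -> (strand, focal-group dominant TSS coordinate,
    other-groups dominant TSS coordinate). Upstream is strand-aware (smaller
    genomic coordinate on '+', larger on '-'); genes whose two TSSs coincide
    are excluded. Returns (n_upstream, n, binomial point probability
    C(n,k) * 0.5^n, one-sided upper-tail probability).
    """
    k = n = 0
    for strand, focal, other in genes.values():
        if focal == other:
            continue
        n += 1
        upstream = focal < other if strand == "+" else focal > other
        k += upstream
    if n == 0:
        raise ValueError("no genes with distinct TSSs")
    point = comb(n, k) * 0.5**n
    tail = sum(comb(n, j) for j in range(k, n + 1)) * 0.5**n
    return k, n, float(point), float(tail)


def proportion_se(p_hat: float, n: int) -> tuple[float, tuple[float, float]]:
    """Standard error and 95% CI of a proportion, clamped to [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p_hat <= 1:
        raise ValueError("p_hat must lie in [0, 1]")
    se = sqrt(p_hat * (1 - p_hat) / n)
    return se, (max(0.0, p_hat - 1.96 * se), min(1.0, p_hat + 1.96 * se))
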