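"""Per-read exon inclusion/exclusion calls and percent-spliced-in (Psi) tables.

An internal exon is "included" in a read when the read's splice junctions
match both exon boundaries within a platform tolerance (+-2 bp PacBio,
+-3 bp ONT, reflecting residual alignment error); it is "excluded" when the
read's alignment spans the exon without those junctions. Terminal exons use
coverage: included only when completely covered, discarded when partially
covered. Psi = inclusion / (inclusion + exclusion) per cell group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .annotation_io import GeneSet
from .read_processing import PLATFORM_TOLERANCE, Csmm

__all__ = [
    "ExonRecord",
    "build_exon_registry",
    "call_exon",
    "exon_counts",
    "psi_table",
    "delta_psi",
    "INCLUDED",
    "EXCLUDED",
    "DISCARDED",
]

INCLUDED = "included"
EXCLUDED = "excluded"
DISCARDED = "discarded"


@dataclass(frozen=True)
class ExonRecord:
    exon_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    terminal: bool  # terminal in every transcript containing it
    overlapping: bool  # overlaps another distinct exon of the same gene


def build_exon_registry(genes: GeneSet) -> dict[str, list[ExonRecord]]:
    """Distinct annotated exons per gene, with terminal/overlap flags.

    An exon is flagged terminal when it is the first or last exon of every
    transcript it appears in; exons that are internal in at least one
    transcript are judged by the junction rule. The overlap flag marks exons
    sharing genomic space with a different exon of the same gene (alternative
    donors/acceptors); it excludes the exon from spatial eligibility but not
    from counting.
    """
    registry: dict[str, list[ExonRecord]] = {}
    for gid in sorted(genes.genes):
        internal_somewhere: set[tuple[int, int]] = set()
        all_exons: set[tuple[int, int]] = set()
        for tx in genes.transcripts_of(gid):
            all_exons.update(tx.exons)
            internal_somewhere.update(tx.exons[1:-1])
        exons = sorted(all_exons)
        g = genes.genes[gid]
        records = []
        for i, (s, e) in enumerate(exons):
            overlapping = any(
                (s2, e2) != (s, e) and s2 < e and s < e2 for s2, e2 in exons
            )
            records.append(
                ExonRecord(
                    exon_id=f"{gid}:{s}-{e}",
                    gene_id=gid,
                    chrom=g.chrom,
                    strand=g.strand,
                    start=s,
                    end=e,
                    terminal=(s, e) not in internal_somewhere,
                    overlapping=overlapping,
                )
            )
        registry[gid] = records
    return registry


def call_exon(read_like, exon: ExonRecord, tolerance: int | None = None) -> str:
    """Classify one (read, exon) pair as included / excluded / discarded.

    ``read_like`` is an AlignedLongRead or a Csmm. Internal exons: included
    iff an intron acceptor falls within +-tolerance of the exon start AND an
    intron donor within +-tolerance of the exon end; else excluded when the
    alignment span covers the exon (spanned without matching junctions);
    else discarded (read ends inside or misses the exon). Terminal exons:
    included iff fully covered by one exonic segment of the read; excluded if
    an intron of the read contains them; otherwise discarded.
    """
    read = getattr(read_like, "read", read_like)
    if tolerance is None:
        tolerance = PLATFORM_TOLERANCE.get(read.platform, 2)
    s, e = exon.start, exon.end

    if not exon.terminal:
        acc_match = any(abs(a - s) <= tolerance for _, a in read.introns)
        don_match = any(abs(d - e) <= tolerance for d, _ in read.introns)
        if acc_match and don_match:
            return INCLUDED
        if read.start <= s and e <= read.end:
            return EXCLUDED
        return DISCARDED

    for bs, be in read.exonic_blocks():
        if bs <= s and e <= be:
            return INCLUDED
    if any(d <= s and e <= a for d, a in read.introns):
        return EXCLUDED
    return DISCARDED


def exon_counts(
    csmms: Iterable[Csmm],
    registry: dict[str, list[ExonRecord]],
    grouping: Callable[[Csmm], str | None],
    tolerance: int | None = None,
) -> pd.DataFrame:
    """Aggregate inclusion/exclusion counts per exon per group (long format)."""
    acc: dict[tuple[str, str], list[int]] = {}
    meta: dict[str, ExonRecord] = {}
    for c in csmms:
        g = grouping(c)
        if g is None or c.gene_id not in registry:
            continue
        for exon in registry[c.gene_id]:
            status = call_exon(c, exon, tolerance)
            if status == DISCARDED:
                continue
            key = (exon.exon_id, g)
            if key not in acc:
                acc[key] = [0, 0]
            acc[key][0 if status == INCLUDED else 1] += 1
            meta[exon.exon_id] = exon
    rows = [
        {
            "exon_id": eid,
            "gene_id": meta[eid].gene_id,
            "group": grp,
            "inclusion": inc,
            "exclusion": exc,
            "terminal": meta[eid].terminal,
            "overlapping": meta[eid].overlapping,
        }
        for (eid, grp), (inc, exc) in sorted(acc.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "exon_id",
            "gene_id",
            "group",
            "inclusion",
            "exclusion",
            "terminal",
            "overlapping",
        ],
    )


def psi_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Add Psi = inclusion/(inclusion+exclusion); NaN when no informative reads."""
    out = counts.copy()
    denom = out["inclusion"] + out["exclusion"]
    out["psi"] = np.where(denom > 0, out["inclusion"] / denom.where(denom > 0, 1), np.nan)
    return out


def delta_psi(psi: pd.DataFrame, group_a: str, group_b: str) -> pd.DataFrame:
    """Per-exon Psi difference (group_a - group_b) for exons defined in both."""
    a = psi[psi["group"] == group_a].set_index("exon_id")
    b = psi[psi["group"] == group_b].set_index("exon_id")
    shared = a.index.intersection(b.index)
    out = pd.DataFrame(
        {
            "gene_id": a.loc[shared, "gene_id"],
            "psi_a": a.loc[shared, "psi"],
            "psi_b": b.loc[shared, "psi"],
        }
    )
    out["delta_psi"] = out["psi_a"] - out["psi_b"]
    return out.dropna(subset=["delta_psi"])
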