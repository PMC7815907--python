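"""Isoform identities, per-group usage tables, annotated-transcript assignment,
and novel-isoform discovery under the enhanced-annotation filters.

An isoform is identified by its TSS peak, exact intron chain and polyA peak
(peak ids rather than raw end coordinates, so end wobble within the
completeness window does not fragment isoforms).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GeneSet, TranscriptModel, write_gtf
from .read_processing import Csmm

__all__ = [
    "IsoformKey",
    "UsageTable",
    "NovelIsoform",
    "REJECT_ANNOTATED_TRUNCATION",
    "REJECT_EXON_SUPPORT",
    "REJECT_INTRON_SUPPORT",
    "REJECT_NOVEL_TRUNCATION",
    "build_usage_tables",
    "group_by_sample",
    "collapse_top_k",
    "assign_to_annotated",
    "is_subchain",
    "load_junction_support",
    "discover_novel",
    "write_enhanced_annotation",
]

# rejection codes, in the order the rules are applied
REJECT_ANNOTATED_TRUNCATION = "annotated_or_truncation"
REJECT_EXON_SUPPORT = "internal_exon_support"
REJECT_INTRON_SUPPORT = "intron_support"
REJECT_NOVEL_TRUNCATION = "truncation_of_novel"


@dataclass(frozen=True)
class IsoformKey:
    gene_id: str
    tss_peak_id: str
    intron_chain: tuple[tuple[int, int], ...]
    polya_peak_id: str

    def canonical(self) -> str:
        chain = ";".join(f"{d}-{a}" for d, a in self.intron_chain) or "."
        return f"{self.gene_id}|{self.tss_peak_id}|{chain}|{self.polya_peak_id}"

    @staticmethod
    def of(c: Csmm) -> "IsoformKey":
        return IsoformKey(c.gene_id, c.tss_peak_id, c.read.introns, c.polya_peak_id)


@dataclass
class UsageTable:
    """Per-gene isoform x cell-group count table.

    ``counts`` rows are canonical isoform strings, columns are group labels.
    Ranks order isoforms by summed abundance across all groups (1 = most
    abundant), ties broken by canonical string order.
    """

    gene_id: str
    counts: pd.DataFrame
    keys: dict[str, IsoformKey] = field(default_factory=dict)

    @property
    def groups(self) -> list[str]:
        return list(self.counts.columns)

    def group_total(self, group: str) -> int:
        return int(self.counts[group].sum())

    def pi(self, group: str) -> pd.Series | None:
        """Fraction of the gene's reads per isoform; None for an empty group."""
        total = self.group_total(group)
        if total == 0:
            return None
        return self.counts[group] / total

    def ranks(self) -> pd.Series:
        order = self.counts.sum(axis=1).sort_values(
            ascending=False, kind="mergesort"
        )  # mergesort keeps the (sorted) index order within ties
        order = order.loc[sorted(order.index)].sort_values(ascending=False, kind="mergesort")
        return pd.Series(np.arange(1, len(order) + 1), index=order.index)

    @staticmethod
    def from_counts(gene_id: str, counts: dict[str, dict[str, int]]) -> "UsageTable":
        """Build directly from {isoform_label: {group: count}} (used in simulations)."""
        df = pd.DataFrame(counts).T.fillna(0).astype(int)
        df = df.loc[sorted(df.index)]
        return UsageTable(gene_id, df)


def group_by_sample(node: str, cellmap) -> Callable[[Csmm], str | None]:
    """Grouping: the read's sample label, restricted to cell types under ``node``.

    This realises region-vs-region comparisons at any hierarchy node, e.g.
    HIPP neurons vs PFC neurons. Reads whose cell type is not under the node
    (or is unmapped, unless node is the root) are left out.
    """
    leaves = set(cellmap.leaves_under(node))
    at_root = node == cellmap.root

    def group(c: Csmm) -> str | None:
        if c.cell_type is None:
            return c.read.sample if at_root else None
        return c.read.sample if c.cell_type in leaves else None

    return group


def build_usage_tables(
    csmms: Iterable[Csmm], grouping: Callable[[Csmm], str | None]
) -> dict[str, UsageTable]:
    """Count isoform keys per gene per cell group.

    ``grouping`` maps a CSMM to a group label (or None to skip the read).
    """
    acc: dict[str, Counter] = defaultdict(Counter)
    keys: dict[str, dict[str, IsoformKey]] = defaultdict(dict)
    groups: set[str] = set()
    for c in csmms:
        g = grouping(c)
        if g is None:
            continue
        groups.add(g)
        key = IsoformKey.of(c)
        ck = key.canonical()
        acc[c.gene_id][(ck, g)] += 1
        keys[c.gene_id][ck] = key

    tables: dict[str, UsageTable] = {}
    for gid in sorted(acc):
        idx = sorted({ck for ck, _ in acc[gid]})
        df = pd.DataFrame(0, index=idx, columns=sorted(groups), dtype=int)
        for (ck, g), n in acc[gid].items():
            df.at[ck, g] = n
        tables[gid] = UsageTable(gid, df, keys[gid])
    return tables


def collapse_top_k(
    table: UsageTable, groups: tuple[str, str], k: int = 10
) -> tuple[np.ndarray, list[str]]:
    """Collapse a two-group count table to at most (k+1) x 2.

    Rows 1..min(k, n) are the k most abundant isoforms by summed count over
    both groups; the extra row sums the remainder and is omitted when n <= k.
    Column sums are preserved.
    """
    a, b = groups
    sub = table.counts[[a, b]]
    order = sub.sum(axis=1).sort_values(ascending=False, kind="mergesort")
    order = order.loc[sorted(order.index)].sort_values(ascending=False, kind="mergesort")
    top = list(order.index[:k])
    mat = sub.loc[top].to_numpy()
    labels = top
    if len(order) > k:
        rest = sub.loc[order.index[k:]].sum(axis=0).to_numpy()
        mat = np.vstack([mat, rest])
        labels = top + ["<other>"]
    return mat, labels


def assign_to_annotated(
    csmm: Csmm, candidates: Sequence[TranscriptModel]
) -> str | None:
    """Pick the annotated transcript (sharing the read's exact intron chain)
    whose ends diverge least from the read's mapped ends.

    Minimises |read_start - tx_start| + |read_end - tx_end|; ties fall back to
    TSS divergence only, then the lexicographically smallest transcript id.
    Returns None for an empty candidate set (novel-candidate read).
    """
    if not candidates:
        return None
    read = csmm.read
    if read.strand == "+":
        tss_div = lambda tx: abs(read.start - tx.start)  # noqa: E731
    else:
        tss_div = lambda tx: abs(read.end - tx.end)  # noqa: E731
    best = min(
        candidates,
        key=lambda tx: (
            abs(read.start - tx.start) + abs(read.end - tx.end),
            tss_div(tx),
            tx.transcript_id,
        ),
    )
    return best.transcript_id


def is_subchain(sub: tuple, full: tuple) -> bool:
    """True iff ``sub`` is a contiguous (proper or equal) subsequence of ``full``."""
    n, m = len(sub), len(full)
    if n == 0 or n > m:
        return False
    return any(full[i : i + n] == sub for i in range(m - n + 1))


def load_junction_support(path: str | Path) -> dict[tuple[str, int, int, str], int]:
    """Short-read splice-junction table: chrom, intron_start, intron_end,
    strand, unique_count (TSV with header)."""
    df = pd.read_table(path)
    return {
        (r.chrom, int(r.intron_start), int(r.intron_end), r.strand): int(r.unique_count)
        for r in df.itertuples()
    }


@dataclass
class NovelIsoform:
    gene_id: str
    chain: tuple[tuple[int, int], ...]
    n_reads: int
    start: int  # modal mapped span of supporting reads
    end: int
    strand: str
    chrom: str
    tss_peak_id: str
    polya_peak_id: str
    accepted: bool = False
    rejection_rule: str | None = None
    intron_support: tuple[int, ...] = ()

    def to_transcript(self, transcript_id: str) -> TranscriptModel:
        bounds = [self.start]
        for d, a in self.chain:
            bounds += [d, a]
        bounds.append(self.end)
        exons = tuple((bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2))
        return TranscriptModel(transcript_id, self.gene_id, self.chrom, self.strand, exons)


def discover_novel(
    csmms: Iterable[Csmm],
    genes: GeneSet,
    sr_junctions: dict[tuple[str, int, int, str], int],
    min_support: int = 2,
) -> list[NovelIsoform]:
    """Apply the enhanced-annotation filters to complete, spliced CSMMs.

    The completeness filters (CAGE/polyA peak match) are already enforced
    upstream; here, per candidate intron chain and in order:

    * novelty — the chain is neither equal to nor a contiguous subsequence
      ("truncated version") of any annotated transcript's chain for the gene;
    * internal-exon support — each internal exon's two flanking junctions have
      >= ``min_support`` short-read records;
    * intron support — every intron has >= ``min_support`` spliced short reads;
    * non-redundancy — a surviving chain that is a contiguous subsequence of
      another surviving chain is removed (the longest is kept).

    Rejections carry the first failed rule.
    """
    groups: dict[tuple[str, tuple], list[Csmm]] = defaultdict(list)
    for c in csmms:
        if c.read.is_spliced:
            groups[(c.gene_id, c.read.introns)].append(c)

    chains_by_gene = genes.chains_by_gene()
    results: list[NovelIsoform] = []
    for (gid, chain), members in sorted(groups.items()):
        annotated = chains_by_gene.get(gid, {})
        ends = Counter((m.read.start, m.read.end) for m in members)
        (start, end), _ = min(ends.items(), key=lambda kv: (-kv[1], kv[0]))
        rep = members[0]
        support = tuple(
            sr_junctions.get((rep.read.chrom, d, a, rep.strand), 0) for d, a in chain
        )
        iso = NovelIsoform(
            gene_id=gid,
            chain=chain,
            n_reads=len(members),
            start=start,
            end=end,
            strand=rep.strand,
            chrom=rep.read.chrom,
            tss_peak_id=Counter(m.tss_peak_id for m in members).most_common(1)[0][0],
            polya_peak_id=Counter(m.polya_peak_id for m in members).most_common(1)[0][0],
            intron_support=support,
        )
        if chain in annotated or any(is_subchain(chain, ann) for ann in annotated):
            iso.rejection_rule = REJECT_ANNOTATED_TRUNCATION
        else:
            # internal exons sit between consecutive introns; their flanking
            # junctions are those two introns
            weak_internal = any(
                support[i] < min_support or support[i + 1] < min_support
                for i in range(len(chain) - 1)
            )
            if weak_internal:
                iso.rejection_rule = REJECT_EXON_SUPPORT
            elif any(s < min_support for s in support):
                iso.rejection_rule = REJECT_INTRON_SUPPORT
        results.append(iso)

    survivors = [r for r in results if r.rejection_rule is None]
    for r in survivors:
        others = [
            s.chain
            for s in survivors
            if s.gene_id == r.gene_id and s.chain != r.chain
        ]
        if any(is_subchain(r.chain, other) for other in others):
            r.rejection_rule = REJECT_NOVEL_TRUNCATION
        else:
            r.accepted = True
    return results


def write_enhanced_annotation(
    accepted: list[NovelIsoform],
    genes: GeneSet,
    per_group_counts: pd.DataFrame | None,
    gtf_path: str | Path,
    counts_path: str | Path | None = None,
) -> list[TranscriptModel]:
    """Write the annotation augmented with accepted novel isoforms.

    Novel transcripts are emitted with source tag ``isodie_novel`` and ids
    ``<gene>.novel<N>``. ``per_group_counts`` (isoform canonical string x
    group, one column per group such as ``P7Hipp_OPCs``) is written alongside
    when given.
    """
    novel_tx: list[TranscriptModel] = []
    per_gene: Counter[str] = Counter()
    for iso in sorted(accepted, key=lambda r: (r.gene_id, r.chain)):
        if not iso.accepted:
            continue
        per_gene[iso.gene_id] += 1
        novel_tx.append(iso.to_transcript(f"{iso.gene_id}.novel{per_gene[iso.gene_id]}"))
    write_gtf(genes, gtf_path, extra_transcripts=novel_tx, header="isodie enhanced annotation")
    if counts_path is not None and per_group_counts is not None:
        per_group_counts.to_csv(counts_path, sep="\t", index=True, index_label="isoform")
    return novel_tx
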