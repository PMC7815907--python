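"""From raw spliced long-read alignments to filtered, cell-typed CSMMs.

A CSMM (consensus-split-mapped molecule) is a spliced alignment that survived
the fixed filter cascade:

    select_alignment -> drop_rrna -> check_consensus -> assign_gene
        -> filter_complete -> deconvolve

Each stage's pass/fail tallies are returned alongside the CSMMs and always
sum back to the number of input reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .annotation_io import CellTypeMap, GeneSet, PeakSet
from .genome import CONSENSUS_MOTIFS, intron_motif

__all__ = [
    "AlignedLongRead",
    "Csmm",
    "StageCounts",
    "select_alignment",
    "check_consensus",
    "assign_gene",
    "filter_complete",
    "drop_rrna",
    "deconvolve",
    "run_pipeline",
    "read_alignments_tsv",
    "read_alignments_sam",
    "write_csmm_tsv",
]

MIN_MAPQ = 20
MAPQ_MARGIN = 20
COMPLETENESS_WINDOW = 50

PLATFORM_TOLERANCE = {"pacbio": 2, "ont": 3}


@dataclass(frozen=True)
class AlignedLongRead:
    read_id: str
    chrom: str
    strand: str
    start: int  # mapped genomic span, half-open
    end: int
    introns: tuple[tuple[int, int], ...]  # (donor, acceptor) pairs, genomic order
    mapq: int = 60
    barcode: str | None = None
    sample: str = ""
    platform: str = "pacbio"

    def __post_init__(self):
        prev = self.start
        for d, a in self.introns:
            if not (self.start <= d < a <= self.end) or d < prev:
                raise ValueError(
                    f"read {self.read_id}: intron chain not sorted within mapped span"
                )
            prev = a

    @property
    def is_spliced(self) -> bool:
        return len(self.introns) > 0

    def exonic_blocks(self) -> tuple[tuple[int, int], ...]:
        """Aligned exonic segments between mapped span ends and introns."""
        blocks = []
        pos = self.start
        for d, a in self.introns:
            blocks.append((pos, d))
            pos = a
        blocks.append((pos, self.end))
        return tuple(blocks)


@dataclass(frozen=True)
class Csmm:
    """A read that passed all filters, with its gene/peak/cell-type labels."""

    read: AlignedLongRead
    gene_ids: tuple[str, ...]
    tss_peak_id: str
    polya_peak_id: str
    cell_type: str | None  # None = barcode unmapped; counted in "bulk" only
    strand: str  # strand of the assigned gene

    @property
    def gene_id(self) -> str:
        return self.gene_ids[0]

    @property
    def ambiguous(self) -> bool:
        return len(self.gene_ids) > 1


@dataclass
class StageCounts:
    input: int = 0
    dropped_mapq: int = 0
    dropped_rrna: int = 0
    dropped_unspliced: int = 0
    dropped_consensus: int = 0
    dropped_no_gene: int = 0
    dropped_ambiguous: int = 0
    dropped_incomplete: int = 0
    passed: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)

    def check(self) -> None:
        total = sum(v for k, v in self.__dict__.items() if k != "input")
        assert total == self.input, f"stage counts {self.as_dict()} do not sum to input"


def select_alignment(alignments: list[AlignedLongRead]) -> AlignedLongRead | None:
    """Unique-alignment mapq filter.

    One alignment: kept iff mapq >= 20. Several alignments: the best one is
    kept iff it outscores the runner-up's mapq by >= 20.
    """
    if not alignments:
        return None
    if len(alignments) == 1:
        return alignments[0] if alignments[0].mapq >= MIN_MAPQ else None
    ranked = sorted(alignments, key=lambda r: r.mapq, reverse=True)
    if ranked[0].mapq - ranked[1].mapq >= MAPQ_MARGIN:
        return ranked[0]
    return None


def check_consensus(read: AlignedLongRead, genome) -> bool:
    """True iff every intron carries a GT-AG, GC-AG or AT-AC motif (strand-corrected)."""
    if not read.introns:
        return False
    for d, a in read.introns:
        if intron_motif(genome, read.chrom, d, a, read.strand) not in CONSENSUS_MOTIFS:
            return False
    return True


def assign_gene(read: AlignedLongRead, genes: GeneSet) -> set[str]:
    """Gene(s) sharing the most annotated splice sites with the read (ties kept)."""
    counts: Counter[str] = Counter()
    for d, a in read.introns:
        for coord in (d, a):
            for gid in genes.splice_site_index.get((read.chrom, coord, read.strand), ()):
                counts[gid] += 1
    if not counts:
        return set()
    best = max(counts.values())
    return {g for g, c in counts.items() if c == best}


def filter_complete(
    read: AlignedLongRead,
    cage: PeakSet,
    polya: PeakSet,
    window: int = COMPLETENESS_WINDOW,
) -> tuple[str | None, str | None]:
    """Match the read's biological 5'/3' ends to CAGE/polyA peaks within ``window`` bp.

    Returns (tss_peak_id, polya_peak_id); the read is "complete" iff both are
    found. Equidistant ties resolve to the more 5' peak for the TSS and the
    more 3' peak for the polyA site.
    """
    if read.strand == "+":
        five, three = read.start, read.end - 1
    else:
        five, three = read.end - 1, read.start
    tss = cage.match(read.chrom, read.strand, five, window, prefer="upstream")
    pa = polya.match(read.chrom, read.strand, three, window, prefer="downstream")
    return tss, pa


def drop_rrna(read: AlignedLongRead, genes: GeneSet) -> bool:
    """True (drop) iff the alignment span overlaps any rRNA gene span (any strand)."""
    for gid in genes.rrna_genes:
        g = genes.genes[gid]
        if g.chrom == read.chrom and read.start < g.end and g.start < read.end:
            return True
    return False


def deconvolve(read: AlignedLongRead, cellmap: CellTypeMap) -> str | None:
    """Exact barcode lookup; None keeps the read in 'bulk' analyses only."""
    return cellmap.lookup(read.barcode)


def run_pipeline(
    reads: Iterable[AlignedLongRead],
    genes: GeneSet,
    genome,
    cage: PeakSet,
    polya: PeakSet,
    cellmap: CellTypeMap | None = None,
    *,
    window: int = COMPLETENESS_WINDOW,
    drop_ambiguous: bool = True,
    spliced_only: bool = True,
) -> tuple[list[Csmm], StageCounts]:
    """Run the fixed filter cascade over reads grouped by read_id.

    ``drop_ambiguous`` drops reads tied between genes (the default avoids
    double counting in the statistics; set False to count such reads once per
    tied gene, flagged ``ambiguous``).
    """
    by_read: dict[str, list[AlignedLongRead]] = {}
    for r in reads:
        by_read.setdefault(r.read_id, []).append(r)

    counts = StageCounts(input=len(by_read))
    csmms: list[Csmm] = []
    rrna_spans = genes.rrna_spans()

    for rid in by_read:
        aln = select_alignment(by_read[rid])
        if aln is None:
            counts.dropped_mapq += 1
            continue
        if any(
            aln.start < e and s < aln.end for s, e in rrna_spans.get(aln.chrom, ())
        ):
            counts.dropped_rrna += 1
            continue
        if spliced_only and not aln.is_spliced:
            counts.dropped_unspliced += 1
            continue
        if not check_consensus(aln, genome):
            counts.dropped_consensus += 1
            continue
        gids = assign_gene(aln, genes)
        if not gids:
            counts.dropped_no_gene += 1
            continue
        if len(gids) > 1 and drop_ambiguous:
            counts.dropped_ambiguous += 1
            continue
        strand = genes.genes[sorted(gids)[0]].strand
        oriented = aln if aln.strand == strand else replace(aln, strand=strand)
        tss, pa = filter_complete(oriented, cage, polya, window)
        if tss is None or pa is None:
            counts.dropped_incomplete += 1
            continue
        cell_type = deconvolve(aln, cellmap) if cellmap is not None else None
        csmms.append(Csmm(oriented, tuple(sorted(gids)), tss, pa, cell_type, strand))
        counts.passed += 1

    counts.check()
    return csmms, counts


# ---------------------------------------------------------------------------
# IO


def _parse_introns(text: str) -> tuple[tuple[int, int], ...]:
    if not text or text in (".", "-"):
        return ()
    out = []
    for part in text.split(";"):
        d, a = part.split("-")
        out.append((int(d), int(a)))
    return tuple(out)


def read_alignments_tsv(path: str | Path, platform: str = "pacbio") -> Iterator[AlignedLongRead]:
    """Plain-text alignment table: read_id, sample, barcode, chrom, strand,
    start, end, introns ("d-a;d-a" or "."), mapq."""
    df = pd.read_table(path, dtype={"barcode": str})
    for row in df.itertuples():
        yield AlignedLongRead(
            read_id=row.read_id,
            chrom=row.chrom,
            strand=row.strand,
            start=int(row.start),
            end=int(row.end),
            introns=_parse_introns(row.introns),
            mapq=int(row.mapq),
            barcode=None if pd.isna(row.barcode) else str(row.barcode),
            sample=getattr(row, "sample", ""),
            platform=platform,
        )


def read_alignments_sam(
    path: str | Path,
    barcode_tag: str = "CB",
    sample: str = "",
    platform: str = "pacbio",
) -> Iterator[AlignedLongRead]:
    """Extract spliced alignments from SAM/BAM; introns from N CIGAR ops."""
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            introns = []
            pos = aln.reference_start
            for op, length in aln.cigartuples or ():
                if op in (0, 7, 8, 2):  # M/=/X consume ref; D too
                    pos += length
                elif op == 3:  # N: intron
                    introns.append((pos, pos + length))
                    pos += length
            yield AlignedLongRead(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                strand="-" if aln.is_reverse else "+",
                start=aln.reference_start,
                end=pos,
                introns=tuple(introns),
                mapq=aln.mapping_quality,
                barcode=aln.get_tag(barcode_tag) if aln.has_tag(barcode_tag) else None,
                sample=sample,
                platform=platform,
            )


def write_csmm_tsv(csmms: list[Csmm], path: str | Path) -> None:
    rows = [
        {
            "read_id": c.read.read_id,
            "sample": c.read.sample,
            "gene_id": ",".join(c.gene_ids),
            "ambiguous": int(c.ambiguous),
            "cell_type": c.cell_type or "",
            "tss_peak": c.tss_peak_id,
            "polya_peak": c.polya_peak_id,
            "chrom": c.read.chrom,
            "strand": c.strand,
            "start": c.read.start,
            "end": c.read.end,
            "introns": ";".join(f"{d}-{a}" for d, a in c.read.introns) or ".",
        }
        for c in csmms
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
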