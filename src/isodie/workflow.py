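"""Convenience wiring: load all reference inputs once, run the read filters,
and produce usage tables for a comparison. Thin glue over the per-stage
modules; everything here is also reachable piecewise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .annotation_io import (
    CellTypeMap,
    GeneSet,
    PeakSet,
    load_annotation,
    load_cell_map,
    load_peaks,
)
from .genome import FastaGenome
from .isoform_catalog import UsageTable, build_usage_tables, group_by_sample
from .read_processing import (
    AlignedLongRead,
    Csmm,
    StageCounts,
    read_alignments_tsv,
    run_pipeline,
)

__all__ = ["Reference", "load_reference", "process_reads", "usage_for_node"]


@dataclass
class Reference:
    genes: GeneSet
    genome: FastaGenome
    cage: PeakSet
    polya: PeakSet
    cellmap: CellTypeMap


def load_reference(
    gtf: str | Path,
    fasta: str | Path,
    cage_bed: str | Path,
    polya_bed: str | Path,
    barcode_map: str | Path,
    hierarchy: str | Path,
    rrna_pattern: str = "rRNA",
) -> Reference:
    return Reference(
        genes=load_annotation(gtf, rrna_pattern=rrna_pattern),
        genome=FastaGenome(fasta),
        cage=load_peaks(cage_bed, "CAGE"),
        polya=load_peaks(polya_bed, "polyA"),
        cellmap=load_cell_map(barcode_map, hierarchy),
    )


def process_reads(
    ref: Reference,
    reads: str | Path | Iterable[AlignedLongRead],
    platform: str = "pacbio",
    **kwargs,
) -> tuple[list[Csmm], StageCounts]:
    """Run the CSMM filter cascade on a reads TSV path or an iterable."""
    if isinstance(reads, (str, Path)):
        reads = read_alignments_tsv(reads, platform=platform)
    return run_pipeline(
        reads, ref.genes, ref.genome, ref.cage, ref.polya, ref.cellmap, **kwargs
    )


def usage_for_node(
    csmms: Iterable[Csmm], ref: Reference, node: str
) -> dict[str, UsageTable]:
    """Isoform usage tables grouped by sample, restricted to one hierarchy node."""
    return build_usage_tables(csmms, group_by_sample(node, ref.cellmap))
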