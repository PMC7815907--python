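from __future__ import annotations

from dataclasses import dataclass

import pytest

from isodie import load_reference, process_reads
from isodie.simulate import SimConfig, simulate


@dataclass
class ProcessedSim:
    result: object  # SimResult
    ref: object  # Reference
    csmms: list
    counts: object  # StageCounts

    @property
    def ledger(self):
        return self.result.ledger


@pytest.fixture(scope="session")
def zero_noise_sim(tmp_path_factory) -> ProcessedSim:
    """Small noise-free study with planted DIE and all novel-isoform rule
    scenarios, processed through the full filter cascade once per session."""
    cfg = SimConfig(
        seed=7,
        n_genes=8,
        depth=30,
        plant_novel=True,
        die_genes={5: ("*",), 6: ("EN", "IN")},
    )
    res = simulate(cfg, tmp_path_factory.mktemp("zero_noise"))
    ref = load_reference(
        res.gtf, res.fasta, res.cage_bed, res.polya_bed, res.barcode_map, res.hierarchy_json
    )
    csmms, counts = process_reads(ref, res.reads_tsv)
    return ProcessedSim(res, ref, csmms, counts)


TINY_GTF = """\
chr1\ttest\tgene\t101\t400\t.\t+\t.\tgene_id "gA"; gene_name "GeneA";
chr1\ttest\ttranscript\t101\t400\t.\t+\t.\tgene_id "gA"; transcript_id "tA1";
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "tA1";
chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "gA"; transcript_id "tA1";
chr1\ttest\ttranscript\t101\t400\t.\t+\t.\tgene_id "gA"; transcript_id "tA2";
chr1\ttest\texon\t101\t400\t.\t+\t.\tgene_id "gA"; transcript_id "tA2";
chr1\ttest\tgene\t501\t800\t.\t+\t.\tgene_id "gB"; gene_name "GeneB";
chr1\ttest\ttranscript\t501\t800\t.\t+\t.\tgene_id "gB"; transcript_id "tB1";
chr1\ttest\texon\t501\t600\t.\t+\t.\tgene_id "gB"; transcript_id "tB1";
chr1\ttest\texon\t701\t800\t.\t+\t.\tgene_id "gB"; transcript_id "tB1";
chr1\ttest\tgene\t901\t1000\t.\t+\t.\tgene_id "gR"; gene_name "Rn45s"; gene_biotype "rRNA";
chr1\ttest\ttranscript\t901\t1000\t.\t+\t.\tgene_id "gR"; transcript_id "tR1"; transcript_biotype "rRNA";
chr1\ttest\texon\t901\t1000\t.\t+\t.\tgene_id "gR"; transcript_id "tR1";
"""


@pytest.fixture(scope="session")
def tiny_gtf(tmp_path_factory):
    path = tmp_path_factory.mktemp("tiny") / "tiny.gtf"
    path.write_text(TINY_GTF)
    return path


@pytest.fixture(scope="session")
def tiny_geneset(tiny_gtf):
    from isodie import load_annotation

    return load_annotation(tiny_gtf)
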