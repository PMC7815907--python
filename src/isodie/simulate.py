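"""Seeded generator of a complete synthetic study: annotation, genome, peak
files, barcode map, short-read junction support, and barcoded long reads with
known per-cell-type isoform usage.

The generator emulates the sampling model the statistics assume: per gene,
per region, per leaf cell type, reads are drawn multinomially from a percent
isoform (Pi) vector. Differential usage is planted by swapping the two most
abundant isoforms of a gene in the second region for a chosen set of cell
types. Optional corruptions model library/alignment artifacts: splice-motif
corruption (misaligned junctions that fail the consensus filter), 5'
truncation (reads that fail the CAGE completeness filter) and bounded
junction wobble. A TruthLedger records every read's origin and expected fate
so downstream estimates can be compared to truth exactly in the zero-noise
limit.

Gene anatomy: six exons E0..E5; isoform 0 uses all six, isoform k (k >= 1)
skips internal exon Ek. Novel-isoform plants add intron chains absent from
the annotation (merged introns across two or more skipped exons) together
with the short-read support pattern that drives each enhanced-annotation
rule.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import GeneModel, GeneSet, TranscriptModel, write_gtf
from .isoform_catalog import (
    REJECT_ANNOTATED_TRUNCATION,
    REJECT_EXON_SUPPORT,
    REJECT_INTRON_SUPPORT,
    REJECT_NOVEL_TRUNCATION,
)

__all__ = ["SimConfig", "TruthLedger", "SimResult", "simulate", "simulate_null"]

DEFAULT_HIERARCHY = {
    "bulk": {"neurons": {"EN": {}, "IN": {}}, "nonneurons": {"Astro": {}, "Vasc": {}}}
}

N_EXONS = 6


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 50
    n_isoforms: int = 4
    base_pi: tuple[float, ...] = (0.5, 0.2, 0.2, 0.1)
    regions: tuple[str, ...] = ("HIPP", "PFC")
    hierarchy: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_HIERARCHY)))
    depth: int = 60  # reads per gene per region per leaf cell type
    barcodes_per_celltype: int = 8
    exon_length: int = 90
    intron_length: int = 120
    gene_gap: int = 300
    peak_width: int = 20
    truncation_rate: float = 0.0
    corrupt_motif_fraction: float = 0.0
    wobble_max: int = 0  # bp; bounded junction wobble (models misalignment)
    wobble_fraction: float = 0.0
    die_genes: dict[int, tuple[str, ...]] | None = None  # gene index -> leaves; ("*",) = all
    null: bool = False
    plant_novel: bool = False
    novel_read_depth: int = 3  # reads per planted chain per region per leaf
    sr_support: int = 10  # default short-read junction support
    platform: str = "pacbio"
    write_sam: bool = False
    chrom: str = "chrS"

    def validate(self) -> None:
        if not (2 <= self.n_isoforms <= N_EXONS - 1):
            raise ValueError("n_isoforms must be between 2 and 5")
        if len(self.base_pi) != self.n_isoforms:
            raise ValueError("base_pi length must equal n_isoforms")
        if abs(sum(self.base_pi) - 1.0) > 1e-9:
            raise ValueError("base_pi must sum to 1")
        if self.plant_novel and self.n_genes < 4:
            raise ValueError("plant_novel needs at least 4 genes")
        for v in (self.truncation_rate, self.corrupt_motif_fraction, self.wobble_fraction):
            if not 0 <= v <= 1:
                raise ValueError("rates must lie in [0, 1]")


def _leaves(hierarchy: dict) -> list[str]:
    out: list[str] = []

    def walk(node: dict) -> None:
        for name, sub in node.items():
            if sub:
                walk(sub)
            else:
                out.append(name)

    walk(next(iter(hierarchy.values())))
    return sorted(out)


@dataclass
class _Gene:
    gene_id: str
    strand: str
    exons: list[tuple[int, int]]  # E0..E5 genomic order
    isoforms: dict[str, tuple[int, ...]]  # label -> exon indices (annotated)
    plants: dict[str, tuple[int, ...]]  # label -> exon indices (unannotated reads)
    weak_introns: set[tuple[int, int]] = field(default_factory=set)
    alt_cage_at: int | None = None  # extra CAGE peak coordinate (5'-truncation plants)

    def chain(self, exon_idx: tuple[int, ...]) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[exon_idx[i]][1], self.exons[exon_idx[i + 1]][0])
            for i in range(len(exon_idx) - 1)
        )

    def span(self, exon_idx: tuple[int, ...]) -> tuple[int, int]:
        return self.exons[exon_idx[0]][0], self.exons[exon_idx[-1]][1]


@dataclass
class TruthLedger:
    """Per-read and per-gene ground truth sufficient to recompute every
    expected pipeline output in the zero-noise limit."""

    config: SimConfig
    genes: dict[str, _Gene]
    pi_true: dict[tuple[str, str, str], dict[str, float]]  # (gene, region, leaf) -> label -> Pi
    reads: pd.DataFrame  # read_id, gene_id, region, cell_type, iso_label, expected_pass, fail_stage
    novel_expect: dict[tuple[str, tuple], tuple[bool, str | None]]
    chain_label: dict[tuple[str, tuple], str]  # (gene, chain) -> isoform label

    # -- usage truth ---------------------------------------------------------

    def passing(self) -> pd.DataFrame:
        return self.reads[self.reads["expected_pass"]]

    def expected_usage(self, region: str, leaves: set[str] | None = None) -> pd.DataFrame:
        """Expected (gene, iso_label) read counts for one region/group."""
        df = self.passing()
        df = df[df["region"] == region]
        if leaves is not None:
            df = df[df["cell_type"].isin(leaves)]
        return df.groupby(["gene_id", "iso_label"]).size().rename("count").reset_index()

    def expected_pi(self, region: str, leaves: set[str] | None = None) -> pd.DataFrame:
        usage = self.expected_usage(region, leaves)
        totals = usage.groupby("gene_id")["count"].transform("sum")
        usage["pi"] = usage["count"] / totals
        return usage

    # -- exon truth ----------------------------------------------------------

    def expected_exon_counts(
        self, region: str, leaves: set[str] | None = None
    ) -> dict[tuple[str, int, int], list[int]]:
        """Structural inclusion/exclusion truth per annotated exon.

        Derived from isoform membership, independently of the junction
        arithmetic the exon caller uses: an exon present in a read's exon set
        is included (excluded when it sits at a read edge but is internal in
        the annotation — its junction cannot be observed); an absent exon
        spanned by the read is excluded; anything else is uninformative.
        """
        df = self.passing()
        df = df[df["region"] == region]
        if leaves is not None:
            df = df[df["cell_type"].isin(leaves)]
        out: dict[tuple[str, int, int], list[int]] = defaultdict(lambda: [0, 0])
        for row in df.itertuples():
            gene = self.genes[row.gene_id]
            t = gene.isoforms.get(row.iso_label) or gene.plants[row.iso_label]
            start, end = gene.span(t)
            members = set(t)
            for i, (s, e) in enumerate(gene.exons):
                terminal = i in (0, N_EXONS - 1)
                key = (row.gene_id, s, e)
                if i in members:
                    if i in (t[0], t[-1]) and not terminal:
                        out[key][1] += 1  # read edge inside an internal exon
                    else:
                        out[key][0] += 1
                elif start <= s and e <= end:
                    out[key][1] += 1
        return dict(out)


@dataclass
class SimResult:
    outdir: Path
    gtf: Path
    fasta: Path
    cage_bed: Path
    polya_bed: Path
    barcode_map: Path
    hierarchy_json: Path
    reads_tsv: Path
    junctions_tsv: Path
    truth_json: Path
    sam_files: dict[str, Path]
    ledger: TruthLedger


def _build_genes(cfg: SimConfig) -> tuple[dict[str, _Gene], int]:
    genes: dict[str, _Gene] = {}
    step = cfg.exon_length + cfg.intron_length
    span = N_EXONS * cfg.exon_length + (N_EXONS - 1) * cfg.intron_length
    pos = cfg.gene_gap
    for i in range(cfg.n_genes):
        gid = f"G{i:04d}"
        strand = "+" if (i < 4 or i % 2 == 0) else "-"
        exons = [(pos + j * step, pos + j * step + cfg.exon_length) for j in range(N_EXONS)]
        isoforms = {"iso0": tuple(range(N_EXONS))}
        for k in range(1, cfg.n_isoforms):
            isoforms[f"iso{k}"] = tuple(j for j in range(N_EXONS) if j != k)
        g = _Gene(gid, strand, exons, isoforms, {})
        if cfg.plant_novel and i < 4:
            if i == 0:
                g.plants = {
                    "novel_ok": (0, 1, 4, 5),
                    "trunc_ann": tuple(range(1, N_EXONS)),
                }
                g.alt_cage_at = exons[1][0]
            elif i == 1:
                g.plants = {"novel_weak_exon": (0, 1, 2, 5)}
                g.weak_introns = {(exons[1][1], exons[2][0])}  # I12
            elif i == 2:
                g.plants = {"novel_weak_intron": (0, 5)}
                g.weak_introns = {(exons[0][1], exons[5][0])}
            elif i == 3:
                g.plants = {"novel_ok3": (0, 1, 4, 5), "novel_trunc": (1, 4, 5)}
                g.alt_cage_at = exons[1][0]
        genes[gid] = g
        pos += span + cfg.gene_gap
    return genes, pos + cfg.gene_gap


def _novel_expectations(genes: dict[str, _Gene]) -> dict[tuple[str, tuple], tuple[bool, str | None]]:
    expect: dict[tuple[str, tuple], tuple[bool, str | None]] = {}
    rules = {
        "trunc_ann": (False, REJECT_ANNOTATED_TRUNCATION),
        "novel_weak_exon": (False, REJECT_EXON_SUPPORT),
        "novel_weak_intron": (False, REJECT_INTRON_SUPPORT),
        "novel_trunc": (False, REJECT_NOVEL_TRUNCATION),
        "novel_ok": (True, None),
        "novel_ok3": (True, None),
    }
    for g in genes.values():
        for label, t in g.plants.items():
            expect[(g.gene_id, g.chain(t))] = rules[label]
    return expect


def _write_fasta(path: Path, chrom: str, length: int, genes: dict[str, _Gene]) -> None:
    seq = np.full(length, ord("C"), dtype=np.uint8)
    # exonic filler differs from intron filler so the sequence looks gene-like
    for g in genes.values():
        for s, e in g.exons:
            seq[s:e] = ord("A")
        intron_pairs = set()
        for t in list(g.isoforms.values()) + list(g.plants.values()):
            intron_pairs.update(g.chain(t))
        for d, a in intron_pairs:
            seq[d:a] = ord("C")
        for d, a in intron_pairs:
            if g.strand == "+":
                seq[d : d + 2] = np.frombuffer(b"GT", dtype=np.uint8)
                seq[a - 2 : a] = np.frombuffer(b"AG", dtype=np.uint8)
            else:
                seq[d : d + 2] = np.frombuffer(b"CT", dtype=np.uint8)
                seq[a - 2 : a] = np.frombuffer(b"AC", dtype=np.uint8)
    text = seq.tobytes().decode()
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, length, 60):
            fh.write(text[i : i + 60] + "\n")


def _geneset(cfg: SimConfig, genes: dict[str, _Gene]) -> GeneSet:
    gmodels: dict[str, GeneModel] = {}
    tmodels: dict[str, TranscriptModel] = {}
    index: dict[tuple[str, int, str], set[str]] = {}
    for gid in sorted(genes):
        g = genes[gid]
        gm = GeneModel(gid, cfg.chrom, g.strand, g.exons[0][0], g.exons[-1][1], name=gid)
        gmodels[gid] = gm
        for label in sorted(g.isoforms):
            t = g.isoforms[label]
            tid = f"{gid}.{label}"
            exons = tuple(g.exons[j] for j in t)
            tx = TranscriptModel(tid, gid, cfg.chrom, g.strand, exons, "protein_coding")
            tmodels[tid] = tx
            gm.transcript_ids.append(tid)
            for d, a in tx.intron_chain:
                index.setdefault((cfg.chrom, d, g.strand), set()).add(gid)
                index.setdefault((cfg.chrom, a, g.strand), set()).add(gid)
    return GeneSet(gmodels, tmodels, index, set())


def _write_peaks(cfg: SimConfig, genes: dict[str, _Gene], cage: Path, polya: Path) -> None:
    w = cfg.peak_width
    cage_rows, polya_rows = [], []
    for gid in sorted(genes):
        g = genes[gid]
        g_start, g_end = g.exons[0][0], g.exons[-1][1]
        five = g_start if g.strand == "+" else g_end - 1
        three = g_end - 1 if g.strand == "+" else g_start
        cage_rows.append((cfg.chrom, five - w // 2, five + w // 2, f"cage_{gid}", 0, g.strand))
        polya_rows.append((cfg.chrom, three - w // 2, three + w // 2, f"pa_{gid}", 0, g.strand))
        if g.alt_cage_at is not None:
            cage_rows.append(
                (cfg.chrom, g.alt_cage_at - w // 2, g.alt_cage_at + w // 2,
                 f"cage_{gid}_alt", 0, g.strand)
            )
    for rows, path in ((cage_rows, cage), (polya_rows, polya)):
        rows.sort(key=lambda r: (r[0], r[1]))
        with open(path, "w") as fh:
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")


def _write_junctions(cfg: SimConfig, genes: dict[str, _Gene], path: Path) -> None:
    rows = []
    for gid in sorted(genes):
        g = genes[gid]
        pairs = set()
        for t in list(g.isoforms.values()) + list(g.plants.values()):
            pairs.update(g.chain(t))
        for d, a in sorted(pairs):
            n = 1 if (d, a) in g.weak_introns else cfg.sr_support
            rows.append((cfg.chrom, d, a, g.strand, n))
    pd.DataFrame(
        rows, columns=["chrom", "intron_start", "intron_end", "strand", "unique_count"]
    ).to_csv(path, sep="\t", index=False)


def _pi_for(cfg: SimConfig, gene_index: int, region: str, leaf: str) -> np.ndarray:
    pi = np.array(cfg.base_pi, dtype=float)
    if cfg.null or not cfg.die_genes:
        return pi
    leaves = cfg.die_genes.get(gene_index)
    if leaves is None:
        return pi
    if region == cfg.regions[1] and ("*" in leaves or leaf in leaves):
        pi[[0, 1]] = pi[[1, 0]]
    return pi


def simulate(config: SimConfig, outdir: str | Path) -> SimResult:
    """Generate the full synthetic study under ``outdir``.

    Outputs are byte-identical for identical configs (including the seed).
    """
    cfg = config
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes, chrom_len = _build_genes(cfg)
    leaves = _leaves(cfg.hierarchy)

    # barcodes: deterministic random 12-mers, unique across cell types
    barcodes: dict[str, list[str]] = {}
    used: set[str] = set()
    for leaf in leaves:
        row = []
        while len(row) < cfg.barcodes_per_celltype:
            bc = "".join(rng.choice(list("ACGT"), size=12))
            if bc not in used:
                used.add(bc)
                row.append(bc)
        barcodes[leaf] = row

    gtf = outdir / "annotation.gtf"
    fasta = outdir / "genome.fa"
    cage = outdir / "cage.bed"
    polya = outdir / "polya.bed"
    bc_map = outdir / "barcodes.tsv"
    hier = outdir / "hierarchy.json"
    reads_tsv = outdir / "reads.tsv"
    junctions = outdir / "junctions.tsv"
    truth = outdir / "truth.json"

    geneset = _geneset(cfg, genes)
    write_gtf(geneset, gtf, header="isodie synthetic annotation")
    _write_fasta(fasta, cfg.chrom, chrom_len, genes)
    _write_peaks(cfg, genes, cage, polya)
    _write_junctions(cfg, genes, junctions)
    with open(bc_map, "w") as fh:
        for leaf in leaves:
            for bc in barcodes[leaf]:
                fh.write(f"{bc}\t{leaf}\n")
    hier.write_text(json.dumps(cfg.hierarchy, indent=1, sort_keys=True))

    # ---- reads -------------------------------------------------------------
    pi_true: dict[tuple[str, str, str], dict[str, float]] = {}
    read_rows = []
    truth_rows = []
    counter = 0

    gene_ids = sorted(genes)
    for gi, gid in enumerate(gene_ids):
        g = genes[gid]
        iso_labels = [f"iso{k}" for k in range(cfg.n_isoforms)]
        for region in cfg.regions:
            for leaf in leaves:
                pi = _pi_for(cfg, gi, region, leaf)
                pi_true[(gid, region, leaf)] = dict(zip(iso_labels, pi.tolist()))
                counts = rng.multinomial(cfg.depth, pi)
                emission: list[str] = []
                for label, n in zip(iso_labels, counts):
                    emission.extend([label] * int(n))
                for label in sorted(g.plants):
                    emission.extend([label] * cfg.novel_read_depth)
                for j, label in enumerate(emission):
                    t = g.isoforms.get(label) or g.plants[label]
                    chain = list(g.chain(t))
                    start, end = g.span(t)
                    expected_pass, fail = True, None

                    if cfg.corrupt_motif_fraction and rng.random() < cfg.corrupt_motif_fraction:
                        d, a = chain[0]
                        chain[0] = (d + 4, a)
                        expected_pass, fail = False, "consensus"
                    elif (
                        cfg.truncation_rate
                        and not g.plants
                        and rng.random() < cfg.truncation_rate
                    ):
                        if g.strand == "+":
                            start = chain[0][1]
                            chain = chain[1:]
                        else:
                            end = chain[-1][0]
                            chain = chain[:-1]
                        expected_pass, fail = False, "incomplete"
                    elif cfg.wobble_fraction and rng.random() < cfg.wobble_fraction:
                        shifts = rng.integers(-cfg.wobble_max, cfg.wobble_max + 1, len(chain) * 2)
                        wobbled = [
                            (d + int(shifts[2 * i]), a + int(shifts[2 * i + 1]))
                            for i, (d, a) in enumerate(chain)
                        ]
                        if any(w != c for w, c in zip(wobbled, chain)):
                            chain = wobbled
                            expected_pass, fail = False, "consensus"

                    rid = f"r{counter:07d}"
                    counter += 1
                    bc = barcodes[leaf][j % cfg.barcodes_per_celltype]
                    read_rows.append(
                        {
                            "read_id": rid,
                            "sample": region,
                            "barcode": bc,
                            "chrom": cfg.chrom,
                            "strand": g.strand,
                            "start": start,
                            "end": end,
                            "introns": ";".join(f"{d}-{a}" for d, a in chain) or ".",
                            "mapq": 60,
                        }
                    )
                    truth_rows.append(
                        {
                            "read_id": rid,
                            "gene_id": gid,
                            "region": region,
                            "cell_type": leaf,
                            "iso_label": label,
                            "expected_pass": expected_pass,
                            "fail_stage": fail,
                        }
                    )

    reads_df = pd.DataFrame(read_rows)
    reads_df.to_csv(reads_tsv, sep="\t", index=False)

    sam_files: dict[str, Path] = {}
    if cfg.write_sam:
        sam_files = _write_sams(cfg, outdir, reads_df, chrom_len)

    chain_label = {
        (gid, genes[gid].chain(t)): label
        for gid in gene_ids
        for label, t in list(genes[gid].isoforms.items()) + list(genes[gid].plants.items())
    }
    ledger = TruthLedger(
        config=cfg,
        genes=genes,
        pi_true=pi_true,
        reads=pd.DataFrame(truth_rows),
        novel_expect=_novel_expectations(genes),
        chain_label=chain_label,
    )

    truth.write_text(
        json.dumps(
            {
                "pi_true": {f"{k[0]}|{k[1]}|{k[2]}": v for k, v in sorted(pi_true.items())},
                "novel": {
                    f"{gid}|{';'.join(f'{d}-{a}' for d, a in chain)}": {
                        "accepted": acc,
                        "rule": rule,
                    }
                    for (gid, chain), (acc, rule) in sorted(ledger.novel_expect.items())
                },
            },
            indent=1,
            sort_keys=True,
        )
    )

    return SimResult(
        outdir=outdir,
        gtf=gtf,
        fasta=fasta,
        cage_bed=cage,
        polya_bed=polya,
        barcode_map=bc_map,
        hierarchy_json=hier,
        reads_tsv=reads_tsv,
        junctions_tsv=junctions,
        truth_json=truth,
        sam_files=sam_files,
        ledger=ledger,
    )


def _write_sams(
    cfg: SimConfig, outdir: Path, reads_df: pd.DataFrame, chrom_len: int
) -> dict[str, Path]:
    import pysam

    out: dict[str, Path] = {}
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": cfg.chrom, "LN": int(chrom_len)}]}
    for region in cfg.regions:
        path = outdir / f"reads.{region}.sam"
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            sub = reads_df[reads_df["sample"] == region]
            for row in sub.itertuples():
                a = pysam.AlignedSegment(fh.header)
                a.query_name = row.read_id
                a.flag = 16 if row.strand == "-" else 0
                a.reference_id = 0
                a.reference_start = int(row.start)
                a.mapping_quality = int(row.mapq)
                cig = []
                pos = int(row.start)
                introns = (
                    []
                    if row.introns == "."
                    else [tuple(map(int, p.split("-"))) for p in row.introns.split(";")]
                )
                for d, aa in introns:
                    cig.append((0, d - pos))
                    cig.append((3, aa - d))
                    pos = aa
                cig.append((0, int(row.end) - pos))
                a.cigartuples = cig
                a.query_sequence = "A" * sum(l for op, l in cig if op == 0)
                a.set_tag("CB", row.barcode)
                fh.write(a)
        out[region] = path
    return out


def simulate_null(config: SimConfig, outdir: str | Path) -> SimResult:
    """Same outputs with identical Pi across regions and cell types (true
    DeltaPi = 0 everywhere); the type-I error harness."""
    return simulate(replace(config, null=True), outdir)
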