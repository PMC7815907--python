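"""Reference input loading: gene annotation, peak intervals, barcode/cell-type maps.

All genomic coordinates inside the package are 0-based half-open, regardless
of the on-disk format (GTF is 1-based inclusive, BED already half-open).
Introns are stored as ``(donor, acceptor)`` = (first intronic base, one past
the last intronic base) in genomic orientation; biological donor/acceptor
roles follow the annotated strand.
"""

from __future__ import annotations

import json
import re
import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "AnnotationError",
    "TranscriptModel",
    "GeneModel",
    "GeneSet",
    "PeakSet",
    "CellTypeMap",
    "load_annotation",
    "load_peaks",
    "load_cell_map",
    "write_gtf",
]


class AnnotationError(ValueError):
    """Raised for malformed reference inputs."""


# ---------------------------------------------------------------------------
# annotation


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # sorted genomic order, half-open
    biotype: str | None = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """(donor, acceptor) pairs between consecutive exons; empty for mono-exonic."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    name: str = ""
    transcript_ids: list[str] = field(default_factory=list)
    is_rrna: bool = False


@dataclass
class GeneSet:
    genes: dict[str, GeneModel]
    transcripts: dict[str, TranscriptModel]
    splice_site_index: dict[tuple[str, int, str], set[str]]
    rrna_genes: set[str]

    def transcripts_of(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[t] for t in self.genes[gene_id].transcript_ids]

    def rrna_spans(self) -> dict[str, list[tuple[int, int]]]:
        spans: dict[str, list[tuple[int, int]]] = {}
        for gid in sorted(self.rrna_genes):
            g = self.genes[gid]
            spans.setdefault(g.chrom, []).append((g.start, g.end))
        for v in spans.values():
            v.sort()
        return spans

    def chains_by_gene(self) -> dict[str, dict[tuple[tuple[int, int], ...], list[str]]]:
        """gene_id -> intron chain -> transcript ids sharing that exact chain."""
        out: dict[str, dict[tuple, list[str]]] = {}
        for tid, tx in self.transcripts.items():
            out.setdefault(tx.gene_id, {}).setdefault(tx.intron_chain, []).append(tid)
        for d in out.values():
            for tids in d.values():
                tids.sort()
        return out


def _check_gtf_lines(path: Path) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) < 9:
                raise AnnotationError(f"malformed GTF record at line {i} of {path}")


def _attr(feature, *names: str) -> str | None:
    for n in names:
        if n in feature.attributes:
            return feature.attributes[n][0]
    return None


def load_annotation(gtf_path: str | Path, rrna_pattern: str = "rRNA") -> GeneSet:
    """Load a GENCODE/Ensembl-dialect GTF into the internal convention.

    ``rrna_pattern`` is a regex matched against gene name/id to flag ribosomal
    RNA genes in addition to any transcript/gene biotype equal to ``rRNA``;
    reads overlapping flagged genes are removed by the read-processing filters.
    """
    gtf_path = Path(gtf_path)
    _check_gtf_lines(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    name_re = re.compile(rrna_pattern) if rrna_pattern else None

    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, TranscriptModel] = {}
    index: dict[tuple[str, int, str], set[str]] = {}
    rrna: set[str] = set()

    for g in db.features_of_type("gene"):
        gid = _attr(g, "gene_id")
        if gid is None:
            raise AnnotationError(f"gene feature without gene_id near {g.seqid}:{g.start}")
        name = _attr(g, "gene_name") or gid
        gm = GeneModel(gid, g.seqid, g.strand, g.start - 1, g.end, name=name)
        biotype = _attr(g, "gene_biotype", "gene_type")
        if biotype == "rRNA" or (name_re and (name_re.search(name) or name_re.search(gid))):
            gm.is_rrna = True
            rrna.add(gid)
        genes[gid] = gm

    for t in db.features_of_type("transcript"):
        tid = _attr(t, "transcript_id")
        gid = _attr(t, "gene_id")
        if tid is None or gid is None:
            raise AnnotationError(
                f"transcript without transcript_id/gene_id near {t.seqid}:{t.start}"
            )
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(t, featuretype="exon")
        )
        if not exons:
            continue
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise AnnotationError(f"overlapping exons in transcript {tid}")
        biotype = _attr(t, "transcript_biotype", "transcript_type")
        tx = TranscriptModel(tid, gid, t.seqid, t.strand, tuple(exons), biotype)
        transcripts[tid] = tx
        if gid not in genes:  # GTF without explicit gene lines for this gene
            genes[gid] = GeneModel(gid, t.seqid, t.strand, tx.start, tx.end)
        gm = genes[gid]
        gm.transcript_ids.append(tid)
        gm.start = min(gm.start, tx.start)
        gm.end = max(gm.end, tx.end)
        if biotype == "rRNA":
            gm.is_rrna = True
            rrna.add(gid)
        for d, a in tx.intron_chain:
            index.setdefault((tx.chrom, d, tx.strand), set()).add(gid)
            index.setdefault((tx.chrom, a, tx.strand), set()).add(gid)

    return GeneSet(genes, transcripts, index, rrna)


def write_gtf(
    geneset: GeneSet,
    path: str | Path,
    extra_transcripts: list[TranscriptModel] | None = None,
    source: str = "isodie",
    header: str | None = None,
) -> None:
    """Write the annotation back to GTF (1-based inclusive coordinates).

    ``extra_transcripts`` are appended with source tag ``isodie_novel`` — used
    by the enhanced-annotation writer.
    """
    extra = extra_transcripts or []
    extra_by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in extra:
        extra_by_gene.setdefault(tx.gene_id, []).append(tx)

    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for gid in sorted(geneset.genes):
            g = geneset.genes[gid]
            novel = extra_by_gene.get(gid, [])
            g_start = min([g.start] + [t.start for t in novel])
            g_end = max([g.end] + [t.end for t in novel])
            attrs = f'gene_id "{gid}"; gene_name "{g.name or gid}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g_start + 1}\t{g_end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            txs = [(tid, geneset.transcripts[tid], source) for tid in g.transcript_ids]
            txs += [(t.transcript_id, t, "isodie_novel") for t in novel]
            for tid, tx, src in txs:
                tattrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                if tx.biotype:
                    tattrs += f' transcript_biotype "{tx.biotype}";'
                fh.write(
                    f"{tx.chrom}\t{src}\ttranscript\t{tx.start + 1}\t{tx.end}\t.\t"
                    f"{tx.strand}\t.\t{tattrs}\n"
                )
                for s, e in tx.exons:
                    fh.write(
                        f"{tx.chrom}\t{src}\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{tattrs}\n"
                    )


# ---------------------------------------------------------------------------
# peaks


@dataclass
class PeakSet:
    """Strand-aware sorted intervals (CAGE or polyA peaks) with stable ids."""

    kind: str  # "CAGE" | "polyA"
    _by_key: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, list[str]]] = field(
        default_factory=dict
    )

    def __len__(self) -> int:
        return sum(len(ids) for *_, ids in self._by_key.values())

    def peak_ids(self) -> list[str]:
        return [pid for *_, ids in self._by_key.values() for pid in ids]

    def interval_of(self, peak_id: str) -> tuple[str, int, int, str] | None:
        for (chrom, strand), (starts, ends, ids) in self._by_key.items():
            for i, pid in enumerate(ids):
                if pid == peak_id:
                    return chrom, int(starts[i]), int(ends[i]), strand
        return None

    def match(
        self, chrom: str, strand: str, coord: int, window: int = 50, prefer: str = "upstream"
    ) -> str | None:
        """Nearest same-strand peak within ``window`` bp of ``coord``.

        Distance is 0 inside the interval, else the gap to the nearest
        boundary of the half-open interval. Ties pick the more 5' peak when
        ``prefer='upstream'`` and the more 3' peak when ``prefer='downstream'``
        (strand-aware).
        """
        key = (chrom, strand)
        if key not in self._by_key:
            return None
        starts, ends, ids = self._by_key[key]
        dist = np.where(
            coord < starts, starts - coord, np.where(coord >= ends, coord - ends, 0)
        )
        ok = np.flatnonzero(dist <= window)
        if ok.size == 0:
            return None
        best = dist[ok].min()
        cands = ok[dist[ok] == best]
        if len(cands) > 1:
            genomic_left = prefer == "upstream" if strand == "+" else prefer == "downstream"
            pick = cands[np.argmin(starts[cands])] if genomic_left else cands[np.argmax(starts[cands])]
        else:
            pick = cands[0]
        return ids[int(pick)]


def load_peaks(bed_path: str | Path, kind: str) -> PeakSet:
    """Load BED6 peaks; unsorted input is sorted, ``.`` names get positional ids."""
    if kind not in ("CAGE", "polyA"):
        raise ValueError(f"unknown peak kind {kind!r}")
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_table(bed_path, header=None, comment="#", usecols=range(6), names=cols)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=cols)
    ps = PeakSet(kind)
    if df.empty:
        return ps
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    seen: dict[str, int] = {}
    pids = []
    for row in df.itertuples():
        pid = row.name if row.name not in (".", "", None) else f"{row.chrom}:{row.start}-{row.end}:{row.strand}"
        if pid in seen:
            seen[pid] += 1
            pid = f"{pid}.{seen[pid]}"
        else:
            seen[pid] = 0
        pids.append(pid)
    df["peak_id"] = pids
    for (chrom, strand), sub in df.groupby(["chrom", "strand"], sort=True):
        ps._by_key[(chrom, strand)] = (
            sub["start"].to_numpy(int),
            sub["end"].to_numpy(int),
            list(sub["peak_id"]),
        )
    return ps


# ---------------------------------------------------------------------------
# barcodes & hierarchy


@dataclass
class CellTypeMap:
    barcode_to_type: dict[str, str]
    children: dict[str, list[str]]  # node -> ordered children; leaves absent/empty
    root: str

    def is_leaf(self, node: str) -> bool:
        return not self.children.get(node)

    def leaves(self) -> list[str]:
        return [n for n in self._all_nodes() if self.is_leaf(n)]

    def _all_nodes(self) -> list[str]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.children.get(n, [])))
        return out

    def leaves_under(self, node: str) -> list[str]:
        if self.is_leaf(node):
            return [node]
        out: list[str] = []
        for c in self.children[node]:
            out.extend(self.leaves_under(c))
        return out

    def lookup(self, barcode: str | None) -> str | None:
        if barcode is None:
            return None
        return self.barcode_to_type.get(barcode)


def _edges_from_json(obj: dict, parent: str | None, edges: list[tuple[str, str]]) -> None:
    for name, sub in obj.items():
        if parent is not None:
            edges.append((parent, name))
        if isinstance(sub, dict):
            _edges_from_json(sub, name, edges)


def load_cell_map(map_path: str | Path, hierarchy_path: str | Path) -> CellTypeMap:
    """Load barcode→cell-type TSV plus a hierarchy (edge-list TSV or nested JSON)."""
    hierarchy_path = Path(hierarchy_path)
    edges: list[tuple[str, str]] = []
    if hierarchy_path.suffix == ".json":
        tree = json.loads(hierarchy_path.read_text())
        if len(tree) != 1:
            raise AnnotationError("hierarchy JSON must have a single root")
        _edges_from_json(tree, None, edges)
        root = next(iter(tree))
    else:
        for line in hierarchy_path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AnnotationError(f"bad hierarchy edge: {line!r}")
            edges.append((parts[0], parts[1]))
        children_set = {c for _, c in edges}
        roots = sorted({p for p, _ in edges} - children_set)
        if len(roots) != 1:
            raise AnnotationError(f"hierarchy must have exactly one root, got {roots}")
        root = roots[0]

    children: dict[str, list[str]] = {}
    parent_of: dict[str, str] = {}
    for p, c in edges:
        if c in parent_of:
            raise AnnotationError(f"node {c!r} has multiple parents")
        parent_of[c] = p
        children.setdefault(p, []).append(c)
    # cycle check: walk up from every node, must terminate at root
    for node in parent_of:
        seen = {node}
        cur = node
        while cur in parent_of:
            cur = parent_of[cur]
            if cur in seen:
                raise AnnotationError("cycle in cell-type hierarchy")
            seen.add(cur)
        if cur != root:
            raise AnnotationError(f"node {node!r} not connected to root {root!r}")

    cm = CellTypeMap({}, children, root)
    leaves = set(cm.leaves())

    bmap: dict[str, str] = {}
    for line in Path(map_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise AnnotationError(f"bad barcode map line: {line!r}")
        bc, ct = parts
        if ct not in leaves:
            raise AnnotationError(f"barcode {bc} maps to non-leaf or unknown group {ct!r}")
        if bc in bmap:
            if bmap[bc] != ct:
                raise AnnotationError(f"barcode {bc} mapped to both {bmap[bc]} and {ct}")
            warnings.warn(f"duplicate barcode {bc} (same label); deduplicated", stacklevel=2)
            continue
        bmap[bc] = ct
    cm.barcode_to_type = bmap
    return cm
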