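"""Genome sequence access and splice-motif checks."""

from __future__ import annotations

from pathlib import Path

from pyfaidx import Fasta

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: dinucleotide pairs accepted as spliceosomal consensus (donor+acceptor)
CONSENSUS_MOTIFS = frozenset({"GTAG", "GCAG", "ATAC"})


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class FastaGenome:
    """Random-access genome over a FASTA file.

    Chromosomes are cached in memory as plain strings on first access (the
    synthetic genomes used here are small); ``fetch`` uses 0-based half-open
    coordinates like the rest of the package.
    """

    def __init__(self, path: str | Path):
        self._fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        self._cache: dict[str, str] = {}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fa

    def chrom_length(self, chrom: str) -> int:
        return len(self._seq(chrom))

    def _seq(self, chrom: str) -> str:
        if chrom not in self._cache:
            if chrom not in self._fa:
                raise KeyError(f"chromosome {chrom!r} not in genome")
            self._cache[chrom] = str(self._fa[chrom][:])
        return self._cache[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seq(chrom)
        if start < 0 or end > len(seq):
            raise ValueError(
                f"coordinates {chrom}:{start}-{end} outside chromosome bounds (len {len(seq)})"
            )
        return seq[start:end]


class DictGenome:
    """In-memory genome (chrom -> sequence string); handy in tests."""

    def __init__(self, seqs: dict[str, str]):
        self._seqs = {k: v.upper() for k, v in seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq):
            raise ValueError(f"coordinates {chrom}:{start}-{end} outside chromosome bounds")
        return seq[start:end]


def intron_motif(genome, chrom: str, donor: int, acceptor: int, strand: str) -> str:
    """Strand-corrected donor+acceptor dinucleotides of one intron.

    The intron occupies ``[donor, acceptor)`` in genomic coordinates. On the
    minus strand the biological donor sits at the genomic right end, so both
    dinucleotides are reverse-complemented and swapped.
    """
    left = genome.fetch(chrom, donor, donor + 2)
    right = genome.fetch(chrom, acceptor - 2, acceptor)
    if strand == "+":
        return left + right
    return revcomp(right) + revcomp(left)
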