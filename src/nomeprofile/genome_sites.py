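"""Dinucleotide site discovery and genome composition statistics.

This module locates CpG and GpC dinucleotides in a reference sequence and
computes observed/expected dinucleotide representation.  Site coordinates
follow the NOME-seq convention: the reported position of a CpG or GpC site
is the position of its cytosine on the 5'-3' strand, since the cytosine is
the base whose methylation a bisulfite readout reports.  For a "CG" match
starting at index ``i`` the site coordinate is ``i``; for a "GC" match it
is ``i + 1``.

All coordinates are 0-based.  BED output is 0-based half-open.  Soft-masked
(lowercase) bases are treated as their uppercase equivalents; ``N`` bases
never participate in a dinucleotide and are excluded from composition
denominators.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterator, Mapping
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Genome",
    "SitePositions",
    "CompositionStats",
    "GenomeError",
    "find_sites",
    "find_sites_genome",
    "dinucleotide_representation",
    "write_sites_bed",
    "read_sites_bed",
]

_ALPHABET = frozenset(b"ACGTN")
_BASES = "ACGT"


class GenomeError(ValueError):
    """Raised for malformed sequences, motifs, or degenerate composition."""


def _as_bytes(seq: str) -> np.ndarray:
    """Uppercase a sequence and return it as a uint8 array, validating the alphabet."""
    b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    if b.size and not set(np.unique(b).tobytes()) <= set(_ALPHABET):
        bad = sorted(set(np.unique(b).tobytes()) - set(_ALPHABET))
        raise GenomeError(f"sequence contains invalid characters: {bytes(bad)!r}")
    return b


class Genome(Mapping):
    """Immutable per-chromosome nucleotide sequences (A, C, G, T, N).

    Behaves as a mapping from chromosome name to uppercase sequence string.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if len(set(sequences)) != len(list(sequences)):
            raise GenomeError("duplicate chromosome names")
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            _as_bytes(seq)  # validates
            self._seqs[name] = seq.upper()

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        """Read a (multi-record, line-wrapped) FASTA file.

        The chromosome name is the first whitespace-delimited token of the
        header line.
        """
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            name = rec.id
            if name in seqs:
                raise GenomeError(f"duplicate chromosome name in FASTA: {name}")
            seqs[name] = str(rec.seq)
        return cls(seqs)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self._seqs.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)


@dataclasses.dataclass(frozen=True)
class SitePositions:
    """Sorted 0-based coordinates of one dinucleotide context on one chromosome.

    Each coordinate points at the cytosine of its dinucleotide.
    """

    chrom: str
    positions: np.ndarray
    context: str  # "CpG" or "GpC"

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise GenomeError("site positions must be strictly increasing")
        if self.context not in ("CpG", "GpC"):
            raise GenomeError(f"unknown context {self.context!r}")

    def __len__(self) -> int:
        return int(self.positions.size)

    def count_in(self, lo: int, hi: int) -> int:
        """Number of sites with lo <= position <= hi (inclusive bounds)."""
        p = self.positions
        return int(np.searchsorted(p, hi, side="right") - np.searchsorted(p, lo, side="left"))


@dataclasses.dataclass(frozen=True)
class CompositionStats:
    """Observed vs expected dinucleotide representation of a genome.

    ``observed`` is occurrences per valid (adjacent non-N) dinucleotide
    position; ``expected`` is the product of the two mononucleotide
    frequencies over non-N bases; ``ratio`` their quotient.
    """

    mono_freq: dict[str, float]
    observed: float
    expected: float
    ratio: float
    n_dinucleotide_positions: int
    n_occurrences: int


def _check_motif(motif: str) -> bytes:
    if len(motif) != 2 or not set(motif.upper()) <= set(_BASES):
        raise GenomeError(f"motif must be a 2-mer over ACGT, got {motif!r}")
    return motif.upper().encode("ascii")


def _site_offset(motif: str) -> int:
    # coordinate of the cytosine: "CG" -> first base, "GC" -> second base
    m = motif.upper()
    if m[0] == "C":
        return 0
    if m[1] == "C":
        return 1
    return 0


def find_sites(seq: str, motif: str, chrom: str = "") -> SitePositions:
    """Locate every occurrence of a dinucleotide motif in one sequence.

    Returns the coordinate of the cytosine of each match ("CG" -> match
    start, "GC" -> match start + 1).  Positions containing N never match.

    >>> find_sites("ACGT", "CG").positions.tolist()
    [1]
    """
    m = _check_motif(motif)
    b = _as_bytes(seq)
    if b.size < 2:
        idx = np.empty(0, dtype=np.int64)
    else:
        idx = np.flatnonzero((b[:-1] == m[0]) & (b[1:] == m[1])).astype(np.int64)
    context = "CpG" if motif.upper() == "CG" else ("GpC" if motif.upper() == "GC" else motif.upper())
    return SitePositions(chrom=chrom, positions=idx + _site_offset(motif), context=context)


def find_sites_genome(genome: Genome, motif: str) -> dict[str, SitePositions]:
    """Per-chromosome :func:`find_sites` over a whole genome."""
    return {chrom: find_sites(genome[chrom], motif, chrom=chrom) for chrom in genome}


def dinucleotide_representation(genome: Genome | str, motif: str) -> CompositionStats:
    """Observed and expected frequency of a dinucleotide motif.

    The expected frequency is the product of the genome's mononucleotide
    frequencies of the motif's two bases (computed over non-N bases); the
    observed frequency is the motif count divided by the number of valid
    dinucleotide positions (adjacent non-N pairs).

    Raises :class:`GenomeError` when the genome has no valid dinucleotide
    position or when the expected frequency is zero (ratio undefined).
    """
    m = _check_motif(motif)
    seqs = [genome] if isinstance(genome, str) else [genome[c] for c in genome]
    base_counts = np.zeros(4, dtype=np.int64)
    n_pairs = 0
    n_occ = 0
    for seq in seqs:
        b = _as_bytes(seq)
        for i, base in enumerate(_BASES.encode("ascii")):
            base_counts[i] += int(np.count_nonzero(b == base))
        if b.size >= 2:
            valid = (b != ord("N"))
            pair_valid = valid[:-1] & valid[1:]
            n_pairs += int(np.count_nonzero(pair_valid))
            n_occ += int(np.count_nonzero((b[:-1] == m[0]) & (b[1:] == m[1])))
    total_bases = int(base_counts.sum())
    if n_pairs == 0:
        raise GenomeError("genome has no valid dinucleotide positions")
    mono = {base: base_counts[i] / total_bases for i, base in enumerate(_BASES)}
    observed = n_occ / n_pairs
    expected = mono[chr(m[0])] * mono[chr(m[1])]
    if expected == 0:
        raise GenomeError("expected dinucleotide frequency is zero; ratio undefined")
    return CompositionStats(
        mono_freq=mono,
        observed=observed,
        expected=expected,
        ratio=observed / expected,
        n_dinucleotide_positions=n_pairs,
        n_occurrences=n_occ,
    )


def write_sites_bed(sites: SitePositions | list[SitePositions], path: str | Path) -> None:
    """Write site positions as BED3 plus a context column (0-based half-open)."""
    items = [sites] if isinstance(sites, SitePositions) else list(sites)
    with open(path, "w") as fh:
        for sp in items:
            for p in sp.positions:
                fh.write(f"{sp.chrom}\t{p}\t{p + 1}\t{sp.context}\n")


def read_sites_bed(path: str | Path) -> list[SitePositions]:
    """Read the BED3+context dialect written by :func:`write_sites_bed`."""
    rows: dict[tuple[str, str], list[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, _end, context = line.split("\t")[:4]
            rows.setdefault((chrom, context), []).append(int(start))
    return [
        SitePositions(chrom=chrom, positions=np.array(sorted(pos), dtype=np.int64), context=ctx)
        for (chrom, ctx), pos in rows.items()
    ]
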