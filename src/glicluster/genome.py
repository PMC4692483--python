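"""Genome I/O and strand-aware binding-site scanning.

Coordinates are 0-based half-open everywhere internally and in BED
output; 1-based inclusive coordinates appear only in human-readable
reports.  Soft-masked (lowercase) sequence is scanned like uppercase —
repeat handling happens at the cluster-filter stage, optionally using
the lowercase runs as a repeat interval set.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from . import _seq
from .pwm import SiteVocabulary

log = logging.getLogger(__name__)


@dataclass
class GenomeAssembly:
    """Ordered chromosome name -> sequence map; case is preserved."""

    chromosomes: dict[str, str]
    softmask_as_repeat: bool = False
    _codes: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")

    def codes(self, chrom: str) -> np.ndarray:
        """Cached int8 encoding of a chromosome (case-insensitive)."""
        if chrom not in self._codes:
            self._codes[chrom] = _seq.encode(self.chromosomes[chrom])
        return self._codes[chrom]

    def __len__(self) -> int:
        return len(self.chromosomes)


@dataclass(frozen=True, order=True)
class BindingSite:
    """A strand-aware motif hit; kmer is stored in sense orientation."""

    chrom: str
    start: int
    end: int
    strand: str
    kmer: str
    mss: float

    @property
    def width(self) -> int:
        return self.end - self.start

    def display_coords(self) -> str:
        """UCSC-style 1-based inclusive rendering for reports."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path, softmask_as_repeat: bool = False) -> GenomeAssembly:
    """Read a (plain or gzipped) FASTA into an assembly, preserving case."""
    chroms: dict[str, str] = {}
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in chroms:
                raise ValueError(f"duplicate FASTA record name: {rec.id!r}")
            chroms[rec.id] = str(rec.seq)
    if not chroms:
        raise ValueError(f"{path}: no FASTA records found")
    return GenomeAssembly(chromosomes=chroms, softmask_as_repeat=softmask_as_repeat)


def write_fasta(genome: GenomeAssembly, path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def softmask_intervals(genome: GenomeAssembly) -> list[tuple[str, int, int]]:
    """Maximal runs of lowercase (soft-masked) sequence as repeat intervals."""
    out: list[tuple[str, int, int]] = []
    for name, seq in genome.chromosomes.items():
        mask = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        low = (mask >= ord("a")) & (mask <= ord("z"))
        if not low.any():
            continue
        padded = np.concatenate([[False], low, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append((name, int(s), int(e)))
    return out


def scan_codes(
    codes: np.ndarray,
    vocab: SiteVocabulary,
    merge_strand_duplicates: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised scan of an encoded sequence.

    Returns (starts, sense_code, mss, strand_plus): per hit, the 0-based
    start, the base-4 code of the sense-orientation k-mer, the MSS, and
    whether the hit is reported on the + strand.  With
    merge_strand_duplicates (default) exact interval duplicates across
    strands collapse into one record keeping the higher-MSS orientation
    (+ on tie); otherwise both orientations are emitted.
    """
    w = vocab.width
    if len(codes) < w:
        log.warning("sequence shorter than scan width %d; no sites", w)
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, np.empty(0), np.empty(0, dtype=bool)
    idx, valid = _seq.window_indices(codes, w)
    s_mss = np.where(valid, vocab.sense_table[idx], np.nan)
    a_mss = np.where(valid, vocab.antisense_table[idx], np.nan)
    s_hit = ~np.isnan(s_mss)
    a_hit = ~np.isnan(a_mss)
    if not merge_strand_duplicates:
        s_starts = np.flatnonzero(s_hit)
        a_starts = np.flatnonzero(a_hit)
        starts = np.concatenate([s_starts, a_starts])
        order = np.argsort(starts, kind="stable")
        sense_code = np.concatenate([idx[s_starts], vocab.rc_table[idx[a_starts]]])[order]
        mss = np.concatenate([s_mss[s_starts], a_mss[a_starts]])[order]
        plus = np.concatenate([np.ones(len(s_starts), bool), np.zeros(len(a_starts), bool)])[order]
        return starts[order].astype(np.int64), sense_code.astype(np.int64), mss, plus
    any_hit = s_hit | a_hit
    starts = np.flatnonzero(any_hit)
    # dedup rule: + wins when both orientations match with equal MSS
    plus = s_hit[starts] & ~(a_hit[starts] & (a_mss[starts] > np.where(s_hit[starts], s_mss[starts], -1)))
    mss = np.where(plus, s_mss[starts], a_mss[starts])
    sense_code = np.where(plus, idx[starts], vocab.rc_table[idx[starts]])
    return starts.astype(np.int64), sense_code.astype(np.int64), mss, plus


def scan_sites(
    genome: GenomeAssembly,
    vocab: SiteVocabulary,
    merge_strand_duplicates: bool = True,
) -> list[BindingSite]:
    """Scan every chromosome; sites sorted by (chrom, start)."""
    if not vocab.sense_kmers:
        raise ValueError("empty site vocabulary")
    sites: list[BindingSite] = []
    for chrom in genome.chromosomes:
        starts, sense_code, mss, plus = scan_codes(genome.codes(chrom), vocab, merge_strand_duplicates)
        w = vocab.width
        for s, c, m, p in zip(starts, sense_code, mss, plus):
            sites.append(
                BindingSite(
                    chrom=chrom,
                    start=int(s),
                    end=int(s) + w,
                    strand="+" if p else "-",
                    kmer=_seq.index_to_kmer(int(c), w),
                    mss=float(m),
                )
            )
    return sites


def write_sites_bed(sites: list[BindingSite], path) -> None:
    """BED6: chrom, start, end, kmer, round(1000*mss), strand."""
    ordered = sorted(sites, key=lambda s: (s.chrom, s.start))
    if ordered != list(sites):
        log.warning("sites were not sorted; writing in sorted order")
    with open(path, "w") as fh:
        for s in ordered:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.kmer}\t{round(1000 * s.mss)}\t{s.strand}\n")


def read_sites_bed(path, vocab: SiteVocabulary | None = None) -> list[BindingSite]:
    """Re-read a BED6 site file; MSS from the vocabulary when given, else score/1000."""
    sites = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, 1):
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(parts)}")
            chrom, start, end, kmer, score, strand = parts[:6]
            mss = vocab.mss_of(kmer) if vocab is not None else int(score) / 1000.0
            sites.append(BindingSite(chrom, int(start), int(end), strand, kmer, mss))
    return sites
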