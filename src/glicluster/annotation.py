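"""Gene-model annotation, locus assignment, exclusion intervals and the
cross-species positional-overlap filter.

Gene models come from refFlat (UCSC dialect, transcripts as rows);
exons, repeats, CTCF boundary regions and pre-lifted cross-species
cluster intervals are plain BED interval sets.  All coordinates are
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

log = logging.getLogger(__name__)


@dataclass
class GeneModel:
    """One refFlat transcript row."""

    gene: str
    transcript: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript}: exons overlap or are unsorted")
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.transcript}: exon outside transcript bounds")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.transcript}: CDS outside transcript bounds")


def read_refflat(path) -> list[GeneModel]:
    """Parse a tab-separated refFlat file (trailing commas in exon lists OK)."""
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, 1):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) != 11:
                raise ValueError(f"{path}:{lineno}: expected 11 refFlat fields, got {len(parts)}")
            (gene, tx, chrom, strand, tx_s, tx_e, cds_s, cds_e, n_exons, ex_s, ex_e) = parts
            starts = [int(x) for x in ex_s.strip(",").split(",") if x]
            ends = [int(x) for x in ex_e.strip(",").split(",") if x]
            if len(starts) != int(n_exons) or len(ends) != int(n_exons):
                raise ValueError(f"{path}:{lineno}: exonCount {n_exons} does not match exon lists")
            models.append(
                GeneModel(
                    gene=gene,
                    transcript=tx,
                    chrom=chrom,
                    strand=strand,
                    tx_start=int(tx_s),
                    tx_end=int(tx_e),
                    cds_start=int(cds_s),
                    cds_end=int(cds_e),
                    exons=list(zip(starts, ends)),
                )
            )
    return models


def write_refflat(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            ex_s = ",".join(str(s) for s, _ in m.exons) + ","
            ex_e = ",".join(str(e) for _, e in m.exons) + ","
            fh.write(
                f"{m.gene}\t{m.transcript}\t{m.chrom}\t{m.strand}\t{m.tx_start}\t{m.tx_end}"
                f"\t{m.cds_start}\t{m.cds_end}\t{len(m.exons)}\t{ex_s}\t{ex_e}\n"
            )


@dataclass
class IntervalSet:
    """Named, sorted set of (chrom, start, end) half-open intervals."""

    name: str
    intervals: list[tuple[str, int, int]]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for c, s, e in self.intervals:
            if s >= e:
                raise ValueError(f"{self.name}: empty/inverted interval {c}:{s}-{e}")
        self.intervals = sorted(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def _tree(self, chrom: str) -> IntervalTree:
        if chrom not in self._trees:
            self._trees[chrom] = IntervalTree.from_tuples(
                (s, e) for c, s, e in self.intervals if c == chrom
            )
        return self._trees[chrom]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any interval on chrom by >= 1 bp."""
        return bool(self._tree(chrom).overlap(start, end))

    def nearest_distance(self, chrom: str, start: int, end: int) -> int | None:
        """Unsigned bp distance to the nearest interval on chrom (0 if overlapping)."""
        best = None
        for c, s, e in self.intervals:
            if c != chrom:
                continue
            if s < end and start < e:
                return 0
            d = s - end if s >= end else start - e
            if best is None or d < best:
                best = d
        return best

    def chroms(self) -> set[str]:
        return {c for c, _, _ in self.intervals}


def read_bed(path, name: str | None = None) -> IntervalSet:
    """BED3+ reader; extra columns ignored."""
    intervals = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, 1):
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return IntervalSet(name=name or str(path), intervals=intervals)


def write_bed(intervals: IntervalSet | list[tuple[str, int, int]], path) -> None:
    rows = intervals.intervals if isinstance(intervals, IntervalSet) else sorted(intervals)
    with open(path, "w") as fh:
        for c, s, e in rows:
            fh.write(f"{c}\t{s}\t{e}\n")


def exon_interval_set(models: list[GeneModel], name: str = "exons") -> IntervalSet:
    return IntervalSet(name=name, intervals=[(m.chrom, s, e) for m in models for s, e in m.exons])


@dataclass
class SiteAnnotation:
    """Nearest gene/transcript, feature label, CTCF distance, locus."""

    gene: str | None
    transcript: str | None
    distance: int | None  # signed: negative = site left of the feature, 0 = overlap
    feature: str | None  # exon | intron | upstream | downstream
    ctcf_distance: int | None = None
    locus: str | None = None


def _hull_distance(start: int, end: int, f_start: int, f_end: int) -> int:
    """Signed distance between interval hulls; 0 when overlapping,
    negative when the site lies left of the feature on the chromosome."""
    if start < f_end and f_start < end:
        return 0
    if end <= f_start:
        return -(f_start - end)
    return start - f_end


def annotate_site(
    interval: tuple[str, int, int],
    models: list[GeneModel],
    ctcf: IntervalSet | None = None,
    use_tss: bool = False,
) -> SiteAnnotation:
    """Annotate an interval with its nearest transcript, feature and CTCF distance.

    Nearest transcript by minimal unsigned hull distance — or distance to
    the transcription start site when use_tss is set — with ties broken
    by transcript name order, logged.  Feature: exon if the interval
    overlaps any exon of the nearest transcript, intron if inside the
    transcript body, else upstream/downstream relative to the transcript
    strand.
    """
    chrom, start, end = interval
    candidates = [m for m in models if m.chrom == chrom]
    if not candidates:
        log.warning("no gene models on %s; site %s:%d-%d unannotated", chrom, chrom, start, end)
        return SiteAnnotation(gene=None, transcript=None, distance=None, feature=None)

    def anchor(m: GeneModel) -> tuple[int, int]:
        if use_tss:
            tss = m.tx_start if m.strand == "+" else m.tx_end - 1
            return tss, tss + 1
        return m.tx_start, m.tx_end

    scored = sorted(
        candidates,
        key=lambda m: (abs(_hull_distance(start, end, *anchor(m))), m.transcript),
    )
    best = scored[0]
    d0 = abs(_hull_distance(start, end, *anchor(best)))
    if len(scored) > 1 and abs(_hull_distance(start, end, *anchor(scored[1]))) == d0:
        log.info("site %s:%d-%d equidistant; tie broken to transcript %s", chrom, start, end, best.transcript)
    dist = _hull_distance(start, end, *anchor(best))
    hull_dist = _hull_distance(start, end, best.tx_start, best.tx_end)
    if hull_dist == 0:
        feature = "exon" if any(start < e and s < end for s, e in best.exons) else "intron"
    else:
        left_of_gene = dist < 0
        upstream_is_left = best.strand == "+"
        feature = "upstream" if left_of_gene == upstream_is_left else "downstream"
    ctcf_d = ctcf.nearest_distance(chrom, start, end) if ctcf is not None else None
    return SiteAnnotation(gene=best.gene, transcript=best.transcript, distance=dist, feature=feature, ctcf_distance=ctcf_d)


def assign_sites_to_loci(
    sites,
    models: list[GeneModel],
    anchor_mss: float = 0.81,
) -> tuple[dict, dict[str, dict[str, int]]]:
    """Assign every site to exactly one gene locus; midpoint boundaries.

    Loci are gene-level hulls (union of a gene's transcripts per
    chromosome).  The boundary between neighbours is the midpoint of the
    gap between their hulls; a site exactly at a midpoint goes to the
    left (lower-coordinate) locus.  Sites are located by their start
    coordinate.  Returns (site -> locus name, per-locus counts with the
    count of high-scoring sites, MSS >= anchor_mss, alongside the total).
    """
    hulls: dict[tuple[str, str], list[int]] = {}
    for m in models:
        key = (m.chrom, m.gene)
        if key not in hulls:
            hulls[key] = [m.tx_start, m.tx_end]
        else:
            hulls[key][0] = min(hulls[key][0], m.tx_start)
            hulls[key][1] = max(hulls[key][1], m.tx_end)
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for (chrom, gene), (s, e) in hulls.items():
        by_chrom.setdefault(chrom, []).append((s, e, gene))
    boundaries: dict[str, tuple[list[float], list[str]]] = {}
    for chrom, loci in by_chrom.items():
        loci.sort()
        cuts = [(loci[i][1] + loci[i + 1][0]) / 2.0 for i in range(len(loci) - 1)]
        boundaries[chrom] = (cuts, [g for _, _, g in loci])
    assignment: dict = {}
    counts: dict[str, dict[str, int]] = {}
    for site in sites:
        if site.chrom not in boundaries:
            log.warning("no gene models on %s; site at %d unassigned", site.chrom, site.start)
            continue
        cuts, names = boundaries[site.chrom]
        i = 0
        while i < len(cuts) and site.start > cuts[i]:
            i += 1
        if i < len(cuts) and site.start == cuts[i]:
            log.info("site at %s:%d exactly at a locus midpoint; assigned left to %s", site.chrom, site.start, names[i])
        locus = names[i]
        assignment[site] = locus
        entry = counts.setdefault(locus, {"n_sites": 0, "n_high_mss": 0})
        entry["n_sites"] += 1
        if site.mss >= anchor_mss:
            entry["n_high_mss"] += 1
    return assignment, counts


def exclusion_overlap(cluster, exons: IntervalSet | None, repeats: IntervalSet | None) -> dict[str, bool]:
    """Per-set flag: does any member site overlap an interval by >= 1 bp?"""
    out = {}
    for name, iset in (("exon", exons), ("repeat", repeats)):
        out[name] = bool(iset) and any(iset.overlaps(s.chrom, s.start, s.end) for s in cluster.sites)
    return out


def ortholog_overlap_filter(clusters, lifted: IntervalSet):
    """Retain clusters overlapping >= 1 bp with any lifted cross-species
    cluster interval; sequence content is never compared.

    `clusters` may be Cluster objects or (chrom, start, end) tuples.
    Raises when the lifted set names chromosomes absent from the cluster
    set's assembly (likely an un-lifted or mismatched file).
    """
    def coords(c):
        return (c.chrom, c.start, c.end) if hasattr(c, "chrom") else tuple(c)

    cluster_chroms = {coords(c)[0] for c in clusters}
    unknown = lifted.chroms() - cluster_chroms if clusters else set()
    if unknown and not (lifted.chroms() & cluster_chroms):
        raise ValueError(f"lifted intervals name unknown chromosomes: {sorted(unknown)}")
    return [c for c in clusters if lifted.overlaps(*coords(c))]
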