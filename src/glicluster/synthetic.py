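"""Self-contained synthetic inputs: genomes with a controllable GC
landscape, planted binding sites and clusters, toy matrices, and
matching refFlat/BED annotation.

Everything a pipeline stage consumes can be generated here with a known
ground truth, so the whole cascade is testable without any downloads.
Backgrounds are drawn segment-by-segment with the requested GC fraction
(G and C equiprobable within the GC class, likewise A/T); planted k-mers
are written at fixed offsets; optional decoy scrubbing re-randomizes any
unplanted window that happens to match the vocabulary until the scan
recovers exactly the planted truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _seq
from .annotation import GeneModel, IntervalSet
from .genome import BindingSite, GenomeAssembly, scan_codes
from .pwm import PositionWeightMatrix, SiteVocabulary, build_pwm

log = logging.getLogger(__name__)


@dataclass
class PlantedSite:
    chrom: str
    offset: int
    kmer: str
    strand: str = "+"


@dataclass
class PlantedCluster:
    """A homotypic cluster: n_sites k-mers evenly spread over max_span bp."""

    chrom: str
    start: int
    n_sites: int
    max_span: int
    mss_range: tuple[float, float] = (0.75, 1.0)


@dataclass
class FixtureSpec:
    """Recipe for a synthetic genome with known truth.

    gc_segments: per chromosome, a list of (length, gc_fraction) pieces;
    their lengths define the chromosome length.
    """

    seed: int
    gc_segments: dict[str, list[tuple[int, float]]]
    planted_sites: list[PlantedSite] = field(default_factory=list)
    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    scrub_decoys: bool = True
    max_scrub_rounds: int = 50

    def chrom_length(self, chrom: str) -> int:
        return sum(length for length, _ in self.gc_segments[chrom])

    def validate(self) -> None:
        for chrom, segs in self.gc_segments.items():
            for length, gc in segs:
                if length <= 0 or not (0.0 <= gc <= 1.0):
                    raise ValueError(f"bad GC segment ({length}, {gc}) on {chrom}")
        for p in self.planted_sites:
            if p.offset < 0 or p.offset + len(p.kmer) > self.chrom_length(p.chrom):
                raise ValueError(f"planted site out of bounds: {p}")
        for pc in self.planted_clusters:
            if pc.start < 0 or pc.start + pc.max_span > self.chrom_length(pc.chrom):
                raise ValueError(f"planted cluster out of bounds: {pc}")


@dataclass
class FixtureTruth:
    """Ground truth emitted alongside a synthetic genome."""

    sites: list[BindingSite]
    clusters: list[tuple[str, int, int]]
    gene_models: list[GeneModel] = field(default_factory=list)
    exons: IntervalSet | None = None
    repeats: IntervalSet | None = None
    ctcf: IntervalSet | None = None
    lifted: IntervalSet | None = None


def make_toy_matrix(consensus: str, sharpness: float, name: str = "toy", civ_min: float = 70.0) -> PositionWeightMatrix:
    """PWM giving the consensus base frequency `sharpness` at each position
    and (1 - sharpness)/3 to the rest.  At sharpness 1 the vocabulary at
    min_mss 1.0 is exactly the consensus."""
    if not 0.0 < sharpness <= 1.0:
        raise ValueError("sharpness must be in (0, 1]")
    rows = np.full((len(consensus), 4), (1.0 - sharpness) / 3.0)
    for i, b in enumerate(consensus.upper()):
        rows[i, "ACGT".index(b)] = sharpness
    return build_pwm(rows, name=name, civ_min=civ_min)


def _segment_bases(segs: list[tuple[int, float]], rng: np.random.Generator) -> np.ndarray:
    parts = []
    for length, gc in segs:
        is_gc = rng.random(length) < gc
        half = rng.integers(0, 2, size=length, dtype=np.int8)
        # A=0/T=3 within AT, C=1/G=2 within GC, equiprobable
        codes = np.where(is_gc, 1 + half, np.where(half == 0, 0, 3)).astype(np.int8)
        parts.append(codes)
    return np.concatenate(parts)


def _segment_gc_at(segs: list[tuple[int, float]], pos: int) -> float:
    off = 0
    for length, gc in segs:
        if pos < off + length:
            return gc
        off += length
    raise IndexError(pos)


def _expand_clusters(spec: FixtureSpec, vocab: SiteVocabulary, rng: np.random.Generator) -> list[PlantedSite]:
    """Turn planted-cluster recipes into concrete planted sites."""
    out: list[PlantedSite] = []
    for pc in spec.planted_clusters:
        lo, hi = pc.mss_range
        pool = sorted(k for k, m in vocab.sense_kmers.items() if lo <= m <= hi)
        if not pool:
            raise ValueError(f"no vocabulary k-mer with MSS in [{lo}, {hi}]")
        gap = (pc.max_span - vocab.width) // max(pc.n_sites - 1, 1)
        if gap < vocab.width:
            raise ValueError(f"cluster {pc} too dense: sites would overlap")
        for i in range(pc.n_sites):
            kmer = pool[int(rng.integers(len(pool)))]
            strand = "+" if rng.integers(2) == 0 else "-"
            out.append(PlantedSite(pc.chrom, pc.start + i * gap, kmer, strand))
    return out


def make_genome(
    spec: FixtureSpec,
    vocab: SiteVocabulary,
) -> tuple[GenomeAssembly, FixtureTruth]:
    """Build the synthetic assembly and its ground truth.

    With scrubbing on, every unplanted window matching the vocabulary is
    re-randomized (planted bases are never touched) until a scan recovers
    exactly the planted sites; unsatisfiable specs raise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    planted = list(spec.planted_sites) + _expand_clusters(spec, vocab, rng)
    by_chrom: dict[str, list[PlantedSite]] = {}
    for p in planted:
        by_chrom.setdefault(p.chrom, []).append(p)
    chroms: dict[str, str] = {}
    truth_sites: list[BindingSite] = []
    for chrom, segs in spec.gc_segments.items():
        codes = _segment_bases(segs, rng)
        protected = np.zeros(len(codes), dtype=bool)
        for p in sorted(by_chrom.get(chrom, []), key=lambda p: p.offset):
            written = p.kmer if p.strand == "+" else _seq.reverse_complement(p.kmer)
            w = len(written)
            if protected[p.offset : p.offset + w].any():
                raise ValueError(f"planted sites overlap at {chrom}:{p.offset}")
            codes[p.offset : p.offset + w] = _seq.encode(written)
            protected[p.offset : p.offset + w] = True
            truth_sites.append(
                BindingSite(chrom, p.offset, p.offset + w, p.strand, p.kmer, vocab.mss_of(p.kmer))
            )
        if spec.scrub_decoys:
            codes = _scrub(codes, vocab, protected, segs, spec, rng, chrom)
        chroms[chrom] = _seq.decode(codes)
    truth_sites.sort(key=lambda s: (s.chrom, s.start))
    clusters = [
        (pc.chrom, pc.start, pc.start + (pc.n_sites - 1) * ((pc.max_span - vocab.width) // max(pc.n_sites - 1, 1)) + vocab.width)
        for pc in spec.planted_clusters
    ]
    genome = GenomeAssembly(chromosomes=chroms)
    _verify_truth(genome, vocab, truth_sites, spec)
    return genome, FixtureTruth(sites=truth_sites, clusters=clusters)


def _scrub(
    codes: np.ndarray,
    vocab: SiteVocabulary,
    protected: np.ndarray,
    segs: list[tuple[int, float]],
    spec: FixtureSpec,
    rng: np.random.Generator,
    chrom: str,
) -> np.ndarray:
    w = vocab.width
    planted_offsets = _planted_offsets(protected, w)
    for _round in range(spec.max_scrub_rounds):
        starts, _, _, _ = scan_codes(codes, vocab)
        decoys = [int(s) for s in starts if int(s) not in planted_offsets]
        if not decoys:
            return codes
        for s in decoys:
            for j in range(s, s + w):
                if not protected[j]:
                    gc = _segment_gc_at(segs, j)
                    if rng.random() < gc:
                        codes[j] = 1 + rng.integers(2)
                    else:
                        codes[j] = 0 if rng.integers(2) == 0 else 3
    raise ValueError(
        f"could not scrub decoy sites on {chrom} in {spec.max_scrub_rounds} rounds; "
        "lower the GC fraction or use a smaller vocabulary"
    )


def _planted_offsets(protected: np.ndarray, width: int) -> set[int]:
    """Start offsets whose whole window is protected (i.e. a planted site)."""
    if not protected.any():
        return set()
    conv = np.convolve(protected.astype(np.int64), np.ones(width, dtype=np.int64), "valid")
    return set(np.flatnonzero(conv == width).tolist())


def _verify_truth(genome: GenomeAssembly, vocab: SiteVocabulary, truth_sites: list[BindingSite], spec: FixtureSpec) -> None:
    """Brute-force check: planted windows match, and (when scrubbed) no others do."""
    planted = {(s.chrom, s.start) for s in truth_sites}
    for chrom in genome.chromosomes:
        starts, _, _, _ = scan_codes(genome.codes(chrom), vocab)
        found = {(chrom, int(s)) for s in starts}
        missing = {p for p in planted if p[0] == chrom} - found
        if missing:
            raise AssertionError(f"planted sites not recovered by scan: {sorted(missing)[:5]}")
        if spec.scrub_decoys:
            extras = found - planted
            if extras:
                raise AssertionError(f"unscrubbed decoy sites remain: {sorted(extras)[:5]}")


def make_annotation(
    spec: FixtureSpec,
    genome: GenomeAssembly,
    truth: FixtureTruth,
    genes_per_chrom: int = 4,
    exon_cluster_index: int | None = 0,
    repeat_cluster_index: int | None = 1,
    lifted_cluster_indices: tuple[int, ...] | None = None,
) -> FixtureTruth:
    """Attach toy annotation exercising every filter branch.

    Genes are tiled evenly across each chromosome.  By default the first
    planted cluster gets an exon overlapping one of its sites, the
    second gets a repeat, later ones stay clean; the lifted set covers
    all planted clusters unless indices are given.
    """
    models: list[GeneModel] = []
    for chrom, seq in genome.chromosomes.items():
        L = len(seq)
        slot = L // genes_per_chrom
        for g in range(genes_per_chrom):
            tx_s = g * slot + slot // 10
            tx_e = g * slot + (9 * slot) // 10
            mid = (tx_s + tx_e) // 2
            exons = [(tx_s, tx_s + slot // 10), (mid, mid + slot // 10), (tx_e - slot // 10, tx_e)]
            models.append(
                GeneModel(
                    gene=f"{chrom}_gene{g}",
                    transcript=f"{chrom}_tx{g}.1",
                    chrom=chrom,
                    strand="+" if g % 2 == 0 else "-",
                    tx_start=tx_s,
                    tx_end=tx_e,
                    cds_start=tx_s,
                    cds_end=tx_e,
                    exons=exons,
                )
            )
    exon_ivs = [(m.chrom, s, e) for m in models for s, e in m.exons]
    repeat_ivs: list[tuple[str, int, int]] = []
    lifted_ivs: list[tuple[str, int, int]] = []
    ctcf_ivs: list[tuple[str, int, int]] = []
    for i, (chrom, c_start, c_end) in enumerate(truth.clusters):
        first_site = next(s for s in truth.sites if s.chrom == chrom and s.start >= c_start)
        if exon_cluster_index is not None and i == exon_cluster_index:
            exon_ivs.append((chrom, first_site.start, first_site.end + 10))
        if repeat_cluster_index is not None and i == repeat_cluster_index:
            repeat_ivs.append((chrom, first_site.start - 5, first_site.start + 4))
        if lifted_cluster_indices is None or i in lifted_cluster_indices:
            lifted_ivs.append((chrom, max(0, c_start - 20), c_end + 20))
        ctcf_ivs.append((chrom, max(0, c_start - 2000), max(1, c_start - 1900)))
    truth.gene_models = models
    truth.exons = IntervalSet("exons", exon_ivs)
    truth.repeats = IntervalSet("repeats", repeat_ivs) if repeat_ivs else IntervalSet("repeats", [])
    truth.ctcf = IntervalSet("ctcf", ctcf_ivs)
    truth.lifted = IntervalSet("lifted", lifted_ivs)
    return truth


def default_fixture_spec(seed: int = 0, chrom_length: int = 100_000) -> FixtureSpec:
    """Three planted 4-5 site clusters on one 100 kb chromosome with a
    two-level GC landscape; used by the end-to-end tests and examples."""
    half = chrom_length // 2
    return FixtureSpec(
        seed=seed,
        gc_segments={"chrS": [(half, 0.35), (chrom_length - half, 0.55)]},
        planted_clusters=[
            PlantedCluster("chrS", chrom_length // 10, 4, 800, (0.75, 1.0)),
            PlantedCluster("chrS", (2 * chrom_length) // 5, 4, 800, (0.75, 1.0)),
            PlantedCluster("chrS", (3 * chrom_length) // 4, 5, 800, (0.85, 1.0)),
        ],
    )
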