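"""Randomized background genomes and composition-corrected site ensembles.

Three randomization models estimate how often motif sites occur by
chance:

* ``random`` — every base redrawn uniformly from ACGT; destroys the GC
  landscape entirely.
* ``shuffle3mer`` — the sequence is parsed into contiguous non-overlapping
  3-mers which are then shuffled; preserves mono-nucleotide (and coarse
  tri-nucleotide) composition globally but homogenizes it locally.
* ``flip_gc_at`` — every base is independently replaced by itself or its
  complement with probability 1/2; the GC/AT identity of every single
  position, hence the GC content of every window, is preserved exactly.

Because a GC-rich motif occurs by chance more often in GC-rich sequence,
only the flip model gives an unbiased local expectation.  Flipping still
yields fewer motif hits than the native chromosome, so backgrounds are
composition-corrected: sites found across many raw replicates are pooled
per k-mer, and replicate site maps are rebuilt by sampling positions from
the pools so that every replicate carries exactly the native chromosome's
per-k-mer site counts.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from . import _seq
from .genome import BindingSite, GenomeAssembly, scan_codes
from .pwm import SiteVocabulary

log = logging.getLogger(__name__)

BACKGROUND_MODELS = ("random", "shuffle3mer", "flip_gc_at")


# ---------------------------------------------------------------------------
# sequence randomizers


def _require_codes(seq: str | np.ndarray) -> tuple[np.ndarray, bool]:
    if isinstance(seq, str):
        return _seq.encode(seq), True
    return np.asarray(seq, dtype=np.int8), False


def bg_random(seq: str | np.ndarray, rng: np.random.Generator) -> str | np.ndarray:
    """Model 1: every non-N base redrawn uniformly from ACGT; N kept in place."""
    codes, was_str = _require_codes(seq)
    out = rng.integers(0, 4, size=len(codes), dtype=np.int8)
    out[codes == _seq.N_CODE] = _seq.N_CODE
    return _seq.decode(out) if was_str else out


def bg_shuffle3mer(seq: str | np.ndarray, rng: np.random.Generator) -> str | np.ndarray:
    """Model 2: contiguous non-overlapping 3-mer blocks shuffled.

    A trailing remainder of 1-2 bases stays in place.
    """
    codes, was_str = _require_codes(seq)
    n_blocks = len(codes) // 3
    out = codes.copy()
    if n_blocks > 1:
        blocks = codes[: 3 * n_blocks].reshape(n_blocks, 3)
        out[: 3 * n_blocks] = blocks[rng.permutation(n_blocks)].reshape(-1)
    return _seq.decode(out) if was_str else out


def bg_flip_gc_at(seq: str | np.ndarray, rng: np.random.Generator) -> str | np.ndarray:
    """Model 3: each base independently kept or complemented (p = 1/2 each).

    G<->C and A<->T swaps preserve the GC identity of every position, so
    the GC content of every window of every width is exactly that of the
    input.  N preserved.
    """
    codes, was_str = _require_codes(seq)
    flip = rng.integers(0, 2, size=len(codes), dtype=np.int8).astype(bool)
    out = codes.copy()
    sel = flip & (codes != _seq.N_CODE)
    out[sel] = 3 - codes[sel]
    return _seq.decode(out) if was_str else out


_MODEL_FUNCS = {"random": bg_random, "shuffle3mer": bg_shuffle3mer, "flip_gc_at": bg_flip_gc_at}


def background_model(name: str):
    if name not in _MODEL_FUNCS:
        raise ValueError(f"unknown background model {name!r}; choose from {BACKGROUND_MODELS}")
    return _MODEL_FUNCS[name]


# ---------------------------------------------------------------------------
# flank GC profiling


@dataclass
class GCProfile:
    """Per-site flank GC fractions (site bases excluded) with summary stats."""

    fractions: np.ndarray
    flank: int
    n_excluded: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.fractions)) if len(self.fractions) else float("nan")

    @property
    def sem(self) -> float:
        if len(self.fractions) < 2:
            return float("nan")
        return float(np.std(self.fractions, ddof=1) / np.sqrt(len(self.fractions)))

    def binned(self, n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        counts, edges = np.histogram(self.fractions, bins=n_bins, range=(0.0, 1.0))
        return counts, edges

    def write_tsv(self, path) -> None:
        """Per-site flank GC fractions plus a summary row."""
        with open(path, "w") as fh:
            fh.write("record\tgc_fraction\n")
            for i, f in enumerate(self.fractions):
                fh.write(f"site_{i}\t{f:.6f}\n")
            fh.write(f"mean\t{self.mean:.6f}\n")
            fh.write(f"sem\t{self.sem:.6f}\n")
            fh.write(f"n_excluded\t{self.n_excluded}\n")


def gc_context_profile(
    sites: list[BindingSite] | np.ndarray,
    seq: str | np.ndarray,
    flank: int = 50,
    width: int | None = None,
) -> GCProfile:
    """GC fraction of the `flank` bp on each side of every site.

    `sites` is either BindingSite records or an array of start offsets
    (then `width` is required).  Sites without a full flank on both sides
    are excluded and counted.
    """
    codes, _ = _require_codes(seq)
    if isinstance(sites, np.ndarray) or (sites and isinstance(sites[0], (int, np.integer))):
        starts = np.asarray(sites, dtype=np.int64)
        if width is None:
            raise ValueError("width is required when sites are bare offsets")
        ends = starts + width
    else:
        starts = np.array([s.start for s in sites], dtype=np.int64)
        ends = np.array([s.end for s in sites], dtype=np.int64)
    is_gc = ((codes == 1) | (codes == 2)).astype(np.float64)
    cum = np.concatenate([[0.0], np.cumsum(is_gc)])
    ok = (starts >= flank) & (ends + flank <= len(codes))
    n_excluded = int((~ok).sum())
    s, e = starts[ok], ends[ok]
    gc = (cum[s] - cum[s - flank]) + (cum[e + flank] - cum[e])
    return GCProfile(fractions=gc / (2.0 * flank), flank=flank, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# site pools and composition-corrected ensembles


@dataclass
class SitePool:
    """Pooled background site positions for one chromosome.

    positions[k-mer code] holds every start coordinate at which that
    (sense-orientation) k-mer was found across the raw replicates,
    duplicates retained.  replicate_totals supports the raw-count vs
    native-count comparison.
    """

    chrom: str
    width: int
    model: str
    n_raw: int
    positions: dict[int, np.ndarray]
    replicate_totals: np.ndarray
    mss_by_code: dict[int, float]

    @property
    def total(self) -> int:
        return int(sum(len(v) for v in self.positions.values()))


def build_site_pool(
    seq: str | np.ndarray,
    vocab: SiteVocabulary,
    model: str,
    rng: np.random.Generator,
    n_raw: int = 1000,
    chrom: str = "chr",
    dedupe_positions: bool = False,
) -> SitePool:
    """Generate `n_raw` randomized sequences, scan each, pool all hits.

    By default a coordinate hit in several replicates appears several
    times in the pool (sampling is uniform over pool entries);
    dedupe_positions collapses each k-mer's pool to distinct coordinates.
    """
    randomize = background_model(model)
    codes, _ = _require_codes(seq)
    pooled: dict[int, list[np.ndarray]] = defaultdict(list)
    totals = np.zeros(n_raw, dtype=np.int64)
    mss_by_code: dict[int, float] = {}
    for r in range(n_raw):
        bg = randomize(codes, rng)
        starts, sense_code, mss, _ = scan_codes(bg, vocab)
        totals[r] = len(starts)
        for code in np.unique(sense_code):
            pooled[int(code)].append(starts[sense_code == code])
            mss_by_code.setdefault(int(code), float(mss[sense_code == code][0]))
    positions = {c: np.concatenate(v) for c, v in pooled.items()}
    if dedupe_positions:
        positions = {c: np.unique(v) for c, v in positions.items()}
    if not positions:
        log.warning("background pool for %s is empty: no vocabulary k-mer ever occurred", chrom)
    return SitePool(
        chrom=chrom,
        width=vocab.width,
        model=model,
        n_raw=n_raw,
        positions=positions,
        replicate_totals=totals,
        mss_by_code=mss_by_code,
    )


class CompositionError(RuntimeError):
    """Pool cannot supply the native composition even via the MSS-class fallback."""


@dataclass
class BackgroundEnsemble:
    """Composition-corrected background site maps for one chromosome.

    Every replicate holds exactly the native chromosome's per-k-mer site
    counts, at positions drawn from the background pool.
    """

    chrom: str
    width: int
    n_replicates: int
    replicate_starts: list[np.ndarray]
    replicate_codes: list[np.ndarray]
    native_composition: dict[int, int]
    provenance: str = ""
    seed: int | None = None
    _sorted: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len(self.replicate_starts) != self.n_replicates:
            raise ValueError("replicate count mismatch")
        self._sorted = [np.sort(s) for s in self.replicate_starts]

    def counts_in(self, start: int, end: int) -> np.ndarray:
        """Per-replicate count of sites fully contained in [start, end)."""
        lo, hi = start, end - self.width
        if hi < lo:
            return np.zeros(self.n_replicates, dtype=np.int64)
        return np.array(
            [np.searchsorted(s, hi, "right") - np.searchsorted(s, lo, "left") for s in self._sorted],
            dtype=np.int64,
        )

    def expected_count(self, start: int, end: int) -> float:
        return float(self.counts_in(start, end).mean())

    def composition_by_kmer(self) -> dict[str, int]:
        return {_seq.index_to_kmer(c, self.width): n for c, n in self.native_composition.items()}

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("replicate\tchrom\tstart\tend\tkmer\n")
            for r, (starts, codes) in enumerate(zip(self.replicate_starts, self.replicate_codes)):
                order = np.argsort(starts)
                for s, c in zip(starts[order], codes[order]):
                    fh.write(f"{r}\t{self.chrom}\t{s}\t{s + self.width}\t{_seq.index_to_kmer(int(c), self.width)}\n")


def read_ensemble_tsv(path) -> BackgroundEnsemble:
    """Re-load an ensemble written by BackgroundEnsemble.write_tsv."""
    reps: dict[int, list[tuple[int, int]]] = {}
    chrom = None
    width = None
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("replicate\t"):
            raise ValueError(f"{path}: not an ensemble TSV")
        for ln in fh:
            r, c, s, e, kmer = ln.rstrip("\n").split("\t")
            chrom = c
            width = len(kmer)
            reps.setdefault(int(r), []).append((int(s), _seq.kmer_to_index(kmer)))
    if chrom is None:
        raise ValueError(f"{path}: empty ensemble")
    n = max(reps) + 1
    starts = [np.array([s for s, _ in reps.get(r, [])], dtype=np.int64) for r in range(n)]
    codes = [np.array([c for _, c in reps.get(r, [])], dtype=np.int64) for r in range(n)]
    comp: dict[int, int] = defaultdict(int)
    for c in codes[0]:
        comp[int(c)] += 1
    return BackgroundEnsemble(
        chrom=chrom, width=width, n_replicates=n,
        replicate_starts=starts, replicate_codes=codes,
        native_composition=dict(comp), provenance=f"loaded from {path}",
    )


def native_composition(sites: list[BindingSite], chrom: str) -> dict[int, int]:
    """Per-k-mer (sense orientation) site counts of one native chromosome."""
    comp: dict[int, int] = defaultdict(int)
    for s in sites:
        if s.chrom == chrom:
            comp[_seq.kmer_to_index(s.kmer)] += 1
    return dict(comp)


def reconstruct_backgrounds(
    pool: SitePool,
    native: dict[int, int] | list[BindingSite],
    rng: np.random.Generator,
    n: int = 100,
    max_attempts: int = 1000,
) -> BackgroundEnsemble:
    """Rebuild `n` background site maps matching the native composition exactly.

    For each k-mer, each replicate draws exactly the native count of
    positions from that k-mer's pool without replacement; coordinate
    collisions within a replicate are resolved by drawing further pool
    entries.  A k-mer whose pool cannot supply enough distinct positions
    falls back to the pool of the same MSS class (MSS rounded to 0.01,
    logged); if that still cannot supply the count, a hard error advises
    a larger raw-replicate number.
    """
    if not isinstance(native, dict):
        chroms = {s.chrom for s in native}
        if len(chroms) > 1:
            raise ValueError("native sites span multiple chromosomes; pass one chromosome")
        native = native_composition(native, pool.chrom if pool.chrom in chroms else next(iter(chroms)))
    class_pools: dict[int, np.ndarray] = {}

    def mss_class_pool(code: int) -> np.ndarray:
        cls = round(pool.mss_by_code.get(code, -1.0) * 100)
        if cls not in class_pools:
            members = [p for c, p in pool.positions.items() if round(pool.mss_by_code[c] * 100) == cls]
            class_pools[cls] = np.concatenate(members) if members else np.empty(0, dtype=np.int64)
        return class_pools[cls]

    replicate_starts: list[np.ndarray] = []
    replicate_codes: list[np.ndarray] = []
    for _ in range(n):
        used: set[int] = set()
        starts: list[int] = []
        codes_out: list[int] = []
        for code in sorted(native):
            need = native[code]
            taken = _draw_unique(pool.positions.get(code, np.empty(0, dtype=np.int64)), need, used, rng)
            if len(taken) < need:
                fallback = mss_class_pool(code)
                log.warning(
                    "pool exhausted for k-mer %s (need %d, got %d); falling back to MSS-class pool",
                    _seq.index_to_kmer(code, pool.width),
                    need,
                    len(taken),
                )
                taken.extend(_draw_unique(fallback, need - len(taken), used, rng, exclude=set(taken) | used))
            if len(taken) < need:
                raise CompositionError(
                    f"cannot place {need} sites for k-mer "
                    f"{_seq.index_to_kmer(code, pool.width)}: pool too small; "
                    f"increase the raw replicate count (n_raw={pool.n_raw})"
                )
            used.update(taken)
            starts.extend(taken)
            codes_out.extend([code] * need)
        replicate_starts.append(np.array(starts, dtype=np.int64))
        replicate_codes.append(np.array(codes_out, dtype=np.int64))
    return BackgroundEnsemble(
        chrom=pool.chrom,
        width=pool.width,
        n_replicates=n,
        replicate_starts=replicate_starts,
        replicate_codes=replicate_codes,
        native_composition=dict(native),
        provenance=f"model={pool.model} n_raw={pool.n_raw}",
    )


def _draw_unique(
    candidates: np.ndarray,
    need: int,
    used: set[int],
    rng: np.random.Generator,
    exclude: set[int] | None = None,
) -> list[int]:
    """Draw up to `need` distinct positions not in `used` by scanning a
    random permutation of the pool (uniform sampling of pool entries
    without replacement, with collision rejection)."""
    if need <= 0 or len(candidates) == 0:
        return []
    avoid = used if exclude is None else exclude
    taken: list[int] = []
    seen: set[int] = set()
    for i in rng.permutation(len(candidates)):
        p = int(candidates[i])
        if p in avoid or p in seen:
            continue
        taken.append(p)
        seen.add(p)
        if len(taken) == need:
            break
    return taken


def build_ensembles(
    genome: GenomeAssembly,
    sites: list[BindingSite],
    vocab: SiteVocabulary,
    rng: np.random.Generator,
    model: str = "flip_gc_at",
    n_raw: int = 1000,
    n_replicates: int = 100,
) -> dict[str, BackgroundEnsemble]:
    """Per-chromosome composition-corrected ensembles for a whole assembly."""
    ensembles: dict[str, BackgroundEnsemble] = {}
    for chrom in genome.chromosomes:
        comp = native_composition(sites, chrom)
        pool = build_site_pool(genome.codes(chrom), vocab, model, rng, n_raw=n_raw, chrom=chrom)
        ensembles[chrom] = reconstruct_backgrounds(pool, comp, rng, n=n_replicates)
    return ensembles
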