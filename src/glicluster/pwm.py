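"""Position weight matrix model of the Ci/Gli binding preference.

The transcription factor's binding preference is a mono-nucleotide
frequency matrix.  Each position carries a consensus index value (CIV)
between 0 (uniform, uninformative) and 100 (strict single-base
preference); the contiguous run of high-CIV positions forms the scoring
core.  A candidate sequence is scored by matrix similarity (MSS): the
CIV-weighted sum of its base frequencies divided by the same sum for the
consensus, so the consensus scores exactly 1.

The thresholded site vocabulary is the exhaustive set of core-width
k-mers with MSS above a cutoff that also carry concordant C/C or G/G
bases at two positions critical for binding, plus their reverse
complements for antisense matching.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import (
    BASES,
    index_to_kmer,
    kmer_to_index,
    rc_index_table,
    reverse_complement,
)

log = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

MAX_ENUM_WIDTH = 12


class MatrixError(ValueError):
    """Raised for malformed or invalid matrix input."""


@dataclass
class PositionWeightMatrix:
    """Per-position base frequencies with CIV and core-position metadata.

    rows[i, b] is the relative frequency of base BASES[b] at position i.
    core_positions are the contiguous 0-based indices used for scoring;
    consensus is the argmax base at each core position.
    """

    name: str
    rows: np.ndarray
    civ: np.ndarray
    core_positions: np.ndarray
    consensus: str

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != 4:
            raise MatrixError("matrix rows must have shape (L, 4)")
        if not np.allclose(self.rows.sum(axis=1), 1.0, atol=1e-6):
            raise MatrixError("each frequency row must sum to 1")
        self.civ = np.asarray(self.civ, dtype=float)
        if np.any(self.civ < -1e-9) or np.any(self.civ > 100 + 1e-9):
            raise MatrixError("CIV values must lie in [0, 100]")
        self.core_positions = np.asarray(self.core_positions, dtype=int)
        if len(self.consensus) != len(self.core_positions):
            raise MatrixError("consensus length must equal core width")
        if len(self.core_positions) and np.any(np.diff(self.core_positions) != 1):
            raise MatrixError("core positions must be contiguous ascending")

    @property
    def length(self) -> int:
        return self.rows.shape[0]

    @property
    def core_width(self) -> int:
        return len(self.core_positions)


def compute_civ(rows: np.ndarray, alphabet_size: int = 4) -> np.ndarray:
    """Consensus index values per position, 0 (uniform) to 100 (degenerate).

    ci(i) = (100 / ln A) * sum_b f(i,b) * ln(A * f(i,b)) with 0*ln 0 := 0,
    A the alphabet size (4 by default; 5 for the gap-inclusive variant).
    This is the relative-entropy-to-uniform normalisation: exactly 0 at a
    uniform row and exactly 100 when one base has frequency 1.
    """
    rows = np.asarray(rows, dtype=float)
    if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-6):
        raise MatrixError("each frequency row must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rows > 0, rows * np.log(alphabet_size * rows), 0.0)
    civ = (100.0 / math.log(alphabet_size)) * terms.sum(axis=1)
    return np.clip(civ, 0.0, 100.0)


def select_core_positions(civ: np.ndarray, civ_min: float = 70.0) -> np.ndarray:
    """Leftmost maximal contiguous run of positions with CIV > civ_min.

    The run length becomes the scan width.  Raises if no position is
    informative enough.
    """
    civ = np.asarray(civ, dtype=float)
    above = civ > civ_min
    if not above.any():
        raise MatrixError(f"no informative core: no position has CIV > {civ_min}")
    best_start, best_len = 0, 0
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    return np.arange(best_start, best_start + best_len)


def _consensus_from_rows(rows: np.ndarray, positions: np.ndarray) -> str:
    out = []
    for p in positions:
        row = rows[p]
        b = int(np.argmax(row))  # argmax returns first max: alphabetical tie-break
        if (row == row[b]).sum() > 1:
            log.info("consensus tie at position %d resolved alphabetically to %s", p, BASES[b])
        out.append(BASES[b])
    return "".join(out)


def build_pwm(
    rows: np.ndarray,
    name: str = "pwm",
    civ_min: float = 70.0,
    alphabet_size: int = 4,
) -> PositionWeightMatrix:
    """Assemble a PWM from frequency rows: CIV, core run, consensus."""
    rows = np.asarray(rows, dtype=float)
    civ = compute_civ(rows, alphabet_size=alphabet_size)
    core = select_core_positions(civ, civ_min=civ_min)
    consensus = _consensus_from_rows(rows, core)
    return PositionWeightMatrix(name=name, rows=rows, civ=civ, core_positions=core, consensus=consensus)


def load_matrix(
    path,
    format: str = "counts",
    civ_min: float = 70.0,
    alphabet_size: int = 4,
) -> PositionWeightMatrix:
    """Load a TRANSFAC-like (P0 header) or JASPAR PFM matrix file.

    format='counts' normalises each row to frequencies; 'frequencies'
    validates rows as already normalised.
    """
    if format not in ("counts", "frequencies"):
        raise ValueError(f"format must be 'counts' or 'frequencies', got {format!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    stripped = [ln.strip() for ln in lines if ln.strip()]
    if not stripped:
        raise MatrixError(f"{path}: empty matrix file")
    if any(ln.split()[0].upper() == "P0" for ln in stripped):
        name, raw = _parse_transfac(lines, path)
    else:
        name, raw = _parse_jaspar(lines, path)
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise MatrixError(f"{path}: negative matrix entries")
    sums = raw.sum(axis=1)
    if np.any(sums <= 0):
        bad = int(np.where(sums <= 0)[0][0]) + 1
        raise MatrixError(f"{path}: all-zero frequency row at matrix position {bad}")
    rows = raw / sums[:, None]
    if format == "frequencies" and not np.allclose(sums, 1.0, atol=1e-3):
        raise MatrixError(f"{path}: rows do not sum to 1 but format='frequencies'")
    return build_pwm(rows, name=name, civ_min=civ_min, alphabet_size=alphabet_size)


def _parse_transfac(lines: list[str], path) -> tuple[str, list[list[float]]]:
    """TRANSFAC dialect: NA/ID name, 'P0  A  C  G  T' header, numbered rows."""
    name = "matrix"
    order = None
    raw: list[list[float]] = []
    for lineno, ln in enumerate(lines, 1):
        s = ln.strip()
        if not s or s.startswith(("XX", "//")):
            continue
        parts = s.split()
        tag = parts[0].upper()
        if tag in ("NA", "ID", "DE"):
            if len(parts) > 1:
                name = parts[1]
            continue
        if tag == "P0" or tag == "PO":
            cols = [p.upper() for p in parts[1:5]]
            if sorted(cols) != list("ACGT"):
                raise MatrixError(f"{path}:{lineno}: P0 header must name columns A C G T")
            order = [cols.index(b) for b in BASES]
            continue
        if order is not None and parts[0][0].isdigit():
            try:
                vals = [float(v) for v in parts[1:5]]
            except ValueError as e:
                raise MatrixError(f"{path}:{lineno}: unparseable matrix row: {s!r}") from e
            if len(vals) != 4:
                raise MatrixError(f"{path}:{lineno}: expected 4 values, got {len(vals)}")
            raw.append([vals[j] for j in order])
    if not raw:
        raise MatrixError(f"{path}: no matrix rows found after P0 header")
    return name, raw


def _parse_jaspar(lines: list[str], path) -> tuple[str, list[list[float]]]:
    """JASPAR PFM dialect: optional '>' header then 4 base rows (A,C,G,T)."""
    name = "matrix"
    base_rows: dict[str, list[float]] = {}
    row_order = iter(BASES)
    for lineno, ln in enumerate(lines, 1):
        s = ln.strip()
        if not s:
            continue
        if s.startswith(">"):
            name = s[1:].split()[0] if s[1:].split() else name
            continue
        body = s.replace("[", " ").replace("]", " ")
        parts = body.split()
        if parts and parts[0].upper() in _BASE_INDEX and not _is_number(parts[0]):
            base = parts[0].upper()
            vals = parts[1:]
        else:
            try:
                base = next(row_order)
            except StopIteration as e:
                raise MatrixError(f"{path}:{lineno}: more than 4 matrix rows") from e
            vals = parts
        try:
            base_rows[base] = [float(v) for v in vals]
        except ValueError as e:
            raise MatrixError(f"{path}:{lineno}: unparseable matrix row: {s!r}") from e
    if sorted(base_rows) != list("ACGT"):
        raise MatrixError(f"{path}: expected one row per base A, C, G, T")
    lengths = {len(v) for v in base_rows.values()}
    if len(lengths) != 1:
        raise MatrixError(f"{path}: base rows have unequal lengths {sorted(lengths)}")
    ncol = lengths.pop()
    return name, [[base_rows[b][i] for b in BASES] for i in range(ncol)]


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _core_weights(pwm: PositionWeightMatrix) -> tuple[np.ndarray, float]:
    """(civ-weighted frequency table over core positions, consensus score)."""
    core = pwm.core_positions
    weights = pwm.civ[core][:, None] * pwm.rows[core]  # (w, 4)
    denom = float(weights.max(axis=1).sum())
    if denom <= 0:
        raise MatrixError("degenerate matrix: consensus score is zero")
    return weights, denom


def mss_score(seq: str, pwm: PositionWeightMatrix) -> float:
    """Matrix similarity score of a core-width sequence, in [0, 1].

    MSS = sum_i civ(i) f(i, seq_i) / sum_i civ(i) f(i, consensus_i); the
    consensus scores exactly 1.  Sequences containing non-ACGT characters
    are rejected — callers must pre-filter N windows.
    """
    w = pwm.core_width
    if len(seq) != w:
        raise ValueError(f"sequence length {len(seq)} != core width {w}")
    weights, denom = _core_weights(pwm)
    num = 0.0
    for i, ch in enumerate(seq.upper()):
        b = _BASE_INDEX.get(ch)
        if b is None:
            raise ValueError(f"cannot score base {ch!r}; only A/C/G/T allowed")
        num += weights[i, b]
    return num / denom


@dataclass
class SiteVocabulary:
    """Thresholded k-mer vocabulary for both strands.

    sense_kmers maps each passing k-mer to its MSS; antisense_kmers maps
    the reverse complement of each sense k-mer to the sense k-mer's MSS.
    Lookup tables indexed by base-4 k-mer code (NaN = absent) support the
    vectorised genome scanner.
    """

    width: int
    min_mss: float
    concordance_positions: tuple[int, int]
    sense_kmers: dict[str, float]
    antisense_kmers: dict[str, float]
    sense_table: np.ndarray = field(repr=False)
    antisense_table: np.ndarray = field(repr=False)
    rc_table: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.sense_kmers)

    def mss_of(self, kmer: str) -> float:
        """MSS of a sense-orientation vocabulary k-mer."""
        return self.sense_kmers[kmer]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\tstrand_class\tmss\n")
            for k in sorted(self.sense_kmers):
                fh.write(f"{k}\tsense\t{self.sense_kmers[k]:.6f}\n")
            for k in sorted(self.antisense_kmers):
                fh.write(f"{k}\tantisense\t{self.antisense_kmers[k]:.6f}\n")


def enumerate_vocabulary(
    pwm: PositionWeightMatrix,
    min_mss: float = 0.75,
    concordance_positions: tuple[int, int] = (4, 6),
    require_concordance: bool = True,
) -> SiteVocabulary:
    """All core-width k-mers with MSS >= min_mss and concordant C/C or G/G
    bases at the configured (1-based, within-core) positions, plus exact
    reverse complements carrying the sense partner's MSS.
    """
    w = pwm.core_width
    if w > MAX_ENUM_WIDTH:
        raise MatrixError(f"refusing to enumerate 4^{w} k-mers (cap is width {MAX_ENUM_WIDTH})")
    weights, denom = _core_weights(pwm)
    n = 4**w
    # digits[:, j] = base code at position j for every k-mer index
    idx = np.arange(n, dtype=np.int64)
    mss = np.zeros(n)
    for j in range(w):
        digit = (idx >> (2 * (w - 1 - j))) & 3
        mss += weights[j, digit]
    mss /= denom
    keep = mss >= min_mss
    if require_concordance:
        p1, p2 = concordance_positions
        if not (1 <= p1 <= w and 1 <= p2 <= w):
            raise ValueError("concordance positions must lie within the core")
        d1 = (idx >> (2 * (w - p1))) & 3
        d2 = (idx >> (2 * (w - p2))) & 3
        concordant = ((d1 == 1) & (d2 == 1)) | ((d1 == 2) & (d2 == 2))  # C/C or G/G
        keep &= concordant
    sense_idx = np.where(keep)[0]
    rc = rc_index_table(w)
    sense_table = np.full(n, np.nan)
    sense_table[sense_idx] = mss[sense_idx]
    antisense_table = np.full(n, np.nan)
    antisense_table[rc[sense_idx]] = mss[sense_idx]
    sense_kmers = {index_to_kmer(int(i), w): float(mss[i]) for i in sense_idx}
    antisense_kmers = {reverse_complement(k): v for k, v in sense_kmers.items()}
    n_palindromic = sum(1 for k in sense_kmers if reverse_complement(k) == k)
    if n_palindromic:
        log.info("%d vocabulary k-mer(s) are their own reverse complement", n_palindromic)
    return SiteVocabulary(
        width=w,
        min_mss=min_mss,
        concordance_positions=concordance_positions,
        sense_kmers=sense_kmers,
        antisense_kmers=antisense_kmers,
        sense_table=sense_table,
        antisense_table=antisense_table,
        rc_table=rc,
    )


def consensus_gc_percent(pwm_or_kmer) -> float:
    """GC content of a consensus site, as the percentage the reports print."""
    kmer = pwm_or_kmer.consensus if isinstance(pwm_or_kmer, PositionWeightMatrix) else pwm_or_kmer
    gc = sum(1 for c in kmer.upper() if c in "GC")
    return round(100.0 * gc / len(kmer))
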