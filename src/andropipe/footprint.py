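"""Conserved response-element prediction (phylogenetic footprinting).

Promoter windows anchored at the TSS (default -10000..+2000, gene orientation)
are scanned on both strands with position-weight matrices in TRANSFAC flat
format, scored with MATCH-style core (CSS) and matrix (MSS) similarity:

    I(i)   = sum_b f(i,b) * ln(4 f(i,b))          (information vector)
    Current = sum_i I(i) * f(i, s_i)
    MSS    = (Current - Min) / (Max - Min)

with Min/Max the scores of the anti-consensus/consensus; CSS is the same
restricted to the core, the 5 consecutive most informative positions.  Hits
passing both cutoffs are filtered on mean per-base cross-species conservation,
binned by TSS-relative position, and combined with compartment calls to name
candidate direct androgen targets (somatic, responsive, conserved proximal
hit).

Coordinates are 0-based half-open internally; TSS-relative positions are in
gene orientation (upstream negative), and on minus-strand genes upstream means
larger genomic coordinates.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidInputError, ParseError

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: TSS-relative bin edges (half-open [lo, hi)) and their report labels
BIN_EDGES = (-10000, -5000, -2000, -1000, 0, 200, 400, 1000, 2000)
BIN_LABELS = (
    "-10000/-5000",
    "-5000/-2000",
    "-2000/-1000",
    "-1000/0",
    "0/+200",
    "+200/+400",
    "+400/+1000",
    "+1000/+2000",
)
PROXIMAL_WINDOW = (-2000, 400)
DEFAULT_WINDOW = (-10000, 2000)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------


@dataclass
class PWM:
    """Position frequency/weight matrix with MATCH information vector and core."""

    id: str
    freqs: np.ndarray  # (L, 4), rows sum to 1
    counts: np.ndarray | None = None  # original TRANSFAC counts, if parsed
    info: np.ndarray = field(init=False)
    core_start: int = field(default=-1)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise InvalidInputError("freqs must be (L, 4)")
        sums = self.freqs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise InvalidInputError(f"matrix {self.id}: rows must sum to 1")
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.freqs * np.log(4.0 * self.freqs)
        terms[self.freqs == 0] = 0.0  # 0 * ln 0 := 0
        self.info = terms.sum(axis=1)
        if self.core_start < 0:
            w = self.core_length
            sums5 = np.convolve(self.info, np.ones(w), mode="valid")
            # ties toward the lowest start index
            self.core_start = int(np.argmax(np.round(sums5, 12)))

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @property
    def core_length(self) -> int:
        return min(5, self.length)

    @property
    def core_slice(self) -> slice:
        return slice(self.core_start, self.core_start + self.core_length)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        """PWM scoring the reverse complement; core mirrored to stay consistent."""
        rc_freqs = self.freqs[::-1, ::-1].copy()
        rc = PWM(
            id=self.id,
            freqs=rc_freqs,
            counts=None,
            core_start=self.length - self.core_start - self.core_length,
        )
        return rc


def read_transfac(path) -> list[PWM]:
    """Parse a TRANSFAC flat file (AC/ID/P0 blocks) into PWMs.

    Counts are converted to frequencies row-wise; a count row not summing to
    a positive value is a parse error reported with its line number.
    """
    pwms: list[PWM] = []
    acc = name = None
    rows: list[list[float]] = []

    def flush(lineno: int) -> None:
        nonlocal acc, name, rows
        if rows:
            counts = np.asarray(rows, dtype=float)
            freqs = counts / counts.sum(axis=1, keepdims=True)
            pwms.append(PWM(id=(acc or name or f"PWM{len(pwms) + 1}"), freqs=freqs, counts=counts))
        acc = name = None
        rows = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("XX", "P0", "PO", "CC", "BF", "DE")):
                continue
            if line.startswith("//"):
                flush(lineno)
                continue
            if line.startswith("AC"):
                acc = line[2:].strip()
                continue
            if line.startswith("ID"):
                name = line[2:].strip()
                continue
            fields = line.split()
            if fields and fields[0].isdigit():
                try:
                    vals = [float(x) for x in fields[1:5]]
                except (ValueError, IndexError):
                    raise ParseError(f"line {lineno}: malformed count row: {line!r}")
                if len(vals) != 4:
                    raise ParseError(f"line {lineno}: expected 4 counts, got {len(vals)}")
                if sum(vals) <= 0:
                    raise ParseError(f"line {lineno}: count row does not sum > 0")
                rows.append(vals)
    flush(-1)
    if not pwms:
        raise ParseError("no matrices found")
    return pwms


def write_transfac(pwms: Sequence[PWM], path) -> None:
    """Write matrices in TRANSFAC flat format (count rows if available)."""
    with open(path, "w") as fh:
        for m in pwms:
            table = m.counts if m.counts is not None else m.freqs
            fh.write(f"AC  {m.id}\nXX\nP0      A      C      G      T\n")
            for i, row in enumerate(table, start=1):
                cells = "  ".join(f"{v:g}" for v in row)
                fh.write(f"{i:02d}  {cells}\n")
            fh.write("XX\n//\n")


def similarity_scores(m: PWM, s: str) -> tuple[float, float]:
    """(MSS, CSS) of one sequence of the matrix's length.

    A degenerate position set (Max == Min) scores 1 by definition.
    """
    if len(s) != m.length:
        raise InvalidInputError(f"sequence length {len(s)} != matrix length {m.length}")
    try:
        idx = np.array([_BASE_INDEX[c] for c in s.upper()])
    except KeyError as exc:
        raise InvalidInputError(f"non-ACGT symbol {exc} in sequence") from exc

    def _score(sl: slice) -> float:
        info = m.info[sl]
        f = m.freqs[sl]
        cur = float((info * f[np.arange(len(info)), idx[sl]]).sum())
        lo = float((info * f.min(axis=1)).sum())
        hi = float((info * f.max(axis=1)).sum())
        if hi - lo <= 0:
            return 1.0
        return (cur - lo) / (hi - lo)

    return _score(slice(None)), _score(m.core_slice)


# ---------------------------------------------------------------------------
# Promoter windows and scanning
# ---------------------------------------------------------------------------


@dataclass
class PromoterRegion:
    """A TSS-anchored scan window in gene orientation.

    ``seq`` is the window sequence read 5'->3' along the gene; ``rel_start``
    is the TSS-relative position of seq[0] (after truncation at contig
    bounds).
    """

    gene_id: str
    contig: str
    strand: str
    tss: int  # 0-based genomic position of the TSS base
    seq: str
    rel_start: int
    window: tuple[int, int] = DEFAULT_WINDOW

    def genomic_interval(self, rel: int, length: int) -> tuple[int, int]:
        """Genomic 0-based half-open interval of a motif at TSS-relative ``rel``."""
        if self.strand == "+":
            return self.tss + rel, self.tss + rel + length
        return self.tss - rel - length + 1, self.tss - rel + 1


def promoter_region(
    genome: Mapping[str, str],
    gene_id: str,
    contig: str,
    strand: str,
    tss: int,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> PromoterRegion:
    """Extract the oriented promoter window, truncated at contig bounds."""
    if strand not in "+-":
        raise InvalidInputError(f"strand must be + or -, got {strand!r}")
    contig_seq = str(genome[contig])
    lo, hi = window
    if strand == "+":
        g_lo, g_hi = tss + lo, tss + hi
        c_lo, c_hi = max(0, g_lo), min(len(contig_seq), g_hi)
        seq = contig_seq[c_lo:c_hi].upper()
        rel_start = c_lo - tss
    else:
        # rel position r maps to genomic tss - r
        g_lo, g_hi = tss - hi + 1, tss - lo + 1
        c_lo, c_hi = max(0, g_lo), min(len(contig_seq), g_hi)
        seq = reverse_complement(contig_seq[c_lo:c_hi].upper())
        rel_start = tss - (c_hi - 1)
    return PromoterRegion(gene_id, contig, strand, tss, seq, rel_start, window)


@dataclass
class MotifHit:
    """One retained PWM match in a promoter window."""

    gene_id: str
    matrix_id: str
    contig: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str  # strand of the matching motif
    rel_start: int  # TSS-relative, gene orientation (5'-most motif end)
    mss: float
    css: float
    sequence: str  # matched sequence in motif orientation
    conservation: float | None = None
    bin: str | None = None
    proximal: bool | None = None


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _scan_oriented(m: PWM, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (positions, MSS, CSS) of every valid window against ``m``."""
    L = m.length
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0, int), np.empty(0), np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows < 4).all(axis=1)
    pos = np.flatnonzero(valid)
    if pos.size < n:
        logger.debug("matrix %s: skipped %d windows with non-ACGT symbols", m.id, n - pos.size)
    win = windows[pos].astype(int)

    def _scores(sl: slice) -> np.ndarray:
        info = m.info[sl]
        f = m.freqs[sl]
        cur = (info * f[np.arange(len(info))[None, :], win[:, sl]]).sum(axis=1)
        lo = float((info * f.min(axis=1)).sum())
        hi = float((info * f.max(axis=1)).sum())
        if hi - lo <= 0:
            return np.ones(win.shape[0])
        return (cur - lo) / (hi - lo)

    return pos, _scores(slice(None)), _scores(m.core_slice)


def scan_promoter(
    m: PWM,
    p: PromoterRegion,
    css_min: float = 0.8,
    mss_min: float = 0.8,
) -> list[MotifHit]:
    """Scan one promoter window on both strands.

    CSS is tested first, then MSS (MATCH's two-stage filter).  Hits are
    reported at the TSS-relative position of their 5'-most end in gene
    orientation, whichever strand matched.
    """
    codes = _encode(p.seq)
    hits: list[MotifHit] = []
    for oriented, matrix in ((True, m), (False, m.reverse_complement())):
        pos, mss, css = _scan_oriented(matrix, codes)
        keep = (css >= css_min) & (mss >= mss_min)
        for i, ms, cs in zip(pos[keep], mss[keep], css[keep]):
            rel = p.rel_start + int(i)
            start, end = p.genomic_interval(rel, m.length)
            window_seq = p.seq[i : i + m.length]
            if oriented:
                strand = p.strand
                seq = window_seq
            else:
                strand = "-" if p.strand == "+" else "+"
                seq = reverse_complement(window_seq)
            hits.append(
                MotifHit(
                    gene_id=p.gene_id,
                    matrix_id=m.id,
                    contig=p.contig,
                    start=start,
                    end=end,
                    strand=strand,
                    rel_start=rel,
                    mss=float(ms),
                    css=float(cs),
                    sequence=seq,
                )
            )
    hits.sort(key=lambda h: (h.rel_start, h.strand, h.matrix_id))
    return hits


# ---------------------------------------------------------------------------
# Conservation, binning, candidate calling
# ---------------------------------------------------------------------------


@dataclass
class ConservationTrack:
    """Per-base conservation scores in [0, 1] keyed by contig.

    Positions not covered by the track are treated as score 0.
    """

    scores: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for contig, arr in self.scores.items():
            arr = np.asarray(arr, dtype=float)
            if ((arr < 0) | (arr > 1)).any():
                raise InvalidInputError(f"conservation scores outside [0,1] on {contig}")
            self.scores[contig] = arr

    def mean(self, contig: str, start: int, end: int) -> float:
        """Mean score over [start, end); missing bases contribute 0."""
        if end <= start:
            raise InvalidInputError("empty interval")
        arr = self.scores.get(contig)
        total = 0.0
        if arr is not None:
            lo, hi = max(0, start), min(len(arr), end)
            if hi > lo:
                total = float(arr[lo:hi].sum())
        return total / (end - start)


def conservation_filter(
    hits: Iterable[MotifHit], track: ConservationTrack, min_score: float = 0.8
) -> list[MotifHit]:
    """Annotate hits with mean conservation; keep those with mean >= min_score."""
    kept = []
    for h in hits:
        h.conservation = track.mean(h.contig, h.start, h.end)
        # the cutoff is inclusive; guard the comparison against float error in
        # the mean so a true boundary score (e.g. mean of 0.9/0.9/0.6) passes
        if h.conservation >= min_score - 1e-9:
            kept.append(h)
    return kept


def assign_bin(rel_start: int) -> tuple[str | None, bool]:
    """(bin label, proximal flag) for a TSS-relative start; None if outside."""
    proximal = PROXIMAL_WINDOW[0] <= rel_start < PROXIMAL_WINDOW[1]
    for lo, hi, label in zip(BIN_EDGES[:-1], BIN_EDGES[1:], BIN_LABELS):
        if lo <= rel_start < hi:
            return label, proximal
    return None, proximal


def bin_hits(hits: Iterable[MotifHit]) -> list[MotifHit]:
    """Attach bin labels and proximal flags; drop hits outside the window."""
    kept = []
    for h in hits:
        label, proximal = assign_bin(h.rel_start)
        if label is None:
            logger.info("hit at %+d outside scan window, dropped", h.rel_start)
            continue
        h.bin, h.proximal = label, proximal
        kept.append(h)
    return kept


def candidate_direct_targets(
    hits: Iterable[MotifHit],
    compartment: Mapping[str, str],
    responsive: Mapping[str, bool],
) -> list[str]:
    """Genes that are androgen-responsive, somatic, and carry >= 1 conserved
    proximal hit; sorted by (proximal hit count desc, gene id)."""
    counts: dict[str, int] = {}
    for h in hits:
        if h.proximal:
            counts[h.gene_id] = counts.get(h.gene_id, 0) + 1
    genes = [
        g
        for g, c in counts.items()
        if c >= 1 and responsive.get(g, False) and compartment.get(g) == "somatic"
    ]
    return sorted(genes, key=lambda g: (-counts[g], g))


def mss_histogram_fp_rate(
    hits_per_promoter: Sequence[int], n_promoters: int
) -> float:
    """Empirical conserved-hit rate per promoter (diagnostics for random DNA)."""
    if n_promoters <= 0:
        raise InvalidInputError("n_promoters must be positive")
    return float(sum(hits_per_promoter)) / n_promoters
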