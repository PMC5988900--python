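"""PWM construction and genome scanning for master-regulator binding sites.

The scanner slides a position weight matrix over the genome and scores every
window of length L with the average per-position information score

    S = (1/L) * sum_{n=1..L} (2 + log2 f(n, x_n))

where f(n, x) is the frequency of nucleotide x at motif position n.  A
perfectly conserved consensus scores 2 bits per position; a uniform column
contributes 0.  Scores are normalized by the maximum attainable score S_max
(the consensus path through the matrix) and windows at or above a relative
threshold (default 60%) are reported as hits.

Degenerate IUPAC motifs (the CcrM methylation target GANTC) are matched
exactly; GANTC is its own reverse complement, so one genomic duplex site is
reported once, not once per strand.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .io import GenomeSequence, PeakInterval

__all__ = [
    "PWM",
    "MotifHit",
    "PromoterWindow",
    "DegenerateMotif",
    "build_pwm",
    "score_window",
    "scan_genome",
    "match_degenerate",
    "promoter_window",
    "count_sites_in_window",
    "count_peak_overlaps",
    "loop_accessibility",
    "reverse_complement",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Per-position nucleotide frequency model of a binding motif.

    ``freqs`` is an (L, 4) array over A, C, G, T; rows sum to 1.  Zero
    frequencies are permitted (an unpseudocounted consensus matrix): a
    window using such a base scores -inf and can never pass a threshold.
    """

    motif_id: str
    freqs: np.ndarray
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4 or f.shape[0] < 2:
            raise ValueError("PWM needs an (L, 4) frequency matrix with L >= 2")
        if (f < 0).any():
            raise ValueError("PWM frequencies must be nonnegative")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        object.__setattr__(self, "freqs", f)

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @property
    def score_matrix(self) -> np.ndarray:
        """(L, 4) matrix of per-position contributions 2 + log2 f."""
        with np.errstate(divide="ignore"):
            return 2.0 + np.log2(self.freqs)

    @property
    def max_score(self) -> float:
        """S_max: the score of the best (consensus) path through the matrix."""
        return float(self.score_matrix.max(axis=1).mean())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.freqs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            freqs=self.freqs[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
        )

    @classmethod
    def from_matrix(
        cls, mat: np.ndarray, motif_id: str, pseudocount: float = 0.5,
        frequency_floor: float = 1e-6,
    ) -> "PWM":
        """Build from a per-position count or frequency matrix.

        Rows summing to ~1 are treated as frequencies and floored at
        ``frequency_floor``; otherwise rows are counts and ``pseudocount``
        is added to each cell before normalization.
        """
        mat = np.asarray(mat, dtype=float)
        if (mat < 0).any():
            raise ValueError("negative PWM entries")
        sums = mat.sum(axis=1)
        if (sums == 0).any():
            raise ValueError("PWM row sums to 0")
        if np.allclose(sums, 1.0, atol=1e-3):
            mat = np.maximum(mat, frequency_floor)
        else:
            mat = mat + pseudocount
        mat = mat / mat.sum(axis=1, keepdims=True)
        return cls(motif_id=motif_id, freqs=mat, pseudocount=pseudocount)


@dataclass(frozen=True)
class MotifHit:
    """A scored motif occurrence in plus-strand 1-based inclusive coordinates.

    For circular genomes a hit straddling the origin has end < start.
    """

    motif_id: str
    start: int
    end: int
    strand: str
    raw_score: float
    relative_score: float
    matched_sequence: str


@dataclass(frozen=True)
class PromoterWindow:
    """The regulatory region scanned around one TSS (1-based inclusive)."""

    ncrna_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int


@dataclass(frozen=True)
class DegenerateMotif:
    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        bad = [c for c in pat if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC character(s) {bad} in pattern {self.pattern!r}")
        object.__setattr__(self, "pattern", pat)

    @property
    def length(self) -> int:
        return len(self.pattern)

    def is_palindromic(self) -> bool:
        """True when the pattern equals its own IUPAC reverse complement."""
        return self.pattern == self.pattern.translate(_IUPAC_COMPLEMENT)[::-1]

    def regex(self) -> str:
        return "".join(
            c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in self.pattern
        )


def build_pwm(
    aligned_sites: list[str], pseudocount: float = 0.5, motif_id: str = "motif"
) -> PWM:
    """Estimate a PWM from equal-length aligned binding sites.

    f(n, x) = (count(n, x) + pseudocount) / (N + 4 * pseudocount).
    """
    if not aligned_sites:
        raise ValueError("need at least one aligned site")
    L = len(aligned_sites[0])
    if any(len(s) != L for s in aligned_sites):
        raise ValueError("aligned sites have unequal lengths")
    counts = np.zeros((L, 4))
    for site in aligned_sites:
        site = site.upper()
        for n, c in enumerate(site):
            if c not in _CODE:
                raise ValueError(f"non-ACGT character {c!r} in site {site!r}")
            counts[n, _CODE[c]] += 1
    freqs = (counts + pseudocount) / (len(aligned_sites) + 4 * pseudocount)
    return PWM(motif_id=motif_id, freqs=freqs, pseudocount=pseudocount)


def score_window(pwm: PWM, window_sequence: str) -> float:
    """Score one window of length L with the average information score."""
    seq = window_sequence.upper()
    if len(seq) != pwm.length:
        raise ValueError(f"window length {len(seq)} != motif length {pwm.length}")
    if "N" in seq:
        raise ValueError("window contains N and cannot be scored")
    m = pwm.score_matrix
    return float(sum(m[n, _CODE[c]] for n, c in enumerate(seq)) / pwm.length)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(256, 4, dtype=np.int8)
    for b, i in _CODE.items():
        code[ord(b)] = i
    return code[arr]


def _window_scores(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """Scores of all windows over an integer-coded sequence; NaN where N occurs."""
    L = pwm.length
    m = pwm.score_matrix
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (win < 4).all(axis=1)
    scores = np.full(n_win, np.nan)
    if valid.any():
        w = win[valid]
        scores[valid] = m[np.arange(L), w].mean(axis=1)
    return scores


def scan_genome(
    pwm: PWM,
    genome: GenomeSequence,
    rel_threshold: float = 0.6,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan every genomic window on the requested strands and keep hits with
    relative score >= ``rel_threshold``.

    Circular genomes include windows wrapping past the origin.  Minus-strand
    hits are reported in plus-strand coordinates with strand '-'.  Windows
    containing N are skipped.
    """
    s_max = pwm.max_score
    if s_max <= 0:
        raise ValueError("degenerate PWM, relative score undefined (S_max <= 0)")
    L = pwm.length
    n = len(genome)
    if n < L:
        raise ValueError(f"genome length {n} < motif length {L}")

    seq = genome.sequence + (genome.sequence[: L - 1] if genome.circular else "")
    codes = _encode(seq)
    strands = ["+"] + (["-"] if both_strands else [])
    hits: list[MotifHit] = []
    for strand in strands:
        mat = pwm if strand == "+" else pwm.reverse_complement()
        scores = _window_scores(mat, codes)
        keep = np.flatnonzero(~np.isnan(scores) & (scores / s_max >= rel_threshold))
        for i in keep:
            start = int(i) + 1
            end = (start + L - 2) % n + 1
            hits.append(
                MotifHit(
                    motif_id=pwm.motif_id,
                    start=start,
                    end=end,
                    strand=strand,
                    raw_score=float(scores[i]),
                    relative_score=float(scores[i]) / s_max,
                    matched_sequence=seq[i:i + L] if strand == "+"
                    else reverse_complement(seq[i:i + L]),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def match_degenerate(
    motif: DegenerateMotif | str,
    genome: GenomeSequence,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Exact matches of a degenerate IUPAC motif, relative score fixed at 1.

    Self-reverse-complementary patterns (GANTC) mark a single duplex site;
    they are reported once on the plus strand even when ``both_strands``.
    """
    if isinstance(motif, str):
        motif = DegenerateMotif(motif)
    L = motif.length
    n = len(genome)
    seq = genome.sequence + (genome.sequence[: L - 1] if genome.circular else "")
    pattern = re.compile("(?=(" + motif.regex() + "))")

    def _find(hay: str, strand: str) -> list[MotifHit]:
        out = []
        for m in pattern.finditer(hay):
            i = m.start()
            if i >= n:  # wrapped duplicate of position i - n
                continue
            start = i + 1
            end = (start + L - 2) % n + 1
            out.append(
                MotifHit(
                    motif_id=motif.pattern,
                    start=start,
                    end=end,
                    strand=strand,
                    raw_score=float("nan"),
                    relative_score=1.0,
                    matched_sequence=m.group(1),
                )
            )
        return out

    hits = _find(seq, "+")
    if both_strands and not motif.is_palindromic():
        rc = reverse_complement(genome.sequence)
        rc_ext = rc + (rc[: L - 1] if genome.circular else "")
        for m in pattern.finditer(rc_ext):
            i = m.start()
            if i >= n:
                continue
            # map [i, i+L-1] on the reverse strand back to plus coordinates
            start = (n - (i + L)) % n + 1
            end = (start + L - 2) % n + 1
            hits.append(
                MotifHit(
                    motif_id=motif.pattern,
                    start=start,
                    end=end,
                    strand="-",
                    raw_score=float("nan"),
                    relative_score=1.0,
                    matched_sequence=m.group(1),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def promoter_window(
    record,
    upstream: int = 100,
    downstream: int = 50,
    genome_length: int | None = None,
    circular: bool = True,
    chrom: str = "chr",
) -> PromoterWindow:
    """Extract the promoter region around a TSS.

    Plus strand: [TSS - upstream, TSS + downstream]; minus strand mirrored:
    [TSS - downstream, TSS + upstream].  With a circular genome the window
    wraps around the origin; coordinates stay within [1, genome_length].
    """
    tss = record.tss_position
    if tss < 1:
        raise ValueError(f"nonpositive TSS {tss}")
    if record.strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream, tss + upstream
    if genome_length is not None:
        if tss > genome_length:
            raise ValueError(f"TSS {tss} beyond genome length {genome_length}")
        if circular:
            start = (start - 1) % genome_length + 1
            end = (end - 1) % genome_length + 1
        else:
            start = max(start, 1)
            end = min(end, genome_length)
    return PromoterWindow(
        ncrna_id=record.id, chrom=chrom, start=start, end=end,
        strand=record.strand, tss=tss,
    )


def _span_length(start: int, end: int, n: int | None) -> int:
    if n is None or end >= start:
        return end - start + 1
    return (end - start) % n + 1


def count_sites_in_window(
    hits: list[MotifHit], window: PromoterWindow, genome_length: int | None = None
) -> int:
    """Count hits whose full extent lies inside the window (wrap-aware).

    A binding site is counted only if entirely contained; overlapping hits
    are all counted individually.
    """
    wlen = _span_length(window.start, window.end, genome_length)
    count = 0
    for h in hits:
        hlen = _span_length(h.start, h.end, genome_length)
        if genome_length is None:
            inside = window.start <= h.start and h.end <= window.end
        else:
            off = (h.start - window.start) % genome_length
            inside = off + hlen <= wlen
        if inside:
            count += 1
    return count


def _segments(start: int, end: int, n: int | None) -> list[tuple[int, int]]:
    """Split a possibly origin-wrapping interval into linear segments."""
    if n is None or end >= start:
        return [(start, end)]
    return [(start, n), (1, end)]


def count_peak_overlaps(
    peaks: list[PeakInterval], window: PromoterWindow, genome_length: int | None = None
) -> int:
    """Count peaks overlapping the window by at least one position."""
    wsegs = _segments(window.start, window.end, genome_length)
    count = 0
    for p in peaks:
        psegs = _segments(p.start, p.end, genome_length)
        if any(
            ws <= pe and ps <= we
            for ws, we in wsegs
            for ps, pe in psegs
        ):
            count += 1
    return count


def loop_accessibility(dot_bracket: str, interval: tuple[int, int]) -> float:
    """Fraction of positions in [i, j] (1-based) that are unpaired ('.').

    An sRNA seed region buried in a stem cannot base-pair with its target;
    this is the simple accessibility measure used to vet predicted
    interaction regions against a folded structure.
    """
    depth = 0
    for c in dot_bracket:
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise ValueError("unbalanced dot-bracket string")
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if depth != 0:
        raise ValueError("unbalanced dot-bracket string")
    i, j = interval
    if not (1 <= i <= j <= len(dot_bracket)):
        raise ValueError(f"interval {interval} out of range for length {len(dot_bracket)}")
    region = dot_bracket[i - 1:j]
    return region.count(".") / len(region)
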