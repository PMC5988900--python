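"""Readers and writers for the file formats the pipeline consumes and emits.

All in-memory coordinates are 1-based inclusive, the convention used by the
TSS tables this package works with.  BED files (0-based, half-open) are
converted at the file boundary and nowhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "PeakInterval",
    "read_fasta",
    "read_catalog",
    "read_pwm",
    "read_peaks",
    "write_hits_bed",
    "write_peaks_bed",
]

_ALLOWED = set("ACGTN")

CATALOG_COLUMNS = [
    "ccna", "multiple_tss", "phase", "tss", "strand",
    "0", "20", "40", "60", "80", "100", "120", "140",
    "annotation",
]
TIME_COLUMNS = ["0", "20", "40", "60", "80", "100", "120", "140"]

PHASES = ("G1", "G1-S", "S", "G2", "G1-G2")


@dataclass(frozen=True)
class GenomeSequence:
    """A single (by default circular) chromosome."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("empty genome sequence")
        bad = next((i for i, c in enumerate(self.sequence) if c not in _ALLOWED), None)
        if bad is not None:
            raise ValueError(
                f"illegal character {self.sequence[bad]!r} at position {bad + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Return the subsequence [start, end], 1-based inclusive.

        For circular genomes the interval may wrap past the origin
        (start > end or coordinates beyond the length).
        """
        n = len(self.sequence)
        if not self.circular:
            if not (1 <= start <= end <= n):
                raise IndexError(f"interval [{start}, {end}] outside linear genome of length {n}")
            return self.sequence[start - 1:end]
        length = (end - start) % n + 1
        s0 = (start - 1) % n
        doubled = self.sequence + self.sequence
        return doubled[s0:s0 + length]


@dataclass(frozen=True)
class PeakInterval:
    """A ChIP-seq peak (or other genomic interval), 1-based inclusive."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")


def _normalize_sequence(raw: str) -> str:
    seq = raw.upper()
    if "U" in seq:
        warnings.warn("sequence contains U; folding to T", stacklevel=3)
        seq = seq.replace("U", "T")
    return seq


def read_fasta(path: str | Path, circular: bool = True) -> GenomeSequence:
    """Read a single-record genome FASTA into a :class:`GenomeSequence`.

    Multi-record files are rejected: the analysis assumes one chromosome.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise ValueError(
            f"{path}: expected a single genome record, found {len(records)}"
        )
    rec = records[0]
    return GenomeSequence(
        name=rec.id, sequence=_normalize_sequence(str(rec.seq)), circular=circular
    )


def read_aligned_sites(path: str | Path) -> list[str]:
    """Read a FASTA of aligned, equal-length binding sites."""
    sites = [_normalize_sequence(str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not sites:
        raise ValueError(f"{path}: no sites found")
    if len({len(s) for s in sites}) != 1:
        raise ValueError(f"{path}: aligned sites have differing lengths")
    return sites


def read_catalog(path: str | Path) -> "list":
    """Read the ncRNA catalog TSV into a list of NcRNARecord.

    Expected columns: ccna, multiple_tss, phase, tss, strand, the eight
    synchrony time points (0..140 min at 20-min steps) and annotation.
    '/' denotes an absent phase or absent multiple-TSS index.
    """
    from .phases import NcRNARecord, TimeCourseProfile, normalize_category

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing catalog column(s) {missing}")

    records: list[NcRNARecord] = []
    seen: set[tuple[str, int]] = set()
    for _, row in df.iterrows():
        ccna = row["ccna"].strip()
        strand = row["strand"].strip().replace("−", "-")
        if strand not in {"+", "-"}:
            raise ValueError(f"{path}: bad strand {row['strand']!r} for {ccna}")
        phase = row["phase"].strip()
        if phase == "/":
            phase = None
        elif phase not in PHASES:
            raise ValueError(f"{path}: unknown phase {phase!r} for {ccna}")
        mtss = row["multiple_tss"].strip()
        multiple_tss = None if mtss == "/" else int(mtss)
        tss = int(row["tss"])
        key = (ccna, tss)
        if key in seen:
            raise ValueError(f"{path}: duplicated (id, TSS) pair {key}")
        seen.add(key)
        try:
            values = tuple(float(row[c]) for c in TIME_COLUMNS)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric expression for {ccna}: {exc}") from exc
        records.append(
            NcRNARecord(
                id=ccna,
                tss_position=tss,
                strand=strand,
                multiple_tss_index=multiple_tss,
                category=normalize_category(row["annotation"].strip()),
                timecourse=TimeCourseProfile(values=values),
                phase=phase,
            )
        )
    return records


def read_pwm(path: str | Path, motif_id: str | None = None, pseudocount: float = 0.5):
    """Read a PWM from a 4-column count/frequency TSV or an aligned-site FASTA.

    TSV input: header A C G T, one row per motif position.  Count rows are
    pseudocounted and normalized; frequency rows (summing to ~1) get a small
    floor before renormalization so no frequency is exactly zero.
    """
    from .motifs import PWM, build_pwm

    path = Path(path)
    name = motif_id or path.stem
    with open(path) as fh:
        head = fh.read(1)
    if head == ">":
        sites = read_aligned_sites(path)
        return build_pwm(sites, pseudocount=pseudocount, motif_id=name)

    df = pd.read_csv(path, sep="\t")
    cols = [c.strip().upper() for c in df.columns]
    if sorted(cols) != ["A", "C", "G", "T"]:
        raise ValueError(f"{path}: PWM matrix must have exactly columns A, C, G, T")
    df.columns = cols
    mat = df[["A", "C", "G", "T"]].to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError(f"{path}: negative PWM entries")
    return PWM.from_matrix(mat, motif_id=name, pseudocount=pseudocount)


def read_peaks(path: str | Path) -> list[PeakInterval]:
    """Read a BED file of peaks, converting to 1-based inclusive coordinates."""
    peaks: list[PeakInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: BED start {start} >= end {end}")
            label = fields[3] if len(fields) > 3 else None
            peaks.append(PeakInterval(chrom=chrom, start=start + 1, end=end, label=label))
    return peaks


def write_peaks_bed(peaks: Iterable[PeakInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            name = p.label if p.label is not None else "."
            fh.write(f"{p.chrom}\t{p.start - 1}\t{p.end}\t{name}\n")


def write_hits_bed(hits: Sequence, path: str | Path, chrom: str = "chr") -> None:
    """Write motif hits as BED6 (score = 1000 x relative score, rounded)."""
    with open(path, "w") as fh:
        for h in hits:
            score = round(1000 * h.relative_score)
            fh.write(
                f"{chrom}\t{h.start - 1}\t{h.end}\t{h.motif_id}\t{score}\t{h.strand}\n"
            )


def read_hits_bed(path: str | Path) -> list:
    """Read a BED6 file of motif hits back into MotifHit objects.

    The raw score is not stored in BED; it is restored as relative_score
    (score / 1000) with raw_score unset (NaN).
    """
    from .motifs import MotifHit

    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 line needs 6 fields")
            hits.append(
                MotifHit(
                    motif_id=fields[3],
                    start=int(fields[1]) + 1,
                    end=int(fields[2]),
                    strand=fields[5],
                    raw_score=float("nan"),
                    relative_score=float(fields[4]) / 1000.0,
                    matched_sequence="",
                )
            )
    return hits
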