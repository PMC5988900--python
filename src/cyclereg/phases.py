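"""Catalog selection and cell-cycle phase classification of synchrony
expression time courses.

Synchronized *Caulobacter* swarmer cells progress G1 -> S -> G2 over roughly
140 minutes, so an 8-point time course sampled every 20 minutes places an
expression peak within a cell-cycle phase: a 0-min peak marks G1 (swarmer),
20 min the G1->S transition, 40-100 min S phase, and 120-140 min G2/division.
Profiles high at both ends of the course but low mid-cycle are called G1-G2.

The classifier is a declared heuristic: it gates on dynamic range (fold
change and a minimum peak level), applies a U-shape test for G1-G2, then
maps the peak time to a phase.  All constants are exposed as arguments.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NcRNARecord",
    "TimeCourseProfile",
    "FilterReport",
    "select_study_set",
    "classify_phase",
    "classify_catalog",
    "count_by_phase",
    "normalize_category",
]

TIME_GRID = (0, 20, 40, 60, 80, 100, 120, 140)

PHASES = ("G1", "G1-S", "S", "G2", "G1-G2")

CATEGORIES = (
    "small ncRNA",
    "cell-cycle regulated",
    "translational machinery",
    "tmRNA",
    "characterized",
    "stationary phase",
    "medium-specific",
    "other",
)

# annotation strings as they appear in catalog files -> controlled vocabulary
_CATEGORY_ALIASES = {
    "small non-coding rna": "small ncRNA",
    "small ncrna": "small ncRNA",
    "cell cycle regulated": "cell-cycle regulated",
    "cell-cycle regulated": "cell-cycle regulated",
    "trna": "translational machinery",
    "ribosomal": "translational machinery",
    "ribosome-related": "translational machinery",
    "translational machinery": "translational machinery",
    "tmrna": "tmRNA",
    "characterized": "characterized",
    "stationary phase": "stationary phase",
    "minimal medium": "medium-specific",
    "rich medium": "medium-specific",
    "medium-specific": "medium-specific",
}


def normalize_category(annotation: str) -> str:
    return _CATEGORY_ALIASES.get(annotation.strip().lower(), "other")


@dataclass(frozen=True)
class TimeCourseProfile:
    """Eight expression values on the 0..140 min synchrony grid."""

    values: tuple
    times: tuple = TIME_GRID

    def __post_init__(self) -> None:
        if len(self.values) != len(self.times):
            raise ValueError(
                f"expected {len(self.times)} expression values, got {len(self.values)}"
            )
        if any(v < 0 for v in self.values):
            raise ValueError("expression values must be nonnegative")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))


@dataclass(frozen=True)
class NcRNARecord:
    """One TSS-level catalog entry."""

    id: str
    tss_position: int
    strand: str
    category: str
    timecourse: TimeCourseProfile
    multiple_tss_index: int | None = None
    phase: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.phase is not None and self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class FilterReport:
    """Record counts through the catalog selection chain."""

    input_records: int
    input_ncrnas: int
    after_machinery_exclusion: int
    after_characterized_exclusion: int
    removed_translational: int
    removed_tmrna: int
    removed_characterized: int


def select_study_set(catalog: list[NcRNARecord]) -> tuple[list[NcRNARecord], FilterReport]:
    """Apply the catalog-selection filter chain.

    From the TSS-characterized catalog, drop translational-machinery RNAs
    (tRNAs and ribosome-related) and the tmRNA, then drop previously
    characterized ncRNAs.  Counts are reported at distinct-ncRNA level.
    """

    def n_ids(records):
        return len({r.id for r in records})

    removed_translational = [r for r in catalog if r.category == "translational machinery"]
    removed_tmrna = [r for r in catalog if r.category == "tmRNA"]
    survivors = [
        r for r in catalog if r.category not in {"translational machinery", "tmRNA"}
    ]
    after_machinery = n_ids(survivors)
    removed_characterized = [r for r in survivors if r.category == "characterized"]
    final = [r for r in survivors if r.category != "characterized"]
    report = FilterReport(
        input_records=len(catalog),
        input_ncrnas=n_ids(catalog),
        after_machinery_exclusion=after_machinery,
        after_characterized_exclusion=n_ids(final),
        removed_translational=n_ids(removed_translational),
        removed_tmrna=n_ids(removed_tmrna),
        removed_characterized=n_ids(removed_characterized),
    )
    logger.info(
        "catalog selection: %d TSS-characterized ncRNAs -> %d after excluding "
        "translational machinery and tmRNA -> %d after excluding characterized",
        report.input_ncrnas, report.after_machinery_exclusion,
        report.after_characterized_exclusion,
    )
    return final, report


def classify_phase(
    profile: TimeCourseProfile,
    fold_threshold: float = 4.0,
    min_peak: float = 5.0,
    ushape_factor: float = 3.0,
) -> str | None:
    """Assign a cell-cycle phase to a synchrony time course, or None if flat.

    1. Dynamic-range gate: (max+1)/(min+1) >= ``fold_threshold`` and
       max >= ``min_peak``; otherwise the profile is not cell-cycle regulated.
    2. U-shape test: both endpoint values exceed ``ushape_factor`` times the
       mid-cycle minimum (40-100 min, +1 regularized) -> G1-G2.
    3. Otherwise the peak time maps to a phase: 0 -> G1, 20 -> G1-S,
       40-100 -> S, 120-140 -> G2.

    The +1 regularizer keeps ratios finite on the exact zeros that occur in
    real expression tables.
    """
    v = np.asarray(profile.values)
    t = np.asarray(profile.times)
    vmax, vmin = v.max(), v.min()
    if vmax < min_peak or (vmax + 1.0) / (vmin + 1.0) < fold_threshold:
        return None
    mid = v[(t >= 40) & (t <= 100)]
    mid_min = mid.min()
    if (v[0] + 1.0) >= ushape_factor * (mid_min + 1.0) and (
        v[-1] + 1.0
    ) >= ushape_factor * (mid_min + 1.0):
        return "G1-G2"
    peak_time = int(t[int(v.argmax())])
    if peak_time == 0:
        return "G1"
    if peak_time == 20:
        return "G1-S"
    if 40 <= peak_time <= 100:
        return "S"
    return "G2"


def classify_catalog(
    records: list[NcRNARecord],
    fold_threshold: float = 4.0,
    min_peak: float = 5.0,
    ushape_factor: float = 3.0,
) -> list[NcRNARecord]:
    """Return copies of ``records`` with ``phase`` set by the classifier."""
    return [
        replace(
            r,
            phase=classify_phase(
                r.timecourse, fold_threshold=fold_threshold,
                min_peak=min_peak, ushape_factor=ushape_factor,
            ),
        )
        for r in records
    ]


def count_by_phase(records: list[NcRNARecord], level: str = "tss") -> dict:
    """Tally phase labels at TSS-row or distinct-ncRNA level.

    ``tss`` counts phase-annotated rows.  ``ncrna`` counts distinct ids: an
    id with several phase-annotated TSSs is counted once, its phase taken by
    majority over its rows (conflict -> warning; tie broken by the row with
    the smallest TSS coordinate).
    """
    counts: Counter = Counter()
    if level == "tss":
        for r in records:
            if r.phase is not None:
                counts[r.phase] += 1
    elif level == "ncrna":
        by_id: dict[str, list[NcRNARecord]] = {}
        for r in records:
            if r.phase is not None:
                by_id.setdefault(r.id, []).append(r)
        for ncrna_id, rows in by_id.items():
            phases = Counter(r.phase for r in rows)
            if len(phases) > 1:
                warnings.warn(
                    f"{ncrna_id}: conflicting phase labels {dict(phases)}; "
                    "using majority/first-TSS rule",
                    stacklevel=2,
                )
            best = max(phases.values())
            candidates = {p for p, c in phases.items() if c == best}
            phase = min(
                (r for r in rows if r.phase in candidates),
                key=lambda r: r.tss_position,
            ).phase
            counts[phase] += 1
    else:
        raise ValueError(f"level must be 'tss' or 'ncrna', got {level!r}")
    return {p: counts.get(p, 0) for p in PHASES}
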