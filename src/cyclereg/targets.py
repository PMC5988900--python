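"""Integration of per-tool sRNA target predictions and functional enrichment.

Three prediction tools play asymmetric roles: RNApredator supplies the
candidate list (its top-ranked targets per ncRNA), and a candidate is kept
only when confirmed by CopraRNA (presence in its list) or by TargetRNA2 (a
significant interaction p-value).  Confirmed targets are then annotated with
cell-cycle-related functional categories, and the fraction of ncRNAs whose
targets include a bona fide cell-cycle regulator is compared between
cell-cycle-regulated (phase-labelled) and static ncRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TargetPrediction",
    "confirmed_targets",
    "annotate_targets",
    "cellcycle_fraction",
    "read_predictions",
    "read_annotation",
    "FUNCTION_CATEGORIES",
]

TOOLS = ("predator", "copra", "targetrna2")

FUNCTION_CATEGORIES = (
    "Cell cycle",
    "Cell division",
    "Flagellum",
    "Pilus",
    "Stalk",
    "Chromosome partitioning",
    "ppGpp",
)
_CATEGORY_BY_LOWER = {c.lower(): c for c in FUNCTION_CATEGORIES}


def normalize_function(name: str) -> str:
    key = name.strip().lower()
    if key not in _CATEGORY_BY_LOWER:
        raise ValueError(f"unknown functional category {name!r}")
    return _CATEGORY_BY_LOWER[key]


@dataclass(frozen=True)
class TargetPrediction:
    """One tool's prediction of an ncRNA -> mRNA interaction."""

    ncrna_id: str
    gene_locus: str
    tool: str
    rank: int
    score: float = 0.0
    p_value: float | None = None
    mrna_interval: tuple[int, int] | None = None
    ncrna_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.tool not in TOOLS:
            raise ValueError(f"unknown tool {self.tool!r}")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def read_predictions(path: str | Path, tool: str) -> list[TargetPrediction]:
    """Read a per-tool prediction TSV (columns: ncrna, gene, rank, and
    optionally score, p_value)."""
    df = pd.read_csv(path, sep="\t")
    preds = []
    for _, row in df.iterrows():
        p_value = None
        if "p_value" in df.columns and pd.notna(row.get("p_value")):
            p_value = float(row["p_value"])
        preds.append(
            TargetPrediction(
                ncrna_id=str(row["ncrna"]),
                gene_locus=str(row["gene"]),
                tool=tool,
                rank=int(row["rank"]),
                score=float(row["score"]) if "score" in df.columns else 0.0,
                p_value=p_value,
            )
        )
    return preds


def confirmed_targets(
    predator: list[TargetPrediction],
    copra: list[TargetPrediction],
    targetrna2: list[TargetPrediction],
    top_n: int = 100,
    p_max: float = 0.05,
) -> list[tuple[str, str]]:
    """Integrate the three tools under the confirmation rule.

    A pair (ncRNA, gene) is retained iff the gene is within RNApredator's
    top ``top_n`` predictions for that ncRNA AND the gene is listed by
    CopraRNA or carries a TargetRNA2 p-value < ``p_max``.  Gene loci match
    case-insensitively.  Output is deduplicated and sorted.
    """
    candidates: dict[tuple[str, str], str] = {}
    for p in predator:
        if p.rank <= top_n:
            candidates.setdefault((p.ncrna_id, p.gene_locus.casefold()), p.gene_locus)
    copra_set = {(p.ncrna_id, p.gene_locus.casefold()) for p in copra}
    tr2_set = {
        (p.ncrna_id, p.gene_locus.casefold())
        for p in targetrna2
        if p.p_value is not None and p.p_value < p_max
    }
    retained = [
        (ncrna, candidates[key])
        for key in sorted(candidates)
        if key in copra_set or key in tr2_set
        for ncrna in [key[0]]
    ]
    return retained


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a locus -> functional categories table (columns: gene, functions,
    the latter comma-separated)."""
    df = pd.read_csv(path, sep="\t")
    annotation: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        cats = {
            normalize_function(c)
            for c in str(row["functions"]).split(",")
            if c.strip() and c.strip() != "/"
        }
        annotation[str(row["gene"]).casefold()] = cats
    return annotation


def annotate_targets(
    pairs: list[tuple[str, str]],
    annotation: dict[str, set[str]],
) -> dict[str, tuple[set[str], set[str]]]:
    """Per-ncRNA union of target functional categories and significant loci.

    Loci are listed for every category except Flagellum (flagellar regulons
    are large and their members are left unenumerated).  A locus absent from
    the annotation contributes nothing and is logged.
    """
    ann = {k.casefold(): v for k, v in annotation.items()}
    out: dict[str, tuple[set[str], set[str]]] = {}
    for ncrna_id, locus in pairs:
        cats, loci = out.setdefault(ncrna_id, (set(), set()))
        locus_cats = ann.get(locus.casefold())
        if locus_cats is None:
            logger.warning("locus %s for %s not in functional annotation", locus, ncrna_id)
            continue
        cats |= locus_cats
        if locus_cats - {"Flagellum"}:
            loci.add(locus)
    return out


def cellcycle_fraction(
    rows: list[tuple[str, str | None, set[str]]],
    category: str = "Cell cycle",
) -> dict[str, tuple[int, int]]:
    """Enrichment of a functional category among dynamic vs static ncRNAs.

    ``rows`` are integrated-table rows (ncrna_id, phase-or-None, categories).
    Distinct ncRNAs with at least one phase-labelled row form the dynamic
    group, those with at least one unlabelled row the static group; an id
    appearing in both groups is counted in both denominators.  k counts ids
    whose category union (within the group) contains ``category`` exactly.
    """
    dynamic: dict[str, set[str]] = {}
    static: dict[str, set[str]] = {}
    for ncrna_id, phase, cats in rows:
        group = dynamic if phase is not None else static
        group.setdefault(ncrna_id, set()).update(cats)
    k1 = sum(1 for cats in dynamic.values() if category in cats)
    k2 = sum(1 for cats in static.values() if category in cats)
    result = {"dynamic": (k1, len(dynamic)), "static": (k2, len(static))}
    for name, (k, n) in result.items():
        pct = 100.0 * k / n if n else 0.0
        logger.info("%s ncRNAs with %r targets: %d of %d (%.1f%%)", name, category, k, n, pct)
    return result
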