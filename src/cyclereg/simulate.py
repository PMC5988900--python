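"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure function of (config, seed): a GC-matched random
chromosome with motif instances planted at controlled relative scores, a
TSS catalog whose 8-point synchrony time courses follow phase-specific peak
templates under multiplicative lognormal noise, three-tool target-prediction
tables with configurable confirmation overlap, and ChIP-seq-like peak
intervals.  Each generator also returns the ground truth it planted, so
recovery can be asserted rather than eyeballed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenomeSequence, PeakInterval, write_peaks_bed
from .motifs import PWM, reverse_complement, score_window
from .phases import TIME_GRID, NcRNARecord, TimeCourseProfile

__all__ = [
    "SimulationConfig",
    "gen_genome",
    "gen_timecourses",
    "gen_prediction_tables",
    "gen_peaks",
    "write_all",
    "catalog_to_tsv",
]

_BASES = np.array(list("ACGT"))

# Study-condition defaults: phase mix mirroring the 42-ncRNA study set
# (6 G1, 2 G1-S, 10 S, 2 G2, 2 G1-G2, rest flat), C. crescentus-like GC.
DEFAULT_PHASE_MIX = {"G1": 6, "G1-S": 2, "S": 10, "G2": 2, "G1-G2": 2, None: 20}


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 20000
    gc_content: float = 0.67
    planted_sites: list = field(default_factory=list)  # (pwm_id, count, (lo, hi))
    pwms: dict = field(default_factory=dict)  # pwm_id -> PWM
    phase_mix: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_MIX))
    noise_sigma: float = 0.2
    fold_range: tuple = (8.0, 32.0)
    amplitude_range: tuple = (10.0, 1000.0)
    targets_per_ncrna: int = 3
    predator_list_length: int = 100
    tool_overlap: dict = field(default_factory=lambda: {"copra": 0.8, "targetrna2": 0.8})
    n_peaks: int = 20
    peak_width_range: tuple = (50, 400)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        for tool, frac in self.tool_overlap.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"tool_overlap[{tool!r}] must be in [0, 1]")
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")


def _background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _sample_site(
    pwm: PWM, lo: float, hi: float, rng: np.random.Generator, max_tries: int = 10000
) -> str:
    """Rejection-sample a sequence from the PWM whose relative score lies in
    [lo, hi].  Low ranges are topped up by mutating the consensus."""
    s_max = pwm.max_score
    for _ in range(max_tries):
        seq = "".join(
            _BASES[rng.choice(4, p=pwm.freqs[n])] for n in range(pwm.length)
        )
        if lo <= score_window(pwm, seq) / s_max <= hi:
            return seq
    # column sampling rarely reaches low relative scores; mutate the consensus
    consensus = list(pwm.consensus())
    for _ in range(max_tries):
        seq = consensus.copy()
        n_mut = rng.integers(1, pwm.length + 1)
        for pos in rng.choice(pwm.length, size=n_mut, replace=False):
            seq[pos] = _BASES[rng.integers(4)]
        cand = "".join(seq)
        if lo <= score_window(pwm, cand) / s_max <= hi:
            return cand
    raise RuntimeError(
        f"could not sample a site for {pwm.motif_id} with relative score in [{lo}, {hi}]"
    )


def gen_genome(
    config: SimulationConfig, name: str = "synthetic_chr"
) -> tuple[GenomeSequence, pd.DataFrame]:
    """Generate a random circular chromosome with planted motif instances.

    Returns the genome and a truth table (pwm_id, start, end, strand,
    relative_score, sequence) of the planted, non-overlapping sites.
    """
    rng = np.random.default_rng(config.seed)
    codes = _background(rng, config.genome_length, config.gc_content)
    occupied: list[tuple[int, int]] = []
    truth_rows = []
    for pwm_id, count, (lo, hi) in config.planted_sites:
        pwm = config.pwms[pwm_id]
        L = pwm.length
        for _ in range(count):
            site = _sample_site(pwm, lo, hi, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            planted = site if strand == "+" else reverse_complement(site)
            for _try in range(10000):
                start0 = int(rng.integers(0, config.genome_length - L))
                if all(start0 + L <= s or start0 >= e for s, e in occupied):
                    break
            else:
                raise RuntimeError("could not place planted sites without overlap")
            occupied.append((start0, start0 + L))
            codes[start0:start0 + L] = [("ACGT").index(c) for c in planted]
            truth_rows.append(
                {
                    "pwm_id": pwm_id,
                    "start": start0 + 1,
                    "end": start0 + L,
                    "strand": strand,
                    "relative_score": score_window(pwm, site) / pwm.max_score,
                    "sequence": site,
                }
            )
    genome = GenomeSequence(
        name=name, sequence="".join(_BASES[codes]), circular=True
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["pwm_id", "start", "end", "strand", "relative_score", "sequence"],
    ).sort_values(["start"]).reset_index(drop=True)
    return genome, truth


# multiplier templates per phase: baseline 1, peak `fold`
def _phase_template(phase: str | None, fold: float) -> np.ndarray:
    t = np.ones(len(TIME_GRID))
    if phase == "G1":
        t[0] = fold
    elif phase == "G1-S":
        t[1] = fold
    elif phase == "S":
        t[2], t[3], t[4] = fold / 2, fold, fold / 2
    elif phase == "G2":
        t[6], t[7] = fold / 2, fold
    elif phase == "G1-G2":
        t[0], t[6], t[7] = fold, fold / 2, fold
    elif phase is not None:
        raise ValueError(f"unknown phase {phase!r}")
    return t


def gen_timecourses(
    config: SimulationConfig,
) -> tuple[list[NcRNARecord], dict[str, str | None]]:
    """Generate a TSS catalog with phase-templated synchrony time courses.

    Per ncRNA the template (peak at the phase's characteristic time,
    U-shaped for G1-G2, flat for None) is scaled by a log-uniform amplitude
    and perturbed by multiplicative lognormal noise of width ``noise_sigma``.
    Returns the records (phase unset) and the ground-truth phase per id.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_total = sum(config.phase_mix.values())
    spacing = max(config.genome_length // max(n_total, 1), 1)
    records: list[NcRNARecord] = []
    truth: dict[str, str | None] = {}
    i = 0
    for phase, count in config.phase_mix.items():
        for _ in range(count):
            i += 1
            ncrna_id = f"CCNA_R9{i:03d}"
            amp = float(
                np.exp(rng.uniform(*np.log(config.amplitude_range)))
            )
            fold = float(np.exp(rng.uniform(*np.log(config.fold_range))))
            noise = np.exp(rng.normal(0.0, config.noise_sigma, size=len(TIME_GRID)))
            values = tuple(amp * _phase_template(phase, fold) * noise)
            records.append(
                NcRNARecord(
                    id=ncrna_id,
                    tss_position=1 + (i - 1) * spacing % config.genome_length,
                    strand="+" if i % 2 else "-",
                    category="small ncRNA",
                    timecourse=TimeCourseProfile(values=values),
                )
            )
            truth[ncrna_id] = phase
    return records, truth


def gen_prediction_tables(
    config: SimulationConfig, truth: dict[str, set[str]]
) -> dict[str, pd.DataFrame]:
    """Emulate the three target-prediction tools with controlled overlap.

    RNApredator ranks every true target near the top and fills its list with
    decoys; CopraRNA and TargetRNA2 each independently confirm a true target
    with their configured probability.  TargetRNA2 p-values are < 0.05 for
    included true targets; its decoy genes come from a pool disjoint from
    the RNApredator list, so decoys never pass the confirmation rule.
    """
    rng = np.random.default_rng(config.seed + 2)
    p_copra = config.tool_overlap.get("copra", 0.8)
    p_tr2 = config.tool_overlap.get("targetrna2", 0.8)
    predator_rows, copra_rows, tr2_rows = [], [], []
    for ncrna_id in sorted(truth):
        genes = sorted(truth[ncrna_id])
        n_decoys = config.predator_list_length - len(genes)
        decoys = [f"decoy_{ncrna_id}_{j}" for j in range(n_decoys)]
        ranked = genes + decoys
        for rank, gene in enumerate(ranked, start=1):
            predator_rows.append(
                {"ncrna": ncrna_id, "gene": gene, "rank": rank,
                 "score": -float(rng.uniform(5, 25))}
            )
        offlist = [f"offlist_{ncrna_id}_{j}" for j in range(10)]
        rank_c = rank_t = 0
        for gene in genes:
            if rng.random() < p_copra:
                rank_c += 1
                copra_rows.append({"ncrna": ncrna_id, "gene": gene, "rank": rank_c,
                                   "score": -float(rng.uniform(5, 25))})
            if rng.random() < p_tr2:
                rank_t += 1
                tr2_rows.append({"ncrna": ncrna_id, "gene": gene, "rank": rank_t,
                                 "score": -float(rng.uniform(5, 25)),
                                 "p_value": float(rng.uniform(0.0, 0.049))})
        for gene in offlist:
            rank_c += 1
            copra_rows.append({"ncrna": ncrna_id, "gene": gene, "rank": rank_c,
                               "score": -float(rng.uniform(5, 25))})
            rank_t += 1
            tr2_rows.append({"ncrna": ncrna_id, "gene": gene, "rank": rank_t,
                             "score": -float(rng.uniform(5, 25)),
                             "p_value": float(rng.uniform(0.0, 1.0))})
    cols = ["ncrna", "gene", "rank", "score"]
    return {
        "predator": pd.DataFrame(predator_rows, columns=cols),
        "copra": pd.DataFrame(copra_rows, columns=cols),
        "targetrna2": pd.DataFrame(tr2_rows, columns=cols + ["p_value"]),
    }


def gen_peaks(config: SimulationConfig, chrom: str = "synthetic_chr") -> list[PeakInterval]:
    """Random ChIP-seq-like peak intervals on the synthetic chromosome."""
    rng = np.random.default_rng(config.seed + 3)
    peaks = []
    for i in range(config.n_peaks):
        width = int(rng.integers(*config.peak_width_range))
        start = int(rng.integers(1, max(config.genome_length - width, 2)))
        peaks.append(PeakInterval(chrom=chrom, start=start, end=start + width - 1,
                                  label=f"peak_{i + 1}"))
    return sorted(peaks, key=lambda p: p.start)


def catalog_to_tsv(records: list[NcRNARecord], path: str | Path) -> None:
    """Write records in the catalog TSV layout the reader expects."""
    from .io import CATALOG_COLUMNS, TIME_COLUMNS

    rows = []
    for r in records:
        row = {
            "ccna": r.id,
            "multiple_tss": r.multiple_tss_index if r.multiple_tss_index is not None else "/",
            "phase": r.phase if r.phase is not None else "/",
            "tss": r.tss_position,
            "strand": r.strand,
            "annotation": r.category,
        }
        for col, v in zip(TIME_COLUMNS, r.timecourse.values):
            row[col] = f"{v:.4g}"
        rows.append(row)
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def write_all(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit the full synthetic input set into ``out_dir``."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genome, sites = gen_genome(config)
    paths["genome"] = out / "genome.fasta"
    SeqIO.write(
        [SeqRecord(Seq(genome.sequence), id=genome.name, description="synthetic")],
        str(paths["genome"]), "fasta",
    )
    paths["truth_sites"] = out / "truth_sites.bed"
    with open(paths["truth_sites"], "w") as fh:
        for _, row in sites.iterrows():
            fh.write(
                f"{genome.name}\t{row['start'] - 1}\t{row['end']}\t{row['pwm_id']}"
                f"\t{round(1000 * row['relative_score'])}\t{row['strand']}\n"
            )

    records, phase_truth = gen_timecourses(config)
    paths["catalog"] = out / "catalog.tsv"
    catalog_to_tsv(records, paths["catalog"])
    paths["truth_phases"] = out / "truth_phases.tsv"
    pd.DataFrame(
        [{"ccna": k, "phase": v if v is not None else "/"} for k, v in phase_truth.items()]
    ).to_csv(paths["truth_phases"], sep="\t", index=False)

    target_truth = {
        r.id: {f"gene_{r.id}_{j}" for j in range(config.targets_per_ncrna)}
        for r in records
    }
    tables = gen_prediction_tables(config, target_truth)
    for tool, df in tables.items():
        paths[tool] = out / f"{tool}.tsv"
        df.to_csv(paths[tool], sep="\t", index=False)

    # functional annotation of true target genes: a seeded subset are
    # cell-cycle regulators, the rest spread over the other categories
    from .targets import FUNCTION_CATEGORIES

    rng = np.random.default_rng(config.seed + 4)
    ann_rows = []
    for genes in target_truth.values():
        for gene in sorted(genes):
            if rng.random() < 0.4:
                cats = "Cell cycle"
            else:
                cats = FUNCTION_CATEGORIES[1 + int(rng.integers(len(FUNCTION_CATEGORIES) - 1))]
            ann_rows.append({"gene": gene, "functions": cats})
    paths["annotation"] = out / "annotation.tsv"
    pd.DataFrame(ann_rows).to_csv(paths["annotation"], sep="\t", index=False)

    paths["peaks"] = out / "peaks.bed"
    write_peaks_bed(gen_peaks(config, chrom=genome.name), paths["peaks"])
    return paths
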