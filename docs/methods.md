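# Methods

## Scope and data model

The package links the four master cell-cycle regulators of *Caulobacter
crescentus* (DnaA, GcrA, CtrA, CcrM) to a catalog of non-coding RNAs along
two directions: regulator → ncRNA evidence from promoter sequence and
ChIP-seq occupancy, and ncRNA → target evidence from integrated
interaction predictions. All genomic coordinates are 1-based inclusive
internally — the convention of the TSS tables it consumes — and BED
(0-based, half-open) is converted only at file boundaries. The chromosome
is treated as circular by default: windows and motif hits may wrap past the
origin (several catalog TSSs sit within 200 bp of coordinate 1), and a
wrapped hit is represented with end < start.

The three published tables bundled under `cyclereg/data/` (TSS catalog with
synchrony time courses, integrated target functions, per-promoter site
counts) are inputs, transcribed verbatim; nothing in the package regenerates
them from raw sequence, because the specific CtrA/DnaA matrices and the
reference genome they were derived from are external resources. The motif
machinery is instead validated against synthetic chromosomes with planted
ground truth.

## PWM scanning

A PWM is an (L, 4) matrix of per-position nucleotide frequencies. From
aligned sites, f(n, x) = (count + p) / (N + 4p) with pseudocount p = 0.5 by
default; matrices supplied as frequencies are floored at 1e-6 and
renormalized. Zero frequencies (pseudocount 0) are legal: the affected
window scores −∞ and can never pass a threshold, which makes an
unpseudocounted consensus matrix behave as an exact matcher.

A window is scored by S = (1/L) Σₙ (2 + log₂ f(n, xₙ)) — the average
per-position information contribution, 2 bits for a perfectly conserved
position, 0 for a uniform one. Scores are normalized by S_max, the score of
the consensus path, and hits with S/S_max ≥ 0.6 are retained; the bound is
inclusive ("at least 60%"), and uniform matrices (S_max = 0) are rejected
since the ratio is undefined. Minus-strand windows are scored with the
reverse-complemented matrix and reported in plus-strand coordinates.
Windows containing N are skipped. The scanner is vectorized (stride-tricks
sliding windows over an integer-coded sequence); its contract is pinned by
a deliberately naive pure-Python brute-force scorer in the test suite, with
agreement asserted over random (PWM, sequence, threshold) draws on both
strands, circular and linear.

The CcrM methylation target GANTC is matched as a degenerate IUPAC pattern
with overlapping-match semantics. GANTC equals its own reverse complement
under IUPAC, so one genomic duplex site would otherwise be reported twice;
self-reverse-complementary patterns are therefore reported once, on the
plus strand. Non-palindromic patterns are matched on both strands.

Promoter windows span upstream 100 / downstream 50 nt around the TSS
(151 nt total), mirrored on the minus strand. Motif hits are counted per
window under a full-containment rule (a binding site functions only if
entirely within the region), ChIP-seq peaks under an any-overlap rule
(peaks are wide relative to the window); both are wrap-aware.

## Phase classification

The catalog's phase labels derive from 8-point synchrony time courses
(0–140 min at 20-min steps), but no formal calling rule accompanies them,
so the classifier here is a declared reconstruction with every constant
exposed:

1. **Dynamic-range gate** — a profile is unregulated (phase `None`) unless
   (max+1)/(min+1) ≥ 4 and max ≥ 5 expression units. The +1 keeps ratios
   finite on the exact zeros present in real tables, at the cost of exact
   scale invariance near the thresholds.
2. **U-shape test** — both endpoints ≥ 3× the 40–100-min minimum
   (+1-regularized on both sides) → G1-G2 (expressed in swarmer and
   predivisional cells, silent mid-replication).
3. **Peak-time map** — 0 min → G1, 20 → G1-S, 40–100 → S, 120–140 → G2,
   reflecting swarmer isolation at t = 0, the G1→S transition at ~20 min
   and division at ~140 min.

The rule reproduces the five unambiguous anchor profiles from the published
catalog exactly (G1, S, G1-S, G1-G2 and flat exemplars) and ≥ 95% of labels
on synthetic profiles at realistic noise, but it does not reproduce every
published row: several printed labels are evidently curated (profiles with
strong fold change labelled unregulated, and vice versa). Tests assert the
anchors and the synthetic recovery, not the curated residue. At
distinct-ncRNA level an id with conflicting per-TSS phases is counted once
by majority, ties broken by the smallest TSS coordinate — this is why the
catalog yields 23 phase calls at TSS level but 22 distinct dynamic ncRNAs.

## Catalog selection

From the TSS-characterized catalog, translational-machinery RNAs (tRNAs,
ribosome-associated) and the tmRNA are excluded first, then previously
characterized sRNAs (CrfA, GsrN). The published table prints only the
surviving entries, so `datasets.full_tss_catalog()` reconstructs the
pre-filter catalog of 88 distinct ncRNAs by appending synthetic stand-ins
for the excluded classes (flat time courses, evenly spaced TSSs) and
re-tagging two bundled single-TSS entries as the characterized pair; the
stand-ins are labelled synthetic in the docstring. The chain then yields
88 → 44 → 42 at distinct-ncRNA level.

## Target integration and enrichment

RNApredator supplies candidates (top 100 per ncRNA); a candidate is
confirmed by presence in CopraRNA's list or a TargetRNA2 p-value < 0.05
(records without a p-value cannot confirm). Loci match case-insensitively;
synonym resolution is out of scope. The retained-pair set is monotone in
top_n and p_max by construction, a property the tests assert.

Confirmed targets are annotated with a controlled vocabulary of seven
cell-cycle-related categories; significant loci are listed for every
category except Flagellum (flagellar regulons are large and their members
left unenumerated). Enrichment compares the fraction of ncRNAs whose
category union contains exactly "Cell cycle" (distinct from
"Cell division") between phase-labelled and unlabelled groups; an ncRNA
appearing in both groups (one TSS labelled, another not) is counted in both
denominators. On the bundled tables this yields 13/22 dynamic vs 7/23
static. Loop accessibility of a predicted interaction region — the
fraction of unpaired positions in a dot-bracket structure — is provided as
a vetting utility; folding itself is consumed, not computed.

## Network assembly

Per-ncRNA site counts (rows of the same ncRNA summed across its TSSs)
become typed regulator → ncRNA edges weighted by the count. A full CtrA
site suppresses half-site edges for that ncRNA (a full site already implies
direct regulation); weights are not summed across types. Master-regulator
proteins and their own transcripts are distinct nodes (upper-case "CtrA"
protein vs lower-case "ctrA" target), keeping feed-forward loops acyclic.
Exports (SIF, GraphML, TSV) sort edges lexicographically so identical
inputs give byte-identical files.

## Synthetic data

The generators are pure functions of (config, seed) via numpy's Generator:

- **Genome** — i.i.d. background at configurable GC (default 0.67,
  matching the organism's GC-rich chromosome), with motif instances
  rejection-sampled from the PWM until their relative score falls in a
  requested range (consensus-mutation fallback for low ranges; bounded
  retries), planted at non-overlapping positions on random strands and
  recorded in a truth table. Every planted site rescored from the emitted
  genome falls in its requested range, which is what makes threshold
  recovery assertable.
- **Time courses** — per-phase multiplier templates (peak `fold` at the
  phase's characteristic time; U-shaped for G1-G2; flat for `None`), scaled
  by a log-uniform amplitude (10–1000) and perturbed by multiplicative
  lognormal noise (σ = 0.2 by default; the real table's values span 0 to
  ~26,000, i.e. heavy right tails, which motivates multiplicative noise).
  Fold changes are drawn log-uniformly from 8–32. The default phase mix
  mirrors the study set (6 G1, 2 G1-S, 10 S, 2 G2, 2 G1-G2, 20 flat).
- **Prediction tables** — true targets ranked at the top of a 100-entry
  candidate list padded with decoys; each confirming tool independently
  includes a true target with its configured overlap probability, with
  TargetRNA2 p-values < 0.05 for included truths. Confirming-tool decoys
  are drawn from a pool disjoint from the candidate list, so at overlap 1.0
  the integration recovers exactly the truth set and at 0.0 nothing.

What the synthetic data does *not* emulate: positional correlation between
promoters and planted sites, chromosomal replication-timing gradients in
expression, shared targets between ncRNAs, and tool-specific score
distributions. Passing synthetic tests therefore demonstrates correctness
of the algorithms under the stated statistical model, not biological
validity of predictions on real genomes.

## Numerical and design choices

- Pseudocount 0.5; frequency floor 1e-6 for matrices supplied as
  frequencies (log of zero otherwise).
- Retention threshold 0.6 with an inclusive comparison; exactness at the
  boundary is tested with a PWM whose column frequencies are powers of two,
  so window scores are exact binary floats.
- Overlapping above-threshold hits are all reported (no greedy
  non-overlapping selection): a 151-nt promoter can legitimately contain
  several half-sites, and the bundled count table does record multiples.
- `classify` tie at the peak: first time point wins (argmax semantics);
  profile times are fixed to the 0–140 grid.
- Rejection sampling caps: 10,000 draws per planted site (twice: column
  sampling, then consensus mutation) and 10,000 placement attempts.
- Problem sizes in tests and the acceptance script (genomes of 1–20 kb,
  100 random scanner instances, 1000 synthetic profiles) were chosen as the
  smallest sizes at which the properties are non-trivially exercised; all
  complete in seconds.

## Known limitations

- The published motif-count table cannot be regenerated here: the CtrA and
  DnaA matrices and the reference chromosome it was produced from are not
  bundled. The table is consumed as input; the scanner is validated on
  synthetic ground truth instead.
- The phase classifier is a reconstruction; curated published labels
  disagree with any mechanical rule on a minority of rows.
- Locus synonyms are not resolved; gene identity is a case-insensitive
  string match.
- CopraRNA confirmation has no significance cutoff of its own (any listed
  gene confirms), mirroring the integration rule's asymmetry between tools.
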