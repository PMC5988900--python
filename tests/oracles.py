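"""Independent brute-force reference implementations used only by tests.

Deliberately written in plain Python (no numpy, no shared code with the
package's scanner) so they can serve as oracles for the vectorized paths.
"""

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def revcomp(seq):
    return "".join(_COMP[c] for c in reversed(seq))


def window_score(freqs, window):
    """freqs: list over positions of dicts base -> frequency."""
    return sum(2 + math.log2(freqs[n][c]) for n, c in enumerate(window)) / len(window)


def max_score(freqs):
    return sum(max(2 + math.log2(f) for f in col.values()) for col in freqs) / len(freqs)


def brute_force_scan(freqs, seq, circular, threshold, both_strands=True):
    """All (start, strand) positions, 1-based, whose window scores at least
    threshold * S_max; windows containing N are skipped."""
    L = len(freqs)
    n = len(seq)
    smax = max_score(freqs)
    doubled = seq + seq
    starts = range(n) if circular else range(n - L + 1)
    hits = set()
    for i in starts:
        w = doubled[i:i + L]
        if "N" in w:
            continue
        if window_score(freqs, w) / smax >= threshold:
            hits.add((i + 1, "+"))
        if both_strands and window_score(freqs, revcomp(w)) / smax >= threshold:
            hits.add((i + 1, "-"))
    return hits


def brute_force_degenerate(pattern, seq, circular, both_strands=True):
    """(start, strand) set of degenerate matches; palindromic patterns are
    collapsed to one plus-strand record per duplex site."""
    L = len(pattern)
    n = len(seq)
    doubled = seq + seq
    starts = range(n) if circular else range(n - L + 1)

    def matches(w, pat):
        return all(c in IUPAC_SETS[p] for c, p in zip(w, pat))

    palindromic = pattern == "".join(
        {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}[c] for c in reversed(pattern)
    )
    hits = set()
    for i in starts:
        w = doubled[i:i + L]
        if matches(w, pattern):
            hits.add((i + 1, "+"))
        if both_strands and not palindromic and matches(revcomp(w), pattern):
            hits.add((i + 1, "-"))
    return hits


def interval_overlap_count(peaks, window):
    """Quadratic any-overlap count over plain (start, end) tuples."""
    ws, we = window
    return sum(1 for ps, pe in peaks if ps <= we and ws <= pe)
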