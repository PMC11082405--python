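"""Independent brute-force oracles used to cross-check the package.

Everything here is written as literal loops over the problem definition,
deliberately sharing no code path with the implementation under test.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
    "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def pam_ok(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in _IUPAC[p] for b, p in zip(seq, pattern))


def longest_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def gc_in_range(seq: str) -> bool:
    gc = sum(1 for c in seq if c in "GC")
    return 30 * len(seq) <= 100 * gc <= 75 * len(seq)


def brute_screen(seq: str, pos: int, ref: str, editor):
    """Site outcome by sliding a (spacer+PAM) window over both strands.

    ``pos`` is 1-based. Returns (label_or_'editable',
    [(start, end, strand, protospacer, pam, p), ...]).
    """
    L, pat = editor.spacer_length, editor.pam_pattern
    P = len(pat)
    if editor.editor_class.value == "CBE":
        strand = {"C": "+", "G": "-"}.get(ref)
    else:
        strand = {"A": "+", "T": "-"}.get(ref)
    if strand is None:
        return "base_match_error", []

    pam_found = False
    in_window = []
    n = len(seq)
    for start0 in range(n - L - P + 1):          # 0-based window start
        if strand == "+":
            proto = seq[start0:start0 + L]
            pam = seq[start0 + L:start0 + L + P]
            start1, end1 = start0 + 1, start0 + L
            if not (start1 <= pos <= end1):
                continue
            p = pos - start1 + 1
        else:
            # window layout on the minus strand: PAM then protospacer in
            # plus coordinates; both read as reverse complement
            pam = rc(seq[start0:start0 + P])
            proto = rc(seq[start0 + P:start0 + P + L])
            start1, end1 = start0 + P + 1, start0 + P + L
            if not (start1 <= pos <= end1):
                continue
            p = end1 - pos + 1
        if "N" in proto or "N" in pam:
            continue
        if proto[p - 1] != editor.target_base:
            continue
        if not pam_ok(pam, pat):
            continue
        pam_found = True
        if editor.window_start <= p <= editor.window_end:
            in_window.append((start1, end1, strand, proto, pam, p))
    if not pam_found:
        return "no_PAM", []
    if not in_window:
        return "activity_window_error", []
    kept = [c for c in in_window if longest_run(c[3]) <= 6]
    if not kept:
        return "continuous_identical_base_error", []
    kept = [c for c in kept if gc_in_range(c[3])]
    if not kept:
        return "GC_ratio_error", []
    return "editable", kept


def brute_offtargets(sequences: dict[str, str], query: str, max_mm: int,
                     pam_patterns=None, exclude=None):
    """All-positions mismatch scan. Returns a set of
    (chrom, start, end, strand, n_mismatches)."""
    L = len(query)
    P = len(pam_patterns[0]) if pam_patterns else 0
    hits = set()
    for chrom, seq in sequences.items():
        n = len(seq)
        for start0 in range(n - L - P + 1):
            window = seq[start0:start0 + L]
            mm = sum(1 for a, b in zip(window, query) if a != b)
            if mm <= max_mm and (
                    not pam_patterns
                    or any(pam_ok(seq[start0 + L:start0 + L + P], pat)
                           for pat in pam_patterns)):
                hits.add((chrom, start0 + 1, start0 + L, "+", mm))
        rseq = rc(seq)
        for start0 in range(n - L - P + 1):
            window = rseq[start0:start0 + L]
            mm = sum(1 for a, b in zip(window, query) if a != b)
            if mm <= max_mm and (
                    not pam_patterns
                    or any(pam_ok(rseq[start0 + L:start0 + L + P], pat)
                           for pat in pam_patterns)):
                hits.add((chrom, n - start0 - L + 1, n - start0, "-", mm))
    if exclude is not None:
        hits = {h for h in hits if h[:4] != exclude}
    return hits


def rra_exact(normalized_ranks) -> float:
    """Exact RRA score via the binomial tail identity
    BetaCDF(x; k, n-k+1) = P(Bin(n, x) >= k)."""
    r = sorted(normalized_ranks)
    n = len(r)
    best = 1.0
    for k, x in enumerate(r, start=1):
        tail = sum(math.comb(n, j) * x**j * (1 - x)**(n - j)
                   for j in range(k, n + 1))
        best = min(best, tail)
    return best


def rra_montecarlo(normalized_ranks, rng, n_draws: int = 100_000):
    """(estimate, per-k exact-se floor) for the min-over-k order-statistic
    probability, from sorted samples of 5 independent uniforms."""
    import numpy as np

    r = sorted(normalized_ranks)
    draws = np.sort(rng.uniform(size=(n_draws, len(r))), axis=1)
    probs = [(draws[:, k] <= r[k]).mean() for k in range(len(r))]
    return float(min(probs)), n_draws
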