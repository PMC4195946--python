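"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with the simplest possible algorithms
(quadratic DP, O(n^2) enumeration, literal re-scoring) and stay independent
of the package's implementation paths, sharing only the documented
conventions (scoring semantics, tie-breaks).
"""

from __future__ import annotations

NEG = float("-inf")


def sw_oracle(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -10,
    gap_extend: int = -25,
):
    """Plain quadratic Gotoh local alignment.

    Same documented conventions as the package aligner: gap of length L
    costs open + (L-1)*extend; N mismatches everything; endpoint is the
    first maximal cell in row-major order; traceback prefers substitution,
    then vertical gap (gap in B), then horizontal, and closing a gap over
    extending it.  Returns (score, aligned_a, aligned_b, a_start, b_start).
    """

    def s(x: str, y: str) -> int:
        return match if (x == y and x in "ACGT") else mismatch

    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s(a[i - 1], b[j - 1]), E[i][j], F[i][j])
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    ga, gb = [], []
    i, j, state = bi, bj, "H"
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            if H[i - 1][j - 1] + s(a[i - 1], b[j - 1]) == H[i][j]:
                ga.append(a[i - 1])
                gb.append(b[j - 1])
                i -= 1
                j -= 1
            elif F[i][j] == H[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "E":
            ga.append("-")
            gb.append(b[j - 1])
            state = "H" if H[i][j - 1] + gap_open == E[i][j] else "E"
            j -= 1
        else:
            ga.append(a[i - 1])
            gb.append("-")
            state = "H" if H[i - 1][j] + gap_open == F[i][j] else "F"
            i -= 1
    return int(best), "".join(reversed(ga)), "".join(reversed(gb)), i, j


def identity_of(ga: str, gb: str) -> float:
    """Identical-column fraction over all columns (gaps and N never match)."""
    if not ga:
        return 0.0
    hits = sum(1 for x, y in zip(ga, gb) if x == y and x != "-" and x != "N")
    return hits / len(ga)


def join_oracle(fragments, max_join_gap):
    """Brute-force element spans: group by (chrom, strand, id), sort, split
    at oversized gaps, take min/max."""
    groups = {}
    for f in fragments:
        groups.setdefault((f.chrom, f.strand, f.join_id), []).append((f.start, f.end))
    spans = []
    for key, ivs in groups.items():
        ivs.sort()
        cur = [ivs[0]]
        far = ivs[0][1]
        for s, e in ivs[1:]:
            if s - far > max_join_gap:
                spans.append((key[0], min(x for x, _ in cur), max(y for _, y in cur), key[1], key[2]))
                cur = []
                far = e
            cur.append((s, e))
            far = max(far, e)
        spans.append((key[0], min(x for x, _ in cur), max(y for _, y in cur), key[1], key[2]))
    return sorted(spans)


def pairs_oracle(elements, min_sep, max_sep):
    """O(n^2) candidate-pair enumeration."""
    out = set()
    for ea in elements:
        for eb in elements:
            if ea is eb:
                continue
            lo, hi = (ea, eb) if (ea.start, ea.end) <= (eb.start, eb.end) else (eb, ea)
            if lo.chrom != hi.chrom or lo.strand != hi.strand:
                continue
            sep = hi.start - lo.end
            if min_sep <= sep <= max_sep:
                out.add(((lo.chrom, lo.start, lo.end), (hi.chrom, hi.start, hi.end)))
    return out


def merge_oracle(spans):
    """Classic sort-and-sweep interval merge of (start, end) tuples with
    strict (>= 1 bp) overlap."""
    spans = sorted(spans)
    merged = []
    for s, e in spans:
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def median_pairwise_oracle(positions):
    """All-pairs median distance by literal enumeration."""
    import statistics

    ds = [
        abs(positions[i] - positions[j])
        for i in range(len(positions))
        for j in range(i + 1, len(positions))
    ]
    return statistics.median(ds)


def scan_oracle(seq, pwm, threshold):
    """Re-score every offset on both strands with the PWM's own scorer.

    Returns a set of (offset, strand) with score fraction strictly above
    the threshold; windows containing non-ACGT bases are skipped.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[c] for c in reversed(seq))
    k = pwm.length
    span = pwm.max_score - pwm.min_score
    hits = set()
    for strand, s in (("+", seq), ("-", rc)):
        for off in range(len(s) - k + 1):
            kmer = s[off : off + k]
            if any(c not in "ACGT" for c in kmer):
                continue
            frac = (pwm.score(kmer) - pwm.min_score) / span
            if frac > threshold:
                genomic = off if strand == "+" else len(seq) - k - off
                hits.add((genomic, strand))
    return hits
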