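"""Recombination-hotspot motif scanning and the two enrichment statistics.

The motif is a degenerate 13-mer consensus (default ``CCNCCNTNNCCNC``)
turned into a log-odds position weight matrix against a uniform background.
Hit strength is the fraction of the maximum attainable score after shifting
so the minimum attainable score is zero, making the >85% rule well defined
with negative weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotation_io import GenomeSource
from .pair_finder import reverse_complement

__all__ = [
    "MotifPwm",
    "MotifHit",
    "EnrichmentReport",
    "HOTSPOT_CONSENSUS",
    "build_pwm",
    "scan_sequence",
    "motif_density",
    "sample_background",
    "background_rate",
    "cluster_enrichment",
    "density_comparison",
]

HOTSPOT_CONSENSUS = "CCNCCNTNNCCNC"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class MotifPwm:
    """Log-odds PWM (columns ordered A, C, G, T)."""

    matrix: np.ndarray
    consensus: str

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=1).sum())

    def score(self, kmer: str) -> float:
        if len(kmer) != self.length:
            raise ValueError("k-mer length does not match motif length")
        total = 0.0
        for j, base in enumerate(kmer.upper()):
            if base not in _BASE_INDEX:
                raise ValueError(f"cannot score ambiguous base {base!r}")
            total += self.matrix[j, _BASE_INDEX[base]]
        return total

    def score_fraction(self, score: float) -> float:
        span = self.max_score - self.min_score
        return (score - self.min_score) / span if span else 1.0


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int  # 0-based offset of the match on the + strand of the sequence
    strand: str
    score: float
    score_fraction: float


@dataclass(frozen=True)
class EnrichmentReport:
    test: str
    observed: float
    expected: float
    p_value: float
    background: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "observed": self.observed,
            "expected": self.expected,
            "p_value": self.p_value,
            "background": self.background,
        }


def build_pwm(
    consensus: str = HOTSPOT_CONSENSUS, specified_base_weight: float = 0.85
) -> MotifPwm:
    """Log-odds PWM from a degenerate IUPAC consensus.

    Each column gives ``specified_base_weight`` probability to the allowed
    bases (split equally; uniform for N) and splits the remainder over the
    others; weights are log(p / 0.25).
    """
    if not consensus:
        raise ValueError("empty consensus")
    if not 0.0 < specified_base_weight < 1.0:
        raise ValueError("specified_base_weight must be in (0, 1)")
    mat = np.zeros((len(consensus), 4), dtype=np.float64)
    for j, code in enumerate(consensus.upper()):
        if code not in _IUPAC:
            raise ValueError(f"unknown IUPAC code {code!r}")
        allowed = _IUPAC[code]
        if len(allowed) == 4:
            probs = [0.25] * 4
        else:
            p_in = specified_base_weight / len(allowed)
            p_out = (1.0 - specified_base_weight) / (4 - len(allowed))
            probs = [p_in if b in allowed else p_out for b in "ACGT"]
        mat[j] = [math.log(p / 0.25) for p in probs]
    return MotifPwm(matrix=mat, consensus=consensus.upper())


def _scan_strand(codes: np.ndarray, pwm: MotifPwm) -> np.ndarray:
    """Score every offset; offsets whose window contains a non-ACGT base
    score -inf."""
    k = pwm.length
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.float64)
    n_off = n - k + 1
    scores = np.zeros(n_off, dtype=np.float64)
    valid = np.ones(n_off, dtype=bool)
    for j in range(k):
        window = codes[j : j + n_off]
        ok = window >= 0
        valid &= ok
        scores += pwm.matrix[j][np.where(ok, window, 0)]
    scores[~valid] = -np.inf
    return scores


def scan_sequence(
    seq: str, pwm: MotifPwm, threshold: float = 0.85, seq_id: str = "."
) -> list[MotifHit]:
    """Slide the PWM over both strands; emit hits with score fraction
    strictly above ``threshold``.  Windows containing N are skipped.
    Offsets are always reported on the + strand of ``seq``."""
    from ._sw import encode

    hits: list[MotifHit] = []
    k = pwm.length
    span = pwm.max_score - pwm.min_score
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        scores = _scan_strand(encode(s), pwm)
        frac = (scores - pwm.min_score) / span if span else np.ones_like(scores)
        for off in np.flatnonzero(frac > threshold):
            offset = int(off) if strand == "+" else len(seq) - k - int(off)
            hits.append(
                MotifHit(
                    seq_id=seq_id,
                    offset=offset,
                    strand=strand,
                    score=float(scores[off]),
                    score_fraction=float(frac[off]),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def motif_density(seq: str, pwm: MotifPwm, threshold: float = 0.85) -> float:
    """Strong-match hits per kb of sequence."""
    if not seq:
        raise ValueError("empty sequence")
    return len(scan_sequence(seq, pwm, threshold)) / (len(seq) / 1000.0)


def sample_background(
    genome: GenomeSource,
    lengths,
    n: int = 10_000,
    seed: int | None = None,
    max_n_fraction: float = 0.1,
    max_tries: int = 100,
) -> list[tuple[str, int, int]]:
    """Sample ``n`` intervals uniformly from the genome, with lengths drawn
    with replacement from ``lengths``; intervals whose N fraction exceeds
    ``max_n_fraction`` are redrawn."""
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    lengths = [int(x) for x in lengths]
    if not lengths:
        raise ValueError("need at least one template length")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.sequences)
    sizes = np.array([len(genome.sequences[c]) for c in chroms], dtype=np.float64)
    out = []
    for _ in range(n):
        length = lengths[rng.integers(0, len(lengths))]
        for _try in range(max_tries):
            ci = rng.choice(len(chroms), p=sizes / sizes.sum())
            chrom = chroms[ci]
            room = len(genome.sequences[chrom]) - length
            if room < 0:
                continue
            start = int(rng.integers(0, room + 1))
            seq = genome.fetch(chrom, start, start + length)
            if seq.count("N") / length <= max_n_fraction:
                out.append((chrom, start, start + length))
                break
        else:
            raise RuntimeError("could not place background interval; genome too gappy")
    return out


def background_rate(
    genome: GenomeSource,
    pwm: MotifPwm,
    lengths,
    threshold: float = 0.85,
    n: int = 10_000,
    seed: int | None = None,
) -> float:
    """Genome-background strong-match rate in hits per bp, estimated from
    randomly sampled intervals of comparable length."""
    intervals = sample_background(genome, lengths, n=n, seed=seed)
    total_hits = 0
    total_bp = 0
    for chrom, start, end in intervals:
        seq = genome.fetch(chrom, start, end)
        total_hits += len(scan_sequence(seq, pwm, threshold))
        total_bp += end - start
    return total_hits / total_bp if total_bp else 0.0


def cluster_enrichment(
    clusters,
    element_seqs: dict[str, str],
    pwm: MotifPwm,
    background_rate: float,
    threshold: float = 0.85,
    flank: int = 500,
) -> EnrichmentReport:
    """One-sided exact Poisson test for motif excess inside breakpoint
    clusters (each extended by ``flank`` bp per side, clipped to sequence
    bounds).  ``clusters`` holds (seq_id, start, end) element-local intervals.
    """
    observed = 0
    total_len = 0
    for seq_id, start, end in clusters:
        if seq_id not in element_seqs:
            raise KeyError(f"unknown element {seq_id!r}")
        seq = element_seqs[seq_id]
        lo = max(0, start - flank)
        hi = min(len(seq), end + flank)
        if lo >= hi:
            raise ValueError(f"empty cluster interval on {seq_id}")
        observed += len(scan_sequence(seq[lo:hi], pwm, threshold))
        total_len += hi - lo
    expected = background_rate * total_len
    if observed == 0:
        p = 1.0
    else:
        p = float(stats.poisson.sf(observed - 1, expected))  # P(X >= observed)
    return EnrichmentReport(
        test="one-sided exact Poisson",
        observed=float(observed),
        expected=float(expected),
        p_value=min(max(p, np.nextafter(0, 1)), 1.0),
        background=f"rate {background_rate:.3e} hits/bp over {total_len} bp interrogated",
    )


def density_comparison(
    cnv_element_densities,
    reference,
    alternative: str | None = None,
    method: str = "exact",
) -> EnrichmentReport:
    """Rank-based comparison of per-element motif densities.

    * scalar ``reference`` -> one-sample Wilcoxon signed-rank of the
      densities against that value (default alternative: greater);
    * sequence ``reference`` -> two-sample Mann-Whitney rank comparison
      (default alternative: two-sided).
    """
    dens = np.asarray(cnv_element_densities, dtype=np.float64)
    if dens.size < 1:
        raise ValueError("need at least one density")
    if np.isscalar(reference) or isinstance(reference, (int, float)):
        alt = alternative or "greater"
        diffs = dens - float(reference)
        if np.all(diffs == 0):
            p = 1.0
        else:
            mode = "exact" if method == "exact" else "approx"
            res = stats.wilcoxon(diffs, alternative=alt, method=mode)
            p = float(res.pvalue)
        return EnrichmentReport(
            test=f"wilcoxon-signed-rank ({alt}, {method})",
            observed=float(np.median(dens)),
            expected=float(reference),
            p_value=max(min(p, 1.0), np.nextafter(0, 1)),
            background=f"n={dens.size} vs scalar reference",
        )
    ref = np.asarray(reference, dtype=np.float64)
    alt = alternative or "two-sided"
    mode = "exact" if method == "exact" else "asymptotic"
    res = stats.mannwhitneyu(dens, ref, alternative=alt, method=mode)
    return EnrichmentReport(
        test=f"mann-whitney ({alt}, {method})",
        observed=float(np.median(dens)),
        expected=float(np.median(ref)),
        p_value=max(min(float(res.pvalue), 1.0), np.nextafter(0, 1)),
        background=f"n={dens.size} vs n={ref.size} reference elements",
    )
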