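"""Enumerate, align and filter candidate element pairs genome-wide.

The screen mirrors classic NAHR-substrate searches: same chromosome, same
orientation, bounded separation, then a local alignment that must reach an
identity and length threshold, and finally exclusion of pairs that overlap
directly oriented high-identity segmental duplications.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _sw
from .annotation_io import GenomeSource, HervElement, SegDup

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "HervPair",
    "DEFAULT_SCORING",
    "filter_elements_by_length",
    "enumerate_candidate_pairs",
    "local_align",
    "alignment_identity",
    "align_pair",
    "filter_pairs",
    "exclude_lcr_overlapping_pairs",
    "find_pairs",
    "write_pairs_tsv",
    "read_pairs_tsv",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring; a length-L gap costs gap_open + (L-1)*gap_extend."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -10
    gap_extend: int = -25

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class AlignmentResult:
    """A local alignment of two sequences.

    ``a_start``/``a_end`` (and the b counterparts) are element-local 0-based
    half-open coordinates of the aligned segment.  ``identity`` counts
    identical columns over all alignment columns, gap columns included.
    """

    aligned_a: str
    aligned_b: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    score: int
    identity: float
    aln_length: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b) or len(self.aligned_a) != self.aln_length:
            raise ValueError("gapped rows must both have aln_length columns")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity out of [0,1]")

    def column_positions(self) -> tuple[list[int], list[int]]:
        """Per-column element-local positions in A and B (-1 at gap columns)."""
        pa, pb = [], []
        i, j = self.a_start, self.b_start
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            pa.append(i if ca != "-" else -1)
            pb.append(j if cb != "-" else -1)
            if ca != "-":
                i += 1
            if cb != "-":
                j += 1
        return pa, pb


@dataclass(frozen=True)
class HervPair:
    """Two same-strand elements with their local alignment.

    ``elem_a`` is the proximal element (lower start coordinate);
    ``separation`` is the distance between inner edges.
    """

    elem_a: HervElement
    elem_b: HervElement
    alignment: AlignmentResult
    same_orientation: bool = True

    def __post_init__(self) -> None:
        if self.elem_a.chrom != self.elem_b.chrom:
            raise ValueError("pair spans two chromosomes")
        if self.elem_a.start > self.elem_b.start:
            raise ValueError("elem_a must be the proximal element")

    @property
    def chrom(self) -> str:
        return self.elem_a.chrom

    @property
    def separation(self) -> int:
        return self.elem_b.start - self.elem_a.end

    @property
    def pair_id(self) -> str:
        return (
            f"{self.chrom}:{self.elem_a.start}-{self.elem_a.end}"
            f"__{self.elem_b.start}-{self.elem_b.end}({self.elem_a.strand})"
        )


def filter_elements_by_length(
    elements: list[HervElement], min_length: int = 4000
) -> list[HervElement]:
    """Keep elements whose span is at least ``min_length`` (boundary inclusive)."""
    if min_length <= 0:
        raise ValueError("min_length must be positive")
    return [e for e in elements if e.length >= min_length]


def enumerate_candidate_pairs(
    elements: list[HervElement],
    min_sep: int = 10_000,
    max_sep: int = 10_000_000,
) -> list[tuple[HervElement, HervElement]]:
    """All same-chromosome, same-strand pairs with inner-edge separation in
    [min_sep, max_sep].  Overlapping elements (negative separation) never pair."""
    by_chrom: dict[str, list[HervElement]] = {}
    for e in elements:
        by_chrom.setdefault(e.chrom, []).append(e)
    out = []
    for chrom in sorted(by_chrom):
        elems = sorted(by_chrom[chrom], key=lambda e: (e.start, e.end))
        for i, ea in enumerate(elems):
            for eb in elems[i + 1 :]:
                if eb.strand != ea.strand:
                    continue
                sep = eb.start - ea.end
                if sep > max_sep:
                    break  # sorted by start; later elements only farther
                if sep < 0:
                    continue  # overlapping elements are never paired
                if min_sep <= sep <= max_sep:
                    out.append((ea, eb))
    return out


def local_align(
    seq_a: str, seq_b: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> AlignmentResult:
    """Optimal affine-gap local alignment (see :mod:`herv_nahr._sw` for the
    deterministic tie-break conventions).  N mismatches everything."""
    score, a0, a1, b0, b1, ga, gb = _sw.sw_align(
        seq_a, seq_b, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    aln_length = len(ga)
    ident = _column_identity(ga, gb) if aln_length else 0.0
    return AlignmentResult(
        aligned_a=ga,
        aligned_b=gb,
        a_start=a0,
        a_end=a1,
        b_start=b0,
        b_end=b1,
        score=score,
        identity=ident,
        aln_length=aln_length,
    )


def _column_identity(ga: str, gb: str) -> float:
    ident = sum(
        1 for x, y in zip(ga, gb) if x == y and x != "-" and x != "N" and x != "n"
    )
    return ident / len(ga)


def alignment_identity(alignment: AlignmentResult, count_gaps: bool = True) -> float:
    """Fraction of identical columns.

    With ``count_gaps`` (default) the denominator is all alignment columns;
    otherwise gap columns are excluded from the denominator.
    """
    ident = sum(
        1
        for x, y in zip(alignment.aligned_a, alignment.aligned_b)
        if x == y and x != "-" and x.upper() != "N"
    )
    if count_gaps:
        denom = alignment.aln_length
    else:
        denom = sum(
            1
            for x, y in zip(alignment.aligned_a, alignment.aligned_b)
            if x != "-" and y != "-"
        )
    return ident / denom if denom else 0.0


def align_pair(
    elem_a: HervElement,
    elem_b: HervElement,
    genome: GenomeSource,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> HervPair:
    """Align two same-strand elements and wrap them as a :class:`HervPair`.

    Both sequences are taken on the + genome strand for + pairs and both
    reverse-complemented for - pairs (equivalent for pair scoring).
    """
    if elem_a.strand != elem_b.strand:
        raise ValueError("pair elements must share a strand")
    sa = elem_a.sequence(genome)
    sb = elem_b.sequence(genome)
    if elem_a.strand == "-":
        sa = reverse_complement(sa)
        sb = reverse_complement(sb)
    aln = local_align(sa, sb, scoring)
    return HervPair(elem_a=elem_a, elem_b=elem_b, alignment=aln)


def filter_pairs(
    pairs: list[HervPair],
    min_identity: float = 0.94,
    min_aln_length: int = 2000,
) -> list[HervPair]:
    """Keep pairs meeting both identity and alignment-length thresholds
    (both boundaries inclusive)."""
    return [
        p
        for p in pairs
        if p.alignment.identity >= min_identity and p.alignment.aln_length >= min_aln_length
    ]


def _overlaps(start1: int, end1: int, start2: int, end2: int) -> bool:
    return start1 < end2 and start2 < end1


def exclude_lcr_overlapping_pairs(
    pairs: list[HervPair],
    segdups: list[SegDup],
    lcr_min_identity: float = 0.94,
    lcr_min_sep: int = 5_000,
    lcr_max_sep: int = 10_000_000,
) -> list[HervPair]:
    """Drop pairs overlapping a qualifying segmental duplication.

    Qualifying records are directly oriented ('+' relative orientation),
    intrachromosomal, with fracMatch > ``lcr_min_identity`` and copy
    separation (inner-edge gap) within [lcr_min_sep, lcr_max_sep].  A pair is
    dropped when either element overlaps either copy by >= 1 bp.
    """
    qualifying = []
    for sd in segdups:
        if sd.other_strand != "+" or sd.chrom != sd.other_chrom:
            continue
        if sd.frac_match <= lcr_min_identity:
            continue
        if sd.start <= sd.other_start:
            gap = sd.other_start - sd.end
        else:
            gap = sd.start - sd.other_end
        if lcr_min_sep <= gap <= lcr_max_sep:
            qualifying.append(sd)
    out = []
    for p in pairs:
        hit = False
        for sd in qualifying:
            if sd.chrom != p.chrom:
                continue
            for es, ee in ((p.elem_a.start, p.elem_a.end), (p.elem_b.start, p.elem_b.end)):
                if _overlaps(es, ee, sd.start, sd.end) or _overlaps(
                    es, ee, sd.other_start, sd.other_end
                ):
                    hit = True
                    break
            if hit:
                break
        if not hit:
            out.append(p)
    return out


def find_pairs(
    elements: list[HervElement],
    genome: GenomeSource,
    segdups: list[SegDup] | None = None,
    min_length: int = 4000,
    min_sep: int = 10_000,
    max_sep: int = 10_000_000,
    min_identity: float = 0.94,
    min_aln_length: int = 2000,
    scoring: ScoringScheme = DEFAULT_SCORING,
    same_family_only: bool = False,
) -> list[HervPair]:
    """Run the full pair screen: length filter, candidate enumeration,
    alignment, identity/length filter, and optional LCR exclusion.

    ``same_family_only`` pre-screens candidates by shared rep_name to bound
    runtime on large inputs (cross-family alignments essentially never reach
    the identity/length thresholds).
    """
    kept = filter_elements_by_length(elements, min_length=min_length)
    candidates = enumerate_candidate_pairs(kept, min_sep=min_sep, max_sep=max_sep)
    if same_family_only:
        candidates = [(a, b) for a, b in candidates if a.name == b.name]
    aligned = [align_pair(a, b, genome, scoring) for a, b in candidates]
    pairs = filter_pairs(aligned, min_identity=min_identity, min_aln_length=min_aln_length)
    if segdups:
        pairs = exclude_lcr_overlapping_pairs(pairs, segdups, lcr_min_identity=min_identity)
    return pairs


_PAIR_COLS = (
    "chrom",
    "a_start",
    "a_end",
    "b_start",
    "b_end",
    "strand",
    "identity",
    "aln_length",
    "separation",
    "score",
)


def write_pairs_tsv(pairs: list[HervPair], path: str, meta: list[str] | None = None) -> None:
    """TSV report, one pair per row; coordinates 0-based half-open (BED-like)."""
    with open(path, "w") as fh:
        for line in meta or []:
            fh.write("#" + line.rstrip("\n") + "\n")
        fh.write("#" + "\t".join(_PAIR_COLS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.chrom}\t{p.elem_a.start}\t{p.elem_a.end}\t{p.elem_b.start}\t"
                f"{p.elem_b.end}\t{p.elem_a.strand}\t{p.alignment.identity:.6f}\t"
                f"{p.alignment.aln_length}\t{p.separation}\t{p.alignment.score}\n"
            )


def read_pairs_tsv(path: str) -> list[dict]:
    """Read a pairs TSV back as plain dicts (no sequences attached)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append(
                {
                    "chrom": parts[0],
                    "a_start": int(parts[1]),
                    "a_end": int(parts[2]),
                    "b_start": int(parts[3]),
                    "b_end": int(parts[4]),
                    "strand": parts[5],
                    "identity": float(parts[6]),
                    "aln_length": int(parts[7]),
                    "separation": int(parts[8]),
                    "score": int(parts[9]),
                }
            )
    return rows
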