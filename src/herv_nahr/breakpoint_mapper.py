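"""Localize crossovers between paralogous elements using cis-morphisms.

A *cis-morphism* (paralogous sequence variant) is a base or indel difference
between the two aligned elements of a pair.  A recombinant junction sequence
follows element A's alleles up to the crossover and element B's alleles
after it; the crossover is therefore bounded by the last A-matching and
first B-matching informative cis-morphism.

Reported coordinates are 1-based (genome-browser convention); internal
positions are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pair_finder import AlignmentResult, ScoringScheme, local_align

__all__ = [
    "CisMorphism",
    "BreakpointCall",
    "JunctionMappingError",
    "find_cis_morphisms",
    "map_junction",
    "uncertainty_widths",
    "cnv_size",
    "format_size",
    "windowed_identity",
    "load_confirmed_breakpoints",
    "read_breakpoint_table",
    "write_breakpoint_table",
]


class JunctionMappingError(ValueError):
    """Raised when a junction cannot be interpreted as a single A->B crossover."""


@dataclass(frozen=True)
class CisMorphism:
    """One difference between the two elements of an aligned pair.

    ``column`` indexes the alignment column (first column of the run for
    indels).  ``pos_a``/``pos_b`` are element-local 0-based positions of the
    first affected base; for a gap the position where the missing bases
    would insert.
    """

    column: int
    kind: str  # substitution | insertion_in_a | insertion_in_b
    pos_a: int
    pos_b: int
    base_a: str
    base_b: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion_in_a", "insertion_in_b"):
            raise ValueError(f"unknown cis-morphism kind {self.kind!r}")


@dataclass(frozen=True)
class BreakpointCall:
    """A crossover localized between two informative cis-morphisms.

    Bound semantics: ``start_max``/``start_min`` bracket the proximal
    breakpoint (coordinates on element A's chromosome copy) and
    ``stop_min``/``stop_max`` the distal one (on element B's copy); all
    1-based.  ``column_lo``/``column_hi`` are the flanking alignment columns.
    """

    sample_id: str
    locus: str
    cnv_type: str
    chrom: str
    start_max: int
    start_min: int
    stop_min: int
    stop_max: int
    column_lo: int = -1
    column_hi: int = -1
    n_ambiguous: int = 0

    def __post_init__(self) -> None:
        if not (self.start_max <= self.start_min <= self.stop_min <= self.stop_max):
            raise ValueError(
                "bounds must satisfy start_max <= start_min <= stop_min <= stop_max"
            )

    @property
    def coordinates(self) -> str:
        return f"{self.chrom}:{self.start_max}-{self.stop_max}"


def find_cis_morphisms(alignment: AlignmentResult) -> list[CisMorphism]:
    """All columns (indel runs counted once) where the elements differ."""
    pa, pb = alignment.column_positions()
    ga, gb = alignment.aligned_a, alignment.aligned_b
    out: list[CisMorphism] = []
    col = 0
    n = alignment.aln_length
    while col < n:
        ca, cb = ga[col], gb[col]
        if ca == "-" or cb == "-":
            gap_in_a = ca == "-"
            run_end = col
            seq = []
            while run_end < n and (
                ga[run_end] == "-" if gap_in_a else gb[run_end] == "-"
            ):
                seq.append(gb[run_end] if gap_in_a else ga[run_end])
                run_end += 1
            pos_a = pa[col] if not gap_in_a else _next_position(pa, col)
            pos_b = pb[col] if gap_in_a else _next_position(pb, col)
            out.append(
                CisMorphism(
                    column=col,
                    kind="insertion_in_b" if gap_in_a else "insertion_in_a",
                    pos_a=pos_a,
                    pos_b=pos_b,
                    base_a="-" if gap_in_a else "".join(seq),
                    base_b="".join(seq) if gap_in_a else "-",
                )
            )
            col = run_end
        else:
            if ca != cb:
                out.append(
                    CisMorphism(
                        column=col,
                        kind="substitution",
                        pos_a=pa[col],
                        pos_b=pb[col],
                        base_a=ca,
                        base_b=cb,
                    )
                )
            col += 1
    return out


def _next_position(positions: list[int], col: int) -> int:
    """Element-local position at which a gap run anchors: the next consumed
    base, or one past the last consumed base at the alignment's right edge."""
    for c in range(col, len(positions)):
        if positions[c] >= 0:
            return positions[c]
    last = max((p for p in positions if p >= 0), default=-1)
    return last + 1


# ---------------------------------------------------------------------------
# Junction mapping

_JUNCTION_SCORING = ScoringScheme(match=1, mismatch=-1, gap_open=-5, gap_extend=-1)


def _position_map(junction: str, elem_seq: str) -> dict[int, int]:
    """Map element-local positions -> junction positions via local alignment."""
    aln = local_align(junction, elem_seq, _JUNCTION_SCORING)
    pj, pe = aln.column_positions()
    return {e: j for j, e in zip(pj, pe) if e >= 0 and j >= 0}


def _call_allele(
    cm: CisMorphism,
    junction: str,
    map_a: dict[int, int],
    map_b: dict[int, int],
) -> str | None:
    """Which element's allele the junction carries at this cis-morphism
    (``"A"``/``"B"``), or None if ambiguous/uncovered."""
    if cm.kind == "substitution":
        calls = set()
        for m, p in ((map_a, cm.pos_a), (map_b, cm.pos_b)):
            j = m.get(p)
            if j is None:
                continue
            # demand locally consistent mapping: neighbours align consecutively
            if m.get(p - 1) != j - 1 or m.get(p + 1) != j + 1:
                continue
            base = junction[j]
            if base == cm.base_a and base != cm.base_b:
                calls.add("A")
            elif base == cm.base_b and base != cm.base_a:
                calls.add("B")
            else:
                calls.add("?")  # matches neither allele: flag, never call
        if len(calls) == 1 and calls != {"?"}:
            return calls.pop()
        return None
    # Indel: the allele *with* the extra bases is checked by whether those
    # bases are present in the junction; the allele *without* by whether the
    # junction runs straight across the insertion point.
    if cm.kind == "insertion_in_a":
        with_pos, without_pos = cm.pos_a, cm.pos_b
        inserted = cm.base_a
        map_with, map_without = map_a, map_b
        with_allele, without_allele = "A", "B"
    else:
        with_pos, without_pos = cm.pos_b, cm.pos_a
        inserted = cm.base_b
        map_with, map_without = map_b, map_a
        with_allele, without_allele = "B", "A"
    # "with" allele: the inserted bases and one base of context on each side
    # must map to consecutive junction positions with matching bases.
    length = len(inserted)
    span = [map_with.get(with_pos + k) for k in range(-1, length + 1)]
    has_with = (
        all(j is not None for j in span)
        and all(span[k + 1] == span[k] + 1 for k in range(len(span) - 1))
        and all(junction[span[1 + k]] == inserted[k] for k in range(length))
    )
    # "without" allele: the junction runs straight across the insertion point.
    j_left = map_without.get(without_pos - 1)
    j_right = map_without.get(without_pos)
    has_without = j_left is not None and j_right is not None and j_right == j_left + 1
    if has_with == has_without:  # both or neither: ambiguous near indel clusters
        return None
    return with_allele if has_with else without_allele


def map_junction(
    junction_seq: str,
    alignment: AlignmentResult,
    seq_a: str,
    seq_b: str,
    chrom: str = ".",
    a_offset: int = 0,
    b_offset: int = 0,
    sample_id: str = ".",
    locus: str = ".",
    cnv_type: str = "Del",
) -> BreakpointCall:
    """Localize a recombinant junction's crossover between cis-morphisms.

    ``seq_a``/``seq_b`` are the full element sequences that produced
    ``alignment``; ``a_offset``/``b_offset`` are their genomic start
    positions (0-based) used to report 1-based genomic bounds.

    Raises :class:`JunctionMappingError` when the junction matches a single
    element throughout (no crossover) or switches template more than once
    (possible complex event).
    """
    if not junction_seq:
        raise ValueError("empty junction sequence")
    cis = find_cis_morphisms(alignment)
    if not cis:
        raise JunctionMappingError("elements are identical; no informative cis-morphisms")
    map_a = _position_map(junction_seq, seq_a)
    map_b = _position_map(junction_seq, seq_b)
    calls: list[tuple[CisMorphism, str]] = []
    n_ambiguous = 0
    for cm in cis:
        allele = _call_allele(cm, junction_seq, map_a, map_b)
        if allele is None:
            n_ambiguous += 1
        else:
            calls.append((cm, allele))
    informative = calls
    if not informative:
        raise JunctionMappingError("no informative cis-morphisms covered by the junction")
    alleles = "".join(a for _, a in informative)
    if "B" not in alleles:
        raise JunctionMappingError("junction matches element A throughout; no crossover")
    if "A" not in alleles:
        raise JunctionMappingError("junction matches element B throughout; no crossover")
    first_b = alleles.index("B")
    if first_b == 0:
        raise JunctionMappingError(
            "junction matches element B before any A-matching cis-morphism; no proximal bound"
        )
    if "A" in alleles[first_b:]:
        raise JunctionMappingError("possible complex event: multiple template switches")
    cm_lo = informative[first_b - 1][0]
    cm_hi = informative[first_b][0]
    return BreakpointCall(
        sample_id=sample_id,
        locus=locus,
        cnv_type=cnv_type,
        chrom=chrom,
        start_max=a_offset + cm_lo.pos_a + 1,
        start_min=a_offset + cm_hi.pos_a + 1,
        stop_min=b_offset + cm_lo.pos_b + 1,
        stop_max=b_offset + cm_hi.pos_b + 1,
        column_lo=cm_lo.column,
        column_hi=cm_hi.column,
        n_ambiguous=n_ambiguous,
    )


def uncertainty_widths(call: BreakpointCall) -> tuple[int, int]:
    """(proximal, distal) uncertainty widths in bp."""
    return (call.start_min - call.start_max, call.stop_max - call.stop_min)


def cnv_size(call: BreakpointCall) -> int:
    """CNV size in bases: inner-bound difference (stop_min - start_min)."""
    return call.stop_min - call.start_min


def format_size(bases: int) -> str:
    """Human size string at 3 significant figures (bp / kb / Mb)."""
    if bases < 1000:
        return f"{bases} bp"
    if bases < 10**6:
        value, unit = bases / 1e3, "kb"
    else:
        value, unit = bases / 1e6, "Mb"
    rounded = float(f"{value:.3g}")
    if rounded == int(rounded) and rounded >= 100:
        return f"{int(rounded)} {unit}"
    return f"{rounded:g} {unit}"


def windowed_identity(alignment: AlignmentResult, window: int = 50) -> np.ndarray:
    """Per-column identity over a centered ``window``-column window
    (truncated at the alignment ends)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    ga, gb = alignment.aligned_a, alignment.aligned_b
    eq = np.fromiter(
        (x == y and x != "-" and x.upper() != "N" for x, y in zip(ga, gb)),
        dtype=np.float64,
        count=alignment.aln_length,
    )
    n = eq.shape[0]
    half_lo = (window - 1) // 2
    half_hi = window // 2
    csum = np.concatenate([[0.0], np.cumsum(eq)])
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


# ---------------------------------------------------------------------------
# Breakpoint tables (Table-1-like reports)

_BP_COLS = (
    "patient",
    "locus",
    "type",
    "chrom",
    "start_max",
    "start_min",
    "stop_min",
    "stop_max",
)


def write_breakpoint_table(calls: list[BreakpointCall], path: str, meta=None) -> None:
    with open(path, "w") as fh:
        for line in meta or []:
            fh.write("#" + line.rstrip("\n") + "\n")
        fh.write("#" + "\t".join(_BP_COLS + ("coordinates", "size")) + "\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.locus}\t{c.cnv_type}\t{c.chrom}\t{c.start_max}\t"
                f"{c.start_min}\t{c.stop_min}\t{c.stop_max}\t{c.coordinates}\t"
                f"{format_size(cnv_size(c))}\n"
            )


def read_breakpoint_table(path: str) -> list[BreakpointCall]:
    calls = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}: line {ln}: expected >= 8 columns")
            calls.append(
                BreakpointCall(
                    sample_id=parts[0],
                    locus=parts[1],
                    cnv_type=parts[2],
                    chrom=parts[3],
                    start_max=int(parts[4]),
                    start_min=int(parts[5]),
                    stop_min=int(parts[6]),
                    stop_max=int(parts[7]),
                )
            )
    return calls


def load_confirmed_breakpoints() -> list[BreakpointCall]:
    """The ten molecularly confirmed CNV breakpoint calls bundled with the
    package (GRCh37/hg19 coordinates)."""
    from importlib.resources import files

    path = files("herv_nahr").joinpath("data/confirmed_breakpoints.tsv")
    import tempfile, os

    # importlib.resources may hand back a zip path; materialise if needed.
    try:
        return read_breakpoint_table(str(path))
    except (FileNotFoundError, OSError):  # pragma: no cover
        with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as tmp:
            tmp.write(path.read_text())
            name = tmp.name
        try:
            return read_breakpoint_table(name)
        finally:
            os.unlink(name)
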