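"""Cross-reference CNV calls with predicted element pairs, and place
flanking probes for a targeted array design.

CNV calls carry probe-bounded breakpoint-uncertainty intervals: proximal =
[last normal probe, first altered probe], distal = [last altered probe,
first normal probe].
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation_io import HervElement
from .pair_finder import HervPair

__all__ = [
    "CnvCall",
    "ProbePlacement",
    "uncertainty_intervals_from_probes",
    "match_cnvs_to_pairs",
    "place_flanking_probes",
    "read_cnv_table",
    "write_cnv_table",
]


@dataclass(frozen=True)
class CnvCall:
    """One deletion/duplication call with probe-bounded uncertainty intervals
    (0-based half-open internally)."""

    sample_id: str
    chrom: str
    cnv_type: str  # deletion | duplication
    proximal_start: int
    proximal_end: int
    distal_start: int
    distal_end: int

    def __post_init__(self) -> None:
        if self.cnv_type not in ("deletion", "duplication"):
            raise ValueError(f"unknown CNV type {self.cnv_type!r}")
        if self.proximal_start >= self.proximal_end or self.distal_start >= self.distal_end:
            raise ValueError("uncertainty intervals must be non-empty")
        if self.proximal_end > self.distal_start:
            raise ValueError("proximal uncertainty must lie entirely left of distal")

    @property
    def proximal_uncertainty(self) -> tuple[int, int]:
        return (self.proximal_start, self.proximal_end)

    @property
    def distal_uncertainty(self) -> tuple[int, int]:
        return (self.distal_start, self.distal_end)


@dataclass(frozen=True)
class ProbePlacement:
    """Flanking probes designed around one pair (n per side per element);
    ``probes`` holds (chrom, start, end, label) tuples."""

    pair_id: str
    probes: tuple[tuple[str, int, int, str], ...]
    unplaceable_sides: tuple[str, ...] = ()

    @property
    def placeable(self) -> bool:
        return not self.unplaceable_sides


def uncertainty_intervals_from_probes(
    probe_positions, probe_states
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Probe-run bounds -> (proximal, distal) uncertainty intervals.

    ``probe_states`` entries are 'normal'/'altered' (or 'N'/'A'); the altered
    probes must form one contiguous run with at least one normal probe on
    each side.  Intervals are closed on probe positions and returned as
    half-open [last_normal, first_altered+1) style tuples on positions.
    """
    positions = list(probe_positions)
    states = [str(s).upper()[0] for s in probe_states]
    if len(positions) != len(states):
        raise ValueError("positions and states differ in length")
    if any(positions[i] >= positions[i + 1] for i in range(len(positions) - 1)):
        raise ValueError("probe positions must be strictly increasing")
    if any(s not in "NA" for s in states):
        raise ValueError("probe states must be 'normal' or 'altered'")
    altered = [i for i, s in enumerate(states) if s == "A"]
    if not altered:
        raise ValueError("no altered probes: no CNV to bound")
    first, last = altered[0], altered[-1]
    if last - first + 1 != len(altered):
        raise ValueError("altered probes do not form a contiguous run")
    if first == 0 or last == len(states) - 1:
        raise ValueError("altered run touches the array edge; cannot bound breakpoint")
    proximal = (positions[first - 1], positions[first])
    distal = (positions[last], positions[last + 1])
    return proximal, distal


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def match_cnvs_to_pairs(
    cnvs: list[CnvCall],
    elements: list[HervElement] | None = None,
    pairs: list[HervPair] | None = None,
) -> list[dict]:
    """Flag CNVs with one element in each breakpoint-uncertainty interval.

    Loose mode (``elements``): any element overlapping each interval flags
    the CNV.  Strict mode (``pairs``): the proximal and distal elements must
    additionally be the two elements of one emitted pair, whose id is
    reported.  Returns one record per CNV with flag and supporting ids.
    """
    if (elements is None) == (pairs is None):
        raise ValueError("supply exactly one of elements= or pairs=")
    out = []
    for cnv in cnvs:
        rec = {"cnv": cnv, "flagged": False, "pair_id": None}
        if pairs is not None:
            for p in pairs:
                if p.chrom != cnv.chrom:
                    continue
                if _overlaps(
                    p.elem_a.start, p.elem_a.end, *cnv.proximal_uncertainty
                ) and _overlaps(p.elem_b.start, p.elem_b.end, *cnv.distal_uncertainty):
                    rec["flagged"] = True
                    rec["pair_id"] = p.pair_id
                    break
        else:
            prox = any(
                e.chrom == cnv.chrom
                and _overlaps(e.start, e.end, *cnv.proximal_uncertainty)
                for e in elements
            )
            dist = any(
                e.chrom == cnv.chrom
                and _overlaps(e.start, e.end, *cnv.distal_uncertainty)
                for e in elements
            )
            rec["flagged"] = prox and dist
        out.append(rec)
    return out


def place_flanking_probes(
    pairs: list[HervPair],
    chrom_lengths: dict[str, int],
    n_per_side: int = 5,
    probe_length: int = 60,
    spacing: int = 200,
    repeat_mask: list[tuple[str, int, int]] | None = None,
    search_window: int = 10_000,
) -> list[ProbePlacement]:
    """Place ``n_per_side`` probes immediately outside each element edge.

    Candidate probe starts step outward by ``spacing`` from the element
    edge; positions overlapping any masked repeat interval are skipped, up
    to ``search_window`` bp from the edge.  A side where fewer than
    ``n_per_side`` probes fit is recorded in ``unplaceable_sides`` rather
    than raising.
    """
    mask_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in repeat_mask or []:
        mask_by_chrom.setdefault(chrom, []).append((start, end))
    placements = []
    for pair in pairs:
        chrom = pair.chrom
        chrom_len = chrom_lengths.get(chrom)
        if chrom_len is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        mask = mask_by_chrom.get(chrom, [])
        probes: list[tuple[str, int, int, str]] = []
        unplaceable: list[str] = []
        for elem_label, elem in (("a", pair.elem_a), ("b", pair.elem_b)):
            for side in ("left", "right"):
                placed = _place_side(
                    elem, side, chrom_len, mask, n_per_side, probe_length, spacing,
                    search_window,
                )
                if placed is None:
                    unplaceable.append(f"{elem_label}:{side}")
                else:
                    probes.extend(
                        (chrom, s, s + probe_length, f"{elem_label}:{side}:{i}")
                        for i, s in enumerate(placed)
                    )
        placements.append(
            ProbePlacement(
                pair_id=pair.pair_id,
                probes=tuple(probes),
                unplaceable_sides=tuple(unplaceable),
            )
        )
    return placements


def _place_side(
    elem: HervElement,
    side: str,
    chrom_len: int,
    mask: list[tuple[int, int]],
    n: int,
    probe_length: int,
    spacing: int,
    search_window: int,
) -> list[int] | None:
    step = probe_length + spacing
    placed: list[int] = []
    offset = spacing
    while len(placed) < n:
        if side == "left":
            start = elem.start - offset - probe_length
            if start < 0 or elem.start - start > search_window:
                return None
        else:
            start = elem.end + offset
            if start + probe_length > chrom_len or start - elem.end > search_window:
                return None
        end = start + probe_length
        if _overlaps(start, end, elem.start, elem.end):
            return None
        if not any(_overlaps(start, end, ms, me) for ms, me in mask):
            placed.append(start)
        offset += step
    return sorted(placed)


_CNV_COLS = (
    "sample_id",
    "chrom",
    "cnv_type",
    "proximal_start",
    "proximal_end",
    "distal_start",
    "distal_end",
)


def read_cnv_table(path: str) -> list[CnvCall]:
    """TSV dialect with explicit probe-bound columns (0-based half-open)."""
    out = []
    with open(path) as fh:
        header = None
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith("#"):
                header = line.lstrip("#").rstrip("\n").split("\t")
                continue
            parts = line.rstrip("\n").split("\t")
            cols = header or list(_CNV_COLS)
            idx = {c: i for i, c in enumerate(cols)}
            try:
                out.append(
                    CnvCall(
                        sample_id=parts[idx["sample_id"]],
                        chrom=parts[idx["chrom"]],
                        cnv_type=parts[idx["cnv_type"]],
                        proximal_start=int(parts[idx["proximal_start"]]),
                        proximal_end=int(parts[idx["proximal_end"]]),
                        distal_start=int(parts[idx["distal_start"]]),
                        distal_end=int(parts[idx["distal_end"]]),
                    )
                )
            except (KeyError, ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {ln}: {exc}") from exc
    return out


def write_cnv_table(cnvs: list[CnvCall], path: str, meta=None) -> None:
    with open(path, "w") as fh:
        for line in meta or []:
            fh.write("#" + line.rstrip("\n") + "\n")
        fh.write("#" + "\t".join(_CNV_COLS) + "\n")
        for c in cnvs:
            fh.write(
                f"{c.sample_id}\t{c.chrom}\t{c.cnv_type}\t{c.proximal_start}\t"
                f"{c.proximal_end}\t{c.distal_start}\t{c.distal_end}\n"
            )
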