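"""Condense pairs into susceptibility regions and summarise genome coverage."""

from __future__ import annotations

from dataclasses import dataclass

from .pair_finder import HervPair

__all__ = [
    "SusceptibilityRegion",
    "pair_span",
    "condense_regions",
    "condense_spans",
    "coverage_stats",
    "write_regions_bed",
    "write_coverage_tsv",
]


@dataclass(frozen=True)
class SusceptibilityRegion:
    """Maximal merge of overlapping pair spans on one chromosome."""

    chrom: str
    start: int
    end: int
    contributing_pairs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("region must have positive length")

    @property
    def length(self) -> int:
        return self.end - self.start


def pair_span(pair: HervPair) -> tuple[str, int, int]:
    """The genomic segment deletable/duplicable by the pair: outer element span."""
    return (pair.chrom, pair.elem_a.start, pair.elem_b.end)


def condense_spans(spans: list[tuple[str, int, int, str]]) -> list[SusceptibilityRegion]:
    """Sweep-line merge of (chrom, start, end, pair_id) spans; >=1 bp overlap merges."""
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, pid in spans:
        by_chrom.setdefault(chrom, []).append((start, end, pid))
    regions = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom])
        cur_start, cur_end, ids = None, None, []
        for start, end, pid in items:
            if cur_start is None:
                cur_start, cur_end, ids = start, end, [pid]
            elif start < cur_end:  # strict: bookended spans do not merge
                cur_end = max(cur_end, end)
                ids.append(pid)
            else:
                regions.append(
                    SusceptibilityRegion(chrom, cur_start, cur_end, tuple(ids))
                )
                cur_start, cur_end, ids = start, end, [pid]
        if cur_start is not None:
            regions.append(SusceptibilityRegion(chrom, cur_start, cur_end, tuple(ids)))
    return regions


def condense_regions(pairs: list[HervPair]) -> list[SusceptibilityRegion]:
    """Merge overlapping pair spans per chromosome into maximal regions."""
    spans = []
    for p in pairs:
        chrom, start, end = pair_span(p)
        spans.append((chrom, start, end, p.pair_id))
    return condense_spans(spans)


def coverage_stats(
    regions: list[SusceptibilityRegion], chrom_lengths: dict[str, int]
) -> dict:
    """Per-chromosome covered fraction plus genome totals.

    Returns ``{"per_chrom": {chrom: {"covered_bp", "length", "fraction"}},
    "genome": {"covered_bp", "covered_mb", "total_bp", "percent"}}``.
    """
    per_chrom = {
        c: {"covered_bp": 0, "length": length, "fraction": 0.0}
        for c, length in chrom_lengths.items()
    }
    for r in regions:
        if r.chrom not in per_chrom:
            raise KeyError(f"region chromosome {r.chrom!r} missing from chrom lengths")
        if r.end > per_chrom[r.chrom]["length"]:
            raise ValueError(f"region {r.chrom}:{r.start}-{r.end} exceeds chromosome length")
        per_chrom[r.chrom]["covered_bp"] += r.length
    for c, rec in per_chrom.items():
        rec["fraction"] = rec["covered_bp"] / rec["length"] if rec["length"] else 0.0
    covered = sum(rec["covered_bp"] for rec in per_chrom.values())
    total = sum(rec["length"] for rec in per_chrom.values())
    return {
        "per_chrom": per_chrom,
        "genome": {
            "covered_bp": covered,
            "covered_mb": covered / 1e6,
            "total_bp": total,
            "percent": 100.0 * covered / total if total else 0.0,
        },
    }


def write_regions_bed(regions, path: str, meta: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in meta or []:
            fh.write("#" + line.rstrip("\n") + "\n")
        fh.write("#chrom\tstart\tend\tn_pairs\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{len(r.contributing_pairs)}\n")


def write_coverage_tsv(stats: dict, path: str, meta: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in meta or []:
            fh.write("#" + line.rstrip("\n") + "\n")
        fh.write("#chrom\tcovered_bp\tchrom_length\tpercent\n")
        for chrom in sorted(stats["per_chrom"]):
            rec = stats["per_chrom"][chrom]
            fh.write(
                f"{chrom}\t{rec['covered_bp']}\t{rec['length']}\t{100.0 * rec['fraction']:.4f}\n"
            )
        g = stats["genome"]
        fh.write(f"genome\t{g['covered_bp']}\t{g['total_bp']}\t{g['percent']:.4f}\n")
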