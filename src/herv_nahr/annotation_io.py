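"""Readers and writers for the annotation tables and sequences the pipeline touches.

All coordinates are handled 0-based half-open internally.  Report writers
convert to 1-based inclusive coordinates (the convention of genome-browser
tables) at the output boundary only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

__all__ = [
    "RepeatAnnotation",
    "HervElement",
    "GenomeSource",
    "SegDup",
    "AnnotationParseError",
    "read_rmsk_table",
    "write_rmsk_table",
    "join_fragments",
    "read_genome_fasta",
    "write_genome_fasta",
    "write_bed",
    "read_bed",
    "read_segdup_table",
    "write_segdup_table",
    "read_chrom_sizes",
]


class AnnotationParseError(ValueError):
    """Raised for malformed annotation tables; message names the offending line."""


@dataclass(frozen=True)
class RepeatAnnotation:
    """One RepeatMasker fragment row.

    ``join_id`` is the RepeatMasker ID linking fragments of a single
    interrupted element.
    """

    chrom: str
    start: int
    end: int
    strand: str
    rep_name: str
    rep_class: str = ""
    rep_family: str = ""
    join_id: int = 0

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.join_id < 0:
            raise ValueError(f"negative join_id {self.join_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HervElement:
    """A candidate element: RepeatMasker fragments joined by shared ID."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    join_id: int
    fragments: tuple[RepeatAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"invalid element interval {self.start}-{self.end}")
        for f in self.fragments:
            if f.chrom != self.chrom or f.strand != self.strand or f.join_id != self.join_id:
                raise ValueError("fragment does not belong to element")
            if f.start < self.start or f.end > self.end:
                raise ValueError("element interval does not cover fragment")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, genome: "GenomeSource") -> str:
        """Element sequence on the + genome strand (no reverse complement)."""
        return genome.fetch(self.chrom, self.start, self.end)


@dataclass
class GenomeSource:
    """In-memory genome: chromosome name -> upper-case sequence."""

    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(f"interval {chrom}:{start}-{end} out of bounds (len {len(seq)})")
        return seq[start:end]


@dataclass(frozen=True)
class SegDup:
    """One segmental-duplication record (genomicSuperDups dialect).

    ``other_strand`` is the orientation of the paralogous copy relative to
    this one: '+' means directly oriented.
    """

    chrom: str
    start: int
    end: int
    other_chrom: str
    other_start: int
    other_end: int
    other_strand: str
    frac_match: float


# ---------------------------------------------------------------------------
# RepeatMasker tables


_RMSK_REQUIRED = ("genoName", "genoStart", "genoEnd", "strand", "repName", "id")


def _parse_rmsk_ucsc(lines: list[str], path: str) -> list[RepeatAnnotation]:
    header = lines[0].rstrip("\n").lstrip("#").split("\t")
    idx = {name: i for i, name in enumerate(header)}
    for col in _RMSK_REQUIRED:
        if col not in idx:
            raise AnnotationParseError(f"{path}: missing column {col!r} in header")
    out = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        try:
            start = int(parts[idx["genoStart"]])
            end = int(parts[idx["genoEnd"]])
            ann = RepeatAnnotation(
                chrom=parts[idx["genoName"]],
                start=start,
                end=end,
                strand=parts[idx["strand"]],
                rep_name=parts[idx["repName"]],
                rep_class=parts[idx["repClass"]] if "repClass" in idx else "",
                rep_family=parts[idx["repFamily"]] if "repFamily" in idx else "",
                join_id=int(parts[idx["id"]]),
            )
        except (ValueError, IndexError) as exc:
            raise AnnotationParseError(f"{path}: line {ln}: {exc}") from exc
        out.append(ann)
    return out


def _parse_rmsk_out(lines: list[str], path: str) -> list[RepeatAnnotation]:
    # RepeatMasker .out: two header lines + blank, whitespace-separated rows,
    # 1-based inclusive query coordinates, strand 'C' for complement.
    out = []
    for ln, line in enumerate(lines, start=1):
        s = line.strip()
        if not s or s.startswith(("SW", "score")):
            continue
        parts = s.split()
        if len(parts) < 15:
            raise AnnotationParseError(f"{path}: line {ln}: too few columns")
        try:
            start = int(parts[5]) - 1
            end = int(parts[6])
            strand = "+" if parts[8] == "+" else "-"
            rc = parts[10]
            rep_class, _, rep_family = rc.partition("/")
            ann = RepeatAnnotation(
                chrom=parts[4],
                start=start,
                end=end,
                strand=strand,
                rep_name=parts[9],
                rep_class=rep_class,
                rep_family=rep_family,
                join_id=int(parts[14]),
            )
        except ValueError as exc:
            raise AnnotationParseError(f"{path}: line {ln}: {exc}") from exc
        out.append(ann)
    return out


def read_rmsk_table(path: str) -> list[RepeatAnnotation]:
    """Read a repeat annotation table, auto-detecting the dialect.

    Supports the UCSC rmsk tab-separated dialect (header naming
    genoStart/genoEnd/strand/repName/id columns) and the RepeatMasker
    ``.out`` dialect.  Returns 0-based half-open coordinates.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        return []
    first = lines[0]
    if "genoStart" in first and "genoEnd" in first:
        return _parse_rmsk_ucsc(lines, path)
    if first.split()[:1] in (["SW"], ["score"]) or (
        len(first.split()) >= 15 and not first.startswith("#")
    ):
        return _parse_rmsk_out(lines, path)
    raise AnnotationParseError(f"{path}: unrecognised repeat-table dialect")


def write_rmsk_table(annotations: list[RepeatAnnotation], path: str) -> None:
    """Write annotations in the UCSC rmsk dialect (subset of columns)."""
    with open(path, "w") as fh:
        fh.write(
            "#genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\tid\n"
        )
        for a in annotations:
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{a.strand}\t{a.rep_name}\t"
                f"{a.rep_class}\t{a.rep_family}\t{a.join_id}\n"
            )


def join_fragments(
    annotations: list[RepeatAnnotation], max_join_gap: int = 5000
) -> list[HervElement]:
    """Merge fragments sharing (chrom, strand, join_id) into elements.

    Fragments are sorted by start; a run is split wherever the gap between
    consecutive fragments exceeds ``max_join_gap``.  The element name is the
    rep_name of its longest fragment.
    """
    if max_join_gap < 0:
        raise ValueError("max_join_gap must be >= 0")
    groups: dict[tuple[str, str, int], list[RepeatAnnotation]] = {}
    for a in annotations:
        groups.setdefault((a.chrom, a.strand, a.join_id), []).append(a)
    elements = []
    for (chrom, strand, join_id), frags in groups.items():
        frags.sort(key=lambda f: (f.start, f.end))
        run: list[RepeatAnnotation] = []
        run_end = None
        for f in frags:
            if run and f.start - run_end > max_join_gap:
                elements.append(_element_from_run(chrom, strand, join_id, run))
                run = []
                run_end = None
            run.append(f)
            run_end = f.end if run_end is None else max(run_end, f.end)
        if run:
            elements.append(_element_from_run(chrom, strand, join_id, run))
    elements.sort(key=lambda e: (e.chrom, e.start, e.end))
    return elements


def _element_from_run(
    chrom: str, strand: str, join_id: int, run: list[RepeatAnnotation]
) -> HervElement:
    longest = max(run, key=lambda f: (f.length, -f.start))
    return HervElement(
        chrom=chrom,
        start=min(f.start for f in run),
        end=max(f.end for f in run),
        strand=strand,
        name=longest.rep_name,
        join_id=join_id,
        fragments=tuple(run),
    )


# ---------------------------------------------------------------------------
# FASTA / BED / segdup / chrom.sizes


def read_genome_fasta(path: str) -> GenomeSource:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return GenomeSource(sequences=seqs)


def write_genome_fasta(genome: GenomeSource, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome.sequences):
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(intervals, path: str, header: str | None = None) -> None:
    """Write BED lines (0-based half-open); interval tuples may carry
    optional name/score/strand fields."""
    with open(path, "w") as fh:
        if header:
            fh.write("#" + header.lstrip("#").rstrip("\n") + "\n")
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path: str) -> list[tuple]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise AnnotationParseError(f"{path}: line {ln}: fewer than 3 BED columns")
            try:
                iv = (parts[0], int(parts[1]), int(parts[2]), *parts[3:])
            except ValueError as exc:
                raise AnnotationParseError(f"{path}: line {ln}: {exc}") from exc
            if iv[1] < 0 or iv[1] >= iv[2]:
                raise AnnotationParseError(f"{path}: line {ln}: invalid interval")
            out.append(iv)
    return out


_SEGDUP_COLS = (
    "chrom",
    "chromStart",
    "chromEnd",
    "strand",
    "otherChrom",
    "otherStart",
    "otherEnd",
    "fracMatch",
)


def read_segdup_table(path: str) -> list[SegDup]:
    """Read a UCSC genomicSuperDups-style table.

    The ``strand`` column carries the orientation of the paralogous copy
    relative to the record's own copy, matching the UCSC schema.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return []
        cols = header.lstrip("#").rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(cols)}
        for col in _SEGDUP_COLS:
            if col not in idx:
                raise AnnotationParseError(f"{path}: missing column {col!r}")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                sd = SegDup(
                    chrom=parts[idx["chrom"]],
                    start=int(parts[idx["chromStart"]]),
                    end=int(parts[idx["chromEnd"]]),
                    other_chrom=parts[idx["otherChrom"]],
                    other_start=int(parts[idx["otherStart"]]),
                    other_end=int(parts[idx["otherEnd"]]),
                    other_strand=parts[idx["strand"]],
                    frac_match=float(parts[idx["fracMatch"]]),
                )
            except (ValueError, IndexError) as exc:
                raise AnnotationParseError(f"{path}: line {ln}: {exc}") from exc
            out.append(sd)
    return out


def write_segdup_table(segdups: list[SegDup], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_SEGDUP_COLS) + "\n")
        for sd in segdups:
            fh.write(
                f"{sd.chrom}\t{sd.start}\t{sd.end}\t{sd.other_strand}\t"
                f"{sd.other_chrom}\t{sd.other_start}\t{sd.other_end}\t{sd.frac_match}\n"
            )


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise AnnotationParseError(f"{path}: line {ln}: expected 'chrom<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return sizes
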