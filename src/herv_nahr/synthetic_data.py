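"""Synthetic genomes with planted element pairs, junctions, probe grids and
motifs, plus the recorded ground truth that recovery tests check against.

Elements follow the full-length retroviral layout: two identical LTRs
flanking an internal sequence carrying large internal deletions.  Pair
divergence is planted with an exact substitution count (plus optional short
indels) so realized identities are controlled, and every planted feature's
coordinates are recorded in :class:`GroundTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .annotation_io import GenomeSource, RepeatAnnotation
from .pair_finder import (
    DEFAULT_SCORING,
    AlignmentResult,
    ScoringScheme,
    local_align,
    reverse_complement,
)

__all__ = [
    "ElementBlueprint",
    "PlantedPairSpec",
    "SimulationConfig",
    "GroundTruth",
    "random_sequence",
    "make_element_pair",
    "make_genome",
    "make_junction",
    "make_probe_grid",
    "plant_motifs",
    "write_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_sequence(length: int, rng, gc: float = 0.5) -> str:
    """Random sequence with the given GC fraction (split evenly G/C, A/T)."""
    rng = _rng(rng)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


@dataclass(frozen=True)
class ElementBlueprint:
    """Layout of a planted full-length element."""

    ltr_length: int = 450
    internal_length: int = 5000
    internal_deletions: tuple[tuple[int, int], ...] = ((3200, 4400),)
    gc: float = 0.5

    @property
    def element_length(self) -> int:
        deleted = sum(e - s for s, e in self.internal_deletions)
        return 2 * self.ltr_length + self.internal_length - deleted

    def __post_init__(self) -> None:
        for s, e in self.internal_deletions:
            if not 0 <= s < e <= self.internal_length:
                raise ValueError("internal deletion outside internal sequence")


@dataclass(frozen=True)
class PlantedPairSpec:
    """One pair to plant: divergence is the planted difference rate."""

    divergence: float
    separation: int = 30_000
    strand: str = "+"
    indel_rate: float = 0.0  # indel events per substitution
    qualifies: bool = True  # expectation under the screen thresholds

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError("divergence must lie in [0, 0.3]")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    blueprint: ElementBlueprint = field(default_factory=ElementBlueprint)
    pairs: tuple[PlantedPairSpec, ...] = ()
    margin: int = 15_000
    fragment_annotations: bool = False
    fragment_gap: int = 200
    rep_name: str = "HERVH-int"
    gc: float = 0.5

    def __post_init__(self) -> None:
        if self.margin < 0 or self.fragment_gap < 0:
            raise ValueError("margin and fragment_gap must be >= 0")


@dataclass
class GroundTruth:
    """Recorded coordinates and realized properties of planted features."""

    pairs: list[dict] = field(default_factory=list)
    junctions: list[dict] = field(default_factory=list)
    cnvs: list[dict] = field(default_factory=list)
    motifs: list[dict] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "pairs": self.pairs,
                    "junctions": self.junctions,
                    "cnvs": self.cnvs,
                    "motifs": self.motifs,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            pairs=d.get("pairs", []),
            junctions=d.get("junctions", []),
            cnvs=d.get("cnvs", []),
            motifs=d.get("motifs", []),
        )


def _element_sequence(blueprint: ElementBlueprint, rng) -> str:
    ltr = random_sequence(blueprint.ltr_length, rng, blueprint.gc)
    internal = random_sequence(blueprint.internal_length, rng, blueprint.gc)
    kept = []
    pos = 0
    for s, e in sorted(blueprint.internal_deletions):
        kept.append(internal[pos:s])
        pos = e
    kept.append(internal[pos:])
    return ltr + "".join(kept) + ltr


def make_element_pair(
    blueprint: ElementBlueprint,
    divergence: float,
    seed,
    indel_rate: float = 0.0,
    indel_mean_length: float = 2.0,
):
    """Build an element and a diverged copy.

    Exactly ``round(divergence * len)`` substitution positions are planted
    (sampled without replacement), plus ``round(indel_rate * n_subs)`` short
    indels with geometric lengths.  Returns ``(seq_a, seq_b,
    realized_identity, variant_positions)`` where positions are seq_a-local
    (indels anchored at their first affected base) and realized_identity is
    the identical-column fraction of the planted edit script.
    """
    rng = _rng(seed)
    seq_a = _element_sequence(blueprint, rng)
    length = len(seq_a)
    n_subs = int(round(divergence * length))
    sub_pos = sorted(rng.choice(length, size=n_subs, replace=False)) if n_subs else []
    b = list(seq_a)
    for p in sub_pos:
        old = b[p]
        choices = [c for c in "ACGT" if c != old]
        b[p] = choices[rng.integers(0, 3)]
    variant_positions = set(int(p) for p in sub_pos)
    n_indels = int(round(indel_rate * n_subs))
    ins_len = 0
    del_len = 0
    if n_indels:
        # geometric with mean indel_mean_length; applied right-to-left so
        # earlier seq_a coordinates stay valid
        p_geo = 1.0 / indel_mean_length
        taken = variant_positions | {0, length - 1}
        candidates = [p for p in range(1, length - 1) if p not in taken]
        pos_list = sorted(
            rng.choice(len(candidates), size=min(n_indels, len(candidates)), replace=False),
            reverse=True,
        )
        for ci in pos_list:
            p = candidates[ci]
            ilen = int(rng.geometric(p_geo))
            if rng.random() < 0.5:  # deletion in b
                end = min(p + ilen, length - 1)
                del b[p:end]
                del_len += end - p
            else:  # insertion in b
                b[p:p] = list(random_sequence(ilen, rng, blueprint.gc))
                ins_len += ilen
            variant_positions.add(p)
    seq_b = "".join(b)
    columns = length + ins_len
    realized_identity = (length - n_subs - del_len) / columns
    return seq_a, seq_b, realized_identity, sorted(variant_positions)


def make_genome(config: SimulationConfig):
    """Plant one element pair per chromosome.

    Returns ``(genome, annotations, truth)``: a :class:`GenomeSource`, the
    rmsk-style fragment annotations (one join_id per element, optionally
    split into two fragments with a small annotation gap), and the
    :class:`GroundTruth` with coordinates and realized identities.
    """
    rng = _rng(config.seed)
    genome = GenomeSource()
    annotations: list[RepeatAnnotation] = []
    truth = GroundTruth()
    join_id = 1
    for k, spec in enumerate(config.pairs, start=1):
        chrom = f"chr{k}"
        seq_a, seq_b, realized_identity, variants = make_element_pair(
            config.blueprint, spec.divergence, rng, indel_rate=spec.indel_rate
        )
        a_start = config.margin
        a_end = a_start + len(seq_a)
        b_start = a_end + spec.separation
        b_end = b_start + len(seq_b)
        chrom_len = b_end + config.margin
        background = random_sequence(chrom_len, rng, config.gc)
        planted_a = seq_a if spec.strand == "+" else reverse_complement(seq_a)
        planted_b = seq_b if spec.strand == "+" else reverse_complement(seq_b)
        genome.sequences[chrom] = (
            background[:a_start]
            + planted_a
            + background[a_end:b_start]
            + planted_b
            + background[b_end:]
        )
        for start, end in ((a_start, a_end), (b_start, b_end)):
            annotations.extend(
                _annotate_element(
                    config, rng, chrom, start, end, spec.strand, join_id
                )
            )
            join_id += 1
        truth.pairs.append(
            {
                "chrom": chrom,
                "a_start": a_start,
                "a_end": a_end,
                "b_start": b_start,
                "b_end": b_end,
                "strand": spec.strand,
                "separation": spec.separation,
                "divergence": spec.divergence,
                "realized_identity": realized_identity,
                "qualifies": spec.qualifies,
                "variant_positions": variants,
            }
        )
    return genome, annotations, truth


def _annotate_element(
    config: SimulationConfig,
    rng: np.random.Generator,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    join_id: int,
) -> list[RepeatAnnotation]:
    common = dict(
        chrom=chrom, strand=strand, rep_class="LTR", rep_family="ERV1", join_id=join_id
    )
    if not config.fragment_annotations:
        return [
            RepeatAnnotation(start=start, end=end, rep_name=config.rep_name, **common)
        ]
    gap = config.fragment_gap
    mid = int(rng.integers(start + gap + 1, end - gap - 1))
    return [
        RepeatAnnotation(start=start, end=mid, rep_name=config.rep_name, **common),
        RepeatAnnotation(start=mid + gap, end=end, rep_name=config.rep_name, **common),
    ]


def make_junction(
    seq_a: str,
    seq_b: str,
    crossover_column: int,
    read_length: int = 2000,
    alignment: AlignmentResult | None = None,
    scoring: ScoringScheme = DEFAULT_SCORING,
):
    """Recombinant junction switching template at an alignment column.

    The junction follows element A's row for columns < ``crossover_column``
    and element B's row from there on (gaps dropped), trimmed to
    ``read_length`` centred on the crossover.  Returns ``(junction, truth)``
    where truth records the crossover column and the flanking difference
    columns bounding it.
    """
    if alignment is None:
        alignment = local_align(seq_a, seq_b, scoring)
    n = alignment.aln_length
    if not 0 <= crossover_column <= n:
        raise ValueError("crossover column outside alignment")
    prefix = alignment.aligned_a[:crossover_column].replace("-", "")
    suffix = alignment.aligned_b[crossover_column:].replace("-", "")
    junction = prefix + suffix
    centre = len(prefix)
    lo = max(0, centre - read_length // 2)
    hi = min(len(junction), centre + read_length // 2)
    diff_cols = [
        c
        for c in range(n)
        if alignment.aligned_a[c] != alignment.aligned_b[c]
    ]
    lower = [c for c in diff_cols if c < crossover_column]
    upper = [c for c in diff_cols if c >= crossover_column]
    truth = {
        "crossover_column": crossover_column,
        "flank_lo_column": lower[-1] if lower else None,
        "flank_hi_column": upper[0] if upper else None,
        "read_start": lo,
        "read_end": hi,
    }
    return junction[lo:hi], truth


def make_probe_grid(
    region_start: int,
    region_end: int,
    cnv_start: int,
    cnv_end: int,
    spacing: int,
):
    """Uniform probe grid over [region_start, region_end); a probe is
    'altered' iff it lies inside the true CNV interval."""
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    if not region_start <= cnv_start < cnv_end <= region_end:
        raise ValueError("CNV must lie inside the probed region")
    positions = list(range(region_start, region_end, spacing))
    states = ["altered" if cnv_start <= p < cnv_end else "normal" for p in positions]
    return positions, states


def plant_motifs(seq: str, offsets, consensus: str, seed=0) -> str:
    """Write concrete motif instances at the given offsets (N positions are
    filled randomly); overlapping or out-of-bounds offsets raise."""
    rng = _rng(seed)
    offsets = sorted(int(o) for o in offsets)
    k = len(consensus)
    for prev, nxt in zip(offsets, offsets[1:]):
        if nxt < prev + k:
            raise ValueError(f"overlapping motif plants at {prev} and {nxt}")
    out = list(seq)
    for o in offsets:
        if o < 0 or o + k > len(seq):
            raise ValueError(f"motif at {o} outside sequence")
        for j, code in enumerate(consensus.upper()):
            if code == "N":
                out[o + j] = "ACGT"[rng.integers(0, 4)]
            else:
                out[o + j] = code
    return "".join(out)


def write_dataset(config: SimulationConfig, outdir: str) -> GroundTruth:
    """Materialise a full synthetic dataset (FASTA, rmsk TSV, CNV table,
    junction FASTA, truth JSON) under ``outdir``."""
    import os

    from .annotation_io import write_genome_fasta, write_rmsk_table
    from .cnv_crossref import CnvCall, write_cnv_table

    os.makedirs(outdir, exist_ok=True)
    genome, annotations, truth = make_genome(config)
    rng = _rng(config.seed + 1)
    junction_records = []
    cnvs = []
    for i, rec in enumerate(truth.pairs):
        chrom = rec["chrom"]
        seq_a = genome.fetch(chrom, rec["a_start"], rec["a_end"])
        seq_b = genome.fetch(chrom, rec["b_start"], rec["b_end"])
        if rec["strand"] == "-":
            seq_a, seq_b = reverse_complement(seq_a), reverse_complement(seq_b)
        aln = local_align(seq_a, seq_b)
        if aln.aln_length:
            col = int(rng.integers(aln.aln_length // 4, 3 * aln.aln_length // 4))
            junction, jtruth = make_junction(seq_a, seq_b, col, alignment=aln)
            jtruth.update({"chrom": chrom, "pair_index": i})
            junction_records.append((f"junction_{chrom}", junction))
            truth.junctions.append(jtruth)
        # one deletion CNV spanning inner edges, probed at 1-kb spacing
        cnv_start = rec["a_end"] - 100
        cnv_end = rec["b_start"] + 100
        positions, states = make_probe_grid(
            rec["a_start"] - 5000, rec["b_end"] + 5000, cnv_start, cnv_end, spacing=1000
        )
        from .cnv_crossref import uncertainty_intervals_from_probes

        prox, dist = uncertainty_intervals_from_probes(positions, states)
        cnvs.append(
            CnvCall(
                sample_id=f"sim{i+1}",
                chrom=chrom,
                cnv_type="deletion",
                proximal_start=prox[0],
                proximal_end=prox[1] + 1,
                distal_start=dist[0],
                distal_end=dist[1] + 1,
            )
        )
        truth.cnvs.append({"chrom": chrom, "start": cnv_start, "end": cnv_end})
    write_genome_fasta(genome, os.path.join(outdir, "genome.fa"))
    write_rmsk_table(annotations, os.path.join(outdir, "rmsk.tsv"))
    write_cnv_table(cnvs, os.path.join(outdir, "cnvs.tsv"))
    with open(os.path.join(outdir, "junctions.fa"), "w") as fh:
        for name, seq in junction_records:
            fh.write(f">{name}\n{seq}\n")
    truth.to_json(os.path.join(outdir, "truth.json"))
    return truth
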