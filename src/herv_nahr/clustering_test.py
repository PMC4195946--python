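"""Monte-Carlo test for breakpoint clustering within an aligned element pair.

The statistic is the median of all pairwise distances between observed
proximal cis-morphism positions; the null resamples equally sized position
sets uniformly from alignment columns whose 50-bp windowed identity clears a
threshold, maps each position to the nearest cis-morphism at or before it,
and recomputes the statistic.  Clustering means a *small* statistic, so the
empirical p-value is lower-tail, with the standard add-one correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .breakpoint_mapper import find_cis_morphisms, windowed_identity
from .pair_finder import AlignmentResult

__all__ = [
    "ClusteringResult",
    "pairwise_distances",
    "observed_statistic",
    "eligible_positions",
    "mc_null",
    "empirical_p",
    "run_clustering_test",
]


@dataclass(frozen=True)
class ClusteringResult:
    observed_statistic: float
    null_samples: np.ndarray
    n_sets: int
    empirical_p: float
    min_identity_used: float
    rng_seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.empirical_p <= 1.0:
            raise ValueError("empirical p must lie in (0, 1]")
        if len(self.null_samples) != self.n_sets:
            raise ValueError("null_samples length must equal n_sets")

    def to_dict(self) -> dict:
        return {
            "observed_statistic": float(self.observed_statistic),
            "n_sets": int(self.n_sets),
            "empirical_p": float(self.empirical_p),
            "min_identity_used": float(self.min_identity_used),
            "rng_seed": int(self.rng_seed),
            "null_median": float(np.median(self.null_samples)),
        }


def pairwise_distances(positions) -> np.ndarray:
    """All C(n,2) absolute pairwise distances, in a fixed (i<j) order."""
    pos = np.asarray(positions, dtype=np.float64)
    if pos.ndim != 1 or pos.shape[0] < 2:
        raise ValueError("need at least two positions")
    iu, ju = np.triu_indices(pos.shape[0], k=1)
    return np.abs(pos[iu] - pos[ju])


def observed_statistic(positions) -> float:
    """Median of all pairwise distances between observed positions."""
    return float(np.median(pairwise_distances(positions)))


def eligible_positions(
    alignment: AlignmentResult,
    min_identity: float | None = None,
    window: int = 50,
    breakpoint_columns=None,
) -> np.ndarray:
    """Alignment columns whose windowed identity is >= ``min_identity``.

    When ``min_identity`` is None it defaults to the minimum windowed
    identity observed at ``breakpoint_columns``.
    """
    profile = windowed_identity(alignment, window=window)
    if min_identity is None:
        if breakpoint_columns is None or len(breakpoint_columns) == 0:
            raise ValueError("need min_identity or breakpoint_columns")
        cols = np.asarray(breakpoint_columns, dtype=np.intp)
        min_identity = float(profile[cols].min())
    return np.flatnonzero(profile >= min_identity)


def _sample_distinct(rng: np.random.Generator, eligible: np.ndarray, n: int, n_sets: int):
    """Uniform without-replacement n-subsets of ``eligible`` for every set,
    vectorized by redrawing the rows that contain duplicates."""
    m = eligible.shape[0]
    if n > m:
        raise ValueError(f"cannot draw {n} distinct positions from {m} eligible")
    draws = rng.integers(0, m, size=(n_sets, n))
    while True:
        srt = np.sort(draws, axis=1)
        bad = np.flatnonzero((srt[:, 1:] == srt[:, :-1]).any(axis=1))
        if bad.size == 0:
            break
        draws[bad] = rng.integers(0, m, size=(bad.size, n))
    return eligible[draws]


def mc_null(
    alignment: AlignmentResult,
    n_breakpoints: int,
    n_sets: int = 10_000,
    min_identity: float | None = None,
    seed: int | None = None,
    window: int = 50,
    cis_columns=None,
    eligible=None,
    batch: int = 200_000,
) -> np.ndarray:
    """Null distribution of the clustering statistic.

    Each draw samples ``n_breakpoints`` distinct eligible columns, maps each
    to the nearest cis-morphism column at or before it (clamped to the first
    cis-morphism for columns preceding it), and takes the all-pairs median
    distance.  ``cis_columns``/``eligible`` may be precomputed to skip the
    alignment scans.
    """
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    if eligible is None:
        eligible = eligible_positions(alignment, min_identity=min_identity, window=window)
    eligible = np.asarray(eligible, dtype=np.int64)
    if eligible.size == 0:
        raise ValueError("no eligible positions at this identity threshold")
    if cis_columns is None:
        cis_columns = np.array(
            [c.column for c in find_cis_morphisms(alignment)], dtype=np.int64
        )
    cis_columns = np.sort(np.asarray(cis_columns, dtype=np.int64))
    if cis_columns.size == 0:
        raise ValueError("alignment has no cis-morphisms")
    rng = np.random.default_rng(seed)
    out = np.empty(n_sets, dtype=np.float64)
    iu, ju = np.triu_indices(n_breakpoints, k=1)
    done = 0
    while done < n_sets:
        size = min(batch, n_sets - done)
        pos = _sample_distinct(rng, eligible, n_breakpoints, size)
        idx = np.searchsorted(cis_columns, pos, side="right") - 1
        mapped = cis_columns[np.maximum(idx, 0)]
        dists = np.abs(mapped[:, iu] - mapped[:, ju])
        out[done : done + size] = np.median(dists, axis=1)
        done += size
    return out


def empirical_p(observed: float, null_samples) -> float:
    """Lower-tail Monte-Carlo p with add-one correction:
    (1 + #{null <= observed}) / (1 + n)."""
    null = np.asarray(null_samples, dtype=np.float64)
    return float((1 + np.count_nonzero(null <= observed)) / (1 + null.shape[0]))


def run_clustering_test(
    alignment: AlignmentResult,
    breakpoint_columns,
    n_sets: int = 10_000,
    seed: int = 0,
    min_identity: float | None = None,
    window: int = 50,
) -> ClusteringResult:
    """Observed statistic + Monte-Carlo null + empirical p for one locus."""
    cols = np.asarray(breakpoint_columns, dtype=np.int64)
    if cols.shape[0] < 2:
        raise ValueError("need at least two observed breakpoints")
    profile = windowed_identity(alignment, window=window)
    used_identity = (
        float(profile[cols].min()) if min_identity is None else float(min_identity)
    )
    eligible = np.flatnonzero(profile >= used_identity)
    obs = observed_statistic(cols)
    null = mc_null(
        alignment,
        n_breakpoints=cols.shape[0],
        n_sets=n_sets,
        min_identity=used_identity,
        seed=seed,
        window=window,
        eligible=eligible,
    )
    return ClusteringResult(
        observed_statistic=obs,
        null_samples=null,
        n_sets=n_sets,
        empirical_p=empirical_p(obs, null),
        min_identity_used=used_identity,
        rng_seed=seed,
    )
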