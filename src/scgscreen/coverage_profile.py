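"""Genome coverage breadth/depth, rarefaction, and read-partition summaries.

MDA amplifies a single genome exponentially but unevenly, so read mapping
yields patchy coverage: breadth of coverage (fraction of reference
positions hit) saturates well below the theoretical maximum depth.  This
module computes the coverage statistics used to judge single-amplified
genomes: breadth and mean depth from per-base depth tracks, subsampling
rarefaction on read placements, coverage gain per 1000 extra reads,
read depth at annotated features (16S rRNA genes, oriC) relative to the
genomic background, and hierarchical read-partition fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepthTrack",
    "ReadPlacement",
    "Feature",
    "breadth_and_depth",
    "pileup",
    "rarefaction_curve",
    "rarefaction_summary",
    "coverage_gain_rate",
    "feature_relative_depth",
    "read_partition",
    "theoretical_coverage",
    "binned_depth",
]


@dataclass(frozen=True)
class DepthTrack:
    """Per-base read depth over one reference (position i of ``depth`` is
    1-based position i+1)."""

    reference_id: str
    depth: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.depth, dtype=np.int64)
        object.__setattr__(self, "depth", d)
        if d.ndim != 1:
            raise ValueError("depth must be 1-D")
        if np.any(d < 0):
            raise ValueError(f"{self.reference_id}: negative depth")

    @property
    def length(self) -> int:
        return int(len(self.depth))


@dataclass(frozen=True)
class ReadPlacement:
    """A mapped read's interval on a reference, 0-based half-open."""

    reference_id: str
    start: int
    end: int
    read_id: str = ""

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class Feature:
    """Annotated region, 0-based half-open; class is e.g. rRNA16S / oriC / other."""

    name: str
    start: int
    end: int
    feature_class: str = "other"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.name}: invalid interval [{self.start}, {self.end})")


def breadth_and_depth(track: DepthTrack, min_depth: int = 1) -> tuple[float, float]:
    """Breadth (% of positions with depth >= min_depth) and mean depth (x-fold)."""
    if track.length == 0:
        raise ValueError("zero-length reference")
    breadth = 100.0 * float(np.count_nonzero(track.depth >= min_depth)) / track.length
    return breadth, float(track.depth.mean())


def pileup(placements: Sequence[ReadPlacement], ref_len: int,
           reference_id: str = "") -> DepthTrack:
    """Depth track from read intervals (difference-array accumulation)."""
    if ref_len <= 0:
        raise ValueError("reference length must be positive")
    diff = np.zeros(ref_len + 1, dtype=np.int64)
    for p in placements:
        if p.end > ref_len:
            raise ValueError(f"read {p.read_id!r} interval [{p.start},{p.end}) "
                             f"exceeds reference length {ref_len}")
        diff[p.start] += 1
        diff[p.end] -= 1
    return DepthTrack(reference_id or (placements[0].reference_id if placements else ""),
                      np.cumsum(diff[:-1]))


def rarefaction_curve(
    placements: Sequence[ReadPlacement],
    ref_len: int,
    ns: Sequence[int],
    reps: int = 10,
    seed: int | None = None,
    min_depth: int = 1,
) -> pd.DataFrame:
    """Breadth at random read subsamples of increasing size.

    Reads are drawn uniformly without replacement, ``reps`` times per
    requested count, emulating the subsample-and-remap procedure (a fixed
    read maps deterministically, so re-alignment is not needed).  Returns a
    tidy frame with columns n, rep, breadth.
    """
    pool = list(placements)
    total = len(pool)
    rng = np.random.default_rng(seed)
    rows = []
    for n in ns:
        if n < 0 or n > total:
            raise ValueError(f"subsample size {n} outside [0, {total}]")
        for rep in range(reps):
            if n == 0:
                breadth = 0.0
            elif n == total:
                breadth, _ = breadth_and_depth(pileup(pool, ref_len), min_depth)
            else:
                idx = rng.choice(total, size=n, replace=False)
                breadth, _ = breadth_and_depth(
                    pileup([pool[i] for i in idx], ref_len), min_depth)
            rows.append({"n": int(n), "rep": rep, "breadth": breadth})
    return pd.DataFrame(rows)


def rarefaction_summary(curve: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd breadth per subsample size from a rarefaction frame."""
    g = curve.groupby("n")["breadth"]
    return pd.DataFrame({"n": g.mean().index, "mean": g.mean().values,
                         "sd": g.std(ddof=1).fillna(0.0).values}).reset_index(drop=True)


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


def coverage_gain_rate(breadth_low: float, n_low: int,
                       breadth_high: float, n_high: int) -> float:
    """Breadth gain in percentage points per 1000 additional reads,
    rounded to 2 significant figures for reporting."""
    if n_high <= n_low:
        raise ValueError("n_high must exceed n_low")
    rate = (breadth_high - breadth_low) / ((n_high - n_low) / 1000.0)
    return _round_sig(rate, 2)


def feature_relative_depth(track: DepthTrack, features: Sequence[Feature],
                           normalize: str = "background") -> dict[str, float]:
    """Mean depth per feature class divided by the mean depth of the
    background (positions outside every feature).

    ``normalize="genome"`` divides by the genome-wide mean instead.  The
    background itself is reported under the key ``"background"`` (1.0 under
    the default normalization).
    """
    L = track.length
    mask = np.zeros(L, dtype=bool)
    for f in features:
        if f.end > L:
            raise ValueError(f"feature {f.name} exceeds reference length")
        mask[f.start:f.end] = True
    if mask.all():
        raise ValueError("features tile the whole genome; no background remains")
    background_mean = float(track.depth[~mask].mean())
    genome_mean = float(track.depth.mean())
    if genome_mean <= 0:
        raise ValueError("genome mean depth is zero")
    denom = background_mean if normalize == "background" else genome_mean
    if denom <= 0:
        raise ValueError("normalization denominator is zero")
    out: dict[str, float] = {}
    for cls in sorted({f.feature_class for f in features}):
        cls_mask = np.zeros(L, dtype=bool)
        for f in features:
            if f.feature_class == cls:
                cls_mask[f.start:f.end] = True
        out[cls] = float(track.depth[cls_mask].mean()) / denom
    out["background"] = background_mean / denom
    return out


def read_partition(total: int, stage_counts: Mapping[str, int]) -> dict[str, float]:
    """Hierarchical read-assignment fractions.

    Stages are applied in order (e.g. reference genome, then pangenome, then
    protein classifier); each stage consumes from the reads left unassigned
    by earlier stages, and the remainder absorbs the rest so fractions sum
    to exactly 1.
    """
    if total <= 0:
        raise ValueError("total reads must be positive")
    remaining = total
    fractions: dict[str, float] = {}
    for stage, count in stage_counts.items():
        if count < 0:
            raise ValueError(f"stage {stage}: negative count")
        if count > remaining:
            raise ValueError(
                f"stage {stage}: {count} reads exceed the {remaining} still unassigned")
        fractions[stage] = count / total
        remaining -= count
    fractions["other"] = remaining / total
    return fractions


def theoretical_coverage(n_reads: int, read_len: int, genome_len: int) -> float:
    """Maximum theoretical depth of coverage: n_reads * read_len / genome_len."""
    if genome_len <= 0:
        raise ValueError("genome length must be positive")
    return n_reads * read_len / genome_len


def binned_depth(track: DepthTrack, bin_size: int = 1000) -> np.ndarray:
    """Mean depth per fixed-size bin (heatmap-ready; last bin may be short)."""
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    edges = np.arange(0, track.length, bin_size)
    return np.array([track.depth[s:s + bin_size].mean() for s in edges])
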