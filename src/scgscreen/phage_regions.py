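"""Prophage region grouping, representative selection and host-hit triage.

Predicted phage-containing contigs are grouped by the protein their best
hit matches (a proxy for phage taxonomy), one representative per group is
chosen by longest predicted phage region, and nucleotide hits of the
representative against complete host genomes are kept only when both
identity (>98%) and length (>14 kb) are cleared.  Significant hit regions
are trimmed with 5 kb of flanking host sequence, and read-mapping depth
is normalized per million mapped-sample reads for comparable coverage
curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .coverage_profile import DepthTrack
from .mge_network import AlignmentHit

__all__ = [
    "PhagePrediction",
    "GenomicRegion",
    "group_predictions",
    "choose_representative",
    "filter_host_hits",
    "trim_with_flank",
    "normalized_coverage",
    "group_ani_summary",
]


@dataclass(frozen=True)
class PhagePrediction:
    """One predicted phage region on a contig (0-based half-open)."""

    contig_id: str
    contig_len: int
    phage_start: int
    phage_end: int
    best_hit_protein: str
    host_sample: str = ""

    def __post_init__(self):
        if not 0 <= self.phage_start < self.phage_end <= self.contig_len:
            raise ValueError(
                f"{self.contig_id}: phage region [{self.phage_start}, "
                f"{self.phage_end}) outside contig of length {self.contig_len}")

    @property
    def phage_length(self) -> int:
        return self.phage_end - self.phage_start


@dataclass(frozen=True)
class GenomicRegion:
    sequence_id: str
    start: int
    end: int

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.sequence_id}: invalid region [{self.start}, {self.end})")


def group_predictions(
    preds: Sequence[PhagePrediction],
) -> dict[str, list[PhagePrediction]]:
    """Group predictions by best-protein-hit accession (case-sensitive exact
    key); input order is preserved within each group."""
    groups: dict[str, list[PhagePrediction]] = {}
    for p in preds:
        if not p.best_hit_protein:
            raise ValueError(f"{p.contig_id}: missing best-hit accession")
        groups.setdefault(p.best_hit_protein, []).append(p)
    return groups


def choose_representative(group: Sequence[PhagePrediction]) -> PhagePrediction:
    """The member with the longest predicted phage region; ties break to the
    lexicographically smallest contig id."""
    if not group:
        raise ValueError("empty group")
    return min(group, key=lambda p: (-p.phage_length, p.contig_id))


def filter_host_hits(hits: Sequence[AlignmentHit], min_pident: float = 98.0,
                     min_len: int = 14_000) -> list[AlignmentHit]:
    """Significant host-genome hits: identity strictly above ``min_pident``
    AND alignment length strictly above ``min_len``."""
    return [h for h in hits if h.pident > min_pident and h.align_len > min_len]


def trim_with_flank(hit_region: GenomicRegion, seq_len: int,
                    flank: int = 5000) -> GenomicRegion:
    """Extend a hit region by ``flank`` bp on both sides, clipped to the
    sequence bounds."""
    if hit_region.end > seq_len:
        raise ValueError(f"region end {hit_region.end} beyond sequence length {seq_len}")
    if flank < 0:
        raise ValueError("flank must be nonnegative")
    return GenomicRegion(hit_region.sequence_id,
                         max(0, hit_region.start - flank),
                         min(seq_len, hit_region.end + flank))


def normalized_coverage(track: DepthTrack, total_reads: int,
                        scale: float = 1e6) -> np.ndarray:
    """Per-position depth normalized to reads-per-``scale`` total sample
    reads (default per million), making coverage curves comparable across
    samples with different sequencing depths."""
    if total_reads <= 0:
        raise ValueError("total reads must be positive")
    return track.depth.astype(float) * scale / total_reads


def group_ani_summary(
    group: Sequence[PhagePrediction],
    ani: Mapping[tuple[str, str], float],
    tol: float = 0.1,
) -> Optional[tuple[float, float, float]]:
    """(min, mean, max) pairwise average nucleotide identity within a group.

    ``ani`` maps ordered contig-id pairs to percent identity from an
    upstream whole-genome ANI tool; it must be symmetric within ``tol``
    and is summarized over off-diagonal pairs only.  Singleton groups have
    no pairs and return None.
    """
    ids = [p.contig_id for p in group]
    if len(ids) < 2:
        return None
    values = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            try:
                ab, ba = ani[(a, b)], ani[(b, a)]
            except KeyError as exc:
                raise ValueError(f"ANI matrix missing pair {exc}") from exc
            if abs(ab - ba) > tol:
                raise ValueError(f"ANI asymmetric for ({a}, {b}): {ab} vs {ba}")
            values.append((ab + ba) / 2.0)
    arr = np.asarray(values)
    return float(arr.min()), float(arr.mean()), float(arr.max())
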