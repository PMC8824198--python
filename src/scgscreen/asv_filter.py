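"""Single-cell 16S ASV triage against a community profile.

A well that truly received one bacterial cell should yield amplicon reads
dominated by a single amplicon sequence variant (ASV), and that ASV should
be an exact match to one observed in the bulk community profile of the
same sample.  Cells failing the dominance test are mixtures (multiple
cells, or intragenomic 16S polymorphism); dominant ASVs absent from the
community are either reagent ("kitome") contaminants, recognized by genus,
or rare taxa missed by community profiling.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ASVRecord",
    "ASVProfile",
    "CellClassification",
    "TriageSummary",
    "CATEGORY_PASS",
    "CATEGORY_CONTAMINANT",
    "CATEGORY_MIXTURE",
    "CATEGORY_RARE",
    "dominant_fraction",
    "community_match",
    "classify_cell",
    "summarize_classifications",
    "asv_accumulation",
    "accumulation_summary",
]

CATEGORY_PASS = "PASS"
CATEGORY_CONTAMINANT = "CONTAMINANT"
CATEGORY_MIXTURE = "MIXTURE"
CATEGORY_RARE = "RARE_UNMATCHED"
CATEGORIES = (CATEGORY_PASS, CATEGORY_CONTAMINANT, CATEGORY_MIXTURE, CATEGORY_RARE)

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ASVRecord:
    asv_id: str
    sequence: str
    count: int
    taxonomy: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if self.count < 0:
            raise ValueError(f"{self.asv_id}: negative count")
        if seq and not set(seq) <= _VALID_BASES:
            raise ValueError(f"{self.asv_id}: sequence contains non-ACGTN characters")

    @property
    def genus(self) -> Optional[str]:
        return self.taxonomy.get("genus")


@dataclass(frozen=True)
class ASVProfile:
    """Per-sample ASV table (single cell or bulk community)."""

    sample_id: str
    records: tuple[ASVRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.asv_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.sample_id}: duplicate asv_id")

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.records)

    def sequences(self) -> set[str]:
        return {r.sequence for r in self.records}


@dataclass(frozen=True)
class CellClassification:
    sample_id: str
    category: str
    dominant_asv: Optional[str]
    dominant_fraction: float
    matched_community: bool
    warning: Optional[str] = None


@dataclass(frozen=True)
class TriageSummary:
    """Counts and report percentages for the single-cell triage flowchart.

    Percentages are rounded half-up to one decimal.  Failure-category
    percentages are relative to the cells that failed filtering
    (pcr-positive minus passing), matching how the flowchart is read.
    """

    n_sorted: int
    n_pcr_positive: int
    n_pass: int
    n_contaminant: int
    n_mixture: int
    n_rare: int
    pct_positive_of_sorted: float
    pct_pass_of_positive: float
    pct_pass_of_sorted: float
    pct_contaminant_of_failed: float
    pct_mixture_of_failed: float
    pct_rare_of_failed: float


def _round1(x: float) -> float:
    """Round half-up to 1 decimal (report convention; banker's rounding not used)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _pct(numer: int, denom: int) -> float:
    return _round1(100.0 * numer / denom) if denom else 0.0


def dominant_fraction(profile: ASVProfile) -> tuple[str, float]:
    """The highest-count ASV and its share of total reads; ties break to the
    lexicographically smallest asv_id."""
    total = profile.total_count
    if total <= 0:
        raise ValueError(f"{profile.sample_id}: all-zero profile")
    best = min(profile.records, key=lambda r: (-r.count, r.asv_id))
    return best.asv_id, best.count / total


def community_match(sequence: str, community: ASVProfile) -> bool:
    """Exact (100% identity, equal length) match to any community ASV.

    Case-insensitive; no reverse-complement search (amplicons share
    orientation) and no N-tolerant matching.
    """
    if not sequence:
        raise ValueError("empty sequence")
    return sequence.upper() in community.sequences()


def classify_cell(
    profile: ASVProfile,
    community: ASVProfile,
    contaminant_genera: Iterable[str],
    dominance_min: float = 0.70,
) -> CellClassification:
    """Triage one single-cell amplicon profile.

    Evaluation order: (1) no ASV reaching ``dominance_min`` of reads ->
    MIXTURE; (2) dominant ASV exactly present in the community -> PASS;
    (3) dominant ASV's genus on the contaminant list -> CONTAMINANT;
    (4) otherwise RARE_UNMATCHED.  The dominance boundary is inclusive.
    """
    contaminants = set(contaminant_genera)
    asv_id, frac = dominant_fraction(profile)
    dominant = next(r for r in profile.records if r.asv_id == asv_id)
    matched = community_match(dominant.sequence, community)

    if frac < dominance_min:
        return CellClassification(profile.sample_id, CATEGORY_MIXTURE, asv_id, frac, matched)
    if matched:
        return CellClassification(profile.sample_id, CATEGORY_PASS, asv_id, frac, True)
    genus = dominant.genus
    if genus is None:
        msg = f"{profile.sample_id}: dominant ASV {asv_id} lacks a genus label"
        logger.warning(msg)
        return CellClassification(profile.sample_id, CATEGORY_RARE, asv_id, frac, False,
                                  warning=msg)
    if genus in contaminants:
        return CellClassification(profile.sample_id, CATEGORY_CONTAMINANT, asv_id, frac, False)
    return CellClassification(profile.sample_id, CATEGORY_RARE, asv_id, frac, False)


def summarize_classifications(
    cells: Sequence[CellClassification],
    n_sorted: int,
    n_pcr_positive: int,
) -> TriageSummary:
    """Compile flowchart counts and percentages from per-cell calls."""
    if len(cells) != n_pcr_positive:
        raise ValueError(
            f"{len(cells)} classifications but n_pcr_positive={n_pcr_positive}"
        )
    counts = {c: 0 for c in CATEGORIES}
    for cell in cells:
        counts[cell.category] += 1
    n_pass = counts[CATEGORY_PASS]
    n_failed = n_pcr_positive - n_pass
    return TriageSummary(
        n_sorted=n_sorted,
        n_pcr_positive=n_pcr_positive,
        n_pass=n_pass,
        n_contaminant=counts[CATEGORY_CONTAMINANT],
        n_mixture=counts[CATEGORY_MIXTURE],
        n_rare=counts[CATEGORY_RARE],
        pct_positive_of_sorted=_pct(n_pcr_positive, n_sorted),
        pct_pass_of_positive=_pct(n_pass, n_pcr_positive),
        pct_pass_of_sorted=_pct(n_pass, n_sorted),
        pct_contaminant_of_failed=_pct(counts[CATEGORY_CONTAMINANT], n_failed),
        pct_mixture_of_failed=_pct(counts[CATEGORY_MIXTURE], n_failed),
        pct_rare_of_failed=_pct(counts[CATEGORY_RARE], n_failed),
    )


def asv_accumulation(
    plate_asvs: Mapping[str, set[str]],
    max_plates: int = 20,
    sample: Optional[int] = None,
    seed: Optional[int] = None,
):
    """Unique-ASV accumulation over all plate combinations.

    For every subset size m, the union size |ASVs(P_i1) u ... u ASVs(P_im)|
    is computed for all C(n, m) combinations (exhaustive).  With more than
    ``max_plates`` plates the exhaustive sweep is refused unless ``sample``
    requests a per-m random subsample of combinations (seeded).

    Returns a dict m -> sorted list of union sizes.
    """
    if not plate_asvs:
        raise ValueError("empty plate map")
    plates = sorted(plate_asvs)
    n = len(plates)
    if n > max_plates and sample is None:
        raise ValueError(
            f"{n} plates exceeds the exhaustive guard ({max_plates}); "
            "pass sample=<count> to subsample combinations"
        )
    rng = np.random.default_rng(seed) if sample is not None else None
    result: dict[int, list[int]] = {}
    for m in range(1, n + 1):
        if sample is not None and math.comb(n, m) > sample:
            combos = [
                tuple(plates[i] for i in sorted(rng.choice(n, size=m, replace=False)))
                for _ in range(sample)
            ]
        else:
            combos = list(itertools.combinations(plates, m))
        sizes = [len(set().union(*(plate_asvs[p] for p in combo))) for combo in combos]
        result[m] = sorted(sizes)
    return result


def accumulation_summary(accumulation: Mapping[int, Sequence[int]]):
    """Per-m mean/sd/n over the union-size multisets from :func:`asv_accumulation`."""
    rows = []
    for m in sorted(accumulation):
        sizes = np.asarray(accumulation[m], dtype=float)
        rows.append({
            "m": m,
            "mean": float(sizes.mean()),
            "sd": float(sizes.std(ddof=1)) if len(sizes) > 1 else 0.0,
            "n_combinations": int(len(sizes)),
        })
    return rows
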