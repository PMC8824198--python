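"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Every generator is a pure function of its parameters and a seed, and
plants a known truth that the corresponding analysis module must recover:
logistic fluorescence curves with known parameters, single-cell ASV
profiles with a known triage category, read placements with MDA-like
coverage bias, and reciprocal alignment tables with a planted cluster
structure.  None of it simulates actual sequencing reads, chimeras or
basecall errors — only the summary tables the toolkit consumes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .asv_filter import (ASVProfile, ASVRecord, CATEGORY_CONTAMINANT,
                         CATEGORY_MIXTURE, CATEGORY_PASS, CATEGORY_RARE)
from .coverage_profile import ReadPlacement
from .mda_curves import FluorescenceSeries, logistic4
from .mge_network import AlignmentHit, ContigInfo

__all__ = [
    "CurveTruth",
    "CellTruth",
    "CurveParamRanges",
    "default_time_grid",
    "gen_mda_curves",
    "gen_asv_dataset",
    "gen_read_placements",
    "gen_ctn_hits",
]

#: Plausible abundant gut genera used for community ASVs.
_COMMUNITY_GENERA = (
    "Bifidobacterium", "Faecalibacterium", "Bacteroides", "Blautia",
    "Roseburia", "Prevotella", "Akkermansia", "Subdoligranulum",
)
#: Genera for rare, community-absent but credible intestinal taxa.
_RARE_GENERA = ("Holdemanella", "Ruminococcus", "Gemmiger", "Anaerostipes")

V4_AMPLICON_LEN = 215  # uniform trimmed V4 read length


@dataclass(frozen=True)
class CurveTruth:
    """Planted parameters behind one synthetic fluorescence trace."""

    well_id: str
    is_amplified: bool
    baseline: float
    amplitude: float
    rate: float
    midpoint: float
    noise_sd: float


@dataclass(frozen=True)
class CellTruth:
    """Planted triage category behind one synthetic single-cell profile."""

    sample_id: str
    category: str
    dominant_fraction: float
    genus: str


@dataclass(frozen=True)
class CurveParamRanges:
    """Sampling ranges for planted logistic parameters.

    Midpoints sit well inside the 7.5 h run so that 10%-rise threshold
    times land in the empirically observed 100-300 min window; rates for
    amplified wells sit above the 0.1/min amplified-call threshold, since
    the planted dichotomy is amplified vs flat; noise is Gaussian with sd
    expressed as a fraction of the amplitude.
    """

    baseline: tuple[float, float] = (800.0, 1200.0)
    amplitude: tuple[float, float] = (3000.0, 8000.0)
    rate: tuple[float, float] = (0.12, 0.35)
    midpoint: tuple[float, float] = (150.0, 340.0)
    noise_frac: float = 0.01


def default_time_grid() -> np.ndarray:
    """Fluorescence sampling grid: a reading every 3 min for 7.5 h (0-450)."""
    return np.arange(0.0, 450.0 + 1e-9, 3.0)


def gen_mda_curves(
    n_amplified: int,
    n_flat: int,
    time_grid: Optional[Sequence[float]] = None,
    param_ranges: CurveParamRanges | None = None,
    seed: int = 0,
) -> tuple[list[FluorescenceSeries], list[CurveTruth]]:
    """Synthetic SYBR Green traces: logistic risers plus flat wells.

    Amplified wells follow baseline + amplitude/(1+exp(-rate*(t-midpoint)))
    with additive Gaussian noise; flat wells are baseline plus noise of the
    same magnitude.  Identical (parameters, seed) give identical output.
    """
    if n_amplified < 0 or n_flat < 0:
        raise ValueError("well counts must be nonnegative")
    t = np.asarray(default_time_grid() if time_grid is None else time_grid, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    pr = param_ranges or CurveParamRanges()
    if not (t[0] <= pr.midpoint[0] and pr.midpoint[1] <= t[-1]):
        raise ValueError("midpoint range must lie within the time grid")
    rng = np.random.default_rng(seed)

    series, truths = [], []
    for i in range(n_amplified + n_flat):
        amplified = i < n_amplified
        well = f"W{i + 1:03d}"
        baseline = rng.uniform(*pr.baseline)
        amplitude = rng.uniform(*pr.amplitude)
        rate = rng.uniform(*pr.rate)
        midpoint = rng.uniform(*pr.midpoint)
        noise_sd = pr.noise_frac * amplitude
        if amplified:
            signal = logistic4(t, baseline, amplitude, rate, midpoint)
        else:
            signal = np.full_like(t, baseline)
            amplitude, rate = 0.0, 0.0
        values = signal + (rng.normal(0.0, noise_sd, size=t.size) if noise_sd > 0 else 0.0)
        series.append(FluorescenceSeries(well, t.copy(), values))
        truths.append(CurveTruth(well, amplified, baseline, amplitude, rate,
                                 midpoint, noise_sd))
    return series, truths


def _random_unique_seq(rng: np.random.Generator, length: int, taken: set[str]) -> str:
    """Random ACGT k-mer, rejected until unique among ``taken``."""
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if seq not in taken:
            taken.add(seq)
            return seq


def gen_asv_dataset(
    n_community_asvs: int,
    cells_per_category: Mapping[str, int],
    contaminant_genera: Sequence[str],
    seed: int = 0,
    reads_per_cell: tuple[int, int] = (100, 500),
) -> tuple[ASVProfile, list[ASVProfile], list[CellTruth]]:
    """Community profile plus single-cell profiles with planted triage classes.

    PASS cells carry a community ASV at >= 70% relative abundance;
    CONTAMINANT cells are dominated by a non-community ASV labeled with a
    listed contaminant genus; MIXTURE cells have no ASV reaching 70%;
    RARE_UNMATCHED cells are dominated by a non-community ASV from a
    non-contaminant genus.
    """
    if n_community_asvs < 1:
        raise ValueError("need at least one community ASV")
    unknown = set(cells_per_category) - {CATEGORY_PASS, CATEGORY_CONTAMINANT,
                                         CATEGORY_MIXTURE, CATEGORY_RARE}
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    if any(v < 0 for v in cells_per_category.values()):
        raise ValueError("cell counts must be nonnegative")
    contaminant_genera = list(contaminant_genera)
    if cells_per_category.get(CATEGORY_CONTAMINANT, 0) > 0 and not contaminant_genera:
        raise ValueError("contaminant cells requested but contaminant list is empty")
    if cells_per_category.get(CATEGORY_MIXTURE, 0) > 0 and n_community_asvs < 2:
        raise ValueError("mixture cells need at least two community ASVs")

    rng = np.random.default_rng(seed)
    taken: set[str] = set()

    community_records = []
    for i in range(n_community_asvs):
        genus = _COMMUNITY_GENERA[i % len(_COMMUNITY_GENERA)]
        community_records.append(ASVRecord(
            asv_id=f"ASV{i + 1:04d}",
            sequence=_random_unique_seq(rng, V4_AMPLICON_LEN, taken),
            count=int(rng.integers(500, 5000)),
            taxonomy={"genus": genus, "family": genus + "aceae"},
        ))
    community = ASVProfile("community", tuple(community_records))

    def foreign_record(asv_num: int, genus: str, count: int) -> ASVRecord:
        return ASVRecord(
            asv_id=f"XASV{asv_num:04d}",
            sequence=_random_unique_seq(rng, V4_AMPLICON_LEN, taken),
            count=count,
            taxonomy={"genus": genus, "family": genus + "aceae"},
        )

    rare_pool = [g for g in _RARE_GENERA if g not in contaminant_genera]
    if cells_per_category.get(CATEGORY_RARE, 0) > 0 and not rare_pool:
        raise ValueError("no non-contaminant genera left for rare cells")
    cells, truths = [], []
    cell_no, foreign_no = 0, 0

    def minor_community_records(exclude_idx: int, budget: int) -> list[ASVRecord]:
        """Spread ``budget`` reads over 1-2 other community ASVs."""
        out = []
        if budget <= 0 or n_community_asvs < 2:
            return out
        k = 1 if budget < 4 or n_community_asvs == 2 else int(rng.integers(1, 3))
        others = [i for i in range(n_community_asvs) if i != exclude_idx]
        picks = rng.choice(len(others), size=min(k, len(others)), replace=False)
        split = np.diff(np.concatenate(
            [[0], np.sort(rng.integers(0, budget + 1, size=len(picks) - 1)), [budget]]))
        for j, share in zip(picks, split):
            if share > 0:
                src = community_records[others[j]]
                out.append(ASVRecord(src.asv_id, src.sequence, int(share), src.taxonomy))
        return out

    for category in (CATEGORY_PASS, CATEGORY_CONTAMINANT, CATEGORY_MIXTURE, CATEGORY_RARE):
        for _ in range(cells_per_category.get(category, 0)):
            cell_no += 1
            sid = f"cell{cell_no:04d}"
            total = int(rng.integers(*reads_per_cell))
            if category == CATEGORY_MIXTURE:
                # two community ASVs, neither reaching 70%
                frac = rng.uniform(0.40, 0.62)
                idx = int(rng.integers(n_community_asvs))
                dom = int(np.ceil(frac * total))
                dom = min(dom, int(np.floor(0.65 * total)))
                dom = max(dom, 1)
                rest = total - dom
                src = community_records[idx]
                records = [ASVRecord(src.asv_id, src.sequence, dom, src.taxonomy)]
                other_idx = (idx + 1) % n_community_asvs if n_community_asvs > 1 else idx
                if n_community_asvs > 1 and rest > 0:
                    osrc = community_records[other_idx]
                    records.append(ASVRecord(osrc.asv_id, osrc.sequence, max(rest, dom // 2),
                                             osrc.taxonomy))
                    # rebalance so the dominant stays dominant but < 70%
                    if records[1].count >= records[0].count:
                        records[1] = ASVRecord(records[1].asv_id, records[1].sequence,
                                               records[0].count - 1, records[1].taxonomy)
                genus = src.taxonomy["genus"]
            else:
                frac = rng.uniform(0.75, 0.98)
                dom = max(int(np.ceil(frac * total)), int(np.ceil(0.70 * total)))
                rest = total - dom
                if category == CATEGORY_PASS:
                    idx = int(rng.integers(n_community_asvs))
                    src = community_records[idx]
                    records = [ASVRecord(src.asv_id, src.sequence, dom, src.taxonomy)]
                    records += minor_community_records(idx, rest)
                    genus = src.taxonomy["genus"]
                else:
                    foreign_no += 1
                    if category == CATEGORY_CONTAMINANT:
                        genus = contaminant_genera[int(rng.integers(len(contaminant_genera)))]
                    else:
                        genus = rare_pool[int(rng.integers(len(rare_pool)))]
                    records = [foreign_record(foreign_no, genus, dom)]
                    records += minor_community_records(-1, rest)
            profile = ASVProfile(sid, tuple(records))
            dom_count = max(r.count for r in records)
            cells.append(profile)
            truths.append(CellTruth(sid, category, dom_count / profile.total_count, genus))
    return community, cells, truths


def gen_read_placements(
    genome_len: int,
    n_reads: int,
    read_len: int,
    bias_model: str = "uniform",
    seed: int = 0,
    n_windows: int = 200,
    lognormal_sd: float = 1.5,
) -> list[ReadPlacement]:
    """Read intervals under uniform or MDA-like (lognormal-window) bias.

    ``mda_lognormal`` draws a lognormal weight per genome window and then
    samples read start positions proportionally, reproducing the patchy
    breadth characteristic of exponential MDA amplification; as
    ``lognormal_sd`` approaches 0 it degenerates to the uniform model.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be nonnegative")
    if read_len > genome_len:
        raise ValueError("read length exceeds genome length")
    if read_len <= 0 or genome_len <= 0:
        raise ValueError("lengths must be positive")
    rng = np.random.default_rng(seed)
    max_start = genome_len - read_len + 1
    if bias_model == "uniform":
        starts = rng.integers(0, max_start, size=n_reads)
    elif bias_model == "mda_lognormal":
        n_windows = min(n_windows, max_start)
        weights = rng.lognormal(mean=0.0, sigma=lognormal_sd, size=n_windows)
        weights /= weights.sum()
        windows = rng.choice(n_windows, size=n_reads, p=weights)
        edges = np.linspace(0, max_start, n_windows + 1)
        lo = edges[windows]
        hi = np.maximum(edges[windows + 1], lo + 1)
        starts = (lo + rng.random(n_reads) * (hi - lo)).astype(np.int64)
        starts = np.clip(starts, 0, max_start - 1)
    else:
        raise ValueError(f"unknown bias model {bias_model!r}")
    return [ReadPlacement("ref", int(s), int(s) + read_len, f"read{i:07d}")
            for i, s in enumerate(starts)]


def gen_ctn_hits(
    cluster_sizes: Sequence[int],
    contig_len: int = 40_000,
    within_pla: float = 80.0,
    between_pla: float = 5.0,
    seed: int = 0,
) -> tuple[list[ContigInfo], list[AlignmentHit]]:
    """Reciprocal alignment table with a planted cluster structure.

    Every within-cluster contig pair gets reciprocal hits covering
    ``within_pla`` percent of each query; cross-cluster pairs get hits
    covering ``between_pla`` percent (none when 0), so thresholding at
    PLA >= 20 recovers the planted partition exactly.
    """
    if any(s <= 0 for s in cluster_sizes):
        raise ValueError("cluster sizes must be positive")
    if not (within_pla >= 20.0 > between_pla):
        raise ValueError("need within_pla >= 20 > between_pla")
    rng = np.random.default_rng(seed)
    contigs: list[ContigInfo] = []
    clusters: list[list[str]] = []
    for ci, size in enumerate(cluster_sizes):
        members = [f"ctn_c{ci + 1}_{j + 1}" for j in range(size)]
        clusters.append(members)
        contigs.extend(ContigInfo(m, contig_len) for m in members)

    def make_hit(query: str, subject: str, pla_pct: float) -> AlignmentHit:
        span = max(1, int(round(pla_pct / 100.0 * contig_len)))
        qstart = int(rng.integers(1, contig_len - span + 2))
        sstart = int(rng.integers(1, contig_len - span + 2))
        pident = float(rng.uniform(90.0, 99.9))
        return AlignmentHit(query, subject, pident, span, 0, 0,
                            qstart, qstart + span - 1, sstart, sstart + span - 1,
                            evalue=0.0, bitscore=2.0 * span)

    hits: list[AlignmentHit] = []
    for members in clusters:
        for a, b in itertools.combinations(members, 2):
            hits.append(make_hit(a, b, within_pla))
            hits.append(make_hit(b, a, within_pla))
    if between_pla > 0:
        for g1, g2 in itertools.combinations(clusters, 2):
            for a in g1:
                for b in g2:
                    hits.append(make_hit(a, b, between_pla))
                    hits.append(make_hit(b, a, between_pla))
    return contigs, hits
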