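"""Readers and writers for every file dialect the toolkit touches.

All coordinate conversions live here: BED files are 0-based half-open
(matching internal coordinates), tabular alignment files keep the 1-based
inclusive convention of the alignment tools and are only reinterpreted by
the interval math in :mod:`scgscreen.mge_network`.  Depth tables follow
the samtools-depth dialect (reference, 1-based position, depth) and may
omit zero-depth positions, which are filled in on read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .asv_filter import ASVProfile, ASVRecord, CellClassification, TriageSummary
from .coverage_profile import DepthTrack, Feature, ReadPlacement
from .mda_curves import FluorescenceSeries, LogisticFit, WellClassification
from .mge_network import AlignmentHit, ClusterGraph, ContigInfo

__all__ = [
    "RunConfig",
    "read_fluorescence_csv", "write_fluorescence_csv",
    "read_pcr_tsv",
    "read_blast_tab", "write_blast_tab",
    "read_depth_tsv", "write_depth_tsv",
    "read_bed", "write_bed", "read_features_bed",
    "read_asv_profiles", "write_asv_profiles",
    "read_contaminant_list",
    "read_contig_lengths",
    "write_fits_tsv", "write_classifications_tsv", "write_triage_summary_tsv",
    "write_edge_list", "write_clusters_tsv", "write_gml",
]

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


@dataclass
class RunConfig:
    """Toolkit-wide parameters; defaults are the pipeline's published thresholds."""

    k_min: float = 0.1                  # minimum logistic rate for an amplified call
    threshold_fraction: float = 0.10    # fractional rise defining threshold time
    dominance_min: float = 0.70         # single-ASV dominance for cell triage
    pla_min: float = 20.0               # percent length aligned edge cutoff
    inflation: float = 2.0              # MCL inflation
    min_pident: float = 98.0            # phage host-hit identity cutoff (strict >)
    min_hit_len: int = 14_000           # phage host-hit length cutoff (strict >)
    flank: int = 5_000                  # host flanking sequence kept around hits
    rarefaction_reps: int = 10          # subsampling replicates per read count
    min_depth: int = 1                  # depth defining a covered position
    seed: int = 0
    log_level: str = "INFO"
    outdir: str = "."

    def __post_init__(self):
        if not 0 < self.dominance_min <= 1:
            raise ValueError("dominance_min must lie in (0, 1]")
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if not 0 <= self.pla_min <= 100:
            raise ValueError("pla_min must lie in [0, 100]")
        if self.k_min < 0 or self.flank < 0 or self.min_depth < 0:
            raise ValueError("k_min, flank and min_depth must be nonnegative")
        if self.rarefaction_reps < 1:
            raise ValueError("rarefaction_reps must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# --- fluorescence traces ---------------------------------------------------

def read_fluorescence_csv(path) -> list[FluorescenceSeries]:
    """Long-format multicomponent export: columns well, time_min, value."""
    df = pd.read_csv(path)
    missing = {"well", "time_min", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("time_min", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col} at row {int(bad[0]) + 2} "
                f"(value {df.loc[bad[0], col]!r})")
        df[col] = coerced
    series = []
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_min")
        series.append(FluorescenceSeries(str(well),
                                         grp["time_min"].to_numpy(float),
                                         grp["value"].to_numpy(float)))
    return series


def write_fluorescence_csv(series: Sequence[FluorescenceSeries], path) -> None:
    rows = [{"well": s.well_id, "time_min": t, "value": v}
            for s in series for t, v in zip(s.times, s.values)]
    pd.DataFrame(rows, columns=["well", "time_min", "value"]).to_csv(path, index=False)


def read_pcr_tsv(path) -> dict[str, bool]:
    """Well -> 16S PCR positivity (columns well, positive with 0/1)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"well", "positive"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return {str(r.well): bool(int(r.positive)) for r in df.itertuples()}


# --- tabular alignments ----------------------------------------------------

_BLAST_COLS = ("query_id", "subject_id", "pident", "align_len", "mismatches",
               "gap_opens", "qstart", "qend", "sstart", "send", "evalue", "bitscore")


def read_blast_tab(path) -> list[AlignmentHit]:
    """Standard 12-column tabular alignment format, 1-based inclusive
    coordinates; reverse-strand rows are kept as-is and normalized later."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            hits.append(AlignmentHit(
                parts[0], parts[1], float(parts[2]), int(parts[3]),
                int(parts[4]), int(parts[5]), int(parts[6]), int(parts[7]),
                int(parts[8]), int(parts[9]), float(parts[10]), float(parts[11])))
    return hits


def write_blast_tab(hits: Sequence[AlignmentHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(str(getattr(h, c)) for c in _BLAST_COLS) + "\n")


# --- depth and intervals ---------------------------------------------------

def read_depth_tsv(path, ref_len: int, reference_id: Optional[str] = None) -> DepthTrack:
    """samtools-depth dialect: reference, 1-based position, depth; absent
    positions are filled with zero."""
    depth = np.zeros(ref_len, dtype=np.int64)
    ref_seen = reference_id
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            ref, pos_s, d_s = line.split("\t")
            pos, d = int(pos_s), int(d_s)
            if ref_seen is None:
                ref_seen = ref
            elif ref != ref_seen:
                raise ValueError(f"{path}:{lineno}: unexpected reference {ref!r}")
            if not 1 <= pos <= ref_len:
                raise ValueError(f"{path}:{lineno}: position {pos} outside 1..{ref_len}")
            if pos in seen:
                raise ValueError(f"{path}:{lineno}: duplicate position {pos}")
            seen.add(pos)
            depth[pos - 1] = d
    return DepthTrack(ref_seen or "", depth)


def write_depth_tsv(track: DepthTrack, path, omit_zero: bool = True) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(track.depth):
            if omit_zero and d == 0:
                continue
            fh.write(f"{track.reference_id}\t{i + 1}\t{int(d)}\n")


def read_bed(path) -> list[ReadPlacement]:
    """BED intervals (0-based half-open) as read placements."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            name = parts[3] if len(parts) > 3 else f"iv{lineno}"
            out.append(ReadPlacement(parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_bed(placements: Sequence[ReadPlacement], path) -> None:
    with open(path, "w") as fh:
        for p in placements:
            fh.write(f"{p.reference_id}\t{p.start}\t{p.end}\t{p.read_id}\n")


def read_features_bed(path) -> list[Feature]:
    """BED with feature class in column 5 (name in column 4)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: feature BED needs >= 4 columns")
            cls = parts[4] if len(parts) > 4 else "other"
            out.append(Feature(parts[3], int(parts[1]), int(parts[2]), cls))
    return out


# --- ASV tables ------------------------------------------------------------

def read_asv_profiles(table_path, fasta_path) -> list[ASVProfile]:
    """ASV count table (sample, asv_id, count, taxonomy ranks) plus a FASTA
    of ASV sequences keyed by asv_id."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    df = pd.read_csv(table_path, sep="\t", dtype={"sample": str, "asv_id": str})
    missing = {"sample", "asv_id", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"{table_path}: missing columns {sorted(missing)}")
    rank_cols = [c for c in TAXONOMY_RANKS if c in df.columns]
    profiles = []
    for sample, grp in df.groupby("sample", sort=True):
        records = []
        for row in grp.to_dict("records"):  # dict access: "class" is a keyword
            asv_id = row["asv_id"]
            if asv_id not in seqs:
                raise ValueError(f"{table_path}: ASV {asv_id} missing from FASTA")
            taxonomy = {c: row[c] for c in rank_cols if isinstance(row[c], str) and row[c]}
            records.append(ASVRecord(asv_id, seqs[asv_id], int(row["count"]), taxonomy))
        profiles.append(ASVProfile(str(sample), tuple(records)))
    return profiles


def write_asv_profiles(profiles: Sequence[ASVProfile], table_path, fasta_path) -> None:
    rows, fasta = [], {}
    for p in profiles:
        for r in p.records:
            row = {"sample": p.sample_id, "asv_id": r.asv_id, "count": r.count}
            row.update({rank: r.taxonomy.get(rank, "") for rank in TAXONOMY_RANKS})
            rows.append(row)
            fasta[r.asv_id] = r.sequence
    cols = ["sample", "asv_id", "count", *TAXONOMY_RANKS]
    pd.DataFrame(rows, columns=cols).to_csv(table_path, sep="\t", index=False)
    SeqIO.write([SeqRecord(Seq(s), id=a, description="") for a, s in sorted(fasta.items())],
                str(fasta_path), "fasta")


def read_contaminant_list(path) -> set[str]:
    """Plain text, one genus per line; blank lines and # comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_contig_lengths(path) -> list[ContigInfo]:
    """Contig lengths from a 2-column TSV (id, length) or a FASTA file."""
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        return [ContigInfo(rec.id, len(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    out = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: need contig id and length")
        out.append(ContigInfo(parts[0], int(parts[1])))
    return out


# --- result writers --------------------------------------------------------

def write_fits_tsv(fits: Sequence[LogisticFit],
                   calls: Sequence[WellClassification], path) -> None:
    rows = []
    for fit, call in zip(fits, calls):
        rows.append({
            "well": fit.well_id, "baseline": fit.baseline, "amplitude": fit.amplitude,
            "rate": fit.rate, "midpoint": fit.midpoint, "rss": fit.rss,
            "fits_sigmoid": int(call.fits_sigmoid),
            "threshold_time": "" if call.threshold_time is None else call.threshold_time,
            "category": call.category or "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_classifications_tsv(cells: Sequence[CellClassification], path) -> None:
    rows = [{"sample": c.sample_id, "category": c.category,
             "dominant_asv": c.dominant_asv or "",
             "dominant_fraction": c.dominant_fraction,
             "matched_community": int(c.matched_community)} for c in cells]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_triage_summary_tsv(summary: TriageSummary, path) -> None:
    pd.DataFrame([dataclasses.asdict(summary)]).to_csv(path, sep="\t", index=False)


def write_edge_list(cg: ClusterGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_a\tcontig_b\tpla\n")
        for a, b, data in sorted(cg.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['pla']:.4f}\n")


def write_clusters_tsv(cg: ClusterGraph, path) -> None:
    mapping = cg.cluster_of()
    with open(path, "w") as fh:
        fh.write("contig\tcluster_id\n")
        for node in sorted(mapping):
            fh.write(f"{node}\t{mapping[node]}\n")


def write_gml(cg: ClusterGraph, path) -> None:
    import networkx as nx
    g = cg.graph.copy()
    if cg.clusters is not None:
        for node, cid in cg.cluster_of().items():
            g.nodes[node]["cluster"] = cid
    nx.write_gml(g, str(path))
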