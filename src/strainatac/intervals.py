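"""Genomic coordinate model and interval operations.

All coordinates are 0-based, half-open (BED convention). VCF positions are
converted on read by subtracting one. Interval containers are thin frozen
dataclasses; bulk operations work on pandas DataFrames with ``chrom``,
``start``, ``end`` columns so they compose with the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "NFRPeak",
    "Variant",
    "GeneTSS",
    "OffsetMap",
    "ValidationError",
    "overlap_query",
    "classify_activity",
    "nearest_tss",
    "sample_random_regions",
    "lift_coordinates",
]


class ValidationError(ValueError):
    """A record violated an interval or configuration invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval.

    ``start`` is 0-based inclusive, ``end`` exclusive; peaks use strand '.'.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval has empty chrom")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class NFRPeak:
    """Nucleosome-free region with classification state."""

    interval: GenomicInterval
    peak_id: str
    activity: str = "Unset"  # Active | NonActive | Unset
    n_variants: int = 0

    @property
    def center(self) -> int:
        return self.interval.center


@dataclass(frozen=True)
class Variant:
    """Single-nucleotide strain difference, 0-based position.

    ``ref_allele`` is the reference-strain (B6) base, ``alt_allele`` the
    alternate strain (129).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_id: str

    def __post_init__(self) -> None:
        bases = {"A", "C", "G", "T"}
        if self.ref_allele not in bases or self.alt_allele not in bases:
            raise ValidationError(f"non-SNV alleles for {self.variant_id}")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"identical alleles for {self.variant_id}")


@dataclass(frozen=True)
class GeneTSS:
    """Most-active transcription start site selected for a gene."""

    gene_id: str
    chrom: str
    tss_pos: int
    strand: str
    expressed: bool = True

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"TSS strand must be +/- for {self.gene_id}")


@dataclass
class OffsetMap:
    """Piecewise-constant offset map between two strains' coordinates.

    Blocks are (chrom, src_start, src_end, delta): a position x in
    [src_start, src_end) maps to x + delta. Blocks must be non-overlapping
    and the mapping strictly monotone within each chromosome.
    """

    blocks: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.blocks) == 0:
            self.blocks = pd.DataFrame(
                columns=["chrom", "src_start", "src_end", "delta"]
            )
        b = self.blocks.sort_values(["chrom", "src_start"]).reset_index(drop=True)
        for chrom, grp in b.groupby("chrom", sort=False):
            starts = grp["src_start"].to_numpy()
            ends = grp["src_end"].to_numpy()
            deltas = grp["delta"].to_numpy()
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"overlapping map blocks on {chrom}")
            mapped_ends = ends[:-1] + deltas[:-1]
            mapped_starts = starts[1:] + deltas[1:]
            if np.any(mapped_starts < mapped_ends):
                raise ValidationError(f"non-monotone map on {chrom}")
        self.blocks = b

    def inverse(self) -> "OffsetMap":
        inv = self.blocks.copy()
        inv["src_start"] = self.blocks["src_start"] + self.blocks["delta"]
        inv["src_end"] = self.blocks["src_end"] + self.blocks["delta"]
        inv["delta"] = -self.blocks["delta"]
        return OffsetMap(inv)

    @classmethod
    def identity(cls, chrom_sizes: Mapping[str, int]) -> "OffsetMap":
        rows = [
            {"chrom": c, "src_start": 0, "src_end": n, "delta": 0}
            for c, n in chrom_sizes.items()
        ]
        return cls(pd.DataFrame(rows))


def _check_frame(df: pd.DataFrame, what: str) -> None:
    if len(df) == 0:
        return
    bad = (df["start"] >= df["end"]) | (df["start"] < 0)
    if bad.any():
        idx = df.index[bad][0]
        raise ValidationError(f"malformed {what} interval at record {idx!r}")


def overlap_query(
    queries: pd.DataFrame, subjects: pd.DataFrame
) -> pd.DataFrame:
    """All (query_id, subject_id) pairs with at least 1 bp of overlap.

    Half-open semantics: intervals sharing only a boundary do not overlap.
    Frames need columns chrom/start/end and an ``id`` column (falls back to
    the index). Output is sorted by (chrom, query start, query_id,
    subject_id) for determinism.
    """
    q = queries.copy()
    s = subjects.copy()
    for df, name in ((q, "query"), (s, "subject")):
        _check_frame(df, name)
        if "id" not in df.columns:
            df["id"] = df.index.astype(str)
    out_rows: list[pd.DataFrame] = []
    for chrom, qg in q.groupby("chrom", sort=True):
        sg = s[s["chrom"] == chrom]
        if len(sg) == 0:
            continue
        # sweep: sort subjects by start; for each query find candidates by
        # binary search on start, prune by max subject width
        sg = sg.sort_values(["start", "id"], kind="mergesort")
        s_start = sg["start"].to_numpy()
        s_end = sg["end"].to_numpy()
        s_id = sg["id"].to_numpy()
        max_w = int((s_end - s_start).max())
        qg = qg.sort_values(["start", "id"], kind="mergesort")
        for q_start, q_end, q_id in zip(
            qg["start"].to_numpy(), qg["end"].to_numpy(), qg["id"].to_numpy()
        ):
            lo = np.searchsorted(s_start, q_start - max_w, side="left")
            hi = np.searchsorted(s_start, q_end, side="left")
            if hi <= lo:
                continue
            hit = s_end[lo:hi] > q_start
            if not hit.any():
                continue
            sids = np.sort(s_id[lo:hi][hit])
            out_rows.append(
                pd.DataFrame(
                    {"query_id": q_id, "subject_id": sids, "chrom": chrom,
                     "query_start": int(q_start)}
                )
            )
    if not out_rows:
        return pd.DataFrame(columns=["query_id", "subject_id"])
    out = pd.concat(out_rows, ignore_index=True)
    out = out.sort_values(
        ["chrom", "query_start", "query_id", "subject_id"], kind="mergesort"
    )
    return out[["query_id", "subject_id"]].reset_index(drop=True)


def classify_activity(
    peaks: pd.DataFrame,
    h3k27ac_regions: pd.DataFrame,
    flank_bp: int = 1000,
) -> pd.Series:
    """Label each peak Active/NonActive by flanking H3K27ac overlap.

    A peak is Active when at least one H3K27ac region overlaps the window
    [start - flank_bp, end + flank_bp); a single-sided overlap suffices.
    """
    if flank_bp < 0:
        raise ValidationError("flank_bp must be >= 0")
    if "id" not in peaks.columns:
        peaks = peaks.copy()
        peaks["id"] = peaks.index.astype(str)
    expanded = peaks.copy()
    expanded["start"] = (peaks["start"] - flank_bp).clip(lower=0)
    expanded["end"] = peaks["end"] + flank_bp
    hits = overlap_query(expanded, h3k27ac_regions)
    active_ids = set(hits["query_id"])
    labels = np.where(peaks["id"].isin(active_ids), "Active", "NonActive")
    return pd.Series(labels, index=peaks.index, name="activity")


def nearest_tss(
    peaks: pd.DataFrame,
    tss_table: pd.DataFrame,
    promoter_halfwidth: int = 2000,
    expressed_only: bool = True,
) -> pd.DataFrame:
    """Assign each peak its nearest (expressed) TSS gene.

    Distance is ``peak_center - tss_pos`` with a strand-aware sign: positive
    means the peak lies downstream of the TSS in the gene's orientation.
    Ties in absolute distance break to the lexicographically smaller
    gene_id. Peaks on chromosomes absent from the table get gene_id ``None``
    and NaN distance.

    Returns a frame indexed like ``peaks`` with columns gene_id, distance,
    feature (promoter/distal).
    """
    if len(tss_table) == 0:
        raise ValidationError("tss_table is empty")
    tss = tss_table
    if expressed_only and "expressed" in tss.columns:
        tss = tss[tss["expressed"]]
    if len(tss) == 0:
        raise ValidationError("no expressed TSS records")
    out_gene = np.full(len(peaks), None, dtype=object)
    out_dist = np.full(len(peaks), np.nan)
    centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    chroms = peaks["chrom"].to_numpy()
    for chrom, grp in tss.groupby("chrom", sort=False):
        grp = grp.sort_values(["tss_pos", "gene_id"], kind="mergesort")
        pos = grp["tss_pos"].to_numpy()
        genes = grp["gene_id"].to_numpy()
        strands = grp["strand"].to_numpy()
        mask = chroms == chrom
        if not mask.any():
            continue
        c = centers[mask]
        idx = np.searchsorted(pos, c)
        best_gene = np.empty(len(c), dtype=object)
        best_signed = np.empty(len(c))
        for k, (ci, i) in enumerate(zip(c, idx)):
            # candidates: nearest on each side, tie -> smaller gene_id
            cand = []
            for j in (i - 1, i):
                if 0 <= j < len(pos):
                    cand.append(j)
            best = min(
                cand, key=lambda j: (abs(int(ci) - int(pos[j])), genes[j])
            )
            raw = int(ci) - int(pos[best])
            best_signed[k] = raw if strands[best] == "+" else -raw
            best_gene[k] = genes[best]
        out_gene[mask] = best_gene
        out_dist[mask] = best_signed
    feature = np.where(
        np.isnan(out_dist),
        "none",
        np.where(np.abs(out_dist) <= promoter_halfwidth, "promoter", "distal"),
    )
    return pd.DataFrame(
        {"gene_id": out_gene, "distance": out_dist, "feature": feature},
        index=peaks.index,
    )


def sample_random_regions(
    template_peaks: pd.DataFrame,
    n_per_template: int,
    chrom_sizes: Mapping[str, int],
    rng_seed: int,
) -> pd.DataFrame:
    """Width-matched random background regions.

    For each template, draw ``n_per_template`` regions of identical width:
    chromosome sampled with probability proportional to its length (among
    chromosomes long enough to hold the region), start uniform.
    """
    if n_per_template < 1:
        raise ValidationError("n_per_template must be >= 1")
    rng = np.random.default_rng(rng_seed)
    names = np.array(list(chrom_sizes.keys()))
    lengths = np.array([chrom_sizes[c] for c in names], dtype=float)
    widths = (template_peaks["end"] - template_peaks["start"]).to_numpy()
    if (widths > lengths.max()).any():
        raise ValidationError("template wider than every chromosome")
    rows = []
    for t_idx, w in enumerate(widths):
        ok = lengths >= w
        p = lengths * ok
        p = p / p.sum()
        chosen = rng.choice(len(names), size=n_per_template, p=p)
        for j, ci in enumerate(chosen):
            start = int(rng.integers(0, chrom_sizes[names[ci]] - w + 1))
            rows.append(
                {
                    "chrom": names[ci],
                    "start": start,
                    "end": start + int(w),
                    "id": f"bg_{t_idx}_{j}",
                    "template_id": template_peaks.index[t_idx],
                }
            )
    return pd.DataFrame(rows)


def lift_coordinates(
    intervals: pd.DataFrame, offset_map: OffsetMap
) -> pd.DataFrame:
    """Shift intervals into target-strain coordinates via an offset map.

    An interval must sit fully inside one map block; otherwise it is
    returned with ``mappable=False`` and untouched coordinates rather than
    silently shifted.
    """
    out = intervals.copy()
    out["mappable"] = False
    blocks = offset_map.blocks
    for chrom, grp in blocks.groupby("chrom", sort=False):
        starts = grp["src_start"].to_numpy()
        ends = grp["src_end"].to_numpy()
        deltas = grp["delta"].to_numpy()
        mask = out["chrom"] == chrom
        if not mask.any():
            continue
        iv_start = out.loc[mask, "start"].to_numpy()
        iv_end = out.loc[mask, "end"].to_numpy()
        block_idx = np.searchsorted(starts, iv_start, side="right") - 1
        inside = (block_idx >= 0) & (
            iv_end <= ends[np.clip(block_idx, 0, len(ends) - 1)]
        ) & (iv_start >= starts[np.clip(block_idx, 0, len(starts) - 1)])
        d = np.where(inside, deltas[np.clip(block_idx, 0, len(deltas) - 1)], 0)
        out.loc[mask, "start"] = iv_start + d
        out.loc[mask, "end"] = iv_end + d
        out.loc[mask, "mappable"] = inside
    return out
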