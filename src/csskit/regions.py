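"""Significant genomic regions from flagged CSS SNPs.

A *cluster* is a maximal run of map-consecutive SNPs all in the top 1% of
smoothed CSS. A cluster becomes a significant region when it contains at
least one top-0.1% SNP flanked by five or more further top-1% SNPs (total
run length ≥ 6; flanks may be one-sided). Region boundaries are the
positions of the first and last top-1% SNP of the cluster (1-based
inclusive). Clusters within ~1 Mb of each other are merged into a single
region.

"Adjoining" is read strictly (no interleaved sub-threshold SNPs) by
default; ``max_interleaved`` permits a gap-tolerant reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_MIN_CLUSTER_SIZE = 6  # 1 top-0.1% SNP + >= 5 top-1% companions
DEFAULT_MERGE_GAP_BP = 1_000_000


@dataclass
class SelectionRegion:
    chrom: int
    start_bp: int
    end_bp: int
    n_top01: int
    n_top1: int
    peak_css: float
    snp_ids: list = field(default_factory=list)
    merged_from: int = 1

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("region start after end")

    @property
    def length_mb(self) -> float:
        return region_length_mb(self)


def region_length_mb(region: SelectionRegion) -> float:
    """Region span in Mb, (end − start) / 1e6 (reported to 2 decimals)."""
    return (region.end_bp - region.start_bp) / 1e6


def call_clusters(
    track,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    max_interleaved: int = 0,
) -> list[SelectionRegion]:
    """Find qualifying clusters of flagged SNPs in a CSS track.

    ``track`` is a :class:`~csskit.css.CssTrack` or an equivalent DataFrame
    with columns chrom, pos, snp_id, css_smoothed, top01, top1. SNPs
    excluded from the CSS ranking do not interrupt or extend runs.
    """
    df = track.to_frame() if hasattr(track, "to_frame") else track
    df = df[~df["css_smoothed"].isna()].reset_index(drop=True)
    out: list[SelectionRegion] = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("pos").reset_index(drop=True)
        flags1 = grp["top1"].to_numpy(bool)
        for start, end in _runs(flags1, max_interleaved):
            run = grp.iloc[start:end]
            run = run[run["top1"]]  # interleaved non-top1 SNPs never count
            n01 = int(run["top01"].sum())
            if len(run) >= min_cluster_size and n01 >= 1:
                out.append(
                    SelectionRegion(
                        chrom=int(chrom),
                        start_bp=int(run["pos"].iloc[0]),
                        end_bp=int(run["pos"].iloc[-1]),
                        n_top01=n01,
                        n_top1=int(len(run)),
                        peak_css=float(run["css_smoothed"].max()),
                        snp_ids=run["snp_id"].tolist(),
                    )
                )
    return out


def _runs(flags: np.ndarray, max_interleaved: int):
    """Maximal runs of True, optionally bridging ≤ max_interleaved Falses."""
    runs = []
    i, n = 0, flags.size
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        last_true = i
        gap = 0
        while j + 1 < n:
            if flags[j + 1]:
                j += 1
                last_true = j
                gap = 0
            elif gap < max_interleaved:
                j += 1
                gap += 1
            else:
                break
        runs.append((i, last_true + 1))
        i = last_true + 1
    return runs


def merge_regions(
    regions: list[SelectionRegion], max_gap_bp: int = DEFAULT_MERGE_GAP_BP
) -> list[SelectionRegion]:
    """Merge same-chromosome regions whose gap is ≤ max_gap_bp (inclusive).

    Merging is transitive; counts are summed, peaks maximized, and
    ``merged_from`` accumulates. Idempotent and order-invariant.
    """
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start_bp, r.end_bp))
    out: list[SelectionRegion] = []
    for reg in ordered:
        if out and out[-1].chrom == reg.chrom and \
                reg.start_bp - out[-1].end_bp <= max_gap_bp:
            prev = out[-1]
            out[-1] = SelectionRegion(
                chrom=prev.chrom,
                start_bp=prev.start_bp,
                end_bp=max(prev.end_bp, reg.end_bp),
                n_top01=prev.n_top01 + reg.n_top01,
                n_top1=prev.n_top1 + reg.n_top1,
                peak_css=max(prev.peak_css, reg.peak_css),
                snp_ids=prev.snp_ids + reg.snp_ids,
                merged_from=prev.merged_from + reg.merged_from,
            )
        else:
            out.append(replace(reg, snp_ids=list(reg.snp_ids)))
    return out


def call_regions(track, min_cluster_size=DEFAULT_MIN_CLUSTER_SIZE,
                 max_interleaved=0, merge_gap_bp=DEFAULT_MERGE_GAP_BP):
    """Cluster calling followed by proximity merging."""
    return merge_regions(
        call_clusters(track, min_cluster_size, max_interleaved), merge_gap_bp
    )


def regions_to_frame(regions: list[SelectionRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.chrom, r.start_bp, r.end_bp, round(r.length_mb, 2), r.n_top01,
             r.n_top1, r.peak_css, r.merged_from)
            for r in regions
        ],
        columns=["chrom", "start_bp", "end_bp", "length_mb", "n_top01",
                 "n_top1", "peak_css", "merged_from"],
    )


def regions_to_bed(regions: list[SelectionRegion], path) -> None:
    """BED export (0-based half-open)."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start_bp)):
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t"
                     f"css_region\t{r.peak_css:.4f}\n")
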