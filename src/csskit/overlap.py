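"""Candidate-gene-region construction, co-location scoring, chance and
permutation nulls.

Candidate gene regions are built by merging map-consecutive genes lying
within 1 Mb of each other. A selection region *co-locates* with a gene
region when their intervals intersect after padding the gene region by
±1 Mb (closed intervals: touching counts). The chance expectation is the
fraction of the autosomal genome covered by the padded gene-region union;
the permutation null re-runs the entire scan on randomly assigned
pseudo-cohorts of the real cohort sizes and scores their co-location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_GENE_MERGE_GAP_BP = 1_000_000
DEFAULT_PAD_BP = 1_000_000


class OverlapError(ValueError):
    pass


@dataclass
class GeneRegion:
    chrom: int
    start_bp: int
    end_bp: int
    genes: list = field(default_factory=list)


@dataclass
class OverlapReport:
    n_regions: int
    n_colocated: int
    proportion: float  # fraction in [0, 1]
    chance_expectation: float | None
    hits: list  # (region index, [gene names]) per co-located region

    @property
    def percent(self) -> int:
        """Proportion as a whole percent (rounded), as reported in summaries."""
        return int(round(100.0 * self.proportion))


def build_gene_regions(
    gene_table: pd.DataFrame, merge_gap_bp: int = DEFAULT_GENE_MERGE_GAP_BP
) -> list[GeneRegion]:
    """Merge consecutive genes within ``merge_gap_bp`` into candidate regions.

    ``gene_table`` columns: gene, chrom, start, end (1-based inclusive).
    The gap convention is inclusive: a gap of exactly ``merge_gap_bp``
    still merges.
    """
    required = {"gene", "chrom", "start", "end"}
    if not required.issubset(gene_table.columns):
        raise OverlapError(f"gene table needs columns {sorted(required)}")
    bad = gene_table[gene_table["start"] > gene_table["end"]]
    if len(bad):
        raise OverlapError(f"malformed gene interval: {bad['gene'].iloc[0]}")
    out: list[GeneRegion] = []
    for chrom, grp in gene_table.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"]).reset_index(drop=True)
        cur: GeneRegion | None = None
        for row in grp.itertuples(index=False):
            if cur is not None and row.start - cur.end_bp <= merge_gap_bp:
                cur.end_bp = max(cur.end_bp, int(row.end))
                cur.genes.append(row.gene)
            else:
                cur = GeneRegion(int(chrom), int(row.start), int(row.end), [row.gene])
                out.append(cur)
    return out


def colocate(
    selection_regions,
    gene_regions: list[GeneRegion],
    pad_bp: int = DEFAULT_PAD_BP,
    chance: float | None = None,
) -> OverlapReport:
    """Score selection regions against padded candidate gene regions.

    Intervals are closed; a selection region touching a gene region padded
    by ``pad_bp`` on both sides counts as co-located.
    """
    hits = []
    n_col = 0
    for i, reg in enumerate(selection_regions):
        names = []
        for g in gene_regions:
            if g.chrom != reg.chrom:
                continue
            if reg.start_bp <= g.end_bp + pad_bp and g.start_bp - pad_bp <= reg.end_bp:
                names.extend(g.genes)
        if names:
            n_col += 1
            hits.append((i, names))
    n = len(selection_regions)
    return OverlapReport(
        n_regions=n,
        n_colocated=n_col,
        proportion=(n_col / n) if n else 0.0,
        chance_expectation=chance,
        hits=hits,
    )


def _union_length(intervals) -> int:
    """Total bp covered by closed 1-based intervals (union, no double count)."""
    total = 0
    for chrom in sorted({c for c, _, _ in intervals}):
        ivs = sorted((s, e) for c, s, e in intervals if c == chrom)
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
    return total


def chance_expectation(
    gene_regions: list[GeneRegion],
    pad_bp: int,
    autosome_lengths: dict,
) -> float:
    """Fraction of the genome covered by the (padded) gene-region union.

    Padded intervals are clipped to ``autosome_lengths`` (chrom -> bp) and
    merged before summing, so overlaps are never double-counted. Returned
    as a fraction; format with ``100 * x`` to 1 decimal for reports.
    """
    if any(l <= 0 for l in autosome_lengths.values()):
        raise OverlapError("autosome lengths must be positive")
    intervals = []
    for g in gene_regions:
        if g.chrom not in autosome_lengths:
            continue
        s = max(1, g.start_bp - pad_bp)
        e = min(int(autosome_lengths[g.chrom]), g.end_bp + pad_bp)
        if s <= e:
            intervals.append((g.chrom, s, e))
    if not intervals:
        return 0.0
    return _union_length(intervals) / float(sum(autosome_lengths.values()))


def permutation_null(
    panel,
    cohort_sizes: tuple[int, int],
    gene_regions: list[GeneRegion],
    n_sets: int = 5,
    seed: int = 0,
    pad_bp: int = DEFAULT_PAD_BP,
    scan_params=None,
) -> pd.DataFrame:
    """Co-location of scans on randomly permuted cohorts (no-selection null).

    For each set, samples are assigned at random (breed labels ignored,
    samples unweighted) to two pseudo-cohorts of the real cohorts' sizes;
    the full scan — constituent statistics, CSS for both orientations,
    region calling, gene co-location — is repeated. Returns one row per
    set: set, n_regions, n_colocated, proportion.
    """
    from .pipeline import ScanParams, scan_cohorts

    n1, n2 = cohort_sizes
    if n1 + n2 > panel.n_samples:
        raise OverlapError("cohort sizes exceed panel sample count")
    if n1 < 1 or n2 < 1:
        raise OverlapError("cohort sizes must be positive")
    params = scan_params or ScanParams()
    rng = np.random.default_rng(seed)
    rows = []
    ids = np.array(panel.sample_ids, dtype=object)
    for k in range(n_sets):
        perm = rng.permutation(panel.n_samples)
        pseudo_large = list(ids[perm[:n1]])
        pseudo_small = list(ids[perm[n1:n1 + n2]])
        result = scan_cohorts(panel, pseudo_large, pseudo_small, params)
        report = colocate(result.all_regions, gene_regions, pad_bp=pad_bp)
        rows.append((k + 1, report.n_regions, report.n_colocated, report.proportion))
    return pd.DataFrame(rows, columns=["set", "n_regions", "n_colocated", "proportion"])
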