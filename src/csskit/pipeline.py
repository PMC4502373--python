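"""End-to-end orchestration: cohort scan, run configuration, artifacts.

``scan_cohorts`` is the in-memory workhorse: given a QC'd panel and the two
contrasting cohorts it computes the constituent statistics once, derives
both orientations (large-as-candidate and small-as-candidate; F_ST shared,
directional statistics negated), builds both CSS tracks and calls merged
significant regions per orientation.

``run_scan`` is the file-level driver behind the CLI: it reads genotypes,
phenotypes and (optionally) a gene table, applies QC, classifies cohorts,
scans, and writes every artifact with the config hash and seed in a
metadata header.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import cohorts as coh
from . import css as css_mod
from . import overlap as ovl
from . import panel as pio
from . import regions as reg
from . import stats as st

log = logging.getLogger("csskit")


@dataclass
class ScanParams:
    """Statistical parameters of one CSS scan."""

    window_bp: int = css_mod.DEFAULT_WINDOW_BP
    q01: float = css_mod.DEFAULT_Q01
    q1: float = css_mod.DEFAULT_Q1
    ehh_cutoff: float = st.DEFAULT_EHH_CUTOFF
    ehh_max_gap_bp: int = st.DEFAULT_EHH_MAX_GAP_BP
    ehh_max_extend_bp: int = st.DEFAULT_EHH_MAX_EXTEND_BP
    min_cluster_size: int = reg.DEFAULT_MIN_CLUSTER_SIZE
    max_interleaved: int = 0
    merge_gap_bp: int = reg.DEFAULT_MERGE_GAP_BP
    fst_estimator: str = "wc"


@dataclass
class ScanResult:
    tracks: dict  # orientation label -> CssTrack
    regions: dict  # orientation label -> [SelectionRegion]

    @property
    def all_regions(self) -> list:
        out = []
        for key in sorted(self.regions):
            out.extend(self.regions[key])
        return out


def scan_cohorts(panel, large_samples, small_samples,
                 params: ScanParams | None = None) -> ScanResult:
    """CSS scan of both orientations between the two contrasting cohorts."""
    params = params or ScanParams()
    const_large = st.compute_constituents(
        panel, large_samples, small_samples,
        candidate_id="large", reference_id="small",
        ehh_cutoff=params.ehh_cutoff, max_gap_bp=params.ehh_max_gap_bp,
        max_extend_bp=params.ehh_max_extend_bp,
        fst_estimator=params.fst_estimator,
    )
    tracks, regions = {}, {}
    for const in (const_large, const_large.reversed()):
        label = const.candidate_id
        track = css_mod.build_track(
            const, panel.snp_map,
            window_bp=params.window_bp, q01=params.q01, q1=params.q1,
        )
        tracks[label] = track
        regions[label] = reg.call_regions(
            track,
            min_cluster_size=params.min_cluster_size,
            max_interleaved=params.max_interleaved,
            merge_gap_bp=params.merge_gap_bp,
        )
    return ScanResult(tracks=tracks, regions=regions)


# ---------------------------------------------------------------------------
# File-level run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Declarative configuration of a full scan run (YAML-serializable)."""

    genotypes: str = ""
    snp_map: str = ""
    ancestral: str = ""
    samples: str = ""
    phenotypes: str = ""
    gene_table: str = ""
    outdir: str = "css_run"
    maf_min: float = 0.01
    ibs_threshold: float = 0.95
    per_breed_cap: int = 0  # 0 = no cap
    pad_bp: int = ovl.DEFAULT_PAD_BP
    gene_merge_gap_bp: int = ovl.DEFAULT_GENE_MERGE_GAP_BP
    n_permutation_sets: int = 0
    seed: int = 0
    scan: ScanParams = field(default_factory=ScanParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scan = ScanParams(**raw.pop("scan", {}))
        return cls(scan=scan, **raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Hash of the statistical parameters and seed (file paths are
        excluded so the same analysis re-run elsewhere hashes identically)."""
        d = self.to_dict()
        for key in ("genotypes", "snp_map", "ancestral", "samples",
                    "phenotypes", "gene_table", "outdir"):
            d.pop(key, None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:12]


def _meta_header(config: RunConfig) -> str:
    return f"# csskit config={config.digest()} seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_header(config))
        df.to_csv(fh, sep="\t", index=False)


def run_scan(config: RunConfig):
    """Execute the full workflow from files and write the artifact bundle.

    Returns a dict of output paths plus the in-memory :class:`ScanResult`.
    """
    os.makedirs(config.outdir, exist_ok=True)

    def out(name):
        return os.path.join(config.outdir, name)

    panel, read_report = pio.read_panel(
        config.genotypes, config.snp_map or None, config.ancestral or None,
        config.samples or None,
    )
    log.info("loaded %d SNPs x %d samples", panel.n_snps, panel.n_samples)
    panel, dedupe_report = pio.ibs_dedupe(panel, config.ibs_threshold)
    if config.per_breed_cap:
        panel = pio.subsample_per_breed(panel, config.per_breed_cap, config.seed)
    panel, qc_report = pio.qc_filter(panel, maf_min=config.maf_min)
    qc = {
        "read": asdict(read_report),
        "dedupe": asdict(dedupe_report),
        "maf": asdict(qc_report),
        "n_samples_final": panel.n_samples,
        "n_snps_final": panel.n_snps,
    }
    with open(out("qc_report.json"), "w") as fh:
        json.dump(qc, fh, indent=2)

    pheno = pd.read_csv(config.phenotypes)
    summaries = coh.summarize_breeds(pheno)
    assignment = coh.classify_cohorts(summaries)
    _write_tsv(assignment.to_frame(), out("cohorts.tsv"), config)
    with open(out("cohort_summary.json"), "w") as fh:
        json.dump(
            {
                "overall_q1_cm": assignment.overall_q1_cm,
                "overall_median_cm": assignment.overall_median_cm,
                "overall_q3_cm": assignment.overall_q3_cm,
                "quantile_rule": coh.QUANTILE_RULE,
                "n_large": len(assignment.breeds_in("large")),
                "n_small": len(assignment.breeds_in("small")),
            },
            fh, indent=2,
        )
    large, small = coh.cohort_samples(assignment, panel)
    log.info("cohorts: %d large / %d small samples", len(large), len(small))

    result = scan_cohorts(panel, large, small, config.scan)
    paths = {"qc": out("qc_report.json"), "cohorts": out("cohorts.tsv")}
    for label, track in result.tracks.items():
        p = out(f"css_track_{label}.tsv")
        _write_tsv(track.to_frame(), p, config)
        paths[f"track_{label}"] = p
        rp = out(f"regions_{label}.tsv")
        _write_tsv(reg.regions_to_frame(result.regions[label]), rp, config)
        paths[f"regions_{label}"] = rp
        reg.regions_to_bed(result.regions[label], out(f"regions_{label}.bed"))

    if config.gene_table:
        genes = pd.read_csv(config.gene_table, sep="\t")
        gene_regions = ovl.build_gene_regions(genes, config.gene_merge_gap_bp)
        lengths = autosome_lengths_from_map(panel.snp_map)
        chance = ovl.chance_expectation(gene_regions, config.pad_bp, lengths)
        report = ovl.colocate(result.all_regions, gene_regions,
                              pad_bp=config.pad_bp, chance=chance)
        with open(out("overlap_report.json"), "w") as fh:
            json.dump(
                {
                    "n_regions": report.n_regions,
                    "n_colocated": report.n_colocated,
                    "proportion_pct": report.percent,
                    "chance_expectation_pct": round(100.0 * chance, 1),
                    "hits": report.hits,
                    "interval_convention": "closed; touching intersects",
                },
                fh, indent=2,
            )
        paths["overlap"] = out("overlap_report.json")
        if config.n_permutation_sets:
            perm = ovl.permutation_null(
                panel, (len(large), len(small)), gene_regions,
                n_sets=config.n_permutation_sets, seed=config.seed,
                pad_bp=config.pad_bp, scan_params=config.scan,
            )
            _write_tsv(perm, out("permutation.tsv"), config)
            paths["permutation"] = out("permutation.tsv")

    return paths, result


def autosome_lengths_from_map(snp_map: pd.DataFrame) -> dict:
    """Chromosome lengths approximated by the last mapped SNP position."""
    return {
        int(c): int(g["pos"].max()) for c, g in snp_map.groupby("chrom")
    }


# ---------------------------------------------------------------------------
# Manhattan plot data / figure
# ---------------------------------------------------------------------------

def manhattan_frame(result: ScanResult) -> pd.DataFrame:
    """Mirrored two-track plot data: candidate track positive, reference
    (the other orientation) negative, with the top-0.1% cutoffs."""
    frames = []
    for sign, label in ((1.0, "large"), (-1.0, "small")):
        track = result.tracks[label]
        df = track.to_frame()[["chrom", "pos", "css_smoothed", "top01"]].copy()
        df["track"] = label
        df["mirrored"] = sign * df["css_smoothed"]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def plot_manhattan(result: ScanResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = manhattan_frame(result)
    fig, ax = plt.subplots(figsize=(11, 4))
    offset = 0
    ticks, labels = [], []
    for chrom in sorted(df["chrom"].unique()):
        sub = df[df["chrom"] == chrom]
        x = sub["pos"] + offset
        for label, color in (("large", "tab:red"), ("small", "tab:blue")):
            s = sub[sub["track"] == label]
            ax.scatter(s["pos"] + offset, s["mirrored"], s=3, color=color,
                       alpha=0.6, linewidths=0)
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(chrom))
        offset += sub["pos"].max()
    for label, sign, color in (("large", 1, "red"), ("small", -1, "blue")):
        track = result.tracks[label]
        vals = track.css_smoothed[~np.isnan(track.css_smoothed)]
        cut = np.quantile(vals, 1 - track.metadata["q01"])
        ax.axhline(sign * cut, linestyle="--", color=color, linewidth=0.8)
    ax.axhline(0, color="k", linewidth=0.5)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("smoothed CSS (mirrored)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
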