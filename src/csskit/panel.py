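"""Phased haplotype panels: containers, file I/O, polarization and QC.

The central container is :class:`HaplotypePanel`, holding phased biallelic
autosomal SNPs coded 0 = ancestral / 1 = derived, two haplotype rows per
diploid sample, plus a SNP map and a sample table with breed labels.
Coordinates are 1-based inclusive internally (VCF convention); BED exports
convert to 0-based half-open.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

log = logging.getLogger("csskit")

MAP_COLUMNS = ["chrom", "pos", "snp_id", "ancestral", "derived"]
SAMPLE_COLUMNS = ["sample_id", "breed", "cattle_type"]


class PanelError(ValueError):
    """Raised for malformed or inconsistent genotype input."""


@dataclass
class HaplotypePanel:
    """Phased, polarized SNP haplotypes for a multibreed sample set.

    Attributes
    ----------
    snp_map : pandas.DataFrame
        Columns ``chrom`` (int), ``pos`` (1-based int), ``snp_id``,
        ``ancestral``, ``derived``; sorted by (chrom, pos) with strictly
        increasing positions within each chromosome.
    haplotypes : numpy.ndarray
        int8 matrix of shape (2 * n_samples, n_snps); rows ``2i`` and
        ``2i + 1`` are the two phased haplotypes of sample ``i``.
        0 = ancestral allele, 1 = derived allele.
    samples : pandas.DataFrame
        Columns ``sample_id``, ``breed``, ``cattle_type``.
    """

    snp_map: pd.DataFrame
    haplotypes: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.snp_map = self.snp_map.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise PanelError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise PanelError(
                f"haplotype rows ({self.haplotypes.shape[0]}) != "
                f"2 x samples ({len(self.samples)})"
            )
        if self.haplotypes.shape[1] != len(self.snp_map):
            raise PanelError("haplotype columns do not match SNP map length")
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise PanelError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list:
        return self.samples["sample_id"].tolist()

    def hap_rows(self, sample_ids) -> np.ndarray:
        """Haplotype row indices (2 per sample) for the given sample ids."""
        index = pd.Index(self.samples["sample_id"])
        locs = index.get_indexer(list(sample_ids))
        if np.any(locs < 0):
            missing = [s for s, l in zip(sample_ids, locs) if l < 0]
            raise PanelError(f"unknown sample ids: {missing[:5]}")
        return np.repeat(locs * 2, 2) + np.tile([0, 1], len(locs))

    def haplotypes_of(self, sample_ids) -> np.ndarray:
        return self.haplotypes[self.hap_rows(sample_ids)]

    def dosages(self) -> np.ndarray:
        """Per-sample derived-allele counts, shape (n_samples, n_snps)."""
        return (
            self.haplotypes[0::2].astype(np.int16)
            + self.haplotypes[1::2].astype(np.int16)
        )

    # -- subsetting --------------------------------------------------------

    def subset_snps(self, mask) -> "HaplotypePanel":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return HaplotypePanel(
            snp_map=self.snp_map.iloc[idx],
            haplotypes=self.haplotypes[:, idx],
            samples=self.samples.copy(),
        )

    def subset_samples(self, sample_ids) -> "HaplotypePanel":
        rows = self.hap_rows(sample_ids)
        keep = self.samples.set_index("sample_id").loc[list(sample_ids)]
        return HaplotypePanel(
            snp_map=self.snp_map.copy(),
            haplotypes=self.haplotypes[rows],
            samples=keep.reset_index()[SAMPLE_COLUMNS],
        )

    def derived_freq(self, sample_ids=None) -> np.ndarray:
        """Derived allele frequency per SNP over the given (or all) samples."""
        H = self.haplotypes if sample_ids is None else self.haplotypes_of(sample_ids)
        return H.mean(axis=0)


@dataclass
class QcReport:
    """Bookkeeping for panel filtering; counts sum consistently."""

    n_input_snps: int = 0
    n_retained_snps: int = 0
    n_dropped_maf: int = 0
    n_dropped_unmapped: int = 0
    n_dropped_unpolarized: int = 0
    n_dropped_missing: int = 0
    duplicate_pairs: list = field(default_factory=list)

    def validate(self) -> None:
        dropped = (
            self.n_dropped_maf
            + self.n_dropped_unmapped
            + self.n_dropped_unpolarized
            + self.n_dropped_missing
        )
        if self.n_input_snps != self.n_retained_snps + dropped:
            raise PanelError("QcReport counts are inconsistent")

    def to_json(self, path) -> None:
        self.validate()
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _read_map(map_path) -> pd.DataFrame:
    m = pd.read_csv(map_path, sep="\t", comment="#")
    needed = {"chrom", "pos", "snp_id"}
    if not needed.issubset(m.columns):
        raise PanelError(f"SNP map must have columns {sorted(needed)}")
    return m


def _read_ancestral(ancestral_path) -> pd.Series:
    a = pd.read_csv(ancestral_path, sep="\t", comment="#")
    if not {"snp_id", "ancestral"}.issubset(a.columns):
        raise PanelError("ancestral table must have columns snp_id, ancestral")
    return a.set_index("snp_id")["ancestral"]


def _read_samples(samples_path, sample_ids) -> pd.DataFrame:
    if samples_path is None:
        return pd.DataFrame(
            {
                "sample_id": sample_ids,
                "breed": ["unknown"] * len(sample_ids),
                "cattle_type": ["unknown"] * len(sample_ids),
            }
        )
    s = pd.read_csv(samples_path, sep="\t", comment="#")
    if "sample_id" not in s.columns:
        raise PanelError("sample table must have a sample_id column")
    for col in ("breed", "cattle_type"):
        if col not in s.columns:
            s[col] = "unknown"
    s = s.set_index("sample_id").reindex(sample_ids)
    s["breed"] = s["breed"].fillna("unknown")
    s["cattle_type"] = s["cattle_type"].fillna("unknown")
    return s.reset_index()[SAMPLE_COLUMNS]


def read_panel(
    genotype_path,
    map_path=None,
    ancestral_path=None,
    samples_path=None,
) -> tuple[HaplotypePanel, QcReport]:
    """Load a phased panel from VCF or haplotype-matrix TSV and polarize it.

    Sites absent from the SNP map, or whose ancestral allele is not among
    the two observed alleles, or containing missing genotypes, are dropped
    and counted in the returned :class:`QcReport`. Unphased genotypes are a
    hard error naming the first offending record.
    """
    path = str(genotype_path)
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_vcf(path, map_path, ancestral_path, samples_path)
    return _read_hap_tsv(path, map_path, samples_path)


def _read_vcf(path, map_path, ancestral_path, samples_path):
    from cyvcf2 import VCF

    if map_path is None or ancestral_path is None:
        raise PanelError("VCF input requires map_path and ancestral_path")
    snp_map = _read_map(map_path).set_index("snp_id")
    ancestral = _read_ancestral(ancestral_path)

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    rows, columns = [], []
    report = QcReport()
    for var in vcf:
        report.n_input_snps += 1
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if snp_id not in snp_map.index:
            report.n_dropped_unmapped += 1
            continue
        ref, alt = var.REF, (var.ALT[0] if var.ALT else None)
        anc = ancestral.get(snp_id)
        if anc == ref:
            der = alt
            flip = False
        elif anc == alt:
            der = ref
            flip = True
        else:
            report.n_dropped_unpolarized += 1
            log.info("dropping %s: ancestral %s not among alleles %s/%s",
                     snp_id, anc, ref, alt)
            continue
        gts = var.genotypes  # list of [a0, a1, phased]
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=np.int16)
        phased = np.array([bool(g[2]) for g in gts])
        het = alleles[:, 0] != alleles[:, 1]
        if np.any(het & ~phased):
            bad = sample_ids[int(np.flatnonzero(het & ~phased)[0])]
            raise PanelError(
                f"unphased genotype at {snp_id} ({var.CHROM}:{var.POS}) "
                f"sample {bad}; input must be phased"
            )
        if np.any(alleles < 0):
            report.n_dropped_missing += 1
            log.info("dropping %s: missing genotypes", snp_id)
            continue
        codes = alleles.reshape(-1).astype(np.int8)
        if flip:
            codes = (1 - codes).astype(np.int8)
        rows.append(codes)
        row = snp_map.loc[snp_id]
        columns.append((int(row["chrom"]), int(row["pos"]), snp_id, anc, der))

    report.n_retained_snps = len(columns)
    report.validate()
    if not columns:
        raise PanelError(f"no usable sites in {path}")
    cmap = pd.DataFrame(columns, columns=MAP_COLUMNS)
    H = np.column_stack(rows).astype(np.int8)
    order = np.lexsort((cmap["pos"].to_numpy(), cmap["chrom"].to_numpy()))
    cmap = cmap.iloc[order]
    H = H[:, order]
    samples = _read_samples(samples_path, sample_ids)
    return HaplotypePanel(cmap, H, samples), report


def _read_hap_tsv(path, map_path, samples_path):
    """Haplotype-matrix TSV: columns sample_id, hap, then one column per SNP id."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:2]) != ["sample_id", "hap"]:
        raise PanelError("haplotype TSV must start with sample_id, hap columns")
    snp_ids = list(df.columns[2:])
    df = df.sort_values(["sample_id", "hap"], kind="stable")
    sample_ids = df["sample_id"].iloc[0::2].tolist()
    if (df.groupby("sample_id").size() != 2).any():
        raise PanelError("each sample needs exactly 2 haplotype rows")
    H = df[snp_ids].to_numpy(dtype=np.int8)
    report = QcReport(n_input_snps=len(snp_ids), n_retained_snps=len(snp_ids))
    if map_path is not None:
        m = _read_map(map_path).set_index("snp_id")
        keep = [s for s in snp_ids if s in m.index]
        report.n_dropped_unmapped = len(snp_ids) - len(keep)
        report.n_retained_snps = len(keep)
        idx = [snp_ids.index(s) for s in keep]
        H = H[:, idx]
        cmap = m.loc[keep].reset_index()
        for col in ("ancestral", "derived"):
            if col not in cmap.columns:
                cmap[col] = "0" if col == "ancestral" else "1"
        cmap = cmap[MAP_COLUMNS]
    else:
        cmap = pd.DataFrame(
            {
                "chrom": 1,
                "pos": np.arange(1, len(snp_ids) + 1),
                "snp_id": snp_ids,
                "ancestral": "0",
                "derived": "1",
            }
        )
    order = np.lexsort((cmap["pos"].to_numpy(), cmap["chrom"].to_numpy()))
    cmap = cmap.iloc[order]
    H = H[:, order]
    samples = _read_samples(samples_path, sample_ids)
    return HaplotypePanel(cmap, H, samples), report


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_vcf(panel: HaplotypePanel, path, meta: dict | None = None) -> None:
    """Write the panel as phased VCF 4.2 (REF = ancestral, ALT = derived)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=csskit\n")
        for key, val in (meta or {}).items():
            fh.write(f"##csskit_{key}={val}\n")
        for chrom in panel.snp_map["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples["sample_id"].astype(str))
            + "\n"
        )
        H = panel.haplotypes
        for j, row in enumerate(panel.snp_map.itertuples(index=False)):
            gts = "\t".join(
                f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(panel.n_samples)
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ancestral}\t"
                f"{row.derived}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_hap_tsv(panel: HaplotypePanel, path) -> None:
    ids = np.repeat(panel.samples["sample_id"].to_numpy(), 2)
    haps = np.tile([0, 1], panel.n_samples)
    df = pd.DataFrame(panel.haplotypes, columns=panel.snp_map["snp_id"])
    df.insert(0, "hap", haps)
    df.insert(0, "sample_id", ids)
    df.to_csv(path, sep="\t", index=False)


def write_map(panel: HaplotypePanel, path) -> None:
    panel.snp_map[MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def write_ancestral(panel: HaplotypePanel, path) -> None:
    panel.snp_map[["snp_id", "ancestral"]].to_csv(path, sep="\t", index=False)


def write_samples(panel: HaplotypePanel, path) -> None:
    panel.samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------

def qc_filter(
    panel: HaplotypePanel, maf_min: float = 0.01, scope_samples=None
) -> tuple[HaplotypePanel, QcReport]:
    """Retain SNPs with minor allele frequency >= ``maf_min`` in scope.

    Frequency is computed over the haplotypes of ``scope_samples`` (default:
    all samples) — the cattle type under analysis. Monomorphic SNPs are
    always removed.
    """
    if not (0 <= maf_min < 0.5):
        raise PanelError("maf_min must be in [0, 0.5)")
    if scope_samples is None:
        scope_samples = panel.sample_ids
    scope_samples = list(scope_samples)
    if not scope_samples:
        raise PanelError("qc_filter scope is empty")
    freq = panel.derived_freq(scope_samples)
    maf = np.minimum(freq, 1.0 - freq)
    polymorphic = (freq > 0) & (freq < 1)
    keep = polymorphic & (maf >= maf_min)
    report = QcReport(
        n_input_snps=panel.n_snps,
        n_retained_snps=int(keep.sum()),
        n_dropped_maf=int((~keep).sum()),
    )
    report.validate()
    return panel.subset_snps(keep), report


def ibs_matrix(panel: HaplotypePanel) -> np.ndarray:
    """Pairwise identity-by-state over samples.

    IBS(i, j) = mean over SNPs of (2 - |dosage_i - dosage_j|) / 2.
    """
    D = panel.dosages().astype(np.float64)
    from scipy.spatial.distance import squareform, pdist

    if panel.n_samples < 2:
        return np.ones((panel.n_samples, panel.n_samples))
    manhattan = squareform(pdist(D, metric="cityblock"))
    ibs = 1.0 - manhattan / (2.0 * panel.n_snps)
    np.fill_diagonal(ibs, 1.0)
    return ibs


def ibs_dedupe(
    panel: HaplotypePanel, ibs_threshold: float = 0.95
) -> tuple[HaplotypePanel, QcReport]:
    """Remove putative duplicate samples by pairwise IBS.

    For every pair at or above the threshold the later sample in input
    order is removed; removed pairs are listed in the report.
    """
    if not (0 < ibs_threshold <= 1):
        raise PanelError("ibs_threshold must be in (0, 1]")
    ibs = ibs_matrix(panel)
    ids = panel.samples["sample_id"].tolist()
    removed: set[int] = set()
    pairs = []
    n = panel.n_samples
    for j in range(n):
        for i in range(j):
            if i in removed or j in removed:
                continue
            if ibs[i, j] >= ibs_threshold:
                removed.add(j)
                pairs.append((ids[i], ids[j], float(ibs[i, j])))
                break
    keep_ids = [s for k, s in enumerate(ids) if k not in removed]
    report = QcReport(
        n_input_snps=panel.n_snps,
        n_retained_snps=panel.n_snps,
        duplicate_pairs=pairs,
    )
    return panel.subset_samples(keep_ids), report


def subsample_per_breed(
    panel: HaplotypePanel, max_per_breed: int, seed: int = 0
) -> HaplotypePanel:
    """Cap each breed at ``max_per_breed`` samples, chosen uniformly at random."""
    if max_per_breed < 1:
        raise PanelError("max_per_breed must be >= 1")
    rng = np.random.default_rng(seed)
    keep = []
    for breed, grp in panel.samples.groupby("breed", sort=False):
        ids = grp["sample_id"].tolist()
        if len(ids) > max_per_breed:
            sel = rng.choice(len(ids), size=max_per_breed, replace=False)
            ids = [ids[k] for k in sorted(sel)]
        keep.extend(ids)
    return panel.subset_samples(keep)
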