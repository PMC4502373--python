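"""Per-SNP constituent selection statistics between two cohorts.

Three statistics are computed between a *candidate* and a *reference*
cohort of phased haplotypes:

* **F_ST** — Weir–Cockerham (1984) theta in its haploid-observation form
  (each haplotype is one allele observation), or optionally the Hudson
  estimator. Symmetric under cohort swap.
* **ΔDAF** — derived-allele-frequency difference, candidate − reference.
* **XP-EHH** — log-ratio of integrated extended haplotype homozygosity
  (iHH) between the cohorts at every core SNP, genome-standardized.
  Population-level EHH is used: all haplotypes of a cohort enter the curve,
  initially partitioned by the core-SNP allele.

ΔDAF and raw XP-EHH negate exactly under orientation swap; F_ST is shared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import HaplotypePanel

DEFAULT_EHH_CUTOFF = 0.05
DEFAULT_EHH_MAX_GAP_BP = 200_000
# Haplotype sharing from within-breed drift can hold pooled EHH above the
# cutoff over chromosome scales; curves are therefore also truncated at a
# maximum physical extension per side, as cross-population EHH scanners
# conventionally do.
DEFAULT_EHH_MAX_EXTEND_BP = 1_000_000


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def daf(panel: HaplotypePanel, cohort_samples) -> np.ndarray:
    """Derived allele frequency per SNP: derived count / (2 × n samples)."""
    cohort_samples = list(cohort_samples)
    if not cohort_samples:
        raise StatsError("cohort is empty")
    return panel.derived_freq(cohort_samples)


def delta_daf(panel: HaplotypePanel, candidate, reference) -> np.ndarray:
    """daf(candidate) − daf(reference); antisymmetric under swap."""
    if set(candidate) & set(reference):
        raise StatsError("candidate and reference cohorts overlap")
    return daf(panel, candidate) - daf(panel, reference)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def fst_per_snp(
    panel: HaplotypePanel, cohortA, cohortB, estimator: str = "wc"
) -> np.ndarray:
    """Two-population per-SNP F_ST on haplotype (allele-level) counts.

    ``estimator`` is ``"wc"`` (Weir–Cockerham theta, haploid ANOVA form) or
    ``"hudson"``. Sites monomorphic across both cohorts are set to 0.
    """
    HA = panel.haplotypes_of(list(cohortA))
    HB = panel.haplotypes_of(list(cohortB))
    n1, n2 = HA.shape[0], HB.shape[0]
    if n1 < 2 or n2 < 2:
        raise StatsError("each cohort needs at least 2 haplotypes")
    p1 = HA.mean(axis=0)
    p2 = HB.mean(axis=0)
    if estimator == "wc":
        return _wc_theta_haploid(p1, p2, n1, n2)
    if estimator == "hudson":
        return _hudson_fst(p1, p2, n1, n2)
    raise StatsError(f"unknown F_ST estimator: {estimator}")


def _wc_theta_haploid(p1, p2, n1, n2) -> np.ndarray:
    """Weir–Cockerham theta via the one-way ANOVA mean squares on alleles.

    With r = 2 populations of n_i sampled alleles and allele frequencies
    p_i: MSB = Σ n_i (p_i − p̄)², MSW = Σ n_i p_i (1 − p_i) / (N − 2),
    n_c = N − (n1² + n2²)/N, and θ = (MSB − MSW) / (MSB + (n_c − 1) MSW).
    """
    N = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / N
    msb = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # /(r-1) with r=2
    msw = (n1 * p1 * (1.0 - p1) + n2 * p2 * (1.0 - p2)) / (N - 2)
    nc = N - (n1 * n1 + n2 * n2) / N
    denom = msb + (nc - 1.0) * msw
    theta = np.zeros_like(pbar, dtype=float)
    ok = denom > 0
    theta[ok] = (msb[ok] - msw[ok]) / denom[ok]
    return theta


def _hudson_fst(p1, p2, n1, n2) -> np.ndarray:
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    out = np.zeros_like(num, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


# ---------------------------------------------------------------------------
# EHH / iHH
# ---------------------------------------------------------------------------

@dataclass
class EhhCurve:
    """EHH decay outward from a core SNP along one side.

    ``distances_bp[0] == 0`` (the core itself); values are non-increasing
    and truncated below the cutoff or at large inter-SNP gaps.
    """

    core_index: int
    side: str  # "upstream" (toward lower pos) or "downstream"
    distances_bp: np.ndarray
    values: np.ndarray


def _homozygosity(groups: np.ndarray) -> float:
    """Σ C(c_k, 2) / C(n, 2) over group counts of n haplotypes."""
    n = groups.size
    if n < 2:
        return 0.0
    _, counts = np.unique(groups, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _ehh_side(H, positions, core, step, init_groups, ehh_cutoff, max_gap_bp,
              max_extend_bp=None):
    """March outward from ``core`` in direction ``step`` (+1/-1).

    Returns (distances, values) starting at distance 0 with the
    homozygosity of the initial grouping. Truncates when EHH drops below
    the cutoff, an inter-SNP gap exceeds ``max_gap_bp``, the extension
    exceeds ``max_extend_bp``, or the chromosome (matrix) end is reached.
    """
    groups = np.asarray(init_groups, dtype=np.int64).copy()
    n = groups.size
    dists = [0.0]
    vals = [_homozygosity(groups)]
    if vals[0] < ehh_cutoff:
        return np.array([0.0]), np.array(vals)
    j = core
    last_pos = positions[core]
    S = H.shape[1]
    width = 0  # bits consumed since last compression
    while True:
        j += step
        if j < 0 or j >= S:
            break
        if max_gap_bp is not None and abs(positions[j] - last_pos) > max_gap_bp:
            break
        if max_extend_bp is not None and \
                abs(positions[j] - positions[core]) > max_extend_bp:
            break
        groups = groups * 2 + H[:, j]
        width += 1
        if width >= 32:
            _, groups = np.unique(groups, return_inverse=True)
            width = 0
        ehh = _homozygosity(groups)
        if ehh < ehh_cutoff:
            break
        dists.append(float(abs(positions[j] - positions[core])))
        vals.append(ehh)
        last_pos = positions[j]
        if ehh == 0.0 or np.unique(groups).size == n:
            # all haplotypes distinct: EHH stays 0 from here on
            break
    return np.array(dists), np.array(vals)


def ehh(
    panel: HaplotypePanel,
    core_snp: int,
    core_allele: int,
    cohort,
    side: str,
    ehh_cutoff: float = DEFAULT_EHH_CUTOFF,
    max_gap_bp: int | None = DEFAULT_EHH_MAX_GAP_BP,
    max_extend_bp: int | None = None,
) -> EhhCurve:
    """Allele-specific EHH curve among carriers of ``core_allele``.

    EHH at the core is 1 by construction and decays as the carriers'
    extended haplotypes differentiate.
    """
    if side not in ("upstream", "downstream"):
        raise StatsError("side must be 'upstream' or 'downstream'")
    H = panel.haplotypes_of(list(cohort))
    chrom = panel.snp_map["chrom"].to_numpy()
    on_c = np.flatnonzero(chrom == chrom[core_snp])
    Hc = H[:, on_c]
    positions = panel.snp_map["pos"].to_numpy()[on_c]
    core_local = int(np.searchsorted(on_c, core_snp))
    carriers = Hc[:, core_local] == core_allele
    if carriers.sum() < 2:
        raise StatsError(
            f"core SNP {core_snp} allele {core_allele}: fewer than 2 carriers"
        )
    Hc = Hc[carriers]
    step = -1 if side == "upstream" else 1
    d, v = _ehh_side(
        Hc, positions, core_local, step,
        np.zeros(Hc.shape[0], dtype=np.int64), ehh_cutoff, max_gap_bp,
        max_extend_bp,
    )
    return EhhCurve(core_index=core_snp, side=side, distances_bp=d, values=v)


def ihh(curve: EhhCurve) -> float:
    """Trapezoidal integral of EHH over physical distance (bp) for one side."""
    if curve.distances_bp.size < 2:
        return 0.0
    return float(np.trapezoid(curve.values, curve.distances_bp))


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------

def _pop_ihh_chrom_python(H, positions, ehh_cutoff, max_gap_bp, max_extend_bp):
    """Population-level two-sided iHH at every core SNP of one chromosome.

    Carriers of both core alleles are combined into a single group (EHH is
    1 at the core by construction, decaying as extended haplotypes
    differentiate), so iHH measures local haplotype structure and is not
    mechanically coupled to the core allele frequency. Reference
    implementation; the compiled kernel below is the production path.
    """
    S = H.shape[1]
    out = np.zeros(S)
    init = np.zeros(H.shape[0], dtype=np.int64)
    for core in range(S):
        total = 0.0
        for step in (-1, 1):
            d, v = _ehh_side(H, positions, core, step, init, ehh_cutoff,
                             max_gap_bp, max_extend_bp)
            if d.size >= 2:
                total += float(np.trapezoid(v, d))
        out[core] = total
    return out


try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _nb_hom(g, denom):
        s = np.sort(g)
        acc = 0.0
        run = 1
        for i in range(1, s.size):
            if s[i] == s[i - 1]:
                run += 1
            else:
                acc += run * (run - 1.0)
                run = 1
        acc += run * (run - 1.0)
        return acc / denom

    @_njit(cache=True)
    def _nb_relabel(g):
        order = np.argsort(g, kind="mergesort")
        out = np.empty_like(g)
        cur = 0
        out[order[0]] = 0
        for k in range(1, g.size):
            if g[order[k]] != g[order[k - 1]]:
                cur += 1
            out[order[k]] = cur
        return out

    @_njit(cache=True)
    def _nb_pop_ihh(H, pos, ehh_cutoff, max_gap_bp, max_extend_bp):
        n, S = H.shape
        out = np.zeros(S)
        denom = n * (n - 1.0)
        if denom <= 0:
            return out
        for core in range(S):
            total = 0.0
            for sdir in range(2):
                step = -1 if sdir == 0 else 1
                g = np.zeros(n, dtype=np.int64)
                h_prev = 1.0
                d_prev = 0.0
                last_pos = pos[core]
                j = core
                width = 0
                while True:
                    j += step
                    if j < 0 or j >= S:
                        break
                    if abs(pos[j] - last_pos) > max_gap_bp:
                        break
                    d = abs(pos[j] - pos[core])
                    if d > max_extend_bp:
                        break
                    for i in range(n):
                        g[i] = g[i] * 2 + H[i, j]
                    width += 1
                    if width >= 32:
                        g = _nb_relabel(g)
                        width = 0
                    h = _nb_hom(g, denom)
                    if h < ehh_cutoff:
                        break
                    total += 0.5 * (h_prev + h) * (d - d_prev)
                    h_prev = h
                    d_prev = float(d)
                    last_pos = pos[j]
                    if h == 0.0:
                        break
            out[core] = total
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


_BIG_BP = np.int64(2**62)


def _pop_ihh_chrom(H, positions, ehh_cutoff, max_gap_bp, max_extend_bp,
                   engine: str = "auto"):
    if engine == "auto" and _HAVE_NUMBA:
        return _nb_pop_ihh(
            np.ascontiguousarray(H, dtype=np.int8),
            np.asarray(positions, dtype=np.int64),
            float(ehh_cutoff),
            np.int64(max_gap_bp) if max_gap_bp is not None else _BIG_BP,
            np.int64(max_extend_bp) if max_extend_bp is not None else _BIG_BP,
        )
    return _pop_ihh_chrom_python(H, positions, ehh_cutoff, max_gap_bp,
                                 max_extend_bp)


@dataclass
class XpehhResult:
    raw: np.ndarray
    std: np.ndarray
    excluded: np.ndarray  # True where either cohort's iHH is 0


def xpehh(
    panel: HaplotypePanel,
    candidate,
    reference,
    ehh_cutoff: float = DEFAULT_EHH_CUTOFF,
    max_gap_bp: int | None = DEFAULT_EHH_MAX_GAP_BP,
    max_extend_bp: int | None = DEFAULT_EHH_MAX_EXTEND_BP,
    engine: str = "auto",
) -> XpehhResult:
    """Cross-population EHH statistic per core SNP.

    raw = ln(iHH_candidate / iHH_reference); standardized to genome-wide
    mean 0 and sd 1 over non-excluded SNPs. SNPs where either iHH is 0 are
    excluded from downstream ranking.
    """
    Hc = panel.haplotypes_of(list(candidate))
    Hr = panel.haplotypes_of(list(reference))
    chrom = panel.snp_map["chrom"].to_numpy()
    pos = panel.snp_map["pos"].to_numpy()
    ihh_c = np.zeros(panel.n_snps)
    ihh_r = np.zeros(panel.n_snps)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        ihh_c[idx] = _pop_ihh_chrom(
            np.ascontiguousarray(Hc[:, idx]), pos[idx], ehh_cutoff,
            max_gap_bp, max_extend_bp, engine)
        ihh_r[idx] = _pop_ihh_chrom(
            np.ascontiguousarray(Hr[:, idx]), pos[idx], ehh_cutoff,
            max_gap_bp, max_extend_bp, engine)
    excluded = (ihh_c <= 0) | (ihh_r <= 0)
    if excluded.all():
        raise StatsError("all SNPs degenerate for XP-EHH")
    raw = np.full(panel.n_snps, np.nan)
    raw[~excluded] = np.log(ihh_c[~excluded] / ihh_r[~excluded])
    std = standardize(raw, excluded)
    return XpehhResult(raw=raw, std=std, excluded=excluded)


def standardize(raw: np.ndarray, excluded: np.ndarray) -> np.ndarray:
    ok = ~excluded
    mu = raw[ok].mean()
    sd = raw[ok].std()
    std = np.full_like(raw, np.nan)
    std[ok] = (raw[ok] - mu) / sd if sd > 0 else 0.0
    return std


# ---------------------------------------------------------------------------
# Bundled constituent computation
# ---------------------------------------------------------------------------

@dataclass
class ConstituentStats:
    """Per-SNP constituent vectors for one candidate/reference orientation."""

    fst: np.ndarray
    ddaf: np.ndarray
    xpehh_raw: np.ndarray
    xpehh_std: np.ndarray
    excluded: np.ndarray
    candidate_id: str
    reference_id: str

    def reversed(self) -> "ConstituentStats":
        """The opposite orientation: F_ST shared, directional stats negated."""
        raw = -self.xpehh_raw
        return ConstituentStats(
            fst=self.fst,
            ddaf=-self.ddaf,
            xpehh_raw=raw,
            xpehh_std=standardize(raw, self.excluded),
            excluded=self.excluded,
            candidate_id=self.reference_id,
            reference_id=self.candidate_id,
        )

    def z_inputs(self) -> list[np.ndarray]:
        """Constituent vectors ordered for rank combination (larger = more
        evidence of selection in the candidate cohort)."""
        return [self.fst, self.ddaf, self.xpehh_raw]


def compute_constituents(
    panel: HaplotypePanel,
    candidate,
    reference,
    candidate_id: str = "candidate",
    reference_id: str = "reference",
    ehh_cutoff: float = DEFAULT_EHH_CUTOFF,
    max_gap_bp: int | None = DEFAULT_EHH_MAX_GAP_BP,
    max_extend_bp: int | None = DEFAULT_EHH_MAX_EXTEND_BP,
    fst_estimator: str = "wc",
) -> ConstituentStats:
    """All three constituent statistics, candidate vs reference."""
    xp = xpehh(panel, candidate, reference, ehh_cutoff, max_gap_bp, max_extend_bp)
    return ConstituentStats(
        fst=fst_per_snp(panel, candidate, reference, estimator=fst_estimator),
        ddaf=delta_daf(panel, candidate, reference),
        xpehh_raw=xp.raw,
        xpehh_std=xp.std,
        excluded=xp.excluded,
        candidate_id=candidate_id,
        reference_id=reference_id,
    )
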