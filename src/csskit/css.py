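"""Composite selection signal: rank combination, smoothing, thresholds.

The composite statistic combines the constituent tests nonparametrically:

1. rank each constituent genome-wide over the n analyzed SNPs (ascending;
   larger statistic = stronger evidence of selection in the candidate
   cohort), ties sharing the mean rank;
2. convert ranks to fractional ranks r' = rank / (n + 1) ∈ (0, 1);
3. z = Φ⁻¹(r');
4. z̄ = mean of the m constituent z-values at each SNP;
5. p = upper-tail probability of z̄ under N(0, 1/m), i.e. SF(z̄ √m);
6. CSS = −log10(p), smoothed by averaging within ±0.5 Mb around each SNP,
   with the top 0.1% (significant) and top 1% (supporting) of smoothed
   scores flagged genome-wide.

Because only ranks enter, CSS is exactly invariant to any strictly
increasing transform of a constituent statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import norm, rankdata

log = logging.getLogger("csskit")

DEFAULT_WINDOW_BP = 500_000
DEFAULT_Q01 = 0.001
DEFAULT_Q1 = 0.01


class CssError(ValueError):
    pass


def fractional_ranks(stat_vector, mask=None) -> np.ndarray:
    """Fractional ranks r' = rank/(n+1) over included entries.

    ``mask`` marks excluded entries (True = excluded); they receive NaN.
    Ties share the mean of their ranks. An all-tied vector degenerates to
    r' = 0.5 everywhere (with a warning).
    """
    x = np.asarray(stat_vector, dtype=float)
    if x.size == 0:
        raise CssError("cannot rank an empty vector")
    if mask is None:
        mask = np.zeros(x.size, dtype=bool)
    mask = np.asarray(mask, bool) | np.isnan(x)
    ok = ~mask
    n = int(ok.sum())
    if n == 0:
        raise CssError("all entries excluded from ranking")
    vals = x[ok]
    if np.all(vals == vals[0]):
        log.warning("degenerate constituent: all %d values identical", n)
    r = np.full(x.size, np.nan)
    r[ok] = rankdata(vals, method="average") / (n + 1)
    return r


def combine_css(z_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Combine per-constituent z-scores into (mean_z, p, css_raw).

    ``z_matrix`` has shape (n_snps, m). p is the one-sided upper-tail
    probability of the mean under N(0, 1/m): p = SF(z̄ √m).
    """
    Z = np.atleast_2d(np.asarray(z_matrix, dtype=float))
    if Z.ndim != 2:
        raise CssError("z_matrix must be 2-D (n_snps, m)")
    m = Z.shape[1]
    if m < 1:
        raise CssError("need at least one constituent")
    if not np.all(np.isfinite(Z)):
        raise CssError("z-scores must be finite")
    mean_z = Z.mean(axis=1)
    p = norm.sf(mean_z * np.sqrt(m))
    return mean_z, p, -np.log10(p)


def smooth_css(css_raw, snp_map: pd.DataFrame, window_bp: int = DEFAULT_WINDOW_BP,
               mask=None) -> np.ndarray:
    """Positional smoothing: mean of css_raw over SNPs within ±window_bp.

    The window is inclusive (|Δpos| ≤ window_bp) and chromosome-bounded;
    the focal SNP is always included. Excluded SNPs (``mask`` True or NaN
    values) contribute nothing and stay NaN.
    """
    x = np.asarray(css_raw, dtype=float)
    chrom = snp_map["chrom"].to_numpy()
    pos = snp_map["pos"].to_numpy()
    if mask is None:
        mask = np.zeros(x.size, dtype=bool)
    mask = np.asarray(mask, bool) | np.isnan(x)
    out = np.full(x.size, np.nan)
    for c in pd.unique(chrom):
        idx = np.flatnonzero((chrom == c) & ~mask)
        if idx.size == 0:
            continue
        p = pos[idx].astype(np.int64)
        v = x[idx]
        csum = np.concatenate([[0.0], np.cumsum(v)])
        lo = np.searchsorted(p, p - window_bp, side="left")
        hi = np.searchsorted(p, p + window_bp, side="right")
        out[idx] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def threshold_flags(css_smoothed, q01: float = DEFAULT_Q01, q1: float = DEFAULT_Q1,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Flag the genome-wide top q01 and top q1 fractions of smoothed CSS.

    Cutoffs are the empirical (1 − q) quantiles (linear interpolation);
    a SNP is flagged when its value is ≥ the cutoff, so top01 ⊆ top1.
    NaN entries are never flagged.
    """
    x = np.asarray(css_smoothed, dtype=float)
    ok = ~np.isnan(x)
    if not ok.any():
        raise CssError("no included SNPs to threshold")
    vals = x[ok]
    if np.all(vals == vals[0]):
        log.warning("degenerate smoothed CSS: all values equal; flagging all")
    cut01 = np.quantile(vals, 1.0 - q01)
    cut1 = np.quantile(vals, 1.0 - q1)
    top01 = ok & (x >= cut01)
    top1 = (ok & (x >= cut1)) | top01
    return top01, top1


@dataclass
class CssTrack:
    """Aligned per-SNP CSS results for one candidate/reference orientation."""

    snp_map: pd.DataFrame
    fractional: dict  # constituent name -> r' vector
    mean_z: np.ndarray
    p_value: np.ndarray
    css_raw: np.ndarray
    css_smoothed: np.ndarray
    top01: np.ndarray
    top1: np.ndarray
    excluded: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.snp_map[["chrom", "pos", "snp_id"]].copy()
        for name, r in self.fractional.items():
            df[f"r_{name}"] = r
        df["mean_z"] = self.mean_z
        df["p_value"] = self.p_value
        df["css_raw"] = self.css_raw
        df["css_smoothed"] = self.css_smoothed
        df["top01"] = self.top01
        df["top1"] = self.top1
        return df


def build_track(
    constituents,
    snp_map: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    q01: float = DEFAULT_Q01,
    q1: float = DEFAULT_Q1,
) -> CssTrack:
    """Full CSS track from a :class:`~csskit.stats.ConstituentStats`.

    SNPs excluded by any constituent (e.g. degenerate XP-EHH cores) are
    excluded from ranking, smoothing and thresholds.
    """
    names = ["fst", "ddaf", "xpehh"]
    vectors = constituents.z_inputs()
    excluded = np.asarray(constituents.excluded, bool).copy()
    for v in vectors:
        excluded |= np.isnan(v)
    n_excl = int(excluded.sum())
    if n_excl:
        log.info("excluding %d SNPs from CSS ranking", n_excl)
    fractional = {
        name: fractional_ranks(v, mask=excluded) for name, v in zip(names, vectors)
    }
    ok = ~excluded
    Z = np.column_stack([ndtri(fractional[name][ok]) for name in names])
    mean_z = np.full(len(snp_map), np.nan)
    p = np.full(len(snp_map), np.nan)
    css_raw = np.full(len(snp_map), np.nan)
    mean_z[ok], p[ok], css_raw[ok] = combine_css(Z)
    smoothed = smooth_css(css_raw, snp_map, window_bp=window_bp, mask=excluded)
    top01, top1 = threshold_flags(smoothed, q01=q01, q1=q1)
    return CssTrack(
        snp_map=snp_map.reset_index(drop=True),
        fractional=fractional,
        mean_z=mean_z,
        p_value=p,
        css_raw=css_raw,
        css_smoothed=smoothed,
        top01=top01,
        top1=top1,
        excluded=excluded,
        metadata={
            "m": len(names),
            "n": int(ok.sum()),
            "window_bp": window_bp,
            "q01": q01,
            "q1": q1,
            "candidate": constituents.candidate_id,
            "reference": constituents.reference_id,
            "smoothing_boundary": "inclusive",
            "quantile_rule": "linear",
        },
    )
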