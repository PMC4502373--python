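"""Synthetic multibreed haplotype panels with divergent selection on stature.

The generator produces the inputs a composite-selection-signal scan needs:
a phased, ancestrally polarized SNP panel across many breeds, and an
FAO-style phenotype table of per-breed, per-country average male/female
wither heights. Its model:

* A common founder pool of haplotypes is built per genome as a mosaic over a
  small set of prototype haplotypes, giving linkage disequilibrium that
  decays over ~Mb scales (what the haplotype-homozygosity statistics need).
* Each breed then evolves as an independent discrete-generation
  Wright–Fisher population seeded from the pool, with recombination under a
  Haldane map at 1 cM/Mb.
* Stature is additive over a handful of trait loci. Breeds belong to a
  tall, short, or neutral group; tall breeds undergo per-generation
  truncation selection upward on the genetic value of stature, short breeds
  downward, neutral breeds drift.
* The ancestral allele at every SNP is the founder-pool major allele, so
  derived-allele frequencies are polarized exactly as a scan expects.

All randomness flows from ``SimConfig.seed``; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import (
    HaplotypePanel,
    write_vcf,
    write_map,
    write_ancestral,
    write_samples,
)

# Baseline biology of the phenotype model (cm). Wither heights of taurine
# cattle centre near 130 cm with ~10 cm sexual dimorphism.
BASELINE_HEIGHT_CM = 130.0
SEX_OFFSET_CM = 5.0  # males +5, females -5 around the breed mean
BREED_BACKGROUND_SD_CM = 2.0  # polygenic background not carried by the panel

# Founder-pool construction.
N_FOUNDER_HAPLOTYPES = 200
N_PROTOTYPES = 24
MOSAIC_SWITCH_PER_BP = 5e-7  # expected mosaic block ~2 Mb
TRAIT_LOCUS_FOUNDER_DAF = 0.45
# The derived allele at a trait locus arose once, on a single ancestral
# haplotype: founder carriers share that origin background over this span,
# so flanking SNPs hitchhike when the locus is swept.
SWEEP_SHARE_BP = 750_000

RECOMB_MORGANS_PER_BP = 1e-8  # 1 cM/Mb


class SimError(ValueError):
    """Raised for invalid simulation configurations."""


def _default_trait_loci() -> list:
    # one 5 cm locus mid-chromosome on each of the first six autosomes;
    # derived alleles alternate between increasing and decreasing stature,
    # so upward sweeps occur in the tall group at +loci and in the short
    # group at -loci (each cohort orientation detects its own loci)
    return [(c, 40_000_000, 5.0 if c % 2 else -5.0) for c in range(1, 7)]


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic multibreed design.

    Defaults emulate a bovine 50K-chip style panel: 29 autosomes totalling
    ~2.5 Gb, ~36k mapped SNPs (~69 kb spacing), 48 breeds of 12 diploid
    samples each, and truncation selection keeping the top/bottom 20% for
    30 generations at six 5-cm trait loci.
    """

    seed: int = 0
    n_chromosomes: int = 29
    chrom_length_bp: int = 86_000_000
    n_snps_per_chrom: int = 1_250
    n_breeds: int = 48
    samples_per_breed: int = 12
    n_generations_drift: int = 30
    effective_size_per_breed: int = 50
    trait_loci: list = field(default_factory=_default_trait_loci)
    selection_differential: float = 0.20
    n_countries_per_breed: int = 3
    phenotype_noise_sd_cm: float = 1.5

    def validate(self) -> None:
        positive = [
            ("n_chromosomes", self.n_chromosomes),
            ("chrom_length_bp", self.chrom_length_bp),
            ("n_snps_per_chrom", self.n_snps_per_chrom),
            ("n_breeds", self.n_breeds),
            ("samples_per_breed", self.samples_per_breed),
            ("effective_size_per_breed", self.effective_size_per_breed),
            ("n_countries_per_breed", self.n_countries_per_breed),
        ]
        for name, val in positive:
            if val <= 0:
                raise SimError(f"{name} must be positive (got {val})")
        if self.samples_per_breed < 2:
            raise SimError("samples_per_breed must be >= 2")
        if self.samples_per_breed > self.effective_size_per_breed:
            raise SimError("samples_per_breed cannot exceed effective size")
        if self.n_generations_drift < 0:
            raise SimError("n_generations_drift must be >= 0")
        if not (0 <= self.selection_differential <= 1):
            raise SimError("selection_differential must be in [0, 1]")
        if self.phenotype_noise_sd_cm < 0:
            raise SimError("phenotype_noise_sd_cm must be >= 0")
        for chrom, pos, _ in self.trait_loci:
            if not (1 <= chrom <= self.n_chromosomes):
                raise SimError(f"trait locus chromosome {chrom} off the map")
            if not (1 <= pos <= self.chrom_length_bp):
                raise SimError(f"trait locus position {pos} off the chromosome")


@dataclass
class SimTruth:
    """Ground truth recorded by the generator for downstream validation."""

    trait_loci: pd.DataFrame  # chrom, pos, effect_cm, snp_index, snp_id
    breed_groups: dict  # breed -> tall | short | neutral
    breed_daf: pd.DataFrame  # breed, group, snp_id, chrom, pos, daf
    breed_genetic_mean_cm: dict  # breed -> realized mean stature

    def group_daf_contrast(self) -> pd.DataFrame:
        """Mean derived-allele-frequency contrast (tall − short) per locus."""
        d = self.breed_daf
        tall = d[d["group"] == "tall"].groupby("snp_id")["daf"].mean()
        short = d[d["group"] == "short"].groupby("snp_id")["daf"].mean()
        out = (tall - short).rename("daf_contrast").reset_index()
        return out.merge(
            self.trait_loci[["snp_id", "chrom", "pos", "effect_cm"]], on="snp_id"
        )

    def to_json(self, path) -> None:
        payload = {
            "trait_loci": self.trait_loci.to_dict(orient="records"),
            "breed_groups": self.breed_groups,
            "breed_daf": self.breed_daf.to_dict(orient="records"),
            "breed_genetic_mean_cm": self.breed_genetic_mean_cm,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# Founder pool
# ---------------------------------------------------------------------------

def _unique_sorted_positions(rng, n, length) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 8))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _build_founders(config: SimConfig, rng):
    """Mosaic founder pool; returns (snp_map frame, pool matrix, locus indices)."""
    chroms, positions = [], []
    for c in range(1, config.n_chromosomes + 1):
        pos = _unique_sorted_positions(rng, config.n_snps_per_chrom, config.chrom_length_bp)
        chroms.append(np.full(len(pos), c))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    S = len(pos)

    # snap each trait locus to the nearest mapped SNP on its chromosome
    locus_idx = []
    for c, p, _ in config.trait_loci:
        on_c = np.flatnonzero(chrom == c)
        locus_idx.append(int(on_c[np.argmin(np.abs(pos[on_c] - p))]))
    locus_idx = np.array(locus_idx, dtype=int)

    # Chip-ascertained SNPs have a flat-ish intermediate MAF spectrum, not
    # the U-shaped spectrum of sequencing data.
    freq = np.clip(rng.beta(1.5, 1.5, size=S), 0.05, 0.95)
    protos = (rng.random((N_PROTOTYPES, S)) < freq).astype(np.int8)
    # Trait loci: the derived allele appears on a fixed fraction of
    # prototypes (so selection has fuel) and those carrier prototypes share
    # the origin prototype's local haplotype, emulating a mutation that
    # arose once and lets flanking SNPs hitchhike under selection.
    k_derived = int(round(TRAIT_LOCUS_FOUNDER_DAF * N_PROTOTYPES))
    for li in locus_idx:
        carriers = rng.choice(N_PROTOTYPES, size=k_derived, replace=False)
        origin = carriers[0]
        near = (chrom == chrom[li]) & (np.abs(pos - pos[li]) <= SWEEP_SHARE_BP)
        protos[np.ix_(carriers, np.flatnonzero(near))] = protos[origin, near]
        protos[:, li] = 0
        protos[carriers, li] = 1

    # mosaic copying: switch prototype with distance-dependent probability
    gap = np.diff(pos).astype(float)
    gap[np.diff(chrom) != 0] = np.inf  # always re-draw at chromosome starts
    q = np.empty(S)
    q[0] = 1.0
    q[1:] = 1.0 - np.exp(-gap * MOSAIC_SWITCH_PER_BP)
    B = rng.random((N_FOUNDER_HAPLOTYPES, S)) < q[None, :]
    B[:, 0] = True
    cols = np.arange(S)
    switch_col = np.where(B, cols[None, :], -1)
    last_switch = np.maximum.accumulate(switch_col, axis=1)
    draw = rng.integers(0, N_PROTOTYPES, size=(N_FOUNDER_HAPLOTYPES, S))
    path = draw[np.arange(N_FOUNDER_HAPLOTYPES)[:, None], last_switch]
    pool = protos[path, cols[None, :]]

    # polarize: ancestral = founder-pool major allele
    flip = pool.mean(axis=0) > 0.5
    pool[:, flip] = 1 - pool[:, flip]

    bases = np.array(list("ACGT"))
    anc_i = rng.integers(0, 4, size=S)
    der_i = (anc_i + rng.integers(1, 4, size=S)) % 4
    snp_map = pd.DataFrame(
        {
            "chrom": chrom.astype(int),
            "pos": pos.astype(int),
            "snp_id": [f"snp{c}_{p}" for c, p in zip(chrom, pos)],
            "ancestral": bases[anc_i],
            "derived": bases[der_i],
        }
    )
    return snp_map, pool.astype(np.int8), locus_idx


# ---------------------------------------------------------------------------
# Wright–Fisher per breed
# ---------------------------------------------------------------------------

def _crossover_probs(snp_map: pd.DataFrame) -> np.ndarray:
    """Per-interval probability that a gamete switches parental haplotype.

    Haldane map: P(odd crossovers in d Morgans) = (1 - exp(-2 d)) / 2; the
    first SNP of each chromosome restarts with probability 1/2 (independent
    chromosomes).
    """
    pos = snp_map["pos"].to_numpy(float)
    chrom = snp_map["chrom"].to_numpy()
    d = np.diff(pos) * RECOMB_MORGANS_PER_BP
    p = 0.5 * (1.0 - np.exp(-2.0 * d))
    p = np.concatenate([[0.5], p])
    p[np.concatenate([[True], np.diff(chrom) != 0])] = 0.5
    return p


def _gametes(pop: np.ndarray, parents: np.ndarray, xover_p: np.ndarray, rng):
    """One gamete per entry of ``parents`` (diploid indices into pop)."""
    n, S = len(parents), pop.shape[1]
    B = rng.random((n, S)) < xover_p[None, :]
    sel = (np.cumsum(B, axis=1) & 1).astype(bool)
    hapA = pop[2 * parents]
    hapB = pop[2 * parents + 1]
    return np.where(sel, hapA, hapB)


def _evolve_breed(pool, config, group, locus_idx, effects, xover_p, rng):
    N = config.effective_size_per_breed
    rows = rng.integers(0, pool.shape[0], size=2 * N)
    pop = pool[rows].copy()
    k = max(2, int(round(config.selection_differential * N)))
    for _ in range(config.n_generations_drift):
        if group in ("tall", "short") and config.selection_differential > 0:
            dosage = pop[0::2][:, locus_idx] + pop[1::2][:, locus_idx]
            g = dosage.astype(float) @ effects
            order = np.argsort(g, kind="stable")
            parents = order[-k:] if group == "tall" else order[:k]
        else:
            parents = np.arange(N)
        mothers = rng.choice(parents, size=N)
        fathers = rng.choice(parents, size=N)
        new = np.empty_like(pop)
        new[0::2] = _gametes(pop, mothers, xover_p, rng)
        new[1::2] = _gametes(pop, fathers, xover_p, rng)
        pop = new
    return pop


def breed_group_sizes(n_breeds: int) -> tuple[int, int]:
    """Tall/short group sizes: one quarter of breeds each (>= 1)."""
    k = max(1, n_breeds // 4)
    return k, k


def simulate_panel(config: SimConfig) -> tuple[HaplotypePanel, SimTruth]:
    """Simulate the multibreed phased panel and its ground truth."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    snp_map, pool, locus_idx = _build_founders(config, rng)
    effects = np.array([e for _, _, e in config.trait_loci], dtype=float)
    xover_p = _crossover_probs(snp_map)

    n_tall, n_short = breed_group_sizes(config.n_breeds)
    groups = {}
    hap_blocks, sample_rows = [], []
    genetic_mean = {}
    daf_records = []
    background = rng.normal(0.0, BREED_BACKGROUND_SD_CM, size=config.n_breeds)
    for b in range(config.n_breeds):
        breed = f"B{b + 1:02d}"
        if b < n_tall:
            group = "tall"
        elif b >= config.n_breeds - n_short:
            group = "short"
        else:
            group = "neutral"
        groups[breed] = group
        pop = _evolve_breed(pool, config, group, locus_idx, effects, xover_p, rng)
        pick = np.sort(
            rng.choice(config.effective_size_per_breed,
                       size=config.samples_per_breed, replace=False)
        )
        rows = np.repeat(2 * pick, 2) + np.tile([0, 1], len(pick))
        H = pop[rows]
        hap_blocks.append(H)
        for s in range(config.samples_per_breed):
            sample_rows.append((f"{breed}_s{s + 1:02d}", breed, "synthetic"))
        dosage = H[0::2][:, locus_idx] + H[1::2][:, locus_idx]
        g = dosage.astype(float) @ effects
        genetic_mean[breed] = float(BASELINE_HEIGHT_CM + background[b] + g.mean())
        daf = H[:, locus_idx].mean(axis=0)
        for li, f in zip(locus_idx, daf):
            daf_records.append(
                (breed, group, snp_map["snp_id"].iloc[li],
                 int(snp_map["chrom"].iloc[li]), int(snp_map["pos"].iloc[li]),
                 float(f))
            )

    panel = HaplotypePanel(
        snp_map=snp_map,
        haplotypes=np.vstack(hap_blocks),
        samples=pd.DataFrame(sample_rows, columns=["sample_id", "breed", "cattle_type"]),
    )
    loci = snp_map.iloc[locus_idx][["chrom", "pos", "snp_id"]].reset_index(drop=True)
    loci["effect_cm"] = effects
    loci["snp_index"] = locus_idx
    truth = SimTruth(
        trait_loci=loci,
        breed_groups=groups,
        breed_daf=pd.DataFrame(
            daf_records, columns=["breed", "group", "snp_id", "chrom", "pos", "daf"]
        ),
        breed_genetic_mean_cm=genetic_mean,
    )
    return panel, truth


def calibration_config(seed: int = 0) -> SimConfig:
    """Desk-scale strong-selection study conditions.

    Four 100 Mb chromosomes (~10k mapped SNPs at chip-like 40 kb spacing),
    32 breeds of 6 samples (8 tall, 8 short, 16 neutral), truncation
    keeping the top/bottom 20% for 30 generations, and two divergently
    selected 5 cm loci of opposite effect sign (one detectable per cohort
    orientation).
    """
    return SimConfig(
        seed=seed,
        n_chromosomes=4,
        chrom_length_bp=100_000_000,
        n_snps_per_chrom=2500,
        n_breeds=32,
        samples_per_breed=6,
        n_generations_drift=30,
        effective_size_per_breed=50,
        trait_loci=[(1, 50_000_000, 5.0), (2, 50_000_000, -5.0)],
    )


def neutral_config(seed: int = 0, n_chromosomes: int = 5) -> SimConfig:
    """The calibration conditions with selection switched off (no trait
    loci, no truncation); one extra chromosome keeps ~10k SNPs after QC."""
    cfg = calibration_config(seed)
    cfg.n_chromosomes = n_chromosomes
    cfg.selection_differential = 0.0
    cfg.trait_loci = []
    return cfg


# ---------------------------------------------------------------------------
# FAO-style phenotype table
# ---------------------------------------------------------------------------

def simulate_phenotypes(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Country-replicated breed stature table, one row per (breed, country).

    male_cm / female_cm = breed genetic mean ± sex offset + N(0, noise sd).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    rows = []
    for breed in sorted(truth.breed_genetic_mean_cm):
        mean = truth.breed_genetic_mean_cm[breed]
        for c in range(1, config.n_countries_per_breed + 1):
            noise = rng.normal(0.0, config.phenotype_noise_sd_cm, size=2) \
                if config.phenotype_noise_sd_cm > 0 else np.zeros(2)
            rows.append(
                (breed, f"C{c:02d}",
                 mean + SEX_OFFSET_CM + noise[0],
                 mean - SEX_OFFSET_CM + noise[1])
            )
    return pd.DataFrame(rows, columns=["breed", "country", "male_cm", "female_cm"])


# ---------------------------------------------------------------------------
# File bundle
# ---------------------------------------------------------------------------

def write_bundle(panel, truth, phenotypes, outdir, config=None) -> dict:
    """Write VCF + map + ancestral + samples + phenotypes + truth to a directory."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "panel.vcf"),
        "map": os.path.join(outdir, "snp_map.tsv"),
        "ancestral": os.path.join(outdir, "ancestral.tsv"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "phenotypes": os.path.join(outdir, "phenotypes.csv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    meta = {"seed": config.seed} if config is not None else {}
    write_vcf(panel, paths["vcf"], meta=meta)
    write_map(panel, paths["map"])
    write_ancestral(panel, paths["ancestral"])
    write_samples(panel, paths["samples"])
    phenotypes.to_csv(paths["phenotypes"], index=False)
    truth.to_json(paths["truth"])
    if config is not None:
        cfg_path = os.path.join(outdir, "sim_config.json")
        with open(cfg_path, "w") as fh:
            json.dump(asdict(config), fh, indent=2)
        paths["config"] = cfg_path
    return paths
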