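"""Synthetic replication databases and two-population haplotype panels.

Two generators provide ground-truth-known stand-ins for the inputs the
analysis expects:

* ``gen_replication_database`` emulates a curated discovery/replication
  database: diseases, European discovery GWAS with genome-wide
  significant SNPs, and replication attempts in a second ancestry.  A
  fraction ``pi_share`` of associations have their causal effect
  present in the replication population; for those, the replication
  z-score is drawn around the same non-centrality the analytic power
  calculation uses, so simulated and analytic power agree by
  construction.  Non-shared associations behave as true OR = 1 nulls
  in the replication population.

* ``gen_two_pop_haplotypes`` emulates two phased reference panels
  (HapMap-style, e.g. a European and an East Asian panel) for a region
  of >= 650 SNPs around a focal SNP.  A founder-mosaic pool creates
  local LD; two copies of the pool drift apart by Wright-Fisher
  haplotype resampling for a tunable number of generations, so
  allele-frequency and LD divergence grow with drift time.

All randomness flows from one top-level seed; sub-streams are spawned
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ld_divergence import HaplotypePanel
from .power_calc import log_or_standard_error, noncentrality
from .replication_db import TableSet

__all__ = [
    "DbSimConfig",
    "HapSimConfig",
    "TwoPopPanels",
    "gen_replication_database",
    "gen_two_pop_haplotypes",
    "gen_targeted_drift_pair",
    "write_database",
]


@dataclass(frozen=True)
class DbSimConfig:
    """Configuration for the synthetic replication database.

    Defaults emulate the scale of a multi-disease curated database:
    28 diseases with a handful of genome-wide significant SNPs each and
    1-3 replication attempts per SNP in an East Asian-like ancestry,
    with replication sample sizes small enough that per-attempt power
    is spread well below 1 (averaging roughly 0.6).

    pi_share    : probability an association's causal effect exists in
                  the replication population (ground truth).
    or_log_mean, or_log_sd : the discovery |log OR| is |N(mean, sd)|,
                  centered near log(1.2), the typical common-variant
                  effect size.
    maf_range   : discovery-population MAF drawn uniformly here.
    raf_jitter_sd : sd of the Gaussian perturbation applied to the
                  discovery MAF to obtain the replication-population
                  risk-allele frequency.
    winners_curse : when True, the reported discovery OR is resampled
                  conditional on discovery-stage significance,
                  inflating it; off by default (discovery ORs are
                  treated as taken from replication stages).
    """

    n_diseases: int = 28
    assoc_per_disease: int = 5
    attempts_range: tuple[int, int] = (1, 3)
    pi_share: float = 0.8
    or_log_mean: float = 0.182
    or_log_sd: float = 0.12
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_cases_range: tuple[int, int] = (300, 3000)
    n_controls_range: tuple[int, int] = (300, 3000)
    raf_jitter_sd: float = 0.05
    replication_ancestry: str = "EastAsian"
    alpha: float = 0.05
    winners_curse: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.pi_share <= 1.0:
            raise ValueError("pi_share must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("n_diseases", "assoc_per_disease"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("attempts_range", "n_cases_range", "n_controls_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) pair")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class HapSimConfig:
    """Configuration for the two-population haplotype generator.

    Defaults emulate a pair of HapMap-like panels around a focal SNP:
    650 SNPs (enough for the full +/-300-SNP scan with 50-SNP windows),
    around 60 diploid individuals per population, and drift chosen so
    that expected per-SNP F_ST of about 0.077 matches typical
    European/East Asian divergence: F = 1 - (1 - 1/(2N))^g with N = 500
    and g = 80.

    n_founders  : founder haplotypes behind the mosaic pool; small
                  values give stronger baseline LD.
    recomb_prob : per-adjacent-SNP-pair probability that a mosaic
                  switches founder template; controls LD decay.
    maf_floor   : founder allele frequencies are uniform on
                  (maf_floor, 1 - maf_floor); drifted/sampled SNPs may
                  still end up monomorphic and are flagged.
    """

    n_snps: int = 650
    n_founders: int = 16
    n_hap_pool: int = 1000
    n_per_pop: int = 60
    drift_generations: int = 80
    pop_size: int = 500
    recomb_prob: float = 0.03
    maf_floor: float = 0.05
    mean_spacing_bp: int = 840
    chrom: str = "1"
    pop_names: tuple[str, str] = ("EUR", "EAS")
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 2:
            raise ValueError("n_snps must be at least 2")
        if not 0.0 <= self.recomb_prob <= 1.0:
            raise ValueError("recomb_prob must lie in [0, 1]")
        if not 0.0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in (0, 0.5)")
        for name in ("n_founders", "n_hap_pool", "n_per_pop", "pop_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.drift_generations < 0:
            raise ValueError("drift_generations must be non-negative")


@dataclass
class TwoPopPanels:
    """Output of the haplotype generator, with ground truth attached."""

    panel1: HaplotypePanel
    panel2: HaplotypePanel
    founder_freqs: np.ndarray          # target '1'-allele frequencies
    base_pool_freqs: np.ndarray        # realized base-pool frequencies
    pool_freqs: dict[str, np.ndarray]  # post-drift full-pool frequencies
    config: HapSimConfig
    seed: int


# ---------------------------------------------------------------------------
# Replication database


def _draw_significant_p(rng, size):
    """Discovery p-values passing even the imputation threshold (5e-8)."""
    return 10.0 ** rng.uniform(-15.0, -9.0, size=size)


def _winners_curse_or(rng, beta_true, se, p_threshold):
    """Reported |log OR| conditional on discovery significance."""
    z_crit = norm.isf(p_threshold / 2.0)
    out = np.empty_like(beta_true)
    for i, (b, s) in enumerate(zip(beta_true, se)):
        while True:
            draw = rng.normal(b, s)
            if abs(draw) / s > z_crit:
                out[i] = abs(draw)
                break
    return out


def gen_replication_database(config: DbSimConfig) -> TableSet:
    """Generate (studies, associations, attempts) with known sharing truth.

    The associations table carries an extra ``shared_truth`` column
    (True when the causal effect exists in the replication population).
    Every discovery record passes the curation thresholds by
    construction: p < 5e-8, outside the MHC, not sex-specific, and
    positions spaced 500 kb apart so region pruning keeps all of them.
    """
    rng = np.random.default_rng(config.seed)
    streams = rng.spawn(4)
    rng_assoc, rng_attempt, rng_study, rng_wc = streams

    studies, associations, attempts = [], [], []
    snp_counter = 0
    max_attempts = config.attempts_range[1]
    alleles = np.array(list("ACGT"))

    for d in range(config.n_diseases):
        disease = f"disease_{d:02d}"
        disc_id = f"GWAS_{disease}_EUR"
        studies.append({
            "study_id": disc_id,
            "disease": disease,
            "ancestry": "European",
            "year": int(rng_study.integers(2006, 2013)),
            # totals straddle the 10,000-individual small/large split
            "n_gwas_stage": int(rng_study.integers(2_000, 8_000)),
            "n_replication_stage": int(rng_study.integers(2_000, 8_000)),
            "uses_imputation": bool(rng_study.integers(0, 2)),
            "genomic_control_lambda": round(
                float(rng_study.uniform(1.0, 1.1)), 3),
        })
        rep_ids = []
        for r in range(max_attempts):
            rep_id = f"GWAS_{disease}_{config.replication_ancestry}_{r}"
            rep_ids.append(rep_id)
            studies.append({
                "study_id": rep_id,
                "disease": disease,
                "ancestry": config.replication_ancestry,
                "year": int(rng_study.integers(2009, 2013)),
                "n_gwas_stage": int(rng_study.integers(600, 6_000)),
                "n_replication_stage": int(rng_study.integers(600, 6_000)),
                "uses_imputation": bool(rng_study.integers(0, 2)),
                "genomic_control_lambda": round(
                    float(rng_study.uniform(1.0, 1.1)), 3),
            })

        for a in range(config.assoc_per_disease):
            snp_id = f"rs{900_000 + snp_counter}"
            snp_counter += 1
            # chromosome 6 avoided entirely so no SNP falls in the MHC
            chrom = str(int(rng_assoc.choice(
                [c for c in range(1, 23) if c != 6])))
            pos = int(10_000_000 + a * 500_000
                      + rng_assoc.integers(0, 100_000))
            maf = float(rng_assoc.uniform(*config.maf_range))
            beta = abs(rng_assoc.normal(config.or_log_mean, config.or_log_sd))
            beta = max(beta, 1e-6)
            shared = bool(rng_assoc.random() < config.pi_share)
            risk, other = rng_assoc.choice(alleles, size=2, replace=False)
            beta_reported = beta
            if config.winners_curse:
                n_disc = 5_000
                se_disc = float(log_or_standard_error(maf, np.exp(beta),
                                                      n_disc, n_disc))
                beta_reported = float(_winners_curse_or(
                    rng_wc, np.array([beta]), np.array([se_disc]), 5e-8)[0])
            associations.append({
                "snp_id": snp_id,
                "chrom": chrom,
                "pos_bp": pos,
                "disease": disease,
                "discovery_study_id": disc_id,
                "risk_allele": str(risk),
                "other_allele": str(other),
                "or_discovery": float(np.exp(beta_reported)),
                "log_or": float(beta_reported),
                "p_discovery": float(_draw_significant_p(rng_assoc, 1)[0]),
                "maf_discovery_pop": maf,
                "sex_specific": False,
                "region_id": None,
                "shared_truth": shared,
            })
            n_att = int(rng_attempt.integers(config.attempts_range[0],
                                             config.attempts_range[1] + 1))
            for r in range(n_att):
                raf = float(np.clip(
                    maf + rng_attempt.normal(0.0, config.raf_jitter_sd),
                    0.02, 0.98))
                n_cases = int(rng_attempt.integers(*config.n_cases_range))
                n_controls = int(rng_attempt.integers(*config.n_controls_range))
                # same non-centrality as the analytic power calculation
                ncp = float(noncentrality(np.exp(beta), raf,
                                          n_cases, n_controls))
                z = rng_attempt.normal(ncp if shared else 0.0, 1.0)
                se = float(log_or_standard_error(raf, np.exp(beta),
                                                 n_cases, n_controls))
                beta_hat = z * se
                p_rep = float(max(2.0 * norm.sf(abs(z)), 1e-300))
                attempts.append({
                    "snp_id": snp_id,
                    "replication_study_id": rep_ids[r],
                    "ancestry": config.replication_ancestry,
                    "or_replication": float(np.exp(beta_hat)),
                    "p_replication": p_rep,
                    "n_cases": n_cases,
                    "n_controls": n_controls,
                    "raf_replication_pop": raf,
                    "allele_shift_flag": bool((raf > 0.5) != (maf > 0.5)),
                    "power": None,
                    "success": bool(z > 0 and p_rep < config.alpha),
                })

    studies = pd.DataFrame(studies)
    associations = pd.DataFrame(associations)
    attempts = pd.DataFrame(attempts)
    for frame in (studies, associations, attempts):
        frame.attrs["seed"] = config.seed
    return TableSet(studies, associations, attempts)


def write_database(tables: TableSet, outdir) -> dict[str, str]:
    """Write the three TSVs into ``outdir``; returns their paths."""
    from pathlib import Path

    from .replication_db import write_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = tables.studies.attrs.get("seed")
    comment = f"transrep synthetic database; seed={seed}"
    paths = {}
    for name, frame in (("studies", tables.studies),
                        ("associations", tables.associations),
                        ("attempts", tables.attempts)):
        path = outdir / f"{name}.tsv"
        write_table(frame, path, header_comment=comment)
        paths[name] = str(path)
    return paths


# ---------------------------------------------------------------------------
# Two-population haplotypes


def _founder_mosaic_pool(rng, config: HapSimConfig) -> tuple[np.ndarray,
                                                             np.ndarray]:
    """Base haplotype pool as Li-Stephens-style mosaics of founders."""
    n, s, k = config.n_hap_pool, config.n_snps, config.n_founders
    freqs = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=s)
    founders = (rng.random((k, s)) < freqs).astype(np.int8)
    draws = rng.integers(0, k, size=(n, s))
    switch = rng.random((n, s)) < config.recomb_prob
    switch[:, 0] = True
    pos = np.arange(s)
    seg_start = np.maximum.accumulate(np.where(switch, pos, 0), axis=1)
    founder_path = np.take_along_axis(draws, seg_start, axis=1)
    pool = founders[founder_path, pos[None, :]]
    return pool, freqs


def _wright_fisher_drift(rng, pool: np.ndarray, generations: int,
                         pop_size: int) -> np.ndarray:
    """Resample whole haplotypes for ``generations`` at size 2N."""
    current = pool
    n_haps = 2 * pop_size
    for _ in range(generations):
        idx = rng.integers(0, current.shape[0], size=n_haps)
        current = current[idx]
    return current


def _sample_panel(rng, pool: np.ndarray, n_haps: int) -> np.ndarray:
    replace = n_haps > pool.shape[0]
    idx = rng.choice(pool.shape[0], size=n_haps, replace=replace)
    return pool[idx]


def gen_two_pop_haplotypes(config: HapSimConfig) -> TwoPopPanels:
    """Generate two drifted haplotype panels from a common founder pool.

    A shared base pool is built by founder-mosaic copying; two
    independent copies are evolved by ``drift_generations`` of
    Wright-Fisher haplotype resampling at population size ``pop_size``
    diploids (2N haplotypes); 2 * ``n_per_pop`` haplotypes per
    population are then sampled (without replacement when possible).
    SNPs that drift to fixation are retained and flagged monomorphic
    on the panels.
    """
    rng = np.random.default_rng(config.seed)
    rng_pool, rng_pop1, rng_pop2, rng_pos = rng.spawn(4)

    pool, founder_freqs = _founder_mosaic_pool(rng_pool, config)
    spacing = rng_pos.geometric(1.0 / config.mean_spacing_bp,
                                size=config.n_snps)
    positions = 1_000_000 + np.cumsum(spacing)
    snp_ids = [f"snp_{j:04d}" for j in range(config.n_snps)]

    panels = []
    pool_freqs = {}
    for pop_name, pop_rng in ((config.pop_names[0], rng_pop1),
                              (config.pop_names[1], rng_pop2)):
        drifted = _wright_fisher_drift(pop_rng, pool,
                                       config.drift_generations,
                                       config.pop_size)
        pool_freqs[pop_name] = drifted.mean(axis=0)
        haps = _sample_panel(pop_rng, drifted, 2 * config.n_per_pop)
        panels.append(HaplotypePanel(
            sample_ids=[f"{pop_name}_{i:04d}"
                        for i in range(config.n_per_pop)],
            population=pop_name,
            alleles=haps,
            snp_ids=snp_ids,
            chrom=config.chrom,
            pos_bp=positions,
        ))
    return TwoPopPanels(
        panel1=panels[0],
        panel2=panels[1],
        founder_freqs=founder_freqs,
        base_pool_freqs=pool.mean(axis=0),
        pool_freqs=pool_freqs,
        config=config,
        seed=config.seed,
    )


def gen_targeted_drift_pair(config: HapSimConfig, block: slice,
                            extra_generations: int) -> TwoPopPanels:
    """Two-population panels whose divergence is concentrated in one block.

    Both populations drift apart by ``config.drift_generations`` across
    the whole region; the second population then experiences
    ``extra_generations`` of additional Wright-Fisher resampling whose
    effect is restricted to the SNP columns in ``block``.  This mimics a
    locally elevated LD/frequency divergence around a focal SNP with
    genome-typical divergence in the flanks.
    """
    rng = np.random.default_rng(config.seed)
    rng_pool, rng_pop1, rng_pop2, rng_extra, rng_pos = rng.spawn(5)

    pool, founder_freqs = _founder_mosaic_pool(rng_pool, config)
    spacing = rng_pos.geometric(1.0 / config.mean_spacing_bp,
                                size=config.n_snps)
    positions = 1_000_000 + np.cumsum(spacing)
    snp_ids = [f"snp_{j:04d}" for j in range(config.n_snps)]

    drift1 = _wright_fisher_drift(rng_pop1, pool, config.drift_generations,
                                  config.pop_size)
    drift2 = _wright_fisher_drift(rng_pop2, pool, config.drift_generations,
                                  config.pop_size)
    # local extra drift: whole-haplotype resampling applied to the block
    # columns only, decoupling the block from its flanks in population 2
    n_haps = 2 * config.pop_size
    local = drift2
    if extra_generations > 0 and local.shape[0] != n_haps:
        # bring the pool to 2N with one whole-region resample first
        local = local[rng_extra.integers(0, local.shape[0], size=n_haps)]
    for _ in range(extra_generations):
        idx = rng_extra.integers(0, n_haps, size=n_haps)
        local = local.copy()
        local[:, block] = local[idx][:, block]
    drift2 = local

    panels = []
    pool_freqs = {}
    for pop_name, pop_rng, drifted in ((config.pop_names[0], rng_pop1, drift1),
                                       (config.pop_names[1], rng_pop2, drift2)):
        pool_freqs[pop_name] = drifted.mean(axis=0)
        haps = _sample_panel(pop_rng, drifted, 2 * config.n_per_pop)
        panels.append(HaplotypePanel(
            sample_ids=[f"{pop_name}_{i:04d}"
                        for i in range(config.n_per_pop)],
            population=pop_name,
            alleles=haps,
            snp_ids=snp_ids,
            chrom=config.chrom,
            pos_bp=positions,
        ))
    return TwoPopPanels(
        panel1=panels[0],
        panel2=panels[1],
        founder_freqs=founder_freqs,
        base_pool_freqs=pool.mean(axis=0),
        pool_freqs=pool_freqs,
        config=config,
        seed=config.seed,
    )
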