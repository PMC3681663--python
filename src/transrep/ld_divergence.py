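"""Regional LD and heterozygosity divergence between two population panels.

The varLD-style score quantifies how different the local linkage
disequilibrium structure of a SNP window is between two populations.
For each population a matrix of pairwise signed r2 values
(sign(r) * r^2 from the haplotype allele correlation r) is built over
the window's SNPs; the raw score is the sum of absolute differences
between the two matrices' rank-ordered eigenvalues.  Identical LD
structure gives a score of 0; the score grows as the correlation
structures diverge.

Scans slide a 50-SNP window in 5-SNP steps from 300 SNPs upstream to
300 SNPs downstream of a focal (disease-associated) SNP - 121 windows
on a fully flanked region - scoring each window for the varLD raw score
and for the difference in mean expected heterozygosity 2p(1-p).
Empirical significance comes from permuting population labels across
diploid individuals.  A MAF-matched background sampler supports
comparisons against genome-wide expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HaplotypePanel",
    "WindowScore",
    "signed_r2_matrix",
    "varld_raw_score",
    "heterozygosity",
    "sliding_window_scan",
    "permutation_pvalue",
    "maf_matched_background",
    "cumulative_envelope",
    "group_window_comparison",
    "write_vcf",
    "write_populations",
    "read_vcf",
]

MISSING = -1


@dataclass
class HaplotypePanel:
    """Phased haplotypes for one population.

    ``alleles`` has shape (2 * n_individuals, n_snps) with entries in
    {0, 1} (-1 for missing); rows 2i and 2i+1 are the two haplotypes of
    individual i.  SNPs are ordered by strictly increasing position.
    """

    sample_ids: list[str]
    population: str
    alleles: np.ndarray
    snp_ids: list[str]
    chrom: str
    pos_bp: np.ndarray
    monomorphic: np.ndarray = field(init=False)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (haplotypes x SNPs) matrix")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("expected two haplotype rows per individual")
        if self.alleles.shape[1] != len(self.snp_ids):
            raise ValueError("allele columns must match snp_ids")
        if np.any(np.diff(self.pos_bp) <= 0):
            raise ValueError("SNP positions must be strictly increasing")
        freq = self.allele_frequencies()
        self.monomorphic = (freq <= 0.0) | (freq >= 1.0)

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP frequency of the '1' allele, ignoring missing calls."""
        observed = self.alleles != MISSING
        ones = np.where(observed, self.alleles, 0).sum(axis=0)
        counts = observed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, ones / counts, np.nan)


@dataclass(frozen=True)
class WindowScore:
    """Scores for one sliding window relative to a focal SNP."""

    focal_snp: str
    offset: int
    window_snps: int
    varld_raw: float
    het_diff: float
    empirical_p: float | None = None


# ---------------------------------------------------------------------------
# Core scoring


def _haplotype_matrix(panel, snp_indices=None) -> np.ndarray:
    if isinstance(panel, HaplotypePanel):
        matrix = panel.alleles
        ids = panel.snp_ids
    else:
        matrix = np.asarray(panel)
        ids = [str(j) for j in range(matrix.shape[1])]
    if snp_indices is not None:
        matrix = matrix[:, snp_indices]
        ids = [ids[j] for j in np.atleast_1d(np.asarray(snp_indices)).tolist()] \
            if not isinstance(snp_indices, slice) else ids[snp_indices]
    return matrix, ids


def signed_r2_matrix(panel, snp_indices=None):
    """Pairwise signed r2 matrix sign(r) * r^2 over a SNP window.

    ``panel`` is a HaplotypePanel or raw (haplotypes x SNPs) 0/1 matrix;
    ``snp_indices`` restricts to a window (slice or index array).
    Monomorphic SNPs get zero off-diagonal entries (diagonal stays 1)
    and are reported in the second return value.  A SNP with no
    observed calls raises.
    """
    matrix, ids = _haplotype_matrix(panel, snp_indices)
    if matrix.shape[1] < 2:
        raise ValueError("need at least two SNPs")
    data = matrix.astype(float)
    missing = matrix == MISSING
    if missing.any():
        all_missing = missing.all(axis=0)
        if all_missing.any():
            bad = ids[int(np.flatnonzero(all_missing)[0])]
            raise ValueError(f"SNP {bad} has no observed alleles")
        data[missing] = np.nan
        r = np.ma.corrcoef(np.ma.masked_invalid(data), rowvar=False).filled(0.0)
    else:
        sd = data.std(axis=0)
        ok = sd > 0
        r = np.zeros((data.shape[1], data.shape[1]))
        if ok.sum() >= 2:
            r[np.ix_(ok, ok)] = np.corrcoef(data[:, ok], rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    signed = r * np.abs(r)
    np.fill_diagonal(signed, 1.0)
    freq = np.nanmean(np.where(matrix == MISSING, np.nan, matrix), axis=0)
    mono = [ids[j] for j in np.flatnonzero((freq <= 0) | (freq >= 1))]
    return signed, mono


def varld_raw_score(m1: np.ndarray, m2: np.ndarray) -> float:
    """Sum of absolute differences between rank-ordered eigenvalues.

    Both matrices must be symmetric and of equal dimension; eigenvalues
    are sorted descending before pairing.  Zero iff the eigenvalue
    spectra coincide (in particular for identical matrices).
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 2 or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square and of equal dimension")
    ev1 = np.sort(np.linalg.eigvalsh(m1))[::-1]
    ev2 = np.sort(np.linalg.eigvalsh(m2))[::-1]
    return float(np.abs(ev1 - ev2).sum())


def heterozygosity(panel, snp_indices=None) -> np.ndarray:
    """Per-SNP expected heterozygosity 2p(1-p) from sample frequencies."""
    matrix, _ = _haplotype_matrix(panel, snp_indices)
    freq = np.nanmean(np.where(matrix == MISSING, np.nan, matrix.astype(float)),
                      axis=0)
    return 2.0 * freq * (1.0 - freq)


# ---------------------------------------------------------------------------
# Sliding-window scan


def _window_bounds(center: int, window: int):
    start = center - window // 2
    return start, start + window


def sliding_window_scan(panel1: HaplotypePanel, panel2: HaplotypePanel,
                        focal_snp, window: int = 50, step: int = 5,
                        span: int = 300) -> pd.DataFrame:
    """Score 50-SNP windows sliding across a focal SNP's region.

    Window centers run from ``span`` SNPs upstream to ``span`` SNPs
    downstream of the focal SNP in steps of ``step`` (121 windows for
    the defaults on a fully flanked region, which needs span + window/2
    SNPs on each side, i.e. 650 in total).  Windows that would cross
    the panel edge are dropped with a warning (truncated scan).

    Returns a DataFrame with columns (focal_snp, offset, window_snps,
    varld_raw, het_diff, empirical_p); het_diff is mean heterozygosity
    of panel1 minus panel2 over the window; empirical_p is left unset.
    """
    if panel1.snp_ids != panel2.snp_ids:
        raise ValueError("panels must share the same SNP map")
    if isinstance(focal_snp, (int, np.integer)):
        focal_index = int(focal_snp)
        focal_id = panel1.snp_ids[focal_index]
    else:
        focal_id = str(focal_snp)
        try:
            focal_index = panel1.snp_ids.index(focal_id)
        except ValueError:
            raise ValueError(f"focal SNP {focal_id!r} not in panel") from None
    n_snps = panel1.n_snps
    offsets = range(-span, span + 1, step)
    rows = []
    dropped = 0
    for offset in offsets:
        center = focal_index + offset
        start, stop = _window_bounds(center, window)
        if start < 0 or stop > n_snps:
            dropped += 1
            continue
        idx = slice(start, stop)
        m1, _ = signed_r2_matrix(panel1, idx)
        m2, _ = signed_r2_matrix(panel2, idx)
        het1 = np.nanmean(heterozygosity(panel1, idx))
        het2 = np.nanmean(heterozygosity(panel2, idx))
        rows.append(WindowScore(
            focal_snp=focal_id,
            offset=offset,
            window_snps=window,
            varld_raw=varld_raw_score(m1, m2),
            het_diff=float(het1 - het2),
        ))
    if dropped:
        warnings.warn(
            f"scan truncated: {dropped} of {len(list(offsets))} windows "
            f"crossed the panel edge (need {span + window // 2} SNPs "
            "flanking the focal SNP on each side)",
            stacklevel=2,
        )
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# Permutation test


def _individual_haplotypes(panel: HaplotypePanel, snp_indices) -> np.ndarray:
    """Window alleles reshaped to (individuals, 2, window_snps)."""
    matrix, _ = _haplotype_matrix(panel, snp_indices)
    return matrix.reshape(panel.n_individuals, 2, -1)


def permutation_pvalue(panel1: HaplotypePanel, panel2: HaplotypePanel,
                       snp_indices, n_perm: int = 1000,
                       seed=None) -> float:
    """Empirical p-value for the varLD score of one window.

    Diploid individuals (keeping their two haplotypes together) are
    relabeled across the two populations preserving sample sizes; the
    p-value is (1 + #{permuted score >= observed}) / (n_perm + 1), so
    it is never smaller than 1/(n_perm + 1).
    """
    if panel1.n_individuals < 2 or panel2.n_individuals < 2:
        raise ValueError("need at least two individuals per population")
    rng = np.random.default_rng(seed)
    ind1 = _individual_haplotypes(panel1, snp_indices)
    ind2 = _individual_haplotypes(panel2, snp_indices)
    pooled = np.concatenate([ind1, ind2], axis=0)
    n1 = ind1.shape[0]
    n_total = pooled.shape[0]

    def score(group1, group2):
        m1, _ = signed_r2_matrix(group1.reshape(-1, group1.shape[-1]))
        m2, _ = signed_r2_matrix(group2.reshape(-1, group2.shape[-1]))
        return varld_raw_score(m1, m2)

    observed = score(ind1, ind2)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_total)
        permuted = pooled[perm]
        if score(permuted[:n1], permuted[n1:]) >= observed - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# MAF-matched background and group comparisons


def maf_matched_background(focal_mafs, panel_mafs, n_groups: int = 100,
                           group_size: int = 47, tol: float = 0.02,
                           widen_tol: float = 0.05, seed=None,
                           exclude=None) -> list[np.ndarray]:
    """Sample groups of SNP indices whose MAFs match the focal SNPs'.

    For each of ``n_groups`` groups, ``group_size`` SNPs are drawn
    without replacement (within the group) from ``panel_mafs``; slot i
    matches the MAF of focal SNP i (cycling through ``focal_mafs``)
    within ``tol``.  When no candidate is available the tolerance is
    widened to ``widen_tol`` with a warning; if still empty an error is
    raised.  ``exclude`` lists panel indices never to sample (e.g. the
    focal SNPs themselves).
    """
    rng = np.random.default_rng(seed)
    focal = np.minimum(np.asarray(focal_mafs, dtype=float),
                       1 - np.asarray(focal_mafs, dtype=float))
    panel = np.minimum(np.asarray(panel_mafs, dtype=float),
                       1 - np.asarray(panel_mafs, dtype=float))
    forbidden = set() if exclude is None else set(np.asarray(exclude).tolist())
    groups = []
    for _ in range(n_groups):
        chosen: list[int] = []
        taken = set(forbidden)
        for slot in range(group_size):
            target = focal[slot % len(focal)]
            candidates = np.flatnonzero(np.abs(panel - target) <= tol)
            candidates = candidates[[c not in taken for c in candidates]]
            if len(candidates) == 0:
                warnings.warn(
                    f"no candidate within +/-{tol} of MAF {target:.3f}; "
                    f"widening to +/-{widen_tol}",
                    stacklevel=2,
                )
                candidates = np.flatnonzero(np.abs(panel - target) <= widen_tol)
                candidates = candidates[[c not in taken for c in candidates]]
            if len(candidates) == 0:
                raise ValueError(
                    f"no MAF-matched candidate for focal MAF {target:.3f}"
                )
            pick = int(rng.choice(candidates))
            chosen.append(pick)
            taken.add(pick)
        groups.append(np.array(chosen, dtype=int))
    return groups


def cumulative_envelope(pvals_by_group, grid=None):
    """Median and 2.5%/97.5% envelope of per-group empirical CDFs.

    ``pvals_by_group`` is a sequence of arrays of empirical p-values
    (one array per background group).  Returns a DataFrame with columns
    (p, median, lo, hi): for each grid point, the across-group median
    and the 95% envelope of the groups' cumulative fractions <= p.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    cdfs = np.stack([
        (np.asarray(p)[:, None] <= grid[None, :]).mean(axis=0)
        for p in pvals_by_group
    ])
    return pd.DataFrame({
        "p": grid,
        "median": np.median(cdfs, axis=0),
        "lo": np.quantile(cdfs, 0.025, axis=0),
        "hi": np.quantile(cdfs, 0.975, axis=0),
    })


def group_window_comparison(scores_a: pd.DataFrame, scores_b: pd.DataFrame,
                            value: str = "varld_raw",
                            p_flag: float = 0.01) -> pd.DataFrame:
    """Mann-Whitney comparison of window scores per offset.

    ``scores_a`` and ``scores_b`` are scan outputs (one row per window
    per region) for two groups of focal SNPs, e.g. non-replicated vs
    replicated.  For each shared offset a two-sided Mann-Whitney test
    compares the two groups' ``value`` distributions; offsets with
    p < ``p_flag`` are flagged significant.
    """
    if len(scores_a) == 0 or len(scores_b) == 0:
        raise ValueError("both score groups must be non-empty")
    offsets = sorted(set(scores_a["offset"]) & set(scores_b["offset"]))
    rows = []
    for offset in offsets:
        a = scores_a.loc[scores_a["offset"] == offset, value].to_numpy(float)
        b = scores_b.loc[scores_b["offset"] == offset, value].to_numpy(float)
        if len(a) < 3 or len(b) < 3:
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({
            "offset": offset,
            "n_a": len(a),
            "n_b": len(b),
            "mean_a": a.mean(),
            "mean_b": b.mean(),
            "u_statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "significant": bool(res.pvalue < p_flag),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF + sidecar I/O


def write_vcf(panels: list[HaplotypePanel], path) -> None:
    """Write panels (sharing a SNP map) as a minimal phased VCF."""
    first = panels[0]
    for panel in panels[1:]:
        if panel.snp_ids != first.snp_ids:
            raise ValueError("panels must share the same SNP map")
    samples = [s for panel in panels for s in panel.sample_ids]
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
        handle.write(f"##contig=<ID={first.chrom}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples) + "\n")
        for j, snp_id in enumerate(first.snp_ids):
            calls = []
            for panel in panels:
                column = panel.alleles[:, j].reshape(-1, 2)
                for a, b in column:
                    fmt = lambda x: "." if x == MISSING else str(int(x))
                    calls.append(f"{fmt(a)}|{fmt(b)}")
            handle.write(
                f"{first.chrom}\t{first.pos_bp[j]}\t{snp_id}\tA\tG\t.\t.\t.\t"
                "GT\t" + "\t".join(calls) + "\n"
            )


def write_populations(panels: list[HaplotypePanel], path) -> None:
    """Write the sample_id TAB population sidecar file."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("sample_id\tpopulation\n")
        for panel in panels:
            for sample in panel.sample_ids:
                handle.write(f"{sample}\t{panel.population}\n")


def read_vcf(vcf_path, pops_path) -> dict[str, HaplotypePanel]:
    """Read a phased VCF plus population sidecar into per-population panels."""
    import pysam

    pops = pd.read_csv(pops_path, sep="\t", dtype=str)
    pop_of = dict(zip(pops["sample_id"], pops["population"]))
    vcf = pysam.VariantFile(str(vcf_path))
    samples = list(vcf.header.samples)
    unknown = [s for s in samples if s not in pop_of]
    if unknown:
        raise ValueError(f"samples missing from population file: {unknown}")
    snp_ids, positions, rows = [], [], []
    chrom = None
    for record in vcf:
        chrom = record.chrom
        snp_ids.append(record.id or f"{record.chrom}:{record.pos}")
        positions.append(record.pos)
        calls = []
        for sample in samples:
            gt = record.samples[sample]["GT"]
            calls.extend(MISSING if a is None else int(a) for a in gt)
        rows.append(calls)
    alleles = np.array(rows, dtype=np.int8).T  # (2*n_samples, n_snps)
    panels = {}
    for population in dict.fromkeys(pop_of[s] for s in samples):
        members = [i for i, s in enumerate(samples) if pop_of[s] == population]
        hap_rows = np.concatenate([[2 * i, 2 * i + 1] for i in members])
        panels[population] = HaplotypePanel(
            sample_ids=[samples[i] for i in members],
            population=population,
            alleles=alleles[hap_rows],
            snp_ids=list(snp_ids),
            chrom=str(chrom),
            pos_bp=np.array(positions, dtype=np.int64),
        )
    return panels
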