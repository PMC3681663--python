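#!/usr/bin/env python
"""LD/heterozygosity divergence scans around focal SNPs.

Simulates two groups of two-population regions: "non-replicated"-like
regions where extra drift is confined to the central 50-SNP block, and
"replicated"-like regions with genome-typical divergence only.  Scans
121 sliding 50-SNP windows (+/-300 SNPs, step 5) per region, compares
the two groups per offset by Mann-Whitney tests, computes permutation
empirical p-values for the central window, and places them against a
MAF-matched random background envelope.

Writes results/ld_scan/{windows,offset_comparison,central_pvalues,
background_envelope}.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from transrep.ld_divergence import (
    cumulative_envelope,
    group_window_comparison,
    maf_matched_background,
    permutation_pvalue,
    sliding_window_scan,
)
from transrep.replication_db import write_table
from transrep.synthetic_data import (
    HapSimConfig,
    gen_targeted_drift_pair,
    gen_two_pop_haplotypes,
)

ROOT = Path(__file__).resolve().parents[1]

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--regions", type=int, default=12,
                    help="regions per group")
parser.add_argument("--perms", type=int, default=199)
parser.add_argument("--out", type=Path, default=ROOT / "results" / "ld_scan")
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

BASE = dict(n_snps=650, drift_generations=40, pop_size=500,
            n_hap_pool=1000, n_per_pop=60)
FOCAL = 325
BLOCK = slice(300, 350)

# -- sliding-window scans -------------------------------------------------
scans = {"non_replicated": [], "replicated": []}
central_p = {"non_replicated": [], "replicated": []}
focal_mafs = []
for i in range(args.regions):
    target = gen_targeted_drift_pair(
        HapSimConfig(seed=args.seed * 10_000 + i, **BASE), BLOCK,
        extra_generations=250)
    null = gen_two_pop_haplotypes(
        HapSimConfig(seed=args.seed * 10_000 + 5000 + i, **BASE))
    focal_mafs.append(float(null.panel1.allele_frequencies()[FOCAL]))
    for label, panels in (("non_replicated", target), ("replicated", null)):
        scan = sliding_window_scan(panels.panel1, panels.panel2, FOCAL)
        scan["group"] = label
        scan["region"] = i
        scans[label].append(scan)
        central_p[label].append(permutation_pvalue(
            panels.panel1, panels.panel2, BLOCK, n_perm=args.perms,
            seed=args.seed * 100 + i))

windows = pd.concat(scans["non_replicated"] + scans["replicated"],
                    ignore_index=True)
write_table(windows, args.out / "windows.tsv")

for label in scans:
    grp = windows[windows["group"] == label]
    central = grp[grp["offset"] == 0]
    print(f"{label:>15}: central varLD "
          f"{central['varld_raw'].mean():.2f} +/- "
          f"{central['varld_raw'].std(ddof=1):.2f}, central |het diff| "
          f"{central['het_diff'].abs().mean():.3f}")

# -- per-offset group comparison ------------------------------------------
comparison = group_window_comparison(
    pd.concat(scans["non_replicated"]), pd.concat(scans["replicated"]))
write_table(comparison, args.out / "offset_comparison.tsv")
sig = comparison.loc[comparison["significant"], "offset"].tolist()
print(f"offsets with Mann-Whitney p<0.01: {sig}")
print("(localized divergence: significance confined near the focal SNP)")

# -- central-window permutation p-values ----------------------------------
pvals = pd.DataFrame({
    "group": (["non_replicated"] * args.regions
              + ["replicated"] * args.regions),
    "empirical_p": central_p["non_replicated"] + central_p["replicated"],
})
write_table(pvals, args.out / "central_pvalues.tsv")
for label in ("non_replicated", "replicated"):
    vals = np.array(central_p[label])
    print(f"{label:>15}: {np.mean(vals < 0.05):.0%} of central windows "
          f"significant at p<0.05 (median p {np.median(vals):.3f})")

# -- MAF-matched background envelope --------------------------------------
# a background "chromosome": window p-values at SNPs whose MAFs match the
# focal SNPs', away from the region edges
background = gen_two_pop_haplotypes(
    HapSimConfig(seed=args.seed * 77 + 3, **BASE))
panel_mafs = background.panel1.allele_frequencies()
edge = np.concatenate([np.arange(0, 30), np.arange(620, 650)])
groups = maf_matched_background(focal_mafs, panel_mafs, n_groups=10,
                                group_size=8, tol=0.02, widen_tol=0.1,
                                seed=args.seed, exclude=edge)
group_pvals = []
for g, snps in enumerate(groups):
    pv = [permutation_pvalue(background.panel1, background.panel2,
                             slice(max(int(s) - 25, 0), int(s) + 25),
                             n_perm=args.perms, seed=args.seed * 31 + g * 100 + k)
          for k, s in enumerate(snps)]
    group_pvals.append(np.array(pv))
envelope = cumulative_envelope(group_pvals)
write_table(envelope, args.out / "background_envelope.tsv")
mid = envelope.iloc[(envelope["p"] - 0.5).abs().idxmin()]
print(f"background envelope at p=0.5: median CDF {mid['median']:.2f} "
      f"(95% envelope {mid['lo']:.2f}-{mid['hi']:.2f}); the background "
      "lies above the diagonal because the two populations have "
      "genome-wide LD divergence, as the replicated group does")
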