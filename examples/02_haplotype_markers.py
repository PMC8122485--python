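"""From SNPs to multi-allelic haplotype (LDB) markers.

SNP calls are filtered for missingness, imputed with LD-kNN, grouped
into local linkage-disequilibrium blocks (r^2 >= 0.7 within a genetic
background, transitively merged), and each block becomes one
multi-allelic marker whose alleles are the distinct local haplotypes.
A final pass removes low-call-rate and high-heterozygosity markers and
poorly covered lines.
"""

import numpy as np

from namhap import markers as mk
from namhap import simcore as sc

gmap = sc.default_genetic_map(n_chrom=2, length_cM=100.0, n_loci_per_chrom=120)
rng = np.random.default_rng(7)
panel = sc.simulate_founders(gmap, n_exotic=6, rng=rng)
families = [
    sc.FamilySpec(f"FAM{i + 1:02d}", panel.reference[i % 2], panel.exotic[i], 25)
    for i in range(6)
]
pop = sc.simulate_nam(sc.NAMDesign(families), panel, gmap, None, rng)
gm = sc.genotype_population(pop, gmap, 0.05, rng, include_parents=True)

# 1. drop SNPs with too many missing calls (>40% codominant, >20% dominant)
gm, report = mk.filter_snps_by_missing(gm)
print("missingness filter:", report)

# 2. impute the remaining gaps from the k nearest lines in local LD
gm = mk.ld_knn_impute(gm, k=5, l=30)
print(f"after LD-kNN imputation: {gm.missing_mask().mean():.3%} missing")

# 3. tag SNPs into LD blocks per genetic background, then merge
groups_per_bg = [
    mk.tag_snps(gm, r2_min=0.7, maf_min=0.01, window_kb=10_000.0, background=bg)
    for bg in ("RP1", "RP2")
]
groups = mk.merge_tag_groups(groups_per_bg, gm.snps)
sizes = [len(g.members) for g in groups]
print(
    f"{len(groups)} tag groups "
    f"(largest {max(sizes)} SNPs, {np.mean(sizes):.2f} on average)"
)

# 4. one multi-allelic marker per group; alleles = distinct haplotypes
hms = mk.build_haplotype_markers(gm, groups)
n_alleles = [m.n_alleles for m in hms.markers]
print(
    f"{hms.n_markers} haplotype markers, "
    f"{np.mean(n_alleles):.2f} alleles per marker on average"
)

# 5. final marker/line quality pass (<70% call rate, >6% het, <50% line)
hms, report = mk.filter_haplotype_markers_and_lines(hms)
print("marker/line filter:", report)
print(f"final set: {hms.n_markers} markers x {hms.n_lines} lines")
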