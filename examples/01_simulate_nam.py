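"""Simulate a nested association mapping (NAM) population.

A NAM design crosses each of several exotic founders to a shared
reference parent, backcrosses the F1 once to the reference, and selfs by
single-seed descent to BC1F4.  Each resulting recombinant inbred line
(RIL) then carries an expected 25% of its genome from its exotic parent,
with residual heterozygosity (1/2)^4 = 6.25% at parent-polymorphic loci.
This script builds such a population and checks both expectations.
"""

import numpy as np

from namhap import simcore as sc

# a 3-chromosome genome, 150 cM each, 200 loci per chromosome
gmap = sc.default_genetic_map(n_chrom=3, length_cM=150.0, n_loci_per_chrom=200)
rng = np.random.default_rng(42)

# two reference parents (RP1, RP2) and six exotic founders (EP01..EP06)
panel = sc.simulate_founders(gmap, n_exotic=6, rng=rng)
print("founders:", ", ".join(panel.names))

# six families of 30 BC1F4 RILs, alternating the reference background
families = [
    sc.FamilySpec(f"FAM{i + 1:02d}", panel.reference[i % 2], panel.exotic[i], 30)
    for i in range(6)
]
pop = sc.simulate_nam(sc.NAMDesign(families), panel, gmap, None, rng)
print(f"simulated {pop.n_lines} RILs in {len(families)} families")

# expectation 1: mean exotic genome share = 0.25
fracs = sc.true_exotic_fractions(pop)
print(f"mean exotic fraction: {fracs.mean():.4f} (expected 0.25)")
print(f"per-line range: {fracs.min():.3f} .. {fracs.max():.3f}")

# expectation 2: residual heterozygosity = 0.0625 at polymorphic loci
het = (pop.origins[:, 0, :] != pop.origins[:, 1, :]).mean()
print(f"mean heterozygosity over all loci: {het:.4f}")

# genotype the population (2% missing calls) for downstream analysis
matrix = sc.genotype_population(pop, gmap, missing_rate=0.02, rng=rng)
print(
    f"genotype matrix: {matrix.n_lines} lines x {matrix.n_snps} SNPs, "
    f"{matrix.missing_mask().mean():.3%} missing"
)
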