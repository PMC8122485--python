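"""Field-trial phenotypes, REML BLUPs and generalized heritability.

Plot-level phenotypes from a randomized complete block trial are fitted
with the mixed model y = mu + genotype + block (all non-intercept terms
random).  Line BLUPs feed selection decisions; generalized (Cullis)
heritability H^2 = 1 - mean PEV of line differences / (2 sigma^2_g)
summarizes trial quality even for unbalanced designs.
"""

import numpy as np

from namhap import phenostats as ph
from namhap import simcore as sc

gmap = sc.default_genetic_map(n_chrom=2, length_cM=100.0, n_loci_per_chrom=80)
rng = np.random.default_rng(5)
panel = sc.simulate_founders(gmap, n_exotic=4, rng=rng)
families = [
    sc.FamilySpec(f"FAM{i + 1:02d}", panel.reference[i % 2], panel.exotic[i], 40)
    for i in range(4)
]
pop = sc.simulate_nam(sc.NAMDesign(families), panel, gmap, None, rng)

# a maturity trait with one major locus, and a residual-noise height trait
maturity = sc.TraitArchitecture(
    "maturity", [("Schr1_40", {0: 0.0, 1: 5.0})], intercept=55.0, residual_sd=1.5
)
height = sc.TraitArchitecture(
    "height", [("Schr2_40", {0: 0.0, 1: -10.0})], intercept=95.0, residual_sd=4.0
)

design = sc.rcbd_design("TRIAL1", pop.line_ids, n_blocks=2, sigma_block=1.0, rng=rng)
plots = sc.simulate_trials(pop, gmap, {"maturity": maturity, "height": height}, [design], rng)
print(f"{len(plots)} plot records, traits: {sorted(plots['trait'].unique())}")

for trait in ("maturity", "height"):
    fit = ph.fit_trial(plots, trait)
    h2 = ph.generalized_heritability(fit)
    print(
        f"{trait}: sigma2_g={fit.sigma2_g:.2f} sigma2_e={fit.sigma2_e:.2f} "
        f"H^2={h2:.3f}"
    )

# selection: keep lines flowering between two named checks, below a cap
fit_m = ph.fit_trial(plots, "maturity")
fit_h = ph.fit_trial(plots, "height")
blups_m = fit_m.mu + fit_m.blups
blups_h = fit_h.mu + fit_h.blups
checks = blups_m.sort_values()
blups_m["CHK_EARLY"] = checks.iloc[int(0.1 * len(checks))]
blups_m["CHK_LATE"] = checks.iloc[int(0.9 * len(checks))]
summary = ph.selection_summary(
    blups_m,
    maturity_checks=("CHK_EARLY", "CHK_LATE"),
    height_max=float(blups_h.median()),
    height_blups=blups_h,
)
print(summary.to_string(index=False))
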