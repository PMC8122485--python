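"""Shared fixtures: small genomes, founder panels and simulated NAM
populations used across the suite.  Everything is generated at test time
from fixed seeds."""

import numpy as np
import pandas as pd
import pytest

from namhap import simcore as sc
from namhap.markers import GenotypeMatrix, HaplotypeMarker, HaplotypeMarkerSet


@pytest.fixture(scope="session")
def small_gmap():
    return sc.default_genetic_map(n_chrom=2, length_cM=100.0, n_loci_per_chrom=60)


@pytest.fixture(scope="session")
def nam_world(small_gmap):
    """A 8-family, two-subpopulation NAM with 20 lines per family, no
    culling, fully genotyped with the parents included."""
    rng = np.random.default_rng(12345)
    panel = sc.simulate_founders(small_gmap, n_exotic=8, rng=rng)
    fams = [
        sc.FamilySpec(
            f"FAM{i + 1:02d}", panel.reference[i % 2], panel.exotic[i], 20
        )
        for i in range(8)
    ]
    design = sc.NAMDesign(fams)
    pop = sc.simulate_nam(design, panel, small_gmap, None, rng)
    matrix = sc.genotype_population(
        pop, small_gmap, missing_rate=0.0, rng=rng, include_parents=True
    )
    return {
        "gmap": small_gmap,
        "panel": panel,
        "design": design,
        "pop": pop,
        "matrix": matrix,
    }


def toy_genotype_matrix(a1, a2, marker_class=None, backgrounds=None, roles=None):
    """Build a GenotypeMatrix from explicit call arrays on a 1-chrom map."""
    a1 = np.asarray(a1, dtype=np.int16)
    a2 = np.asarray(a2, dtype=np.int16)
    n, m = a1.shape
    marker_class = marker_class or ["codominant"] * m
    snps = pd.DataFrame(
        {
            "snp_id": [f"S{j + 1}" for j in range(m)],
            "chrom": "chr1",
            "pos_cM": np.arange(m, dtype=float) + 1.0,
            "pos_bp": (np.arange(m, dtype=np.int64) + 1) * 1000,
            "marker_class": marker_class,
        }
    )
    lines = pd.DataFrame(
        {
            "line_id": [f"L{i + 1}" for i in range(n)],
            "family_id": "FAM1",
            "background": backgrounds or ["BG1"] * n,
            "role": roles or ["ril"] * n,
        }
    )
    return GenotypeMatrix(line_table=lines, snps=snps, a1=a1, a2=a2)


def toy_marker_set(h1, h2, n_alleles=None, backgrounds=None, roles=None, families=None):
    """Build a HaplotypeMarkerSet directly from allele-index call arrays."""
    h1 = np.asarray(h1, dtype=np.int16)
    h2 = np.asarray(h2, dtype=np.int16)
    n, m = h1.shape
    markers = []
    for j in range(m):
        called = h1[:, j] >= 0
        k = (
            n_alleles[j]
            if n_alleles is not None
            else int(max(h1[called, j].max(), h2[called, j].max())) if called.any() else 2
        )
        markers.append(
            HaplotypeMarker(
                marker_id=f"LDB_chr1_{(j + 1) * 1000}",
                chrom="chr1",
                pos_bp=(j + 1) * 1000,
                member_snps=[f"S{j + 1}"],
                alleles={str(a): a for a in range(1, k + 1)},
            )
        )
    lines = pd.DataFrame(
        {
            "line_id": [f"L{i + 1}" for i in range(n)],
            "family_id": families or ["FAM1"] * n,
            "background": backgrounds or ["BG1"] * n,
            "role": roles or ["ril"] * n,
        }
    )
    return HaplotypeMarkerSet(markers=markers, line_table=lines, h1=h1, h2=h2)
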