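"""Breeding-design simulator for two-reference-parent NAM populations.

The crossing scheme mirrors a nested association mapping design with two
elite reference parents: each exotic donor is crossed to a reference
parent, the F1 is backcrossed once to the same reference parent, and the
BC1F1 is advanced by single-seed descent (one random selfed seed per
generation) to BC1F4.  The resulting lines are treated as BC1F4:6
recombinant inbred lines: the two further generations of seed bulking do
not add segregation sampling.

Meiosis uses a Poisson crossover process on the centimorgan scale
(Haldane model, no interference): the crossover count on a chromosome of
length L cM is Poisson(L/100) with breakpoints uniform on [0, L].

Founders are fully homozygous, so a haplotype is fully described by the
founder of origin at each locus; allele tokens are looked up from the
founder panel on demand.  This keeps every allele traceable to exactly
one declared founder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "FounderPanel",
    "Individual",
    "Population",
    "TraitArchitecture",
    "FamilySpec",
    "NAMDesign",
    "TrialDesign",
    "CullingError",
    "default_genetic_map",
    "simulate_founders",
    "founder_individual",
    "make_gamete",
    "cross",
    "self_individual",
    "genetic_value",
    "advance_family",
    "simulate_nam",
    "genotype_population",
    "true_exotic_fractions",
    "rcbd_design",
    "prep_design",
    "simulate_trials",
]


class CullingError(RuntimeError):
    """Raised when the culling window rejects every candidate of a family."""


# ---------------------------------------------------------------------------
# genetic map


@dataclass
class GeneticMap:
    """Ordered loci with genetic (cM) and physical (bp) coordinates.

    ``table`` columns: ``snp_id, chrom, pos_cM, pos_bp, marker_class``
    (marker_class is ``codominant`` or ``dominant``).  Loci must be sorted
    by chromosome then position, strictly increasing in both coordinate
    systems within a chromosome.
    """

    table: pd.DataFrame
    lengths_cM: dict[str, float]

    def __post_init__(self) -> None:
        req = {"snp_id", "chrom", "pos_cM", "pos_bp", "marker_class"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"map table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        if self.table["snp_id"].duplicated().any():
            raise ValueError("snp_ids must be unique genome-wide")
        if not set(self.table["marker_class"]) <= {"codominant", "dominant"}:
            raise ValueError("marker_class must be codominant|dominant")
        self._slices: dict[str, slice] = {}
        start = 0
        for chrom, grp in self.table.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise ValueError("map table must be grouped by chromosome")
            cm = grp["pos_cM"].to_numpy(float)
            bp = grp["pos_bp"].to_numpy(np.int64)
            if np.any(np.diff(cm) <= 0) or np.any(np.diff(bp) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            if chrom not in self.lengths_cM:
                raise ValueError(f"no length for chromosome {chrom}")
            L = self.lengths_cM[chrom]
            if cm[0] < 0 or cm[-1] > L:
                raise ValueError(f"pos_cM outside [0, {L}] on {chrom}")
            if bp[0] < 1:
                raise ValueError("pos_bp must be >= 1")
            self._slices[chrom] = slice(idx[0], idx[-1] + 1)
            start = idx[-1] + 1
        if start != len(self.table):
            raise ValueError("inconsistent map table")

    @property
    def n_loci(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._slices)

    def chrom_slice(self, chrom: str) -> slice:
        return self._slices[chrom]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    def locus_index(self, snp_id: str) -> int:
        pos = self.table.index[self.table["snp_id"] == snp_id]
        if len(pos) == 0:
            raise KeyError(f"unknown snp_id {snp_id!r}")
        return int(pos[0])


def default_genetic_map(
    n_chrom: int = 3,
    length_cM: float = 150.0,
    n_loci_per_chrom: int = 200,
    bp_per_cM: float = 1_000_000.0,
    dominant_every: int = 0,
) -> GeneticMap:
    """Small evenly spaced test genome: ``n_chrom`` chromosomes of
    ``length_cM`` with ``n_loci_per_chrom`` loci each.

    With the default 1 Mb/cM scaling a 10,000 kb physical window spans
    10 cM.  ``dominant_every``: if > 0, every k-th locus is scored as a
    dominant (presence/absence) marker.
    """
    rows = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        cm = np.linspace(
            length_cM / (2 * n_loci_per_chrom),
            length_cM * (1 - 1 / (2 * n_loci_per_chrom)),
            n_loci_per_chrom,
        )
        bp = np.round(cm * bp_per_cM).astype(np.int64) + 1
        for i in range(n_loci_per_chrom):
            cls = (
                "dominant"
                if dominant_every and (i + 1) % dominant_every == 0
                else "codominant"
            )
            rows.append((f"S{chrom}_{i + 1}", chrom, cm[i], int(bp[i]), cls))
    table = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos_cM", "pos_bp", "marker_class"]
    )
    return GeneticMap(table, {f"chr{c + 1}": length_cM for c in range(n_chrom)})


# ---------------------------------------------------------------------------
# founders and individuals


@dataclass
class FounderPanel:
    """Fully homozygous founders: two reference parents plus exotic donors.

    ``alleles[f, m]`` is the (single) allele token carried by founder ``f``
    at locus ``m``; tokens are opaque small integers.
    """

    names: list[str]
    reference: tuple[str, str]
    exotic: list[str]
    alleles: np.ndarray  # (n_founders, n_loci) int16

    def __post_init__(self) -> None:
        if len(self.reference) != 2:
            raise ValueError("exactly two reference parents required")
        if set(self.reference) | set(self.exotic) != set(self.names):
            raise ValueError("names must equal reference + exotic founders")
        if self.alleles.shape[0] != len(self.names):
            raise ValueError("allele matrix / name count mismatch")
        self._index = {n: i for i, n in enumerate(self.names)}

    def founder_index(self, name: str) -> int:
        return self._index[name]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]


def simulate_founders(
    gmap: GeneticMap,
    n_exotic: int,
    rng: np.random.Generator,
    reference_names: tuple[str, str] = ("RP1", "RP2"),
) -> FounderPanel:
    """Draw a biallelic founder panel on ``gmap``.

    Each SNP gets an ancestral allele frequency drawn uniform on
    [0.1, 0.9]; every founder then draws its (homozygous) allele from that
    frequency.  This yields realistic polymorphism rates between any
    parent pair and local haplotype diversity across exotic donors.
    """
    exotic_names = [f"EP{i + 1:02d}" for i in range(n_exotic)]
    names = list(reference_names) + exotic_names
    m = gmap.n_loci
    freq = rng.uniform(0.1, 0.9, size=m)
    alleles = (rng.random((len(names), m)) < freq).astype(np.int16)
    return FounderPanel(
        names=names,
        reference=tuple(reference_names),
        exotic=exotic_names,
        alleles=alleles,
    )


@dataclass
class Individual:
    """A (possibly heterozygous) individual: two founder-origin haplotypes.

    ``origins[h, m]`` is the founder index of haplotype ``h`` at locus
    ``m``; the allele carried is ``panel.alleles[origins[h, m], m]``.
    """

    line_id: str
    family_id: str
    generation: str
    origins: np.ndarray  # (2, n_loci) int16

    def alleles(self, panel: FounderPanel) -> np.ndarray:
        cols = np.arange(panel.n_loci)
        return panel.alleles[self.origins, cols]


@dataclass
class Population:
    """A stack of individuals sharing one panel and map."""

    line_ids: list[str]
    family_ids: list[str]
    generation: str
    origins: np.ndarray  # (n, 2, n_loci) int16
    panel: FounderPanel
    families: pd.DataFrame  # family_id, reference, exotic

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def alleles(self) -> np.ndarray:
        """(n, 2, n_loci) allele tokens."""
        cols = np.arange(self.panel.n_loci)
        return self.panel.alleles[self.origins, cols]

    def individual(self, i: int) -> Individual:
        return Individual(
            self.line_ids[i], self.family_ids[i], self.generation, self.origins[i]
        )


def founder_individual(panel: FounderPanel, name: str, gmap: GeneticMap) -> Individual:
    idx = panel.founder_index(name)
    origins = np.full((2, gmap.n_loci), idx, dtype=np.int16)
    return Individual(name, "founder", "P", origins)


# ---------------------------------------------------------------------------
# meiosis and crossing


def make_gamete(
    parent: Individual, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete: founder-origin vector over all loci.

    Per chromosome the crossover count is Poisson(length_cM/100) with
    breakpoints uniform on [0, length_cM] (no interference); the gamete
    alternates parental haplotypes between breakpoints, starting from a
    haplotype chosen with probability 1/2.
    """
    if gmap.n_loci == 0:
        raise ValueError("empty genetic map")
    out = np.empty(gmap.n_loci, dtype=np.int16)
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        L = gmap.lengths_cM[chrom]
        start = int(rng.integers(2))
        n_co = int(rng.poisson(L / 100.0)) if L > 0 else 0
        if n_co == 0:
            out[sl] = parent.origins[start, sl]
            continue
        pos = gmap.table["pos_cM"].to_numpy(float)[sl]
        breaks = np.sort(rng.uniform(0.0, L, size=n_co))
        hap = (start + np.searchsorted(breaks, pos, side="right")) % 2
        seg = parent.origins[:, sl]
        out[sl] = np.where(hap == 0, seg[0], seg[1])
    return out


def cross(
    mother: Individual,
    father: Individual,
    gmap: GeneticMap,
    rng: np.random.Generator,
    line_id: str = "",
    family_id: str = "",
    generation: str = "",
) -> Individual:
    origins = np.stack([make_gamete(mother, gmap, rng), make_gamete(father, gmap, rng)])
    return Individual(line_id, family_id, generation, origins)


def self_individual(
    parent: Individual, gmap: GeneticMap, rng: np.random.Generator, generation: str = ""
) -> Individual:
    return cross(
        parent, parent, gmap, rng, parent.line_id, parent.family_id, generation
    )


# ---------------------------------------------------------------------------
# trait architectures


@dataclass
class TraitArchitecture:
    """Additive major-gene architecture for one trait.

    ``qtl`` maps locus snp_ids to per-allele effects (trait units);
    heterozygotes take the mean of their two allele effects.
    ``residual_sd`` is either a scalar or a per-trial mapping.
    """

    name: str
    qtl: list[tuple[str, dict[int, float]]]
    intercept: float = 0.0
    residual_sd: float | dict[str, float] = 0.0

    def residual_for(self, trial_id: str) -> float:
        if isinstance(self.residual_sd, dict):
            return float(self.residual_sd[trial_id])
        return float(self.residual_sd)

    def validate(self, gmap: GeneticMap, panel: FounderPanel) -> None:
        for snp_id, effects in self.qtl:
            loc = gmap.locus_index(snp_id)
            present = set(int(a) for a in panel.alleles[:, loc])
            if not present <= set(effects):
                raise ValueError(
                    f"trait {self.name}: effects at {snp_id} do not cover "
                    f"founder alleles {sorted(present)}"
                )


def genetic_value(
    ind: Individual, panel: FounderPanel, gmap: GeneticMap, trait: TraitArchitecture
) -> float:
    value = trait.intercept
    for snp_id, effects in trait.qtl:
        loc = gmap.locus_index(snp_id)
        a0 = int(panel.alleles[ind.origins[0, loc], loc])
        a1 = int(panel.alleles[ind.origins[1, loc], loc])
        value += 0.5 * (effects[a0] + effects[a1])
    return value


# ---------------------------------------------------------------------------
# NAM design and family advancement


@dataclass
class FamilySpec:
    family_id: str
    reference: str
    exotic: str
    n_lines: int

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")


@dataclass
class NAMDesign:
    """Families plus the BC1F2 culling rule.

    ``culling`` maps trait name -> (low, high) acceptance window applied
    to the BC1F2 genetic value; candidates outside any window are
    discarded and redrawn (bounded retries) so family sizes stay as
    designed.
    """

    families: list[FamilySpec]
    culling: dict[str, tuple[float, float]] = field(default_factory=dict)
    max_retries: int = 200


def _passes_culling(
    ind: Individual,
    panel: FounderPanel,
    gmap: GeneticMap,
    trait_models: dict[str, TraitArchitecture],
    culling: dict[str, tuple[float, float]],
) -> bool:
    for trait_name, (low, high) in culling.items():
        v = genetic_value(ind, panel, gmap, trait_models[trait_name])
        if not (low <= v <= high):
            return False
    return True


def advance_family(
    entry: FamilySpec,
    founders: FounderPanel,
    gmap: GeneticMap,
    trait_models: dict[str, TraitArchitecture] | None,
    rng: np.random.Generator,
    culling: dict[str, tuple[float, float]] | None = None,
    max_retries: int = 200,
) -> list[Individual]:
    """Advance one family through the full pedigree to BC1F4:6.

    cross(exotic, reference) -> F1; cross(F1, reference) -> BC1F1; then
    three generations of single-seed-descent selfing (BC1F2..BC1F4).
    Culling windows, if given, are applied to BC1F2 genetic values; a
    failing candidate is redrawn from a fresh BC1F1 so that surviving
    lines reflect the within-family selection.
    """
    for name in (entry.reference, entry.exotic):
        if name not in founders.names:
            raise KeyError(f"founder {name!r} not in panel")
    culling = culling or {}
    if culling and not trait_models:
        raise ValueError("culling requires trait models")
    ref = founder_individual(founders, entry.reference, gmap)
    exo = founder_individual(founders, entry.exotic, gmap)
    lines: list[Individual] = []
    for i in range(entry.n_lines):
        line_id = f"{entry.family_id}_{i + 1:03d}"
        bc1f2 = None
        for _ in range(max_retries):
            f1 = cross(exo, ref, gmap, rng, line_id, entry.family_id, "F1")
            bc1f1 = cross(f1, ref, gmap, rng, line_id, entry.family_id, "BC1F1")
            cand = self_individual(bc1f1, gmap, rng, "BC1F2")
            if _passes_culling(cand, founders, gmap, trait_models or {}, culling):
                bc1f2 = cand
                break
        if bc1f2 is None:
            raise CullingError(
                f"family {entry.family_id}: no BC1F2 candidate passed culling "
                f"after {max_retries} retries"
            )
        bc1f3 = self_individual(bc1f2, gmap, rng, "BC1F3")
        bc1f4 = self_individual(bc1f3, gmap, rng, "BC1F4:6")
        lines.append(bc1f4)
    return lines


def simulate_nam(
    design: NAMDesign,
    founders: FounderPanel,
    gmap: GeneticMap,
    trait_models: dict[str, TraitArchitecture] | None,
    rng: np.random.Generator,
) -> Population:
    """Simulate every family of ``design`` and stack the BC1F4:6 lines."""
    if not design.families:
        raise ValueError("design has no families")
    all_lines: list[Individual] = []
    fam_rows = []
    for entry in design.families:
        fam_rows.append((entry.family_id, entry.reference, entry.exotic))
        all_lines.extend(
            advance_family(
                entry,
                founders,
                gmap,
                trait_models,
                rng,
                culling=design.culling,
                max_retries=design.max_retries,
            )
        )
    origins = np.stack([ind.origins for ind in all_lines])
    return Population(
        line_ids=[ind.line_id for ind in all_lines],
        family_ids=[ind.family_id for ind in all_lines],
        generation="BC1F4:6",
        origins=origins,
        panel=founders,
        families=pd.DataFrame(fam_rows, columns=["family_id", "reference", "exotic"]),
    )


def true_exotic_fractions(pop: Population) -> pd.Series:
    """Per-line fraction of the genome tracing to the exotic parent
    (founder-origin truth, averaged over both haplotypes and all loci)."""
    fam_exotic = dict(zip(pop.families["family_id"], pop.families["exotic"]))
    out = {}
    for i, (lid, fid) in enumerate(zip(pop.line_ids, pop.family_ids)):
        eidx = pop.panel.founder_index(fam_exotic[fid])
        out[lid] = float(np.mean(pop.origins[i] == eidx))
    return pd.Series(out, name="exotic_fraction")


# ---------------------------------------------------------------------------
# genotyping


def genotype_population(
    pop: Population,
    gmap: GeneticMap,
    missing_rate: float,
    rng: np.random.Generator,
    het_preserved: bool = True,
    include_parents: bool = False,
):
    """Score the population on the map's markers.

    Codominant markers report the unordered allele pair; dominant markers
    report presence/absence of the non-reference allele (the reference
    allele being the first reference parent's allele, as in a
    presence/absence assay designed on the reference background).  Calls
    are set missing independently with ``missing_rate``.  With
    ``het_preserved=False`` heterozygous codominant calls are masked to
    missing instead of reported.

    Returns a :class:`namhap.markers.GenotypeMatrix`; with
    ``include_parents=True`` the founders used by the population are
    appended as fully observed lines (role ``parent``).
    """
    from namhap.markers import GenotypeMatrix

    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    panel = pop.panel
    alle = pop.alleles()  # (n, 2, m)
    a1 = np.minimum(alle[:, 0, :], alle[:, 1, :]).astype(np.int16)
    a2 = np.maximum(alle[:, 0, :], alle[:, 1, :]).astype(np.int16)

    cls = gmap.table["marker_class"].to_numpy()
    dom = cls == "dominant"
    if dom.any():
        ref_idx = panel.founder_index(panel.reference[0])
        ref_allele = panel.alleles[ref_idx]  # (m,)
        cols = np.where(dom)[0]
        for j in cols:
            r = ref_allele[j]
            others = np.unique(panel.alleles[:, j])
            others = others[others != r]
            alt = others.min() if len(others) else r
            present = (a1[:, j] != r) | (a2[:, j] != r)
            a1[:, j] = np.where(present, alt, r)
            a2[:, j] = a1[:, j]

    if not het_preserved:
        het = (a1 != a2) & ~dom[None, :]
        a1[het] = -1
        a2[het] = -1

    if missing_rate > 0:
        miss = rng.random(a1.shape) < missing_rate
        a1[miss] = -1
        a2[miss] = -1

    fam_ref = dict(zip(pop.families["family_id"], pop.families["reference"]))
    lines = pd.DataFrame(
        {
            "line_id": pop.line_ids,
            "family_id": pop.family_ids,
            "background": [fam_ref[f] for f in pop.family_ids],
            "role": "ril",
        }
    )

    if include_parents:
        used = list(
            dict.fromkeys(
                list(pop.families["reference"]) + list(pop.families["exotic"])
            )
        )
        pidx = [panel.founder_index(n) for n in used]
        pa = panel.alleles[pidx].astype(np.int16)
        if dom.any():
            for j in np.where(dom)[0]:
                r = ref_allele[j]
                others = np.unique(panel.alleles[:, j])
                others = others[others != r]
                alt = others.min() if len(others) else r
                pa[:, j] = np.where(pa[:, j] != r, alt, r)
        a1 = np.vstack([a1, pa])
        a2 = np.vstack([a2, pa])
        lines = pd.concat(
            [
                lines,
                pd.DataFrame(
                    {
                        "line_id": used,
                        "family_id": "",
                        "background": used,
                        "role": "parent",
                    }
                ),
            ],
            ignore_index=True,
        )

    return GenotypeMatrix(
        line_table=lines, snps=gmap.table.copy(), a1=a1, a2=a2
    )


# ---------------------------------------------------------------------------
# field-trial simulation


@dataclass
class TrialDesign:
    """Plot layout for one trial.

    ``plots`` columns: line_id, block, plot_row, plot_range.  ``sigma_block``
    is the standard deviation of the (shared) random block effect.
    """

    trial_id: str
    plots: pd.DataFrame
    sigma_block: float = 0.0


def rcbd_design(
    trial_id: str,
    line_ids: list[str],
    n_blocks: int,
    sigma_block: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TrialDesign:
    """Randomized complete block design: every line once per block; each
    block occupies one range band of the field grid."""
    rows = []
    for b in range(n_blocks):
        order = list(line_ids)
        if rng is not None:
            order = [order[i] for i in rng.permutation(len(order))]
        for r, lid in enumerate(order):
            rows.append((lid, f"B{b + 1}", r + 1, b + 1))
    plots = pd.DataFrame(rows, columns=["line_id", "block", "plot_row", "plot_range"])
    return TrialDesign(trial_id, plots, sigma_block)


def prep_design(
    trial_id: str,
    lines_rep2: list[str],
    lines_rep1: list[str],
    checks: list[str] | None = None,
    sigma_block: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TrialDesign:
    """Partially replicated layout: ``lines_rep2`` (and checks) appear in
    both blocks, ``lines_rep1`` are split alternately across the blocks."""
    checks = checks or []
    block_entries: list[list[str]] = [list(lines_rep2) + checks for _ in range(2)]
    for i, lid in enumerate(lines_rep1):
        block_entries[i % 2].append(lid)
    rows = []
    for b, entries in enumerate(block_entries):
        order = entries
        if rng is not None:
            order = [entries[i] for i in rng.permutation(len(entries))]
        for r, lid in enumerate(order):
            rows.append((lid, f"B{b + 1}", r + 1, b + 1))
    plots = pd.DataFrame(rows, columns=["line_id", "block", "plot_row", "plot_range"])
    return TrialDesign(trial_id, plots, sigma_block)


def simulate_trials(
    pop: Population,
    gmap: GeneticMap,
    trait_models: dict[str, TraitArchitecture],
    designs: list[TrialDesign],
    rng: np.random.Generator,
    check_values: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Plot-level phenotypes for one or more trials.

    plot value = intercept + sum of QTL allelic effects (heterozygote =
    mean of its two allele effects) + block effect (drawn once per block)
    + residual noise.  ``check_values`` maps trait -> {check_id: genetic
    value} for check varieties that are not NAM lines.

    Returns columns: line_id, trial, block, plot_row, plot_range, trait,
    value.
    """
    check_values = check_values or {}
    line_index = {lid: i for i, lid in enumerate(pop.line_ids)}
    out = []
    for design in designs:
        for trait_name, trait in trait_models.items():
            gvals: dict[str, float] = {}
            for lid in design.plots["line_id"].unique():
                if lid in line_index:
                    gvals[lid] = genetic_value(
                        pop.individual(line_index[lid]), pop.panel, gmap, trait
                    )
                elif lid in check_values.get(trait_name, {}):
                    gvals[lid] = trait.intercept + check_values[trait_name][lid]
                else:
                    raise KeyError(
                        f"line {lid!r} in trial {design.trial_id} is neither in "
                        "the population nor a declared check"
                    )
            blocks = list(design.plots["block"].unique())
            beff = {
                b: (rng.normal(0.0, design.sigma_block) if design.sigma_block > 0 else 0.0)
                for b in blocks
            }
            sd = trait.residual_for(design.trial_id)
            for row in design.plots.itertuples(index=False):
                noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                out.append(
                    (
                        row.line_id,
                        design.trial_id,
                        row.block,
                        row.plot_row,
                        row.plot_range,
                        trait_name,
                        gvals[row.line_id] + beff[row.block] + noise,
                    )
                )
    return pd.DataFrame(
        out,
        columns=["line_id", "trial", "block", "plot_row", "plot_range", "trait", "value"],
    )
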