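"""From SNP calls to filtered, imputed, multi-allelic haplotype markers.

The marker-construction stage converts a line x SNP genotype matrix into
"LDB" haplotype markers: groups of SNPs in strong linkage disequilibrium
are collapsed into a single multi-allelic marker whose alleles are the
distinct local haplotypes observed in the population.  The stages, in the
order they run in the pipeline, are:

1. missingness filtering of raw SNPs (codominant vs dominant thresholds),
2. LD-kNN imputation of remaining missing SNP calls,
3. LD tagging of each target SNP within a physical window,
4. haplotype-marker construction from the (merged) tag groups,
5. marker/line call-rate and heterozygosity filtering.

LD (r^2) is computed within a reference-parent genetic background, since
pooling the two backgrounds would create spurious LD from the
subpopulation split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "TagGroup",
    "HaplotypeMarker",
    "HaplotypeMarkerSet",
    "filter_snps_by_missing",
    "ld_r2",
    "tag_snps",
    "merge_tag_groups",
    "build_haplotype_markers",
    "ld_knn_impute",
    "filter_haplotype_markers_and_lines",
]


@dataclass
class GenotypeMatrix:
    """Line x SNP unordered diploid calls.

    ``a1``/``a2`` hold the sorted allele pair per call (``a1 <= a2``),
    with ``-1`` marking a missing call in both.  ``line_table`` columns:
    line_id, family_id, background, role (``ril``/``parent``/...).
    ``snps`` carries the map metadata (snp_id, chrom, pos_cM, pos_bp,
    marker_class).
    """

    line_table: pd.DataFrame
    snps: pd.DataFrame
    a1: np.ndarray
    a2: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.a1.shape
        if self.a2.shape != (n, m):
            raise ValueError("a1/a2 shape mismatch")
        if len(self.line_table) != n:
            raise ValueError("line_table / call matrix mismatch")
        if len(self.snps) != m:
            raise ValueError("snps / call matrix mismatch")
        self.line_table = self.line_table.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.a1.shape[0]

    @property
    def n_snps(self) -> int:
        return self.a1.shape[1]

    @property
    def line_ids(self) -> list[str]:
        return list(self.line_table["line_id"])

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp_id"].to_numpy()

    def missing_mask(self) -> np.ndarray:
        return self.a1 == MISSING

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return self.missing_mask().mean(axis=0)

    def het_mask(self) -> np.ndarray:
        return (self.a1 != self.a2) & (self.a1 != MISSING)

    def subset(
        self, lines: np.ndarray | None = None, snps: np.ndarray | None = None
    ) -> "GenotypeMatrix":
        """Subset by boolean masks or integer indices (None keeps all)."""
        li = np.arange(self.n_lines) if lines is None else np.asarray(lines)
        si = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if li.dtype == bool:
            li = np.where(li)[0]
        if si.dtype == bool:
            si = np.where(si)[0]
        return GenotypeMatrix(
            line_table=self.line_table.iloc[li].reset_index(drop=True),
            snps=self.snps.iloc[si].reset_index(drop=True),
            a1=self.a1[np.ix_(li, si)].copy(),
            a2=self.a2[np.ix_(li, si)].copy(),
        )

    def background_rows(self, background: str, rils_only: bool = True) -> np.ndarray:
        mask = self.line_table["background"].to_numpy() == background
        if rils_only:
            mask &= self.line_table["role"].to_numpy() == "ril"
        return np.where(mask)[0]

    def dosage(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Per-SNP 0/0.5/1 coding of the second-ranked allele.

        At each SNP the distinct observed alleles (within ``rows``) are
        sorted; the dosage is the count of the larger-coded allele over 2
        (heterozygotes code 0.5).  SNPs with more than two observed
        alleles raise: this coding is for biallelic SNP data.  Missing
        calls are NaN.
        """
        rows = np.arange(self.n_lines) if rows is None else rows
        a1 = self.a1[rows]
        a2 = self.a2[rows]
        out = np.full(a1.shape, np.nan)
        for j in range(a1.shape[1]):
            called = a1[:, j] != MISSING
            obs = np.unique(
                np.concatenate([a1[called, j], a2[called, j]])
            )
            if len(obs) > 2:
                raise ValueError(
                    f"SNP {self.snps['snp_id'].iat[j]!r} has >2 alleles; "
                    "dosage coding requires biallelic SNPs"
                )
            if len(obs) == 0:
                continue
            top = obs[-1]
            d = (a1[:, j] == top).astype(float) + (a2[:, j] == top).astype(float)
            out[called, j] = d[called] / 2.0
        return out

    def maf(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Per-SNP minor allele frequency (biallelic coding; NaN if no calls)."""
        d = self.dosage(rows)
        with np.errstate(invalid="ignore"):
            p = np.nanmean(d, axis=0)
        return np.minimum(p, 1 - p)


# ---------------------------------------------------------------------------
# SNP-level filters


def filter_snps_by_missing(
    matrix: GenotypeMatrix,
    max_missing_codominant: float = 0.40,
    max_missing_dominant: float = 0.20,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Drop codominant SNPs with more than 40% missing calls and dominant
    SNPs with more than 20% missing calls (boundaries are kept: the
    exclusion rule is strict 'greater than').

    Returns the filtered matrix and a report of removal counts.
    """
    frac = matrix.missing_fraction()
    cls = matrix.snps["marker_class"].to_numpy()
    drop = ((cls == "codominant") & (frac > max_missing_codominant)) | (
        (cls == "dominant") & (frac > max_missing_dominant)
    )
    report = {
        "removed_codominant": int(np.sum(drop & (cls == "codominant"))),
        "removed_dominant": int(np.sum(drop & (cls == "dominant"))),
        "retained": int(np.sum(~drop)),
    }
    logger.info("missingness filter: %s", report)
    return matrix.subset(snps=~drop), report


# ---------------------------------------------------------------------------
# linkage disequilibrium


def _pairwise_r2_matrix(dos: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between SNP dosage columns with
    pairwise-complete observations (NaN where undefined)."""
    obs = ~np.isnan(dos)
    x = np.where(obs, dos, 0.0)
    o = obs.astype(float)
    n = o.T @ o
    sx = x.T @ o
    sxx = (x * x).T @ o
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx**2 / n
        vary = varx.T
        r2 = cov**2 / (varx * vary)
        r2[(varx <= 0) | (vary <= 0) | (n < 2)] = np.nan
    return r2


def ld_r2(
    matrix: GenotypeMatrix,
    snp_a: str,
    snp_b: str,
    background: str | None = None,
) -> float:
    """r^2 between two SNPs: squared Pearson correlation of the 0/0.5/1
    homozygote dosage codings over lines called at both SNPs.

    Computed within one reference-parent ``background`` when given (the
    two NAM subpopulations are analysed separately).  Returns NaN when
    either SNP has zero variance among the informative lines.
    """
    rows = (
        matrix.background_rows(background)
        if background is not None
        else np.arange(matrix.n_lines)
    )
    cols = [matrix.snps.index[matrix.snps["snp_id"] == s] for s in (snp_a, snp_b)]
    for s, c in zip((snp_a, snp_b), cols):
        if len(c) == 0:
            raise KeyError(f"unknown snp_id {s!r}")
    sub = matrix.subset(lines=rows, snps=np.array([cols[0][0], cols[1][0]]))
    d = sub.dosage()
    both = ~np.isnan(d).any(axis=1)
    if both.sum() < 2:
        return float("nan")
    r2 = _pairwise_r2_matrix(d[both])
    return float(r2[0, 1])


@dataclass
class TagGroup:
    """A target SNP plus the SNPs tagging it (in LD within the window)."""

    target: str
    members: list[str]
    chrom: str
    pos_bp: int

    def __post_init__(self) -> None:
        if self.target not in self.members:
            raise ValueError("target must be a member of its own group")


def tag_snps(
    matrix: GenotypeMatrix,
    targets: list[str] | None = None,
    r2_min: float = 0.7,
    maf_min: float = 0.01,
    max_missing: float = 0.06,
    window_kb: float = 10_000.0,
    background: str | None = None,
    merge: bool = True,
) -> list[TagGroup]:
    """Group each target SNP with the SNPs that tag it.

    A SNP tags a target when it lies within ``window_kb`` kilobases on
    the same chromosome, has minor allele frequency >= ``maf_min`` and
    missing fraction <= ``max_missing``, and r^2 with the target >=
    ``r2_min``.  Groups sharing members are merged by transitive closure
    so the final groups are disjoint; each merged group is named by the
    target of its leftmost (smallest bp) member.  A target with no tags
    forms a singleton group.
    """
    rows = (
        matrix.background_rows(background)
        if background is not None
        else np.arange(matrix.n_lines)
    )
    snps = matrix.snps
    ids = list(snps["snp_id"])
    if targets is None:
        targets = ids
    unknown = set(targets) - set(ids)
    if unknown:
        raise KeyError(f"unknown targets: {sorted(unknown)[:5]}")
    col = {s: j for j, s in enumerate(ids)}

    maf = matrix.maf(rows)
    miss = matrix.missing_mask()[rows].mean(axis=0)
    eligible = (maf >= maf_min) & (miss <= max_missing)

    chrom = snps["chrom"].to_numpy()
    bp = snps["pos_bp"].to_numpy(np.int64)
    window_bp = window_kb * 1000.0

    dos = matrix.subset(lines=rows).dosage()

    groups: list[set[int]] = []
    targets_of: list[int] = []
    for t in targets:
        jt = col[t]
        cand = np.where(
            (chrom == chrom[jt])
            & (np.abs(bp - bp[jt]) <= window_bp)
            & eligible
        )[0]
        cand = cand[cand != jt]
        members = {jt}
        if len(cand):
            dt = dos[:, jt]
            ok = ~np.isnan(dt)
            for j in cand:
                dj = dos[:, j]
                both = ok & ~np.isnan(dj)
                if both.sum() < 2:
                    continue
                x, y = dt[both], dj[both]
                vx, vy = x.var(), y.var()
                if vx <= 0 or vy <= 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                if r * r >= r2_min:
                    members.add(int(j))
        groups.append(members)
        targets_of.append(jt)

    if merge:
        # transitive-closure merge of overlapping groups (union-find)
        parent = list(range(len(groups)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        owner: dict[int, int] = {}
        for gi, members in enumerate(groups):
            for j in members:
                if j in owner:
                    ra, rb = find(owner[j]), find(gi)
                    if ra != rb:
                        parent[rb] = ra
                else:
                    owner[j] = gi
        merged: dict[int, set[int]] = {}
        mtargets: dict[int, list[int]] = {}
        for gi, members in enumerate(groups):
            r = find(gi)
            merged.setdefault(r, set()).update(members)
            mtargets.setdefault(r, []).append(targets_of[gi])
        out = []
        for r, members in merged.items():
            leftmost = min(members, key=lambda j: (bp[j], ids[j]))
            # target of the leftmost member: the group target closest to it
            cand_t = mtargets[r]
            t = min(cand_t, key=lambda j: (abs(bp[j] - bp[leftmost]), bp[j]))
            out.append(
                TagGroup(
                    target=ids[t],
                    members=sorted((ids[j] for j in members), key=lambda s: bp[col[s]]),
                    chrom=str(chrom[t]),
                    pos_bp=int(bp[t]),
                )
            )
        out.sort(key=lambda g: (g.chrom, g.pos_bp))
        return out

    return [
        TagGroup(
            target=ids[t],
            members=sorted((ids[j] for j in members), key=lambda s: bp[col[s]]),
            chrom=str(chrom[t]),
            pos_bp=int(bp[t]),
        )
        for t, members in zip(targets_of, groups)
    ]


def merge_tag_groups(
    group_lists: list[list[TagGroup]], snps: pd.DataFrame
) -> list[TagGroup]:
    """Merge tag groups from several analyses (e.g. the two genetic
    backgrounds) into disjoint groups by transitive closure on shared
    members; each merged group is named by the target nearest its
    leftmost member."""
    bp = dict(zip(snps["snp_id"], snps["pos_bp"]))
    chrom = dict(zip(snps["snp_id"], snps["chrom"]))
    flat: list[TagGroup] = [g for gl in group_lists for g in gl]
    parent = list(range(len(flat)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    owner: dict[str, int] = {}
    for gi, g in enumerate(flat):
        for s in g.members:
            if s in owner:
                ra, rb = find(owner[s]), find(gi)
                if ra != rb:
                    parent[rb] = ra
            else:
                owner[s] = gi
    merged: dict[int, set[str]] = {}
    mtargets: dict[int, list[str]] = {}
    for gi, g in enumerate(flat):
        r = find(gi)
        merged.setdefault(r, set()).update(g.members)
        mtargets.setdefault(r, []).append(g.target)
    out = []
    for r, members in merged.items():
        leftmost = min(members, key=lambda s: (bp[s], s))
        t = min(mtargets[r], key=lambda s: (abs(bp[s] - bp[leftmost]), bp[s]))
        out.append(
            TagGroup(
                target=t,
                members=sorted(members, key=lambda s: bp[s]),
                chrom=str(chrom[t]),
                pos_bp=int(bp[t]),
            )
        )
    out.sort(key=lambda g: (g.chrom, g.pos_bp))
    return out


# ---------------------------------------------------------------------------
# haplotype markers


@dataclass
class HaplotypeMarker:
    """One multi-allelic LDB marker: alleles are distinct local haplotypes."""

    marker_id: str
    chrom: str
    pos_bp: int
    member_snps: list[str]
    alleles: dict[str, int]  # haplotype string -> 1-based allele index

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def haplotype_of(self, index: int) -> str:
        for h, i in self.alleles.items():
            if i == index:
                return h
        raise KeyError(index)


@dataclass
class HaplotypeMarkerSet:
    """Line x haplotype-marker allele calls (indices; -1 missing)."""

    markers: list[HaplotypeMarker]
    line_table: pd.DataFrame
    h1: np.ndarray
    h2: np.ndarray
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, m = self.h1.shape
        if self.h2.shape != (n, m) or len(self.markers) != m:
            raise ValueError("marker/call shape mismatch")
        if len(self.line_table) != n:
            raise ValueError("line_table/call shape mismatch")
        self.line_table = self.line_table.reset_index(drop=True)

    @property
    def n_lines(self) -> int:
        return self.h1.shape[0]

    @property
    def n_markers(self) -> int:
        return self.h1.shape[1]

    @property
    def line_ids(self) -> list[str]:
        return list(self.line_table["line_id"])

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def marker_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": [m.marker_id for m in self.markers],
                "chrom": [m.chrom for m in self.markers],
                "pos_bp": [m.pos_bp for m in self.markers],
                "n_alleles": [m.n_alleles for m in self.markers],
            }
        )

    def call_rate(self) -> np.ndarray:
        return (self.h1 != MISSING).mean(axis=0)

    def het_fraction(self) -> np.ndarray:
        """Per-marker heterozygous fraction among called lines."""
        called = self.h1 != MISSING
        het = (self.h1 != self.h2) & called
        with np.errstate(invalid="ignore"):
            return np.where(
                called.sum(axis=0) > 0,
                het.sum(axis=0) / np.maximum(called.sum(axis=0), 1),
                0.0,
            )

    def subset(
        self, lines: np.ndarray | None = None, markers: np.ndarray | None = None
    ) -> "HaplotypeMarkerSet":
        li = np.arange(self.n_lines) if lines is None else np.asarray(lines)
        mi = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        if li.dtype == bool:
            li = np.where(li)[0]
        if mi.dtype == bool:
            mi = np.where(mi)[0]
        return HaplotypeMarkerSet(
            markers=[self.markers[j] for j in mi],
            line_table=self.line_table.iloc[li].reset_index(drop=True),
            h1=self.h1[np.ix_(li, mi)].copy(),
            h2=self.h2[np.ix_(li, mi)].copy(),
            log=dict(self.log),
        )


def build_haplotype_markers(
    matrix: GenotypeMatrix, groups: list[TagGroup]
) -> HaplotypeMarkerSet:
    """Collapse each (disjoint) tag group into one multi-allelic marker.

    A line's haplotype string at a group is the ordered concatenation of
    its member-SNP alleles.  Lines with any missing member call are
    missing at the marker; a line heterozygous at more than one member
    SNP is unphasable and also set missing, while a single heterozygous
    member yields an unambiguous heterozygous marker call.  Distinct
    observed haplotype strings become 1-based allele indices in order of
    first observation.  Markers named ``LDB_<chrom>_<bp>`` after the
    group target; monomorphic markers are dropped (logged).
    """
    seen: set[str] = set()
    for g in groups:
        dup = seen & set(g.members)
        if dup:
            raise ValueError(f"tag groups are not disjoint: {sorted(dup)[:5]}")
        seen.update(g.members)

    col = {s: j for j, s in enumerate(matrix.snps["snp_id"])}
    n = matrix.n_lines
    # parents get first crack at allele indices so parental haplotypes take
    # the low numbers, progeny recombinants follow
    roles = matrix.line_table["role"].to_numpy()
    scan_order = np.concatenate(
        [np.where(roles == "parent")[0], np.where(roles != "parent")[0]]
    )
    markers: list[HaplotypeMarker] = []
    h1_cols: list[np.ndarray] = []
    h2_cols: list[np.ndarray] = []
    n_mono = 0
    n_empty = 0
    for g in groups:
        jdx = [col[s] for s in g.members]
        a1 = matrix.a1[:, jdx]
        a2 = matrix.a2[:, jdx]
        any_missing = (a1 == MISSING).any(axis=1)
        n_het = (a1 != a2).sum(axis=1)
        callable_ = ~any_missing & (n_het <= 1)
        if not callable_.any():
            n_empty += 1
            logger.warning("group %s has no fully observed line; dropped", g.target)
            continue
        alleles: dict[str, int] = {}
        c1 = np.full(n, MISSING, dtype=np.int16)
        c2 = np.full(n, MISSING, dtype=np.int16)

        def index_of(hap: tuple[int, ...]) -> int:
            key = ",".join(str(int(a)) for a in hap)
            if key not in alleles:
                alleles[key] = len(alleles) + 1
            return alleles[key]

        for i in scan_order[callable_[scan_order]]:
            hap_a = tuple(a1[i])
            hap_b = tuple(a2[i])
            ia, ib = index_of(hap_a), (index_of(hap_b) if hap_b != hap_a else None)
            if ib is None:
                c1[i] = c2[i] = ia
            else:
                c1[i], c2[i] = min(ia, ib), max(ia, ib)
        if len(alleles) < 2:
            n_mono += 1
            continue
        markers.append(
            HaplotypeMarker(
                marker_id=f"LDB_{g.chrom}_{g.pos_bp}",
                chrom=g.chrom,
                pos_bp=g.pos_bp,
                member_snps=list(g.members),
                alleles=alleles,
            )
        )
        h1_cols.append(c1)
        h2_cols.append(c2)
    logger.info(
        "haplotype markers: %d built, %d monomorphic dropped, %d empty dropped",
        len(markers),
        n_mono,
        n_empty,
    )
    h1 = np.column_stack(h1_cols) if h1_cols else np.empty((n, 0), dtype=np.int16)
    h2 = np.column_stack(h2_cols) if h2_cols else np.empty((n, 0), dtype=np.int16)
    return HaplotypeMarkerSet(
        markers=markers,
        line_table=matrix.line_table.copy(),
        h1=h1,
        h2=h2,
        log={"monomorphic_dropped": n_mono, "empty_dropped": n_empty},
    )


# ---------------------------------------------------------------------------
# LD-kNN imputation


def ld_knn_impute(
    matrix: GenotypeMatrix,
    k: int = 5,
    l: int = 30,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """LD-kNN imputation of missing SNP calls.

    For each SNP with missing calls, the ``l`` SNPs most correlated
    (r^2, pairwise-complete) with it define a distance between lines
    (mean absolute dosage difference over co-observed of those SNPs); the
    ``k`` nearest lines that are observed at the focal SNP cast
    inverse-distance-weighted votes for their genotype call, and the
    winning call is imputed.  Deterministic: distance ties are broken by
    line order and vote ties by the smaller-coded genotype.  SNPs with no
    observed call are left missing (flagged in the log).
    """
    if k < 1 or l < 1:
        raise ValueError("k and l must be >= 1")
    miss = matrix.missing_mask()
    if not miss.any():
        return matrix
    a1 = matrix.a1.copy()
    a2 = matrix.a2.copy()
    dos = matrix.dosage()
    r2 = _pairwise_r2_matrix(dos)
    np.fill_diagonal(r2, -np.inf)
    r2 = np.where(np.isnan(r2), -np.inf, r2)
    n_unimputable = 0
    eps = 1e-9
    for j in np.where(miss.any(axis=0))[0]:
        observed = np.where(~miss[:, j])[0]
        if len(observed) == 0:
            n_unimputable += 1
            continue
        order = np.argsort(-r2[j])
        top = order[: min(l, len(order))]
        top = top[r2[j, top] > -np.inf]
        sub = dos[:, top] if len(top) else None
        for i in np.where(miss[:, j])[0]:
            if sub is not None and sub.shape[1]:
                diff = np.abs(sub[observed] - sub[i][None, :])
                cnt = (~np.isnan(diff)).sum(axis=1)
                with np.errstate(invalid="ignore"):
                    dist = np.where(cnt > 0, np.nansum(diff, axis=1) / np.maximum(cnt, 1), np.inf)
            else:
                dist = np.zeros(len(observed))
            kk = min(k, len(observed))
            nearest = observed[np.argsort(dist, kind="stable")[:kk]]
            nd = np.sort(dist, kind="stable")[:kk]
            votes: dict[tuple[int, int], float] = {}
            for lineidx, d in zip(nearest, nd):
                if not np.isfinite(d):
                    d = 1.0
                key = (int(a1[lineidx, j]), int(a2[lineidx, j]))
                votes[key] = votes.get(key, 0.0) + 1.0 / (d + eps)
            best = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            a1[i, j], a2[i, j] = best
    out = GenotypeMatrix(
        line_table=matrix.line_table.copy(),
        snps=matrix.snps.copy(),
        a1=a1,
        a2=a2,
    )
    if n_unimputable:
        logger.warning("%d SNPs had no observed call and were left missing", n_unimputable)
    return out


# ---------------------------------------------------------------------------
# haplotype-marker / line filters


def filter_haplotype_markers_and_lines(
    hms: HaplotypeMarkerSet,
    min_marker_call_rate: float = 0.70,
    max_marker_het: float = 0.06,
    min_line_call_rate: float = 0.50,
) -> tuple[HaplotypeMarkerSet, dict[str, int]]:
    """Quality filters applied in order: drop markers genotyped in fewer
    than 70% of lines or with heterozygous-call fraction above 6%, then
    drop lines with fewer than 50% of the surviving markers called.
    """
    cr = hms.call_rate()
    het = hms.het_fraction()
    keep_markers = (cr >= min_marker_call_rate) & (het <= max_marker_het)
    report = {
        "markers_removed_call_rate": int(np.sum(cr < min_marker_call_rate)),
        "markers_removed_het": int(
            np.sum((cr >= min_marker_call_rate) & (het > max_marker_het))
        ),
    }
    if not keep_markers.any():
        raise ValueError("all markers removed by quality filters")
    step1 = hms.subset(markers=keep_markers)
    line_cr = (step1.h1 != MISSING).mean(axis=1)
    keep_lines = line_cr >= min_line_call_rate
    report["lines_removed_call_rate"] = int(np.sum(~keep_lines))
    if not keep_lines.any():
        raise ValueError("all lines removed by quality filters")
    out = step1.subset(lines=keep_lines)
    report["markers_retained"] = out.n_markers
    report["lines_retained"] = out.n_lines
    logger.info("marker/line filter: %s", report)
    out.log.update(report)
    return out, report
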