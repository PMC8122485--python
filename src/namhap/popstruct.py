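"""Population structure and introgression from haplotype markers.

Structure is summarized by the genetic similarity coefficient (GSC)
matrix — the proportion of loci identical-by-state between two
individuals — and its eigendecomposition; introgression is summarized as
the per-locus frequency of exotic-parent alleles within each
reference-parent subpopulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from namhap.markers import MISSING, GenotypeMatrix, HaplotypeMarkerSet

logger = logging.getLogger(__name__)

__all__ = [
    "GSCMatrix",
    "EigenStructure",
    "IntrogressionProfile",
    "gsc_matrix",
    "eigen_structure",
    "exotic_allele_frequency",
    "introgression_tracks",
]


@dataclass
class GSCMatrix:
    """Symmetric identity-by-state similarity in [0, 1] with per-pair
    counts of compared loci (pairs with zero comparable loci are NaN)."""

    ids: list[str]
    values: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n) or self.counts.shape != (n, n):
            raise ValueError("GSC shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _call_arrays(obj) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Unordered diploid call pair + line ids from either marker container."""
    if isinstance(obj, HaplotypeMarkerSet):
        return obj.h1, obj.h2, obj.line_ids
    if isinstance(obj, GenotypeMatrix):
        return obj.a1, obj.a2, obj.line_ids
    raise TypeError(f"unsupported call container {type(obj)!r}")


def gsc_matrix(calls) -> GSCMatrix:
    """Pairwise genetic similarity coefficients.

    Per locus the similarity of two unordered diploid genotypes is the
    shared-allele count over 2: 1 if the genotypes are identical, 0.5 if
    they share exactly one allele, 0 otherwise.  The GSC of a pair is the
    mean over loci where both are called.
    """
    h1, h2, ids = _call_arrays(calls)
    n, m = h1.shape
    if n < 2 or m < 1:
        raise ValueError("need >= 2 individuals and >= 1 marker")
    called = h1 != MISSING
    values = np.ones((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(counts, called.sum(axis=1))
    a1 = h1.astype(np.int32)
    a2 = h2.astype(np.int32)
    for i in range(n):
        both = called[i][None, :] & called[i + 1 :]
        # best pairing of unordered pairs {a,b} vs {c,d}
        s = (a1[i][None, :] == a1[i + 1 :]).astype(np.int8) + (
            a2[i][None, :] == a2[i + 1 :]
        ).astype(np.int8)
        t = (a1[i][None, :] == a2[i + 1 :]).astype(np.int8) + (
            a2[i][None, :] == a1[i + 1 :]
        ).astype(np.int8)
        shared = np.maximum(s, t) / 2.0
        cnt = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            sim = np.where(cnt > 0, (shared * both).sum(axis=1) / np.maximum(cnt, 1), np.nan)
        values[i, i + 1 :] = sim
        values[i + 1 :, i] = sim
        counts[i, i + 1 :] = cnt
        counts[i + 1 :, i] = cnt
    n_empty = int(np.sum(np.isnan(values)) // 2)
    if n_empty:
        logger.warning("%d line pairs share no compared locus (GSC missing)", n_empty)
    return GSCMatrix(ids=list(ids), values=values, counts=counts)


@dataclass
class EigenStructure:
    """Top eigenvectors of the centered GSC with percent variance each."""

    ids: list[str]
    vectors: np.ndarray  # (n, n_vectors)
    percent_variance: np.ndarray  # (n_vectors,)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"EV{i + 1}" for i in range(self.vectors.shape[1])]
        return pd.DataFrame(self.vectors, index=self.ids, columns=cols)


def eigen_structure(
    gsc: GSCMatrix, n_vectors: int = 10, center: bool = True
) -> EigenStructure:
    """Eigendecomposition of the (double-centered) GSC matrix.

    Missing pair similarities are imputed to their column means (logged).
    Eigenvalues are reported as percent of the positive-eigenvalue total,
    sorted descending.
    """
    v = np.array(gsc.values, dtype=float)
    if v.shape[0] != v.shape[1]:
        raise ValueError("GSC must be square")
    finite = np.isfinite(v)
    if not finite.all():
        logger.info("imputing %d missing GSC entries to column means", int((~finite).sum()))
        colmean = np.nanmean(np.where(finite, v, np.nan), axis=0)
        ii, jj = np.where(~finite)
        v[ii, jj] = colmean[jj]
        v = (v + v.T) / 2.0
    if not np.allclose(v, v.T, atol=1e-10):
        raise ValueError("GSC matrix is not symmetric")
    n = v.shape[0]
    if center:
        h = np.eye(n) - np.ones((n, n)) / n
        v = h @ v @ h
    w, u = np.linalg.eigh(v)
    order = np.argsort(w)[::-1]
    w, u = w[order], u[:, order]
    pos_total = w[w > 0].sum()
    k = min(n_vectors, n)
    pct = 100.0 * w[:k] / pos_total if pos_total > 0 else np.zeros(k)
    return EigenStructure(ids=list(gsc.ids), vectors=u[:, :k], percent_variance=pct)


# ---------------------------------------------------------------------------
# introgression


@dataclass
class IntrogressionProfile:
    """Exotic-allele frequencies per subpopulation.

    ``locus_freq``: DataFrame (subpop, marker_id, chrom, pos_bp, freq, n)
    where ``freq`` is the exotic-carrier fraction among informative,
    called lines (heterozygous carriers count 0.5).
    ``line_fraction``: per-line mean carrier score over informative loci.
    ``chrom_mean``: per (subpop, chrom) mean locus frequency.
    """

    locus_freq: pd.DataFrame
    line_fraction: pd.Series
    chrom_mean: pd.DataFrame

    def genome_wide_mean(self, subpop: str | None = None) -> float:
        """Frequency pooled over all informative (line, locus) calls."""
        df = self.locus_freq
        if subpop is not None:
            df = df[df["subpop"] == subpop]
        return float((df["freq"] * df["n"]).sum() / df["n"].sum())


def exotic_allele_frequency(
    calls, families: pd.DataFrame
) -> IntrogressionProfile:
    """Exotic-allele frequency at each marker within each subpopulation.

    ``calls`` is a marker container (SNP or haplotype level) whose line
    table includes the parents (role ``parent``).  For each family, the
    informative loci are those where both its reference and exotic parent
    are homozygous, called, and carry different alleles; a line's carrier
    score at such a locus is the fraction of its two alleles matching the
    exotic parent (0, 0.5 or 1).  Frequencies aggregate carrier scores
    across the families sharing a reference parent.
    """
    h1, h2, ids = _call_arrays(calls)
    lt = calls.line_table
    if isinstance(calls, HaplotypeMarkerSet):
        mt = calls.marker_table()
        marker_ids = mt["marker_id"].to_numpy()
        chrom = mt["chrom"].to_numpy()
        bp = mt["pos_bp"].to_numpy()
    else:
        marker_ids = calls.snps["snp_id"].to_numpy()
        chrom = calls.snps["chrom"].to_numpy()
        bp = calls.snps["pos_bp"].to_numpy()
    m = h1.shape[1]
    row_of = {lid: i for i, lid in enumerate(ids)}

    score_sum = {}
    score_cnt = {}
    line_sum = np.zeros(len(ids))
    line_cnt = np.zeros(len(ids))
    fam_of_line = lt["family_id"].to_numpy()
    roles = lt["role"].to_numpy()

    for fam in families.itertuples(index=False):
        if fam.reference not in row_of or fam.exotic not in row_of:
            logger.warning("family %s missing a parent genotype; skipped", fam.family_id)
            continue
        rp, ep = row_of[fam.reference], row_of[fam.exotic]
        rp_hom = (h1[rp] == h2[rp]) & (h1[rp] != MISSING)
        ep_hom = (h1[ep] == h2[ep]) & (h1[ep] != MISSING)
        informative = rp_hom & ep_hom & (h1[rp] != h1[ep])
        rows = np.where((fam_of_line == fam.family_id) & (roles == "ril"))[0]
        if not len(rows) or not informative.any():
            continue
        exo = h1[ep]
        called = h1[rows] != MISSING
        score = (
            (h1[rows] == exo[None, :]).astype(float)
            + (h2[rows] == exo[None, :]).astype(float)
        ) / 2.0
        use = called & informative[None, :]
        sp = fam.reference
        if sp not in score_sum:
            score_sum[sp] = np.zeros(m)
            score_cnt[sp] = np.zeros(m)
        score_sum[sp] += np.where(use, score, 0.0).sum(axis=0)
        score_cnt[sp] += use.sum(axis=0)
        line_sum[rows] += np.where(use, score, 0.0).sum(axis=1)
        line_cnt[rows] += use.sum(axis=1)

    rows_out = []
    for sp in score_sum:
        cnt = score_cnt[sp]
        with np.errstate(invalid="ignore"):
            freq = np.where(cnt > 0, score_sum[sp] / np.maximum(cnt, 1), np.nan)
        for j in range(m):
            if cnt[j] > 0:
                rows_out.append(
                    (sp, marker_ids[j], chrom[j], int(bp[j]), float(freq[j]), int(cnt[j]))
                )
    locus_freq = pd.DataFrame(
        rows_out, columns=["subpop", "marker_id", "chrom", "pos_bp", "freq", "n"]
    )
    with np.errstate(invalid="ignore"):
        line_frac = pd.Series(
            np.where(line_cnt > 0, line_sum / np.maximum(line_cnt, 1), np.nan),
            index=ids,
            name="exotic_fraction",
        )
    line_frac = line_frac[roles == "ril"]
    chrom_mean = (
        locus_freq.groupby(["subpop", "chrom"], as_index=False)["freq"].mean()
    )
    return IntrogressionProfile(
        locus_freq=locus_freq, line_fraction=line_frac, chrom_mean=chrom_mean
    )


def introgression_tracks(
    profile: IntrogressionProfile,
    flag_threshold: float = 0.25,
    gap_bp: int = 10_000_000,
) -> pd.DataFrame:
    """BED-like per-chromosome tracks of exotic-allele frequency.

    Each marker covers the interval between the midpoints to its
    neighbours, truncated to at most ``gap_bp/2`` on each side; stretches
    farther than that from any marker are emitted as ``gap`` rows
    (marker-free regions).  Intervals are 0-based half-open (BED).  The
    ``flag`` column marks frequencies >= ``flag_threshold`` (the
    greater-or-equal rule) as ``high``, others ``low``.
    """
    hw = gap_bp // 2
    out = []
    for (sp, chrom), grp in profile.locus_freq.groupby(["subpop", "chrom"]):
        grp = grp.sort_values("pos_bp")
        pos0 = grp["pos_bp"].to_numpy(np.int64) - 1  # 0-based
        freqs = grp["freq"].to_numpy()
        nloc = len(pos0)
        for i in range(nloc):
            left = max(0, pos0[i] - hw)
            if i > 0:
                mid = (pos0[i - 1] + pos0[i] + 1) // 2
                left = max(left, mid)
            right = pos0[i] + hw + 1
            if i < nloc - 1:
                mid = (pos0[i] + pos0[i + 1] + 1) // 2
                right = min(right, mid)
            flag = "high" if freqs[i] >= flag_threshold else "low"
            out.append((sp, chrom, int(left), int(right), float(freqs[i]), flag))
            if i < nloc - 1:
                nxt = max(0, pos0[i + 1] - hw)
                mid = (pos0[i] + pos0[i + 1] + 1) // 2
                gap_left = right
                gap_right = max(nxt, mid) if pos0[i + 1] - pos0[i] > gap_bp else right
                if gap_right > gap_left:
                    out.append((sp, chrom, int(gap_left), int(gap_right), float("nan"), "gap"))
    return pd.DataFrame(
        out, columns=["subpop", "chrom", "start", "end", "freq", "flag"]
    )
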