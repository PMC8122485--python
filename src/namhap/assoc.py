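"""Two-stage multi-locus multi-allele association scan.

The scan tests multi-allelic haplotype markers against line-level BLUPs,
correcting for population structure with the top eigenvectors of the GSC
matrix as fixed covariates.  Each marker enters the linear model as
``n_alleles - 1`` additive dosage columns (reference allele = the most
frequent; heterozygotes dose 0.5), so a marker-trait association is a
general linear F-test with ``n_alleles - 1`` numerator degrees of
freedom.

Stage 1 preselects markers by a single-locus F-test at ``alpha``;
stage 2 builds a multi-locus model by forward selection alternated with
backward elimination at the same ``alpha`` (optionally Bonferroni-scaled
by the stage-1 count), reporting a partial (type-III) R^2 and per-allele
effects for each retained marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from namhap.markers import MISSING, HaplotypeMarkerSet
from namhap.popstruct import EigenStructure

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerDesign",
    "QTLResult",
    "build_marker_designs",
    "stage1_scan",
    "stage2_stepwise",
    "allele_effects",
    "annotate_known_genes",
    "results_table",
]


@dataclass
class MarkerDesign:
    """Additive allele-dosage design for one multi-allelic marker.

    ``columns[:, j]`` is the dosage (0/0.5/1, mean-imputed where the call
    is missing) of allele ``allele_codes[j + 1]``; ``allele_codes[0]`` is
    the reference allele, which carries no column.  Row dosages over the
    non-reference columns sum to at most 1.
    """

    marker_id: str
    chrom: str
    pos_bp: int
    allele_codes: list[int]
    freqs: np.ndarray  # per allele (same order as allele_codes)
    columns: np.ndarray  # (n_lines, n_alleles - 1)

    @property
    def n_alleles(self) -> int:
        return len(self.allele_codes)


@dataclass
class QTLResult:
    """One retained QTL: marker, significance, variance explained, effects."""

    marker_id: str
    chrom: str
    pos_bp: int
    n_alleles: int
    p_value: float
    r2_percent: float
    allele_effects: dict[int, float] = field(default_factory=dict)
    gene: str = "-"


# ---------------------------------------------------------------------------
# design preparation


def _eigen_frame(eigenvectors) -> pd.DataFrame:
    if isinstance(eigenvectors, EigenStructure):
        return eigenvectors.to_frame()
    if isinstance(eigenvectors, pd.DataFrame):
        return eigenvectors
    raise TypeError("eigenvectors must be an EigenStructure or DataFrame")


def _align_lines(
    hms: HaplotypeMarkerSet, blups: pd.Series, ev: pd.DataFrame
) -> list[str]:
    roles = hms.line_table["role"].to_numpy()
    usable = set(blups.index) & set(ev.index)
    return [
        lid
        for lid, role in zip(hms.line_ids, roles)
        if role == "ril" and lid in usable
    ]


def build_marker_designs(
    hms: HaplotypeMarkerSet, line_ids: list[str]
) -> list[MarkerDesign]:
    """Dosage designs for the given analysis lines (markers monomorphic
    among them are skipped with a log entry)."""
    row_of = {lid: i for i, lid in enumerate(hms.line_ids)}
    rows = np.array([row_of[lid] for lid in line_ids])
    designs = []
    n_mono = 0
    for j, marker in enumerate(hms.markers):
        h1 = hms.h1[rows, j]
        h2 = hms.h2[rows, j]
        called = h1 != MISSING
        obs = np.unique(np.concatenate([h1[called], h2[called]]))
        if len(obs) < 2:
            n_mono += 1
            continue
        dos = np.stack(
            [
                ((h1 == a).astype(float) + (h2 == a).astype(float)) / 2.0
                for a in obs
            ],
            axis=1,
        )
        dos[~called] = np.nan
        freqs = np.nanmean(dos, axis=0)
        order = np.argsort(-freqs, kind="stable")  # most frequent first
        obs = obs[order]
        freqs = freqs[order]
        cols = dos[:, order[1:]]
        colmean = np.nanmean(cols, axis=0)
        nanmask = np.isnan(cols)
        if nanmask.any():
            cols[nanmask] = np.broadcast_to(colmean, cols.shape)[nanmask]
        designs.append(
            MarkerDesign(
                marker_id=marker.marker_id,
                chrom=marker.chrom,
                pos_bp=marker.pos_bp,
                allele_codes=[int(a) for a in obs],
                freqs=freqs,
                columns=cols,
            )
        )
    if n_mono:
        logger.info("%d markers monomorphic in the analysed lines; skipped", n_mono)
    return designs


def _prepare(
    hms: HaplotypeMarkerSet,
    blups: pd.Series,
    eigenvectors,
    n_eigenvectors: int,
):
    ev = _eigen_frame(eigenvectors)
    lines = _align_lines(hms, blups, ev)
    if len(lines) < 3:
        raise ValueError("fewer than 3 aligned analysis lines")
    y = blups.loc[lines].to_numpy(float)
    k = min(n_eigenvectors, ev.shape[1])
    x0 = np.column_stack([np.ones(len(lines)), ev.loc[lines].to_numpy(float)[:, :k]])
    designs = build_marker_designs(hms, lines)
    return y, x0, designs, lines


def _rss_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    coef, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if res.size:
        rss = float(res[0])
    else:
        r = y - x @ coef
        rss = float(r @ r)
    return rss, int(rank)


def _partial_f(
    x_base: np.ndarray, x_full: np.ndarray, y: np.ndarray
) -> tuple[float, float, int] | None:
    """F-test of the columns in ``x_full`` beyond ``x_base``; None when the
    added columns are collinear with the base."""
    rss0, rank0 = _rss_rank(x_base, y)
    rss1, rank1 = _rss_rank(x_full, y)
    df1 = rank1 - rank0
    n = len(y)
    df2 = n - rank1
    if df1 < 1 or df2 < 1:
        return None
    num = max(rss0 - rss1, 0.0) / df1
    den = rss1 / df2
    if den <= 0:
        return (np.inf, 0.0, df1)
    f = num / den
    return (f, float(stats.f.sf(f, df1, df2)), df1)


# ---------------------------------------------------------------------------
# stage 1


def stage1_scan(
    hms: HaplotypeMarkerSet,
    blups: pd.Series,
    eigenvectors,
    alpha: float = 0.0005,
    n_eigenvectors: int = 10,
    return_all: bool = False,
) -> pd.DataFrame:
    """Single-locus preselection scan.

    Each marker's dosage columns are F-tested against the covariate-only
    model (intercept + eigenvectors); markers with p <= ``alpha`` are
    returned sorted by p (all tested markers with ``return_all=True``).
    """
    y, x0, designs, _ = _prepare(hms, blups, eigenvectors, n_eigenvectors)
    rows = []
    for d in designs:
        res = _partial_f(x0, np.hstack([x0, d.columns]), y)
        if res is None:
            logger.info("marker %s collinear with covariates; skipped", d.marker_id)
            continue
        f, p, df1 = res
        rows.append((d.marker_id, d.chrom, d.pos_bp, d.n_alleles, df1, f, p))
    out = pd.DataFrame(
        rows, columns=["marker_id", "chrom", "pos_bp", "n_alleles", "df1", "F", "p"]
    )
    out = out.sort_values(["p", "chrom", "pos_bp"], kind="stable").reset_index(drop=True)
    if return_all:
        out["selected"] = out["p"] <= alpha
        return out
    return out[out["p"] <= alpha].reset_index(drop=True)


# ---------------------------------------------------------------------------
# stage 2


def stage2_stepwise(
    hms: HaplotypeMarkerSet,
    preselected: pd.DataFrame,
    blups: pd.Series,
    eigenvectors,
    alpha: float = 0.0005,
    n_eigenvectors: int = 10,
    bonferroni: bool = False,
) -> list[QTLResult]:
    """Stepwise multi-locus model over the stage-1 markers.

    Forward selection (add the candidate with the smallest partial p, if
    <= alpha) alternates with backward elimination (drop any included
    marker whose partial p given the others exceeds alpha) until the
    model is stable.  With ``bonferroni=True`` alpha is divided by the
    stage-1 marker count.  Each retained marker is reported with its
    partial (type-III) R^2 = partial SS / total corrected SS x 100 and
    frequency-centred per-allele effects; results sort by p ascending.
    """
    if preselected is None or len(preselected) == 0:
        return []
    y, x0, designs, _ = _prepare(hms, blups, eigenvectors, n_eigenvectors)
    dmap = {d.marker_id: d for d in designs}
    cand_ids = [m for m in preselected["marker_id"] if m in dmap]
    if bonferroni:
        alpha = alpha / max(len(cand_ids), 1)

    included: list[str] = []

    def model_matrix(ids: list[str]) -> np.ndarray:
        cols = [x0] + [dmap[m].columns for m in ids]
        return np.hstack(cols)

    changed = True
    n_outer = 0
    while changed and n_outer < 100:
        n_outer += 1
        changed = False
        # forward
        while True:
            base = model_matrix(included)
            best = None
            for m in cand_ids:
                if m in included:
                    continue
                d = dmap[m]
                res = _partial_f(base, np.hstack([base, d.columns]), y)
                if res is None:
                    continue
                _, p, _ = res
                key = (p, d.chrom, d.pos_bp, m)
                if best is None or key < best[0]:
                    best = (key, m)
            if best is not None and best[0][0] <= alpha:
                included.append(best[1])
                changed = True
            else:
                break
        # backward
        while len(included) > 0:
            worst = None
            full = model_matrix(included)
            for m in included:
                rest = model_matrix([i for i in included if i != m])
                res = _partial_f(rest, full, y)
                p = res[1] if res is not None else 1.0
                if worst is None or p > worst[0]:
                    worst = (p, m)
            if worst is not None and worst[0] > alpha:
                included.remove(worst[1])
                changed = True
            else:
                break

    if not included:
        return []

    full = model_matrix(included)
    rss_full, _ = _rss_rank(full, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    results = []
    for m in included:
        d = dmap[m]
        rest = model_matrix([i for i in included if i != m])
        res = _partial_f(rest, full, y)
        p = res[1] if res is not None else np.nan
        rss_rest, _ = _rss_rank(rest, y)
        partial_ss = max(rss_rest - rss_full, 0.0)
        r2 = 100.0 * partial_ss / tss if tss > 0 else np.nan
        effects = _allele_effects_from_fit(full, y, included, dmap, m)
        results.append(
            QTLResult(
                marker_id=m,
                chrom=d.chrom,
                pos_bp=d.pos_bp,
                n_alleles=d.n_alleles,
                p_value=p,
                r2_percent=r2,
                allele_effects=effects,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.chrom, r.pos_bp))
    return results


def _allele_effects_from_fit(
    full: np.ndarray,
    y: np.ndarray,
    included: list[str],
    dmap: dict[str, MarkerDesign],
    marker_id: str,
) -> dict[int, float]:
    coef, *_ = np.linalg.lstsq(full, y, rcond=None)
    # locate this marker's coefficient block
    offset = full.shape[1] - sum(dmap[m].columns.shape[1] for m in included)
    for m in included:
        w = dmap[m].columns.shape[1]
        if m == marker_id:
            beta = np.concatenate([[0.0], coef[offset : offset + w]])
            d = dmap[m]
            mean = float(np.sum(d.freqs * beta))
            return {a: float(b - mean) for a, b in zip(d.allele_codes, beta)}
        offset += w
    raise KeyError(marker_id)


def allele_effects(
    hms: HaplotypeMarkerSet,
    blups: pd.Series,
    eigenvectors,
    included: list[str],
    marker_id: str,
    n_eigenvectors: int = 10,
) -> dict[int, float]:
    """Per-allele effects of ``marker_id`` in the multi-locus model that
    contains ``included`` markers, expressed relative to the
    frequency-weighted mean (so the weighted effects sum to zero)."""
    y, x0, designs, _ = _prepare(hms, blups, eigenvectors, n_eigenvectors)
    dmap = {d.marker_id: d for d in designs}
    full = np.hstack([x0] + [dmap[m].columns for m in included])
    return _allele_effects_from_fit(full, y, included, dmap, marker_id)


# ---------------------------------------------------------------------------
# reporting


def annotate_known_genes(
    results: list[QTLResult],
    anchors: pd.DataFrame,
    window_bp: int = 0,
) -> list[QTLResult]:
    """Label results that hit a known-gene anchor marker.

    ``anchors`` columns: marker_id, gene, and optionally chrom/pos_bp for
    positional matching within ``window_bp`` base pairs.
    """
    by_id = dict(zip(anchors["marker_id"], anchors["gene"]))
    out = []
    for r in results:
        gene = by_id.get(r.marker_id, "-")
        if gene == "-" and {"chrom", "pos_bp"} <= set(anchors.columns):
            near = anchors[
                (anchors["chrom"] == r.chrom)
                & ((anchors["pos_bp"] - r.pos_bp).abs() <= window_bp)
            ]
            if len(near):
                near = near.assign(dist=(near["pos_bp"] - r.pos_bp).abs())
                gene = near.sort_values(["dist", "marker_id"]).iloc[0]["gene"]
        out.append(replace(r, gene=gene))
    return out


def results_table(
    results: list[QTLResult], trait: str = "", environment: str = ""
) -> pd.DataFrame:
    """QTL report shaped like a trait x environment association table."""
    return pd.DataFrame(
        [
            (
                trait,
                environment,
                r.marker_id,
                r.chrom,
                r.n_alleles,
                r.gene,
                r.p_value,
                r.r2_percent,
            )
            for r in results
        ],
        columns=[
            "trait",
            "environment",
            "marker",
            "chromosome",
            "n_alleles",
            "corresponding_gene",
            "p_value",
            "R2_percent",
        ],
    )
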