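"""File formats: VCF 4.2 genotypes, map/phenotype/marker tables.

Coordinate conventions: ``pos_bp`` is 1-based inclusive (the VCF
convention) everywhere in memory and in the map TSV; only the BED-like
introgression track export uses 0-based half-open intervals, converted in
:func:`namhap.popstruct.introgression_tracks`.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from namhap.markers import MISSING, GenotypeMatrix, HaplotypeMarker, HaplotypeMarkerSet

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_map_tsv",
    "read_map_tsv",
    "write_haplotype_markers",
    "read_haplotype_markers",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
]

_BASES = ["A", "C", "G", "T"]


def _allele_token(code: int) -> str:
    """Deterministic nucleotide-string token for an integer allele code."""
    if code < 4:
        return _BASES[code]
    return _BASES[code % 4] * (code // 4 + 1)


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a GenotypeMatrix as VCF 4.2 with GT fields ('.' for missing).

    Allele code ``c`` at a SNP becomes ALT index ``c`` (code 0 is REF);
    tokens are synthetic nucleotide strings.  Sample order follows the
    line table; line metadata are not stored in the VCF (the map TSV and
    a line-assignment table carry them).
    """
    snps = matrix.snps
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=namhap\n")
        for chrom in pd.unique(snps["chrom"]):
            mx = int(snps.loc[snps["chrom"] == chrom, "pos_bp"].max())
            fh.write(f"##contig=<ID={chrom},length={mx + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.line_ids)
            + "\n"
        )
        for j in range(matrix.n_snps):
            a1 = matrix.a1[:, j]
            a2 = matrix.a2[:, j]
            called = a1 != MISSING
            max_code = int(max(a1[called].max(), a2[called].max())) if called.any() else 0
            n_alt = max(max_code, 1)
            ref = _allele_token(0)
            alts = ",".join(_allele_token(c) for c in range(1, n_alt + 1))
            gts = []
            for i in range(matrix.n_lines):
                if a1[i] == MISSING:
                    gts.append("./.")
                else:
                    gts.append(f"{a1[i]}/{a2[i]}")
            fh.write(
                f"{snps['chrom'].iat[j]}\t{snps['pos_bp'].iat[j]}\t"
                f"{snps['snp_id'].iat[j]}\t{ref}\t{alts}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(
    path: str | os.PathLike,
    map_path: str | os.PathLike | None = None,
    line_table: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Read a VCF 4.2 into a GenotypeMatrix.

    Allele codes are GT allele indices (REF = 0).  Genetic-map cM
    positions and marker classes are merged from ``map_path`` (a map TSV)
    when given, else every SNP is treated as codominant with pos_cM NaN.
    ``line_table`` supplies family/background/role per sample; samples
    not listed default to role ``ril`` with empty family/background.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    calls1 = []
    calls2 = []
    for lineno, var in enumerate(vcf):
        if var.gt_types is None:  # pragma: no cover - cyvcf2 always sets this
            raise ValueError(f"malformed record at variant {lineno + 1}")
        rows.append((var.ID, var.CHROM, np.nan, int(var.POS), "codominant"))
        g = np.array([[gt[0], gt[1]] for gt in var.genotypes], dtype=np.int16)
        a1 = np.minimum(g[:, 0], g[:, 1])
        a2 = np.maximum(g[:, 0], g[:, 1])
        missing = (g[:, 0] < 0) | (g[:, 1] < 0)
        a1[missing] = MISSING
        a2[missing] = MISSING
        calls1.append(a1)
        calls2.append(a2)
    snps = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos_cM", "pos_bp", "marker_class"]
    )
    if map_path is not None:
        gm = read_map_tsv(map_path)
        merged = snps[["snp_id", "chrom", "pos_bp"]].merge(
            gm[["snp_id", "pos_cM", "marker_class"]], on="snp_id", how="left"
        )
        merged["marker_class"] = merged["marker_class"].fillna("codominant")
        snps = merged[["snp_id", "chrom", "pos_cM", "pos_bp", "marker_class"]]
    if line_table is None:
        line_table = pd.DataFrame(
            {
                "line_id": samples,
                "family_id": "",
                "background": "",
                "role": "ril",
            }
        )
    else:
        line_table = (
            pd.DataFrame({"line_id": samples})
            .merge(line_table, on="line_id", how="left")
            .fillna({"family_id": "", "background": "", "role": "ril"})
        )
    a1 = np.column_stack(calls1) if calls1 else np.empty((len(samples), 0), np.int16)
    a2 = np.column_stack(calls2) if calls2 else np.empty((len(samples), 0), np.int16)
    return GenotypeMatrix(line_table=line_table, snps=snps, a1=a1, a2=a2)


# ---------------------------------------------------------------------------
# map / phenotype tables


def write_map_tsv(gmap, path: str | os.PathLike) -> None:
    tbl = gmap.table.copy()
    tbl["length_cM"] = tbl["chrom"].map(gmap.lengths_cM)
    tbl.to_csv(path, sep="\t", index=False)


def read_map_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_genetic_map(path: str | os.PathLike):
    """Read a map TSV (with a length_cM column) back into a GeneticMap."""
    from namhap.simcore import GeneticMap

    tbl = read_map_tsv(path)
    lengths = dict(
        tbl.groupby("chrom", sort=False)["length_cM"].first()
        if "length_cM" in tbl
        else tbl.groupby("chrom", sort=False)["pos_cM"].max()
    )
    cols = ["snp_id", "chrom", "pos_cM", "pos_bp", "marker_class"]
    return GeneticMap(tbl[cols], {k: float(v) for k, v in lengths.items()})


def write_phenotypes_csv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, index=False)


def read_phenotypes_csv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# haplotype markers


def write_haplotype_markers(
    hms: HaplotypeMarkerSet, definition_path: str | os.PathLike, calls_path: str | os.PathLike
) -> None:
    """Write (a) a marker-definition TSV (members and allele dictionary)
    and (b) a line x marker allele-index call TSV ('-1/-1' kept numeric,
    het calls as 'i/j')."""
    rows = []
    for m in hms.markers:
        allele_dict = ";".join(f"{h}={i}" for h, i in m.alleles.items())
        rows.append(
            (m.marker_id, m.chrom, m.pos_bp, ",".join(m.member_snps), allele_dict)
        )
    pd.DataFrame(
        rows, columns=["marker_id", "chrom", "pos_bp", "member_snps", "alleles"]
    ).to_csv(definition_path, sep="\t", index=False)

    cols = {}
    for j, m in enumerate(hms.markers):
        col = []
        for i in range(hms.n_lines):
            if hms.h1[i, j] == MISSING:
                col.append(".")
            elif hms.h1[i, j] == hms.h2[i, j]:
                col.append(str(int(hms.h1[i, j])))
            else:
                col.append(f"{int(hms.h1[i, j])}/{int(hms.h2[i, j])}")
        cols[m.marker_id] = col
    calls = pd.DataFrame(cols, index=hms.line_ids)
    meta = hms.line_table.set_index("line_id")[["family_id", "background", "role"]]
    out = meta.join(calls)
    out.index.name = "line_id"
    out.to_csv(calls_path, sep="\t")


def read_haplotype_markers(
    definition_path: str | os.PathLike, calls_path: str | os.PathLike
) -> HaplotypeMarkerSet:
    defs = pd.read_csv(definition_path, sep="\t")
    markers = []
    for row in defs.itertuples(index=False):
        alleles = {}
        for part in str(row.alleles).split(";"):
            h, i = part.rsplit("=", 1)
            alleles[h] = int(i)
        markers.append(
            HaplotypeMarker(
                marker_id=row.marker_id,
                chrom=str(row.chrom),
                pos_bp=int(row.pos_bp),
                member_snps=str(row.member_snps).split(","),
                alleles=alleles,
            )
        )
    calls = pd.read_csv(calls_path, sep="\t", dtype=str).set_index("line_id")
    line_table = calls[["family_id", "background", "role"]].reset_index()
    line_table["family_id"] = line_table["family_id"].fillna("")
    line_table["background"] = line_table["background"].fillna("")
    n = len(line_table)
    h1 = np.full((n, len(markers)), MISSING, dtype=np.int16)
    h2 = np.full((n, len(markers)), MISSING, dtype=np.int16)
    for j, m in enumerate(markers):
        col = calls[m.marker_id]
        for i, v in enumerate(col):
            if v == ".":
                continue
            if "/" in v:
                x, y = v.split("/")
                h1[i, j], h2[i, j] = int(x), int(y)
            else:
                h1[i, j] = h2[i, j] = int(v)
    return HaplotypeMarkerSet(markers=markers, line_table=line_table, h1=h1, h2=h2)
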