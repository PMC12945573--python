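"""VCF / BED / TSV readers and writers.

Reading goes through cyvcf2; writing emits plain uncompressed VCF text
(bgzip-compatible). Coordinates are 1-based inclusive internally; BED
is converted to and from 0-based half-open at the boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, HaplotypePanel
from .qc import SiteRecord

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=panelkit
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed dosage">
"""


def write_vcf(
    path,
    data: HaplotypePanel | GenotypeMatrix,
    dp: np.ndarray | None = None,
    gq: np.ndarray | None = None,
    dosages: np.ndarray | None = None,
) -> None:
    """Write a panel or genotype matrix as uncompressed VCF.

    Haplotype panels write phased GT ("0|1"); genotype matrices write
    unphased GT ("0/1", "./." for missing). Optional per-call DP/GQ
    matrices and a DS dosage matrix add FORMAT fields.
    """
    if isinstance(data, HaplotypePanel):
        samples = data.samples
        variants = data.variants

        def gt(i, k):
            a = data.haplotypes[2 * k, i]
            b = data.haplotypes[2 * k + 1, i]
            return f"{a}|{b}"

    else:
        samples = data.samples
        variants = data.variants
        _GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}

        def gt(i, k):
            v = data.dosages[k, i]
            return "./." if np.isnan(v) else _GT[v]

    fmt = ["GT"]
    if dp is not None:
        fmt.append("DP")
    if gq is not None:
        fmt.append("GQ")
    if dosages is not None:
        fmt.append("DS")
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for chrom in variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for i, row in enumerate(variants.itertuples(index=False)):
            fields = [
                str(row.chrom), str(row.pos), str(row.id), str(row.ref),
                str(row.alt), ".", "PASS", ".", ":".join(fmt),
            ]
            calls = []
            for k in range(len(samples)):
                parts = [gt(i, k)]
                if dp is not None:
                    parts.append(str(int(dp[k, i])))
                if gq is not None:
                    parts.append(str(int(gq[k, i])))
                if dosages is not None:
                    parts.append(f"{dosages[k, i]:.4f}")
                calls.append(":".join(parts))
            fh.write("\t".join(fields) + "\t" + "\t".join(calls) + "\n")


def read_vcf(path, want: str = "genotypes", drop_filtered: bool = False):
    """Parse a VCF into the requested container.

    want="haplotypes" -> (HaplotypePanel, n_multiallelic_skipped);
    unphased GT is an error. want="genotypes" -> (GenotypeMatrix, n).
    want="records" -> (list[SiteRecord] with DP/GQ, n).
    want="dosages" -> ((dosage matrix, variant table, samples), n).
    Multi-allelic records are skipped and counted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    meta = []
    n_multi = 0
    dp_rows, gq_rows, ds_rows = [], [], []
    for line_no, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if drop_filtered and var.FILTER is not None:
            continue
        meta.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}", var.REF, var.ALT[0]))
        gts = var.genotypes  # [allele0, allele1, phased]
        if want == "haplotypes":
            hap_pair = []
            for g in gts:
                if len(g) < 3 or not g[2]:
                    raise ValueError(
                        f"unphased genotype at record {line_no} ({var.CHROM}:{var.POS}); "
                        "haplotype mode requires phased GT"
                    )
                if g[0] < 0 or g[1] < 0:
                    raise ValueError(
                        f"missing genotype at record {line_no}; haplotype mode requires complete calls"
                    )
                hap_pair.append((g[0], g[1]))
            rows.append(hap_pair)
        else:
            geno = []
            for g in gts:
                if g[0] < 0 or g[1] < 0:
                    geno.append(np.nan)
                else:
                    geno.append(float(g[0] + g[1]))
            rows.append(geno)
            if want == "records":
                dp = var.format("DP")
                gq = var.format("GQ")
                dp_rows.append(None if dp is None else dp.ravel().astype(float))
                gq_rows.append(None if gq is None else gq.ravel().astype(float))
            if want == "dosages":
                ds = var.format("DS")
                ds_rows.append(
                    np.asarray(geno, dtype=float) if ds is None else ds.ravel().astype(float)
                )
    variants = pd.DataFrame(meta, columns=["chrom", "pos", "id", "ref", "alt"])
    if want == "haplotypes":
        hap = np.empty((2 * len(samples), len(rows)), dtype=np.uint8)
        for i, pairs in enumerate(rows):
            for k, (a, b) in enumerate(pairs):
                hap[2 * k, i] = a
                hap[2 * k + 1, i] = b
        return HaplotypePanel(hap, variants, samples), n_multi
    if want == "genotypes":
        mat = np.asarray(rows, dtype=float).T if rows else np.empty((len(samples), 0))
        return GenotypeMatrix(mat, variants, samples), n_multi
    if want == "records":
        records = []
        for i, geno in enumerate(rows):
            records.append(
                SiteRecord(
                    chrom=str(variants["chrom"][i]),
                    pos=int(variants["pos"][i]),
                    id=str(variants["id"][i]),
                    ref=str(variants["ref"][i]),
                    alt=str(variants["alt"][i]),
                    genotypes=np.asarray(geno, dtype=float),
                    dp=dp_rows[i],
                    gq=gq_rows[i],
                )
            )
        return records, n_multi
    if want == "dosages":
        mat = np.asarray(ds_rows, dtype=float).T if ds_rows else np.empty((len(samples), 0))
        return (mat, variants, samples), n_multi
    raise ValueError(f"unknown mode {want!r}")


def write_bed(path, intervals: pd.DataFrame) -> None:
    """Write chrom/start/end (already 0-based half-open) as BED."""
    intervals.to_csv(path, sep="\t", header=False, index=False)


def read_kinship_tsv(path) -> pd.DataFrame:
    """3-column kinship table: id1, id2, kinship."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["id1", "id2", "kinship"] + list(df.columns[3:])
    return df


def records_to_genotype_matrix(records) -> GenotypeMatrix:
    """Assemble QC'ed site records back into a GenotypeMatrix."""
    if not records:
        raise ValueError("no records")
    n = records[0].genotypes.size
    mat = np.stack([r.genotypes for r in records], axis=1)
    variants = pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "id": [r.id for r in records],
            "ref": [r.ref for r in records],
            "alt": [r.alt for r in records],
        }
    )
    return GenotypeMatrix(mat, variants, [f"S{i}" for i in range(n)])
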