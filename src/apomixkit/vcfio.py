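"""VCF / GFF3 input and output.

Reading goes through cyvcf2 (htslib); writing emits minimal spec-conformant
VCF 4.2 text so that synthetic cohorts round-trip through the same reader the
analyses use.  Positions are converted between VCF 1-based and the package's
0-based half-open convention here and nowhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, SV_TYPES, GenotypeMatrix, VariantTable


class VCFParseError(ValueError):
    pass


@dataclass
class ReadOptions:
    multiallelic: str = "drop"  # or "split"
    keep_indels: bool = False


def read_vcf(path, options: ReadOptions | None = None):
    """Read a VCF into (VariantTable, GenotypeMatrix).

    Multi-allelic records are dropped (default) or split into one biallelic
    record per ALT.  Records with an unrecognised SVTYPE are skipped and
    counted in a single summary warning.  INFO keys used: SIFT (float),
    SVTYPE, SVLEN, AA.
    """
    options = options or ReadOptions()
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare exceptions on malformed input
        raise VCFParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, dosages, haps = [], [], []
    n_skipped_svtype = 0
    phased_all = True
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1:
            if options.multiallelic == "drop" or not alts:
                continue
        svtype = rec.INFO.get("SVTYPE")
        if svtype is not None and svtype not in SV_TYPES:
            n_skipped_svtype += 1
            continue
        for ai, alt in enumerate(alts):
            if svtype is None:
                if len(rec.REF) == 1 and len(alt) == 1:
                    vtype = "SNP"
                elif options.keep_indels:
                    vtype = "DEL" if len(rec.REF) > len(alt) else "INS"
                else:
                    continue
            else:
                vtype = svtype
            svlen = rec.INFO.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[ai]
            svlen = abs(int(svlen)) if svlen is not None else (
                np.nan if vtype == "SNP" else abs(len(rec.REF) - len(alt)) or np.nan
            )
            sift = rec.INFO.get("SIFT") if vtype == "SNP" else None
            aa = rec.INFO.get("AA")
            if aa is None:
                ancestral = "unknown"
            elif aa == rec.REF:
                ancestral = "ref"
            elif aa == alt:
                ancestral = "alt"
            else:
                ancestral = "unknown"
            dos = np.full(len(samples), MISSING, dtype=np.int8)
            hap = np.zeros((len(samples), 2), dtype=np.int8)
            want = ai + 1
            for si, gt in enumerate(rec.genotypes):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    continue
                dos[si] = sum(a == want for a in alleles)
                hap[si] = [1 if a == want else 0 for a in alleles[:2]]
                phased_all = phased_all and bool(gt[-1])
            rows.append(
                (rec.CHROM, rec.POS - 1, rec.REF, alt, vtype, svlen,
                 float(sift) if sift is not None else np.nan, bool(rec.INFO.get("LOF")),
                 ancestral)
            )
            dosages.append(dos)
            haps.append(hap)
    if n_skipped_svtype:
        warnings.warn(f"skipped {n_skipped_svtype} records with unknown SVTYPE")
    from .core import VARIANT_COLUMNS

    vt = VariantTable(pd.DataFrame(rows, columns=VARIANT_COLUMNS))
    dosage = np.array(dosages, dtype=np.int8).T if dosages else np.zeros((len(samples), 0), np.int8)
    hap_arr = None
    if phased_all and haps:
        hap_arr = np.array(haps, dtype=np.int8).transpose(1, 2, 0)
    gm = GenotypeMatrix(samples, dosage, hap_arr)
    return vt, gm


def write_vcf(vt: VariantTable, gm: GenotypeMatrix, path,
              contig_lengths: dict[str, int] | None = None, phased: bool = False) -> None:
    """Write a biallelic VCF 4.2.  Internal 0-based positions become 1-based."""
    df = vt.df
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=SIFT,Number=1,Type=Float,Description="SIFT score">\n')
        fh.write('##INFO=<ID=LOF,Number=0,Type=Flag,Description="loss of function">\n')
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        sep = "|" if phased and gm.haplotypes is not None else "/"
        for j in range(len(df)):
            row = df.iloc[j]
            info = []
            if row.vtype != "SNP":
                info.append(f"SVTYPE={row.vtype}")
                if not pd.isna(row.svlen):
                    sign = -1 if row.vtype == "DEL" else 1
                    info.append(f"SVLEN={sign * int(row.svlen)}")
            if not pd.isna(row.sift_score):
                info.append(f"SIFT={row.sift_score:.4f}")
            if row.lof_flag:
                info.append("LOF")
            if row.ancestral == "ref":
                info.append(f"AA={row.ref}")
            elif row.ancestral == "alt":
                info.append(f"AA={row.alt}")
            gts = []
            for i in range(len(gm.samples)):
                d = gm.dosage[i, j]
                if d == MISSING:
                    gts.append(f".{sep}.")
                elif sep == "|":
                    a, b = gm.haplotypes[i, :, j]
                    gts.append(f"{a}|{b}")
                else:
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                + (";".join(info) or ".") + "\tGT\t" + "\t".join(gts) + "\n"
            )


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene intervals (chrom, start, end, gene_id; 0-based half-open)
    as GFF3 gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(f"{g.chrom}\tapomixkit\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                     f"ID={g.gene_id}\n")


def read_genes_gff3(path) -> pd.DataFrame:
    """Read gene features from GFF3 into (chrom, start, end, gene_id),
    0-based half-open."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append((feat.seqid, feat.start - 1, feat.end, gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
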