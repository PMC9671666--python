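"""Per-individual deleterious load and hemizygosity.

Deleterious SNPs are defined by SIFT score <= 0.05 (inclusive), LOF by the
annotation flag, and SVs of the configured classes are counted as deleterious
wholesale.  Load is summarised per sample under an additive model (allele
count: het + 2*hom) and a recessive model (homozygous-genotype count) —
heterozygous variants are sheltered from recessive selection, which is the
mechanism by which clonal apomicts accumulate hidden load.

Hemizygosity: a gene is hemizygous when heterozygous deletions remove more
than ``overlap_frac`` (strictly) of its length on one haplotype; g_h is the
fraction of such genes per genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeMatrix, PopulationMap, VariantTable

SV_DELETERIOUS_DEFAULT = frozenset({"DEL", "DUP", "TRA", "INV"})


@dataclass
class DeleteriousSet:
    """Variant indices per deleterious class; classes may overlap (a LOF SNP
    with low SIFT appears in both ``deleterious_snp`` and ``lof``)."""

    deleterious_snp: np.ndarray
    lof: np.ndarray
    deleterious_sv: np.ndarray
    sift_threshold: float
    sv_classes: frozenset

    @property
    def all_indices(self) -> np.ndarray:
        return np.unique(np.concatenate([self.deleterious_snp, self.lof, self.deleterious_sv]))

    def counts(self) -> dict[str, int]:
        return {
            "deleterious_snp": len(self.deleterious_snp),
            "lof": len(self.lof),
            "deleterious_sv": len(self.deleterious_sv),
        }


def classify_deleterious(
    vt: VariantTable,
    sift_threshold: float = 0.05,
    include_lof: bool = True,
    sv_classes=SV_DELETERIOUS_DEFAULT,
) -> DeleteriousSet:
    """Classify variants into deleterious-SNP / LOF / deleterious-SV sets."""
    df = vt.df
    sift = df["sift_score"].to_numpy()
    del_snp = np.flatnonzero((df["vtype"] == "SNP") & (sift <= sift_threshold))
    lof = np.flatnonzero(df["lof_flag"].to_numpy()) if include_lof else np.array([], dtype=int)
    del_sv = np.flatnonzero(df["vtype"].isin(sv_classes).to_numpy())
    if del_snp.size == 0 and lof.size == 0 and del_sv.size == 0:
        warnings.warn("no variants classified as deleterious; check annotations")
    return DeleteriousSet(del_snp, lof, del_sv, sift_threshold, frozenset(sv_classes))


@dataclass
class BurdenSummary:
    """Per sample x class: het/hom genotype counts and derived burdens.

    additive = n_het + 2 * n_hom (allele dosage); recessive = n_hom.
    """

    table: pd.DataFrame  # sample, class, n_het, n_hom, additive_burden, recessive_burden

    def of(self, klass: str) -> pd.DataFrame:
        return self.table[self.table["class"] == klass].set_index("sample")


def burden_per_sample(
    gm: GenotypeMatrix,
    vt: VariantTable,
    dset: DeleteriousSet,
    count_mode: str = "allele",
) -> BurdenSummary:
    """Count deleterious load per sample for every class and pooled.

    ``count_mode='allele'`` makes additive = het + 2*hom; ``'variant'`` counts
    each carried variant once (het + hom).  Missing genotypes contribute
    nothing; all-missing samples come out zero.
    """
    if count_mode not in {"allele", "variant"}:
        raise ValueError(f"unknown count_mode {count_mode!r}")
    classes = {
        "deleterious_snp": dset.deleterious_snp,
        "lof": dset.lof,
        "deleterious_sv": dset.deleterious_sv,
        "pooled": dset.all_indices,
    }
    rows = []
    for klass, idx in classes.items():
        sub = gm.dosage[:, idx]
        n_het = np.sum(sub == 1, axis=1)
        n_hom = np.sum(sub == 2, axis=1)
        additive = n_het + (2 if count_mode == "allele" else 1) * n_hom
        for i, s in enumerate(gm.samples):
            rows.append((s, klass, int(n_het[i]), int(n_hom[i]),
                         int(additive[i]), int(n_hom[i])))
    return BurdenSummary(pd.DataFrame(
        rows, columns=["sample", "class", "n_het", "n_hom",
                       "additive_burden", "recessive_burden"]))


# ---------------------------------------------------------------------------
# hemizygosity


@dataclass
class HemizygosityResult:
    n_genes: int
    n_hemizygous: int
    g_h: float
    hemizygous_genes: list[str] = field(default_factory=list)


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/abutting [start, end) intervals (n x 2)."""
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    merged = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


def hemizygous_fraction(
    genes: pd.DataFrame,
    het_deletions: pd.DataFrame,
    overlap_frac: float = 0.5,
    strict: bool = True,
) -> HemizygosityResult:
    """Fraction of genes with more than ``overlap_frac`` of their length under
    merged heterozygous deletions (strict '>' by default).

    ``genes``: chrom, start, end, gene_id.  ``het_deletions``: chrom, start,
    end (one genome's heterozygous deletion calls).  Splitting a deletion into
    abutting pieces cannot change the result (intervals are merged first).
    """
    if len(genes) == 0:
        raise ValueError("zero genes supplied")
    hemi = []
    for chrom_name, gsub in genes.groupby("chrom", sort=False):
        dels = het_deletions[het_deletions["chrom"] == chrom_name][["start", "end"]].to_numpy()
        merged = _merge_intervals(dels.astype(float))
        for _, g in gsub.iterrows():
            if merged.size:
                ov = np.clip(np.minimum(merged[:, 1], g.end) - np.maximum(merged[:, 0], g.start),
                             0, None).sum()
            else:
                ov = 0.0
            frac = ov / (g.end - g.start)
            if (frac > overlap_frac) if strict else (frac >= overlap_frac):
                hemi.append(g.gene_id)
    return HemizygosityResult(len(genes), len(hemi), len(hemi) / len(genes), hemi)


# ---------------------------------------------------------------------------
# correlation & contrasts


def correlate_burden_introgression(burdens: pd.Series, ancestry: pd.Series):
    """Spearman rank correlation (average ranks for ties; two-sided p from the
    t approximation) between per-sample burden and donor-ancestry proportion."""
    joined = pd.concat([burdens, ancestry], axis=1, join="inner").dropna()
    if len(joined) < 5:
        raise ValueError("need at least 5 paired observations")
    x, y = joined.iloc[:, 0], joined.iloc[:, 1]
    if x.nunique() == 1 or y.nunique() == 1:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class ContrastResult:
    ratio: float
    ci_low: float
    ci_high: float
    mean_a: float
    mean_b: float
    n_boot: int


def burden_contrast(
    burdens: pd.Series,
    pm: PopulationMap,
    group_a,
    group_b,
    statistic: str = "mean",
    n_boot: int = 1000,
    seed: int = 0,
) -> ContrastResult:
    """Ratio of group-A to group-B burden (means or medians) with a seeded
    percentile bootstrap CI.  ``group_a``/``group_b`` are population labels."""
    agg = np.mean if statistic == "mean" else np.median
    sa = [s for g in np.atleast_1d(group_a) for s in pm.samples_of(g)]
    sb = [s for g in np.atleast_1d(group_b) for s in pm.samples_of(g)]
    va = burdens.loc[sa].to_numpy(dtype=float)
    vb = burdens.loc[sb].to_numpy(dtype=float)
    if len(va) == 0 or len(vb) == 0:
        raise ValueError("empty group in burden_contrast")
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        boot[i] = agg(rng.choice(va, len(va))) / agg(rng.choice(vb, len(vb)))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ContrastResult(float(agg(va) / agg(vb)), float(lo), float(hi),
                          float(np.mean(va)), float(np.mean(vb)), n_boot)
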