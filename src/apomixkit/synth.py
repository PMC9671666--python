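"""Synthetic cohorts with recorded ground truth.

Every input the analyses consume can be generated here: K drift-structured
populations (Balding-Nichols allele frequencies at a target F_ST) plus a
near-fixed outgroup, planted donor-ancestry tracts with a truth BED, a
SIFT-like deleterious annotation layer with per-site selection coefficients,
an F1 pseudo-testcross with one apomixis QTL and binomially sequenced
phenotype bulks, non-overlapping gene models with heterozygous deletions at a
configured hemizygosity, and read-support evidence for promoter MITE
insertions.  All stochastic functions require an explicit seed; identical
config + seed gives byte-identical output files.

Default scales emulate the structure of a few-hundred-accession citrus
resequencing resource at desk size: tens of samples per population, tens of
thousands of SNPs over a two-chromosome 20-Mb genome, ~2.5% of SNPs
deleterious with a gamma DFE, and ~36x read depth for count-based evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import VARIANT_COLUMNS, GenotypeMatrix, PopulationMap, VariantTable
from .fwdsim import DFE

BASES = np.array(list("ACGT"))


@dataclass
class IntrogressionPlan:
    donor: str                    # donor population label
    recipients: list              # recipient sample IDs
    m: float = 0.1                # target ancestry fraction per haplotype
    tract_len: float = 1e6        # mean geometric tract length (bp)


@dataclass
class QtlPlan:
    chrom: str = "chr1"
    pos: int = 6_000_000
    n_progeny: int = 554
    bulk_size: int = 30
    depth: int = 60
    n_markers: int = 5000
    morgans_per_bp: float = 5e-8  # 5 cM / Mb


#: default BSA genome: five 12-Mb chromosomes (~60 cM each), QTL mid-chr1
BSA_CONTIGS = {f"chr{i}": 12_000_000 for i in range(1, 6)}


@dataclass
class SvPlan:
    n_genes: int = 200
    gene_len: int = 3000
    hemizygous_fraction: float = 0.1
    covered_frac: float = 0.8     # deletion overlap of a targeted gene (> 0.5)
    n_background: int = 20        # intergenic het deletions per sample


@dataclass
class SynthConfig:
    seed: int
    n_pops: int = 3
    samples_per_pop: int = 20
    n_variants: int = 20000
    fst: float | tuple = 0.2      # scalar, or one F per population
    outgroup_fst: float = 0.99
    n_outgroup: int = 4
    contig_lengths: dict = field(default_factory=lambda: {"chr1": 10_000_000,
                                                          "chr2": 10_000_000})
    deleterious_fraction: float = 0.025
    lof_fraction: float = 0.25    # of deleterious SNPs also flagged LOF
    dfe: DFE = field(default_factory=lambda: DFE(kind="gamma", shape=0.3, mean=0.05))
    anc_beta: float = 0.8         # symmetric Beta shape for ancestral freqs
    depth_mean: float = 36.0
    # lineage-specific substitutions: population -> number of sites driven to
    # fixation for the derived allele in that population only (placed at the
    # lowest-ancestral-frequency sites, emulating species-diagnostic markers)
    private_fixed: dict = field(default_factory=dict)
    # optional hierarchical drift structure replacing the flat K-population
    # layout: an ordered list of (name, parent, fst, n_samples) where parent
    # "ancestral" is the root; n_samples = 0 marks an internal lineage whose
    # frequencies only seed its descendants.  The outgroup is still appended.
    lineages: list | None = None

    def __post_init__(self) -> None:
        fsts = np.atleast_1d(self.fst)
        if len(fsts) not in (1, self.n_pops):
            raise ValueError("fst must be scalar or one value per population")
        for v in (*fsts, self.outgroup_fst, self.deleterious_fraction,
                  self.lof_fraction):
            if not 0 <= v <= 1:
                raise ValueError("all fractions must lie in [0, 1]")

    @property
    def pop_fsts(self) -> list:
        fsts = list(np.atleast_1d(self.fst).astype(float))
        return fsts * self.n_pops if len(fsts) == 1 else fsts


@dataclass
class SyntheticTruth:
    population_labels: dict
    tracts: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["sample", "haplotype", "chrom", "start", "end"]))
    variant_effects: pd.DataFrame | None = None   # s, h, deleterious, lof per variant
    qtl: tuple | None = None                      # (chrom, pos)
    insertion_genotypes: pd.DataFrame | None = None
    g_h: dict | None = None                       # per-sample true hemizygous fraction


def _balding_nichols(p_anc: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    if f <= 0:
        return p_anc.copy()
    a = p_anc * (1 - f) / f
    b = (1 - p_anc) * (1 - f) / f
    return rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))


def simulate_structured_genotypes(cfg: SynthConfig):
    """Drift-structured diploid cohort: (VariantTable, GenotypeMatrix, truth).

    Ancestral frequencies ~ Beta(a, a); population frequencies follow the
    Balding-Nichols Beta at the configured F_ST; haplotypes are Bernoulli
    draws, so genotypes are Binomial(2, p_pop).  The outgroup population is
    simulated at F near 1, leaving it near-fixed at most sites.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_variants
    contigs = list(cfg.contig_lengths)
    per = np.array_split(np.arange(L), len(contigs))
    chrom = np.empty(L, dtype=object)
    pos = np.empty(L, dtype=int)
    for c, idx in zip(contigs, per):
        chrom[idx] = c
        pos[idx] = np.sort(rng.choice(cfg.contig_lengths[c], size=len(idx),
                                      replace=False))
    p_anc = rng.beta(cfg.anc_beta, cfg.anc_beta, size=L)
    if cfg.lineages is None:
        plan = [(f"pop{k + 1}", "ancestral", f, cfg.samples_per_pop)
                for k, f in enumerate(cfg.pop_fsts)]
    else:
        plan = [tuple(x) for x in cfg.lineages]
    plan.append(("outgroup", "ancestral", cfg.outgroup_fst, cfg.n_outgroup))
    freq_of = {"ancestral": p_anc}
    pops, sizes = [], []
    samples, labels, hap_blocks = [], {}, []
    for pop, parent, f, size in plan:
        if parent not in freq_of:
            raise ValueError(f"lineage {pop!r} references unknown parent {parent!r}")
        p_pop = _balding_nichols(freq_of[parent], f, rng)
        freq_of[pop] = p_pop
        if size == 0:
            continue
        pops.append(pop)
        sizes.append(size)
        haps = (rng.random((size, 2, L)) < p_pop).astype(np.int8)
        hap_blocks.append(haps)
        for i in range(size):
            name = f"{pop}_s{i + 1:02d}"
            samples.append(name)
            labels[name] = pop
    haplotypes = np.concatenate(hap_blocks, axis=0)
    if cfg.private_fixed:
        # lowest-p_anc sites carry the private substitutions, disjoint per pop
        order = np.argsort(p_anc)
        cursor = 0
        offsets = dict(zip(pops, np.cumsum([0] + sizes[:-1])))
        for pop, n_sites in cfg.private_fixed.items():
            if pop not in offsets:
                raise ValueError(f"private_fixed for unknown population {pop!r}")
            sites = order[cursor:cursor + n_sites]
            cursor += n_sites
            lo = offsets[pop]
            hi = lo + sizes[pops.index(pop)]
            haplotypes[lo:hi, :, sites] = 1
    dosage = haplotypes.sum(axis=1).astype(np.int8)
    ref = rng.choice(BASES, size=L)
    alt = np.array([rng.choice([b for b in BASES if b != r]) for r in ref])
    # derived allele is the ALT by construction; ancestral left for the
    # polarization step (the outgroup genotypes carry the information)
    df = pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "vtype": "SNP", "svlen": np.nan, "sift_score": np.nan,
        "lof_flag": False, "ancestral": "unknown",
    })[VARIANT_COLUMNS]
    vt = VariantTable(df)
    gm = GenotypeMatrix(samples, dosage, haplotypes)
    return vt, gm, SyntheticTruth(population_labels=labels)


def population_map(truth: SyntheticTruth, roles=None) -> PopulationMap:
    return PopulationMap(dict(truth.population_labels), roles or {})


def plant_introgression_tracts(
    gm: GenotypeMatrix,
    vt: VariantTable,
    truth: SyntheticTruth,
    plan: IntrogressionPlan,
    contig_lengths: dict,
    seed: int,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Replace geometric-length tracts of recipient haplotypes with random
    donor haplotypes until the target ancestry fraction m is covered.

    The truth BED records the exact (merged) replaced intervals per recipient
    haplotype; m is defined over total haplotype length.
    """
    if plan.m == 0 or not plan.recipients:
        return gm, truth
    rng = np.random.default_rng(seed)
    donor_samples = [s for s, p in truth.population_labels.items() if p == plan.donor]
    if set(donor_samples) & set(plan.recipients):
        raise ValueError("donor and recipient samples must be disjoint")
    donor_idx = gm.sample_index(donor_samples)
    hap = gm.haplotypes.copy()
    chrom = vt.chrom
    pos = vt.pos
    genome = sum(contig_lengths.values())
    contigs = list(contig_lengths)
    clens = np.array([contig_lengths[c] for c in contigs], dtype=float)
    rows = []
    for rec in plan.recipients:
        ri = gm.sample_index([rec])[0]
        for hp in (0, 1):
            if plan.m >= 1.0:
                intervals = [(c, 0, contig_lengths[c]) for c in contigs]
            else:
                covered: dict[str, list] = {c: [] for c in contigs}
                total = 0.0
                target = plan.m * genome
                for _ in range(100_000):
                    if total >= target:
                        break
                    c = contigs[rng.choice(len(contigs), p=clens / clens.sum())]
                    length = min(rng.geometric(1.0 / plan.tract_len),
                                 contig_lengths[c])
                    # clip the final tract so realized coverage hits the target
                    length = int(min(length, target - total))
                    if length < 1:
                        break
                    start = int(rng.integers(0, contig_lengths[c] - length + 1))
                    trial = _merge(covered[c] + [(start, start + length)])
                    new_total = total - sum(e - s for s, e in covered[c]) \
                        + sum(e - s for s, e in trial)
                    covered[c] = trial
                    total = new_total
                intervals = [(c, s, e) for c in contigs for s, e in covered[c]]
            for c, s, e in intervals:
                sel = (chrom == c) & (pos >= s) & (pos < e)
                d = donor_idx[rng.integers(0, len(donor_idx))]
                dh = int(rng.integers(0, 2))
                hap[ri, hp, sel] = gm.haplotypes[d, dh, sel]
                rows.append((rec, hp, c, int(s), int(e)))
    new_gm = GenotypeMatrix(gm.samples, hap.sum(axis=1).astype(np.int8), hap)
    tracts = pd.concat(
        [truth.tracts, pd.DataFrame(rows, columns=truth.tracts.columns)],
        ignore_index=True,
    )
    new_truth = replace(truth, tracts=tracts)
    return new_gm, new_truth


def _merge(intervals):
    if not intervals:
        return []
    iv = sorted(intervals)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def attach_deleterious_annotations(
    vt: VariantTable,
    truth: SyntheticTruth,
    fraction: float,
    dfe: DFE,
    seed: int,
    lof_fraction: float = 0.25,
    h: float = 0.0,
) -> tuple[VariantTable, SyntheticTruth]:
    """Mark a fraction of SNPs deleterious: SIFT uniform in [0, 0.05] for the
    chosen set, uniform in (0.05, 1] otherwise; a sub-fraction gets the LOF
    flag.  Per-site s (from the DFE) and h go into the truth table."""
    rng = np.random.default_rng(seed)
    df = vt.df.copy()
    snp = np.flatnonzero(vt.is_snp())
    n_del = int(round(fraction * snp.size))
    del_idx = rng.choice(snp, size=n_del, replace=False) if n_del else np.array([], int)
    sift = np.full(len(df), np.nan)
    sift[snp] = 0.05 + rng.random(snp.size) * 0.95  # (0.05, 1]
    sift[del_idx] = rng.random(n_del) * 0.05         # [0, 0.05]
    lof = np.zeros(len(df), dtype=bool)
    if n_del:
        n_lof = int(round(lof_fraction * n_del))
        lof[rng.choice(del_idx, size=n_lof, replace=False)] = True
    df["sift_score"] = sift
    df["lof_flag"] = lof
    s = np.zeros(len(df))
    s[del_idx] = dfe.draw(n_del, rng)
    effects = pd.DataFrame({
        "s": s, "h": h,
        "deleterious": np.isin(np.arange(len(df)), del_idx),
        "lof": lof,
    })
    return VariantTable(df), replace(truth, variant_effects=effects)


# ---------------------------------------------------------------------------
# F1 pseudo-testcross BSA


def simulate_f1_bsa(plan: QtlPlan, contig_lengths: dict, seed: int):
    """Pseudo-testcross F1 population with one apomixis QTL, bulked and
    sequenced.

    The apomictic parent is heterozygous at the QTL and at every marker (alt
    alleles in coupling with the QTL allele); the sexual parent is homozygous
    reference, so markers segregate 1:1.  Progeny gametes recombine along the
    marker map (Haldane, ``morgans_per_bp``); phenotype = carries the QTL
    allele.  Bulks of extreme phenotypes are sequenced to fixed depth with
    Binomial(depth, bulk allele frequency) alt counts.

    Returns (phenotypes, counts, truth_dict).
    """
    if plan.bulk_size > plan.n_progeny / 2:
        raise ValueError("bulk_size cannot exceed half the progeny")
    rng = np.random.default_rng(seed)
    contigs = list(contig_lengths)
    per = np.array_split(np.arange(plan.n_markers), len(contigs))
    mchrom = np.empty(plan.n_markers, dtype=object)
    mpos = np.empty(plan.n_markers, dtype=int)
    for c, idx in zip(contigs, per):
        mchrom[idx] = c
        mpos[idx] = np.sort(rng.choice(contig_lengths[c], size=len(idx), replace=False))
    # insert the QTL as a pseudo-marker for gamete simulation
    qsel = mchrom == plan.chrom
    insert_at = np.searchsorted(mpos[qsel], plan.pos) + np.flatnonzero(qsel)[0]
    sim_chrom = np.insert(mchrom, insert_at, plan.chrom)
    sim_pos = np.insert(mpos, insert_at, plan.pos)
    n_loci = len(sim_pos)
    # recombination fraction between adjacent loci (0.5 across contig breaks)
    d = np.diff(sim_pos).astype(float) * plan.morgans_per_bp
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    r[sim_chrom[1:] != sim_chrom[:-1]] = 0.5
    flips = np.empty((plan.n_progeny, n_loci), dtype=bool)
    flips[:, 0] = rng.random(plan.n_progeny) < 0.5
    flips[:, 1:] = rng.random((plan.n_progeny, n_loci - 1)) < r
    gamete = np.logical_xor.accumulate(flips, axis=1)  # True = haplotype H1
    phenotype = gamete[:, insert_at]  # carries QTL allele
    gamete_mk = np.delete(gamete, insert_at, axis=1)  # marker alt dosage (0/1)
    carriers = np.flatnonzero(phenotype)
    noncarriers = np.flatnonzero(~phenotype)
    if min(carriers.size, noncarriers.size) < plan.bulk_size:
        raise ValueError("not enough progeny of one phenotype for the bulks")
    bulk_high = rng.choice(carriers, size=plan.bulk_size, replace=False)
    bulk_low = rng.choice(noncarriers, size=plan.bulk_size, replace=False)
    rows = {}
    for tag, bulk in (("high", bulk_high), ("low", bulk_low)):
        freq = gamete_mk[bulk].mean(axis=0) / 2.0  # progeny are Aa or aa
        alt = rng.binomial(plan.depth, freq)
        rows[f"alt_{tag}"] = alt
        rows[f"ref_{tag}"] = plan.depth - alt
    counts = pd.DataFrame({
        "chrom": mchrom, "pos": mpos,
        "ref_high": rows["ref_high"], "alt_high": rows["alt_high"],
        "ref_low": rows["ref_low"], "alt_low": rows["alt_low"],
    })
    truth = {"qtl": (plan.chrom, plan.pos), "phenotypes": phenotype,
             "bulk_high": bulk_high, "bulk_low": bulk_low}
    return phenotype, counts, truth


# ---------------------------------------------------------------------------
# gene models and heterozygous deletions


def simulate_sv_and_genes(plan: SvPlan, contig_lengths: dict, samples, seed: int):
    """Non-overlapping gene models plus per-sample heterozygous deletions.

    A configured fraction of genes per sample is targeted by a deletion
    covering ``covered_frac`` (> 0.5) of the gene; background deletions land
    between genes and never push a gene past 50%.  Returns (genes,
    het_deletions, truth g_h per sample)."""
    rng = np.random.default_rng(seed)
    contigs = list(contig_lengths)
    genes = []
    per = np.array_split(np.arange(plan.n_genes), len(contigs))
    for c, idx in zip(contigs, per):
        n = len(idx)
        slot = contig_lengths[c] // max(n, 1)
        if slot < 2 * plan.gene_len:
            raise ValueError("contigs too short for the requested gene count")
        for k, gi in enumerate(idx):
            start = k * slot + int(rng.integers(0, slot - plan.gene_len))
            genes.append((c, start, start + plan.gene_len, f"gene{gi + 1:04d}"))
    genes_df = pd.DataFrame(genes, columns=["chrom", "start", "end", "gene_id"])
    n_target = int(round(plan.hemizygous_fraction * plan.n_genes))
    del_rows, g_h = [], {}
    for s in samples:
        targets = rng.choice(plan.n_genes, size=n_target, replace=False)
        for gi in targets:
            g = genes_df.iloc[gi]
            span = int(plan.covered_frac * (g.end - g.start))
            start = int(g.start + rng.integers(0, (g.end - g.start) - span + 1))
            del_rows.append((s, g.chrom, start, start + span))
        for _ in range(plan.n_background):
            c = contigs[int(rng.integers(0, len(contigs)))]
            length = int(rng.integers(500, 5000))
            start = int(rng.integers(0, contig_lengths[c] - length))
            iv = (start, start + length)
            sub = genes_df[genes_df.chrom == c]
            ov = np.minimum(sub.end, iv[1]) - np.maximum(sub.start, iv[0])
            frac = np.clip(ov, 0, None) / (sub.end - sub.start)
            if (frac > 0.25).any():  # keep background well below the 50% rule
                continue
            del_rows.append((s, c, iv[0], iv[1]))
        g_h[s] = n_target / plan.n_genes
    dels = pd.DataFrame(del_rows, columns=["sample", "chrom", "start", "end"])
    return genes_df, dels, g_h


# ---------------------------------------------------------------------------
# MITE insertion evidence and sequences


def simulate_insertion_evidence(true_genotypes: pd.DataFrame, depth: int,
                                error: float, seed: int) -> pd.DataFrame:
    """Read support per (sample, locus): insertion reads ~ Binomial(depth,
    theta) with theta = error / 0.5 / 1-error for absent / het / hom."""
    rng = np.random.default_rng(seed)
    theta = true_genotypes["genotype"].map(
        {"absent": error, "het": 0.5, "hom": 1.0 - error}).to_numpy()
    if np.isnan(theta).any():
        raise ValueError("genotype column must be absent/het/hom")
    ins = rng.binomial(depth, theta)
    out = true_genotypes[["sample", "locus"]].copy()
    out["ins_reads"] = ins
    out["ref_reads"] = depth - ins
    return out


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, size=n))


def make_mite_insertion(kind: str, seed: int) -> str:
    """Construct a promoter-insertion haplotype sequence.

    ``fortunella``: three copies of one 202-bp MITE unit, consecutive copies
    sharing a 5-bp TSD -> 3*202 - 2*5 = 596 bp.  ``citrus``: a 202-bp unit
    plus a homologous 227-bp unit (25-bp internal expansion) sharing one
    5-bp TSD -> 202 + 227 - 5 = 424 bp.  ``none``: empty string.
    """
    rng = np.random.default_rng(seed)
    if kind == "none":
        return ""
    tsd = _random_seq(5, rng)
    core = _random_seq(192, rng)
    unit = tsd + core + tsd  # 202 bp, TSD at both ends
    if kind == "fortunella":
        return unit + unit[5:] + unit[5:]
    if kind == "citrus":
        expanded = tsd + core[:96] + _random_seq(25, rng) + core[96:] + tsd  # 227 bp
        return unit + expanded[5:]
    raise ValueError(f"unknown insertion kind {kind!r}")


# ---------------------------------------------------------------------------
# cohort writer


def write_cohort(outdir, vt, gm, truth: SyntheticTruth, contig_lengths,
                 genes=None, het_deletions=None, bulk_counts=None,
                 insertion_evidence=None, insertion_seqs=None) -> dict:
    """Write every generated table in its standard format under ``outdir``.

    VCF (phased GT), population map TSV, truth-tract BED, GFF3 gene models,
    het-deletion BED, bulk-count TSV, insertion-evidence TSV and insertion
    FASTA.  Returns the path map."""
    import os

    from .vcfio import write_gff3, write_vcf

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_vcf(vt, gm, p("cohort.vcf"), contig_lengths, phased=gm.haplotypes is not None)
    PopulationMap(dict(truth.population_labels)).to_tsv(p("populations.tsv"))
    truth.tracts.to_csv(p("true_tracts.bed"), sep="\t", index=False, header=False,
                        columns=["chrom", "start", "end", "sample", "haplotype"])
    if truth.variant_effects is not None:
        truth.variant_effects.to_csv(p("variant_effects.tsv"), sep="\t", index=False)
    if genes is not None:
        write_gff3(genes, p("genes.gff3"))
    if het_deletions is not None:
        het_deletions.to_csv(p("het_deletions.bed"), sep="\t", index=False,
                             header=False, columns=["chrom", "start", "end", "sample"])
    if bulk_counts is not None:
        bulk_counts.to_csv(p("bulk_counts.tsv"), sep="\t", index=False)
    if insertion_evidence is not None:
        insertion_evidence.to_csv(p("insertion_evidence.tsv"), sep="\t", index=False)
    if insertion_seqs is not None:
        with open(p("insertions.fasta"), "w") as fh:
            for name, seq in insertion_seqs.items():
                fh.write(f">{name}\n{seq}\n")
    return paths
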