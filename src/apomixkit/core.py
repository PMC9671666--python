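"""Shared data model and statistical primitives.

Everything downstream (introgression scans, load summaries, BSA, the MITE
caller) operates on three containers defined here: a :class:`VariantTable`
describing biallelic SNP/SV records, a :class:`GenotypeMatrix` of per-sample
dosages (optionally phased), and a :class:`PopulationMap` binding samples to
populations and analysis roles (P1/P2/P3/outgroup/...).

Coordinates are 0-based half-open internally; VCF positions are converted on
read/write.  Also housed here: outgroup polarization, per-population derived
allele frequencies, genomic windowing, the weighted block jackknife and
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MISSING = -1  # dosage sentinel

SV_TYPES = ("DEL", "DUP", "INV", "TRA", "INS")
VTYPES = ("SNP",) + SV_TYPES

VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "vtype",
    "svlen",
    "sift_score",
    "lof_flag",
    "ancestral",
]


class ConfigurationError(ValueError):
    """Raised when population roles or analysis options are inconsistent."""


@dataclass
class VariantTable:
    """Biallelic variant records (SNPs and SVs), sorted by (chrom, pos).

    ``pos`` is 0-based.  ``ancestral`` is one of ``"ref"``, ``"alt"``,
    ``"unknown"``.  ``sift_score`` is defined for SNPs only (NaN elsewhere);
    ``svlen`` for SVs only.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"VariantTable missing columns: {missing_cols}")
        df = self.df
        order = np.lexsort((df["pos"].to_numpy(), df["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(df))):
            df = df.iloc[order].reset_index(drop=True)
        bad = ~df["vtype"].isin(VTYPES)
        if bad.any():
            raise ValueError(f"unknown vtype values: {df.loc[bad, 'vtype'].unique()}")
        snp = df["vtype"] == "SNP"
        if (df.loc[snp, "ref"].str.len() != 1).any() or (
            df.loc[snp, "alt"].str.len() != 1
        ).any():
            raise ValueError("SNP records must have single-base ref and alt")
        if df.loc[~snp, "sift_score"].notna().any():
            raise ValueError("sift_score present only for SNPs")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    def is_snp(self) -> np.ndarray:
        return (self.df["vtype"] == "SNP").to_numpy()

    def with_ancestral(self, ancestral: np.ndarray) -> "VariantTable":
        df = self.df.copy()
        df["ancestral"] = ancestral
        return VariantTable(df)


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix, -1 for missing.

    ``haplotypes`` (samples x 2 x variants, uint8), when present, must sum to
    the dosage at every non-missing entry.
    """

    samples: list[str]
    dosage: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2 or self.dosage.shape[0] != len(self.samples):
            raise ValueError("dosage must be (n_samples, n_variants)")
        if self.haplotypes is not None:
            hap_sum = self.haplotypes.sum(axis=1).astype(np.int8)
            called = self.dosage != MISSING
            if not np.array_equal(hap_sum[called], self.dosage[called]):
                raise ValueError("haplotype sums disagree with dosages")

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def sample_index(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample not in GenotypeMatrix: {exc}") from exc


@dataclass
class PopulationMap:
    """sample -> population labels plus role bindings (P1, P2, P3, outgroup, ...)."""

    assignments: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pops = set(self.assignments.values())
        for role, pop in self.roles.items():
            if pop not in pops:
                raise ConfigurationError(f"role {role!r} bound to empty population {pop!r}")
        og = self.roles.get("outgroup")
        if og is not None:
            for role in ("P1", "P2", "P3"):
                if self.roles.get(role) == og:
                    raise ConfigurationError("outgroup population must be disjoint from P1-P3")

    def samples_of(self, population: str) -> list[str]:
        out = [s for s, p in self.assignments.items() if p == population]
        if not out:
            raise ConfigurationError(f"population {population!r} has no samples")
        return out

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p)
        return list(seen)

    @classmethod
    def from_tsv(cls, path, roles: dict[str, str] | None = None) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                         dtype=str, comment="#")
        return cls(dict(zip(df["sample"], df["population"])), roles or {})

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample": list(self.assignments), "population": list(self.assignments.values())}
        ).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class AlleleFreqTable:
    """Per-population derived-allele frequencies (NaN where masked).

    ``freq`` has one column per population, aligned row-wise with ``sites``.
    ``n_alleles`` holds the called-allele counts entering each denominator.
    """

    freq: pd.DataFrame
    n_alleles: pd.DataFrame
    sites: pd.DataFrame  # chrom, pos (0-based)

    def p(self, population: str) -> np.ndarray:
        return self.freq[population].to_numpy()

    def mask_for(self, populations) -> np.ndarray:
        """True where every requested population has a defined frequency."""
        return ~np.any([np.isnan(self.p(q)) for q in populations], axis=0)


# ---------------------------------------------------------------------------
# polarization and frequencies


def polarize_by_outgroup(
    vt: VariantTable,
    gm: GenotypeMatrix,
    pm: PopulationMap,
    max_og_minor: float = 0.1,
) -> VariantTable:
    """Set the ancestral allele to the outgroup major allele.

    Sites where the outgroup minor-allele frequency exceeds ``max_og_minor``,
    or where no outgroup sample is called, are marked ``unknown`` and are
    excluded from polarized statistics downstream.  Idempotent: the call
    depends only on outgroup genotypes.
    """
    if not 0 <= max_og_minor < 0.5:
        raise ValueError("max_og_minor must be in [0, 0.5)")
    og_pop = pm.roles.get("outgroup")
    if og_pop is None:
        raise ConfigurationError("no outgroup role bound in PopulationMap")
    idx = gm.sample_index(pm.samples_of(og_pop))
    dos = gm.dosage[idx, :].astype(float)
    dos[dos == MISSING] = np.nan
    n_called = 2 * np.sum(~np.isnan(dos), axis=0)
    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(dos, axis=0) / np.where(n_called > 0, n_called, np.nan)
    minor = np.minimum(alt_freq, 1.0 - alt_freq)
    ancestral = np.where(alt_freq > 0.5, "alt", "ref").astype(object)
    unknown = np.isnan(alt_freq) | (minor > max_og_minor)
    ancestral[unknown] = "unknown"
    return vt.with_ancestral(ancestral)


def derived_dosage(vt: VariantTable, gm: GenotypeMatrix) -> np.ndarray:
    """Dosage on the derived-allele scale; NaN at missing or unpolarized sites."""
    d = gm.dosage.astype(float)
    d[d == MISSING] = np.nan
    anc = vt.df["ancestral"].to_numpy()
    flip = anc == "alt"
    d[:, flip] = 2.0 - d[:, flip]
    d[:, anc == "unknown"] = np.nan
    return d


def derived_freqs(
    gm: GenotypeMatrix,
    vt: VariantTable,
    pm: PopulationMap,
    populations,
    min_n: int = 2,
) -> AlleleFreqTable:
    """Per-population derived-allele frequencies from polarized dosages.

    Missing genotypes drop out of the denominator; populations with fewer
    than ``min_n`` called alleles at a site are masked (NaN) there.
    """
    dd = derived_dosage(vt, gm)
    freqs, counts = {}, {}
    for pop in populations:
        idx = gm.sample_index(pm.samples_of(pop))
        sub = dd[idx, :]
        n = 2 * np.sum(~np.isnan(sub), axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(sub, axis=0) / np.where(n > 0, n, np.nan)
        p[n < min_n] = np.nan
        freqs[pop] = p
        counts[pop] = n
    sites = vt.df[["chrom", "pos"]].copy()
    return AlleleFreqTable(pd.DataFrame(freqs), pd.DataFrame(counts), sites)


# ---------------------------------------------------------------------------
# windows


def make_windows(contig_lengths: dict[str, int], size: int, step: int | None = None) -> pd.DataFrame:
    """Tile each contig with half-open [start, end) windows; the final partial
    window is retained.  ``step < size`` yields overlapping windows."""
    if size < 1:
        raise ValueError("size must be >= 1")
    step = size if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    rows = []
    for chrom, length in contig_lengths.items():
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + size, length)))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def assign_to_windows(windows: pd.DataFrame, chrom: np.ndarray, pos: np.ndarray):
    """Yield (window_row_index, site_index_array) for sites in each window."""
    for i, row in windows.iterrows():
        sel = np.flatnonzero((chrom == row.chrom) & (pos >= row.start) & (pos < row.end))
        yield i, sel


# ---------------------------------------------------------------------------
# block jackknife


@dataclass
class BlockJackknifeResult:
    estimate: float
    se: float
    z: float
    p: float
    n_blocks: int
    degenerate: bool = False


def block_jackknife(
    loo_estimates,
    weights=None,
    estimate: float | None = None,
) -> BlockJackknifeResult:
    """Weighted delete-one-block jackknife (Busing-style).

    ``loo_estimates[j]`` is the statistic recomputed with block j removed;
    ``weights[j]`` is that block's weight (e.g. its informative-site count).
    With equal weights this reduces to the classic delete-1 jackknife.
    Scale-invariant in the weights.
    """
    theta_loo = np.asarray(loo_estimates, dtype=float)
    n = theta_loo.size
    if n < 2:
        raise ValueError("need at least 2 blocks")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    W = w.sum()
    theta_hat = float(np.average(theta_loo, weights=w)) if estimate is None else float(estimate)
    h = W / w
    tau = h * theta_hat - (h - 1.0) * theta_loo
    theta_J = n * theta_hat - float(np.sum((1.0 - w / W) * theta_loo))
    var = float(np.sum((tau - theta_J) ** 2 / (h - 1.0)) / n)
    se = np.sqrt(max(var, 0.0))
    if se > 0:
        z = theta_hat / se
        p = 2.0 * stats.norm.sf(abs(z))
        return BlockJackknifeResult(theta_hat, se, z, p, n)
    # degenerate variance: identical leave-one-out estimates
    if theta_hat == 0.0:
        return BlockJackknifeResult(theta_hat, 0.0, 0.0, 1.0, n, degenerate=True)
    return BlockJackknifeResult(theta_hat, 0.0, np.inf if theta_hat > 0 else -np.inf,
                                0.0, n, degenerate=True)


def ratio_jackknife(num_blocks, den_blocks, weights=None) -> BlockJackknifeResult:
    """Jackknife for a ratio-of-sums statistic from per-block numerator and
    denominator sums.  Weights default to per-block denominators."""
    num = np.asarray(num_blocks, dtype=float)
    den = np.asarray(den_blocks, dtype=float)
    if den.sum() == 0:
        raise ZeroDivisionError("zero denominator genome-wide")
    keep = den != 0  # blocks with no information cannot be left out meaningfully
    num, den = num[keep], den[keep]
    estimate = num.sum() / den.sum()
    loo = (num.sum() - num) / (den.sum() - den)
    w = den if weights is None else np.asarray(weights, dtype=float)[keep]
    return block_jackknife(loo, w, estimate=estimate)


def make_blocks(chrom: np.ndarray, pos: np.ndarray, n_blocks: int = 20) -> np.ndarray:
    """Assign each site to one of ``n_blocks`` contiguous equal-span blocks
    spanning the genome (blocks never straddle a contig boundary)."""
    chroms = pd.unique(chrom)
    spans = {c: (pos[chrom == c].min(), pos[chrom == c].max() + 1) for c in chroms}
    total = sum(hi - lo for lo, hi in spans.values())
    block_ids = np.zeros(len(pos), dtype=int)
    offset = 0.0
    for c in chroms:
        lo, hi = spans[c]
        sel = chrom == c
        frac = (offset + (pos[sel] - lo)) / total
        block_ids[sel] = np.minimum((frac * n_blocks).astype(int), n_blocks - 1)
        offset += hi - lo
    return block_ids


# ---------------------------------------------------------------------------
# FDR


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values propagate as NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# tabular output


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(df: pd.DataFrame, path, score: str | None = None, name: str | None = None) -> None:
    """Write intervals as BED (BED5 when a score column is named)."""
    out = df[["chrom", "start", "end"]].copy()
    if score is not None:
        out["name"] = df[name] if name is not None else "."
        out["score"] = df[score]
    out.to_csv(path, sep="\t", header=False, index=False)
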