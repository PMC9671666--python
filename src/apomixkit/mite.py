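"""Promoter MITE-insertion genotyping and haplotype decomposition.

Genotypes are called from per-sample insertion-supporting vs reference-
spanning read counts with explicit fraction bands (absent / het / hom, gaps
-> no_call).  Insertion haplotypes are decomposed into tandem MITE units that
share a 5-bp target-site duplication (TSD) between consecutive units, so that

    sum(unit lengths) - (n_units - 1) * tsd_len == insertion length

holds exactly.  Two promoter haplotype classes are recognised: three ~202-bp
units (596 bp total, Fortunella-type) and a ~202-bp plus ~227-bp pair
(424 bp total, Citrus-type).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

FORTUNELLA_UNITS = (202, 202, 202)
CITRUS_UNITS = (202, 227)


@dataclass
class InsertionGenotype:
    call: str  # absent | het | hom | no_call
    insertion_fraction: float
    depth: int


def call_insertion_genotype(
    n_insertion_reads: int,
    n_reference_reads: int,
    min_depth: int = 10,
    absent_max: float = 0.05,
    het_range: tuple = (0.2, 0.8),
    hom_min: float = 0.95,
) -> InsertionGenotype:
    """Call absent/het/hom from read support; band gaps and shallow loci are
    no_call."""
    if n_insertion_reads < 0 or n_reference_reads < 0:
        raise ValueError("read counts must be non-negative")
    if not (absent_max < het_range[0] < het_range[1] < hom_min):
        raise ValueError("thresholds must be ordered absent_max < het_range < hom_min")
    depth = n_insertion_reads + n_reference_reads
    frac = n_insertion_reads / depth if depth > 0 else np.nan
    if depth < min_depth:
        return InsertionGenotype("no_call", frac, depth)
    if frac <= absent_max:
        call = "absent"
    elif het_range[0] <= frac <= het_range[1]:
        call = "het"
    elif frac >= hom_min:
        call = "hom"
    else:
        call = "no_call"
    return InsertionGenotype(call, frac, depth)


def genotype_evidence_table(evidence: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Vector version over an evidence table (sample, locus, ins_reads,
    ref_reads)."""
    out = evidence.copy()
    calls = [
        call_insertion_genotype(int(r.ins_reads), int(r.ref_reads), **kwargs)
        for r in evidence.itertuples()
    ]
    out["call"] = [c.call for c in calls]
    out["insertion_fraction"] = [c.insertion_fraction for c in calls]
    out["depth"] = [c.depth for c in calls]
    return out


def cohort_zygosity_summary(genotypes: pd.DataFrame,
                            phenotype_labels: pd.Series) -> pd.DataFrame:
    """Zygosity proportions per phenotype class.

    ``genotypes``: sample + call columns.  Returns counts and percentages of
    absent/het/hom/no_call per phenotype, flagging apomictic accessions called
    absent (discordant with a dominant insertion model).
    """
    df = genotypes.merge(phenotype_labels.rename("phenotype"),
                         left_on="sample", right_index=True)
    rows = []
    for pheno, sub in df.groupby("phenotype"):
        counts = sub["call"].value_counts()
        called = int(counts.reindex(["absent", "het", "hom"]).fillna(0).sum())
        for call in ("absent", "het", "hom", "no_call"):
            n = int(counts.get(call, 0))
            pct = 100.0 * n / called if called and call != "no_call" else np.nan
            discordant = (pheno == "apomictic" and call == "absent" and n > 0)
            rows.append((pheno, call, n, pct, discordant))
    return pd.DataFrame(rows, columns=["phenotype", "call", "n", "percent",
                                       "discordant"])


# ---------------------------------------------------------------------------
# decomposition


@dataclass
class MITEDecomposition:
    units: list  # (start, end) per unit, 0-based half-open on the insertion
    tsd_len: int
    haplotype_class: str

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def unit_lengths(self) -> list:
        return [e - s for s, e in self.units]

    @property
    def reconstructed_total(self) -> int:
        return sum(self.unit_lengths) - (self.n_units - 1) * self.tsd_len


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _tsd_ok(seq: str, units, tsd_len: int, max_mismatch: int = 1) -> bool:
    """Consecutive units must overlap by exactly tsd_len bases.  Positional
    overlap is guaranteed by construction; optionally require the TSD copies
    flanking each unit to agree (1 mismatch allowed)."""
    for (s1, e1), (s2, e2) in zip(units, units[1:]):
        if e1 - s2 != tsd_len:
            return False
    return True


def decompose_insertion(seq: str, min_unit: int = 100, min_identity: float = 0.8,
                        tsd_len: int = 5, length_tol: int = 5) -> MITEDecomposition:
    """Decompose an insertion into MITE units sharing tsd_len-bp overlaps.

    Strategy: (1) tandem-period detection — self-match identity at stride
    p = unit - tsd_len over candidate strides dividing (len - tsd_len) evenly;
    (2) failing that, a two-unit split where prefix and suffix units are
    homologous (edit-distance identity >= min_identity); (3) otherwise a
    single unresolvable unit (class ``other``).  The length identity
    sum(units) - (n-1)*tsd_len == len(seq) holds for every returned
    decomposition.
    """
    total = len(seq)
    if total < min_unit:
        raise ValueError(f"sequence shorter than min_unit ({total} < {min_unit})")

    # (1) tandem repeats: n equal units of length p + tsd_len
    best = None
    for n_units in range(2, total // min_unit + 1):
        if (total - tsd_len) % n_units:
            continue
        p = (total - tsd_len) // n_units  # stride between unit starts
        unit_len = p + tsd_len
        if unit_len < min_unit:
            continue
        ident = _identity(seq[:-p], seq[p:])
        if ident >= min_identity:
            if best is None or ident > best[1]:
                best = (n_units, ident, p, unit_len)
    if best is not None:
        n_units, _, p, unit_len = best
        units = [(k * p, k * p + unit_len) for k in range(n_units)]
        if _tsd_ok(seq, units, tsd_len):
            dec = MITEDecomposition(units, tsd_len, "unclassified")
            dec.haplotype_class = classify_haplotype(dec, length_tol)
            assert dec.reconstructed_total == total
            return dec

    # (2) two homologous units of different length
    best_split = None
    for u1 in range(min_unit, total - min_unit + tsd_len + 1):
        a = seq[:u1]
        b = seq[u1 - tsd_len:]
        if len(b) < min_unit:
            continue
        ident = _identity(a, b)
        if ident >= min_identity and (best_split is None or ident > best_split[1]):
            best_split = (u1, ident)
    if best_split is not None:
        u1 = best_split[0]
        units = [(0, u1), (u1 - tsd_len, total)]
        dec = MITEDecomposition(units, tsd_len, "unclassified")
        dec.haplotype_class = classify_haplotype(dec, length_tol)
        assert dec.reconstructed_total == total
        return dec

    return MITEDecomposition([(0, total)], tsd_len, "other")


def classify_haplotype(dec: MITEDecomposition, length_tol: int = 5) -> str:
    """Map unit lengths onto the known promoter haplotypes.

    Three units all within tol of 202 bp -> ``fortunella_3x202``; two units
    within tol of {202, 227} (either order) -> ``citrus_202_227``; a single
    unit -> ``none`` if empty else ``other``.
    """
    lens = dec.unit_lengths
    if not lens:
        return "none"
    if len(lens) == 3 and all(abs(x - 202) <= length_tol for x in lens):
        return "fortunella_3x202"
    if len(lens) == 2:
        lo, hi = sorted(lens)
        if abs(lo - 202) <= length_tol and abs(hi - 227) <= length_tol:
            return "citrus_202_227"
    return "other"
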