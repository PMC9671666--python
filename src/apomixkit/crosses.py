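"""Hypothetical-cross exposure of recessive deleterious load.

For a pair of parents genotyped at deleterious loci, the primary metric is
the expected fraction of those loci at which a Mendelian F1 would be
homozygous for the deleterious allele:

    r(i, j) = (1/n_loci) * sum_l (d_i(l)/2) * (d_j(l)/2)

where d is the deleterious-allele dosage.  An alternative reading — the
Jaccard overlap of the parents' carrier sets — is also provided.  Cohorts of
within-group and between-group crosses are enumerated after seeded
down-sampling to a common group size, and summarised as the percent change of
the between-group mean relative to the within-group mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd

from .burden import DeleteriousSet
from .core import MISSING, GenotypeMatrix, PopulationMap


def _pair_dosages(gm: GenotypeMatrix, i: int, j: int, dset: DeleteriousSet):
    sub = gm.dosage[:, dset.all_indices]
    di = sub[i].astype(float)
    dj = sub[j].astype(float)
    ok = (di != MISSING) & (dj != MISSING)
    return di[ok], dj[ok]


def expected_f1_hom_ratio(dosage_i, dosage_j) -> float:
    """Expected fraction of usable deleterious loci homozygous-derived in a
    Mendelian F1 of the two parents.  Loci missing in either parent are
    excluded pairwise."""
    di = np.asarray(dosage_i, dtype=float)
    dj = np.asarray(dosage_j, dtype=float)
    ok = (di != MISSING) & (dj != MISSING)
    if not ok.any():
        raise ValueError("zero usable loci for this parent pair")
    return float(np.mean((di[ok] / 2.0) * (dj[ok] / 2.0)))


def shared_carrier_ratio(dosage_i, dosage_j) -> float:
    """Jaccard overlap of the parents' deleterious-carrier locus sets."""
    di = np.asarray(dosage_i, dtype=float)
    dj = np.asarray(dosage_j, dtype=float)
    ok = (di != MISSING) & (dj != MISSING)
    if not ok.any():
        raise ValueError("zero usable loci for this parent pair")
    ci = di[ok] > 0
    cj = dj[ok] > 0
    union = np.sum(ci | cj)
    if union == 0:
        return 0.0
    return float(np.sum(ci & cj) / union)


def monte_carlo_f1_hom_ratio(dosage_i, dosage_j, n_draws: int = 10000,
                             seed: int = 0) -> float:
    """Gamete-sampling check of :func:`expected_f1_hom_ratio` (validation)."""
    rng = np.random.default_rng(seed)
    di = np.asarray(dosage_i, dtype=float)
    dj = np.asarray(dosage_j, dtype=float)
    ok = (di != MISSING) & (dj != MISSING)
    di, dj = di[ok], dj[ok]
    gi = rng.random((n_draws, di.size)) < di / 2.0
    gj = rng.random((n_draws, dj.size)) < dj / 2.0
    return float(np.mean(gi & gj))


@dataclass
class CrossDesign:
    group_a: str
    group_b: str
    downsample_n: int
    seed: int
    metric: str = "expected_hom"  # or "shared_carrier"


@dataclass
class CrossResult:
    pairs: pd.DataFrame       # design, parent_i, parent_j, r
    means: dict[str, float]   # per design mean r
    percent_change: float     # 100*(mean_within - mean_between)/mean_within


def cross_cohort(
    gm: GenotypeMatrix,
    dset: DeleteriousSet,
    pm: PopulationMap,
    design: CrossDesign,
) -> CrossResult:
    """Enumerate all unordered within-A, within-B and between-group parent
    pairs after down-sampling each group to ``downsample_n`` (seeded, without
    replacement), and compare mean overlap ratios.

    percent_change > 0 means between-group crosses expose less recessive load
    than within-group crosses.
    """
    metric = {"expected_hom": expected_f1_hom_ratio,
              "shared_carrier": shared_carrier_ratio}[design.metric]
    rng = np.random.default_rng(design.seed)
    chosen = {}
    for g in (design.group_a, design.group_b):
        members = pm.samples_of(g)
        if len(members) < design.downsample_n:
            raise ValueError(f"group {g!r} smaller than downsample_n={design.downsample_n}")
        chosen[g] = list(rng.choice(members, size=design.downsample_n, replace=False))
    sub = gm.dosage[:, dset.all_indices].astype(float)
    index = {s: k for k, s in enumerate(gm.samples)}
    rows = []
    def emit(tag, pairs_iter):
        for si, sj in pairs_iter:
            di, dj = sub[index[si]], sub[index[sj]]
            rows.append((tag, si, sj, metric(di, dj)))
    emit(f"within-{design.group_a}", combinations(chosen[design.group_a], 2))
    emit(f"within-{design.group_b}", combinations(chosen[design.group_b], 2))
    emit("between", product(chosen[design.group_a], chosen[design.group_b]))
    pairs = pd.DataFrame(rows, columns=["design", "parent_i", "parent_j", "r"])
    means = pairs.groupby("design")["r"].mean().to_dict()
    mean_within = np.mean([means[f"within-{design.group_a}"],
                           means[f"within-{design.group_b}"]])
    pct = 100.0 * (mean_within - means["between"]) / mean_within if mean_within else np.nan
    return CrossResult(pairs, means, float(pct))
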