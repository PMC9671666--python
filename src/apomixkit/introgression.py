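"""Site-pattern introgression statistics and divergence scans.

Implements the frequency-based ABBA-BABA family for a ((P1,P2),P3),O trio —
Patterson's D with block-jackknife significance, Martin's windowed f_d, the
f4 statistic and f4-ratio admixture proportion, and Malinsky's tree-aware
f-branch summary — plus windowed D_xy divergence and diagnostic-marker
ancestry profiling of individual samples.

All statistics consume per-population derived-allele frequencies
(:class:`~apomixkit.core.AlleleFreqTable`); masked sites are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AlleleFreqTable,
    BlockJackknifeResult,
    GenotypeMatrix,
    VariantTable,
    assign_to_windows,
    bh_fdr,
    block_jackknife,
    derived_dosage,
    make_blocks,
    ratio_jackknife,
)


@dataclass
class TrioSpec:
    """Populations playing P1, P2, P3 and outgroup in ((P1,P2),P3),O."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self) -> None:
        if len({self.p1, self.p2, self.p3, self.outgroup}) != 4:
            raise ValueError("trio populations must be four distinct labels")

    @property
    def labels(self):
        return [self.p1, self.p2, self.p3, self.outgroup]


@dataclass
class DStatResult:
    d: float
    sum_abba: float
    sum_baba: float
    jackknife: BlockJackknifeResult
    f_d: float | None = None
    undefined: bool = False


@dataclass
class F4RatioResult:
    f4_num: float
    f4_den: float
    alpha: float
    jackknife: BlockJackknifeResult
    undefined: bool = False


def site_patterns(aft: AlleleFreqTable, trio: TrioSpec):
    """Per-site ABBA and BABA weights (NaN at masked sites).

    abba = (1-p1) p2 p3 (1-pO);  baba = p1 (1-p2) p3 (1-pO).
    """
    p1, p2, p3, po = (aft.p(q) for q in trio.labels)
    abba = (1 - p1) * p2 * p3 * (1 - po)
    baba = p1 * (1 - p2) * p3 * (1 - po)
    return abba, baba


def _block_sums(values, chrom, pos, used, n_blocks):
    block_ids = make_blocks(chrom[used], pos[used], n_blocks)
    sums = np.zeros((len(values), n_blocks))
    counts = np.bincount(block_ids, minlength=n_blocks).astype(float)
    for i, v in enumerate(values):
        sums[i] = np.bincount(block_ids, weights=v[used], minlength=n_blocks)
    return sums, counts


def patterson_d(
    aft: AlleleFreqTable,
    trio: TrioSpec,
    windows: pd.DataFrame | None = None,
    n_blocks: int = 20,
    min_sites: int = 10,
):
    """Genome-wide Patterson's D with jackknife Z/p, and optional per-window D.

    Returns (DStatResult, WindowTable-or-None).  Windows with fewer than
    ``min_sites`` informative (abba+baba > 0) sites get NaN.
    """
    abba, baba = site_patterns(aft, trio)
    used = aft.mask_for(trio.labels)
    chrom = aft.sites["chrom"].to_numpy()
    pos = aft.sites["pos"].to_numpy()
    sum_abba = float(np.nansum(abba[used]))
    sum_baba = float(np.nansum(baba[used]))
    if not used.any() or sum_abba + sum_baba == 0:
        jk = BlockJackknifeResult(np.nan, np.nan, np.nan, np.nan, 0, degenerate=True)
        return DStatResult(np.nan, sum_abba, sum_baba, jk, undefined=True), None
    (num_b, den_b), _ = _block_sums(
        [abba - baba, abba + baba], chrom, pos, used, n_blocks
    )
    informative = np.bincount(
        make_blocks(chrom[used], pos[used], n_blocks),
        weights=((abba + baba)[used] > 0).astype(float), minlength=n_blocks,
    )
    keep = den_b > 0
    jk = block_jackknife(
        (num_b.sum() - num_b[keep]) / (den_b.sum() - den_b[keep]),
        weights=informative[keep],
        estimate=num_b.sum() / den_b.sum(),
    )
    result = DStatResult(jk.estimate, sum_abba, sum_baba, jk)
    wt = None
    if windows is not None:
        wt = _window_ratio(windows, chrom, pos, used, abba - baba, abba + baba,
                           (abba + baba) > 0, min_sites, "D")
    return result, wt


def _window_ratio(windows, chrom, pos, used, num, den, informative, min_sites, colname):
    rows = []
    for i, sel in assign_to_windows(windows, chrom, pos):
        sel = sel[used[sel]]
        n_inf = int(np.sum(informative[sel]))
        if n_inf < min_sites or np.nansum(den[sel]) == 0:
            val = np.nan
        else:
            val = float(np.nansum(num[sel]) / np.nansum(den[sel]))
        w = windows.iloc[i]
        rows.append((w.chrom, w.start, w.end, n_inf, val))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites_used", colname])


def f_d(
    aft: AlleleFreqTable,
    trio: TrioSpec,
    windows: pd.DataFrame,
    min_sites: int = 10,
) -> pd.DataFrame:
    """Windowed f_d (dynamic-donor admixture-fraction estimator).

    The denominator substitutes, at every site, whichever of P2/P3 has the
    higher derived frequency for both donor slots.  Windows where D < 0 are
    reported NaN: the estimator is undefined there.
    """
    p1, p2, p3, po = (aft.p(q) for q in trio.labels)
    abba, baba = site_patterns(aft, trio)
    pd_max = np.maximum(p2, p3)
    abba_d = (1 - p1) * pd_max * pd_max * (1 - po)
    baba_d = p1 * (1 - pd_max) * pd_max * (1 - po)
    used = aft.mask_for(trio.labels)
    chrom = aft.sites["chrom"].to_numpy()
    pos = aft.sites["pos"].to_numpy()
    num, den = abba - baba, abba_d - baba_d
    out = _window_ratio(windows, chrom, pos, used, num, den,
                        (abba + baba) > 0, min_sites, "f_d")
    # D < 0 windows -> NaN
    dwin = _window_ratio(windows, chrom, pos, used, num, abba + baba,
                         (abba + baba) > 0, min_sites, "D")
    out.loc[dwin["D"] < 0, "f_d"] = np.nan
    return out


def f4(aft: AlleleFreqTable, a: str, b: str, c: str, d: str) -> float:
    """Mean over usable sites of (pA - pB)(pC - pD)."""
    used = aft.mask_for([a, b, c, d])
    if not used.any():
        return np.nan
    pa, pb, pc, pdd = (aft.p(q)[used] for q in (a, b, c, d))
    return float(np.mean((pa - pb) * (pc - pdd)))


def f4_ratio(
    aft: AlleleFreqTable,
    a: str,
    b: str,
    c: str,
    x: str,
    outgroup: str,
    n_blocks: int = 20,
    den_tol: float = 1e-12,
) -> F4RatioResult:
    """Admixture proportion alpha = f4(A,O;X,C) / f4(A,O;B,C).

    X is the putatively admixed population between sources B (alpha=1 pole)
    and C (alpha=0 pole); A is an unadmixed reference on B's side.
    """
    used = aft.mask_for([a, b, c, x, outgroup])
    pa, pb, pc, px, po = (aft.p(q) for q in (a, b, c, x, outgroup))
    num = (pa - po) * (px - pc)
    den = (pa - po) * (pb - pc)
    chrom = aft.sites["chrom"].to_numpy()
    pos = aft.sites["pos"].to_numpy()
    (num_b, den_b), counts = _block_sums([num, den], chrom, pos, used, n_blocks)
    f4n, f4den = num_b.sum() / used.sum(), den_b.sum() / used.sum()
    if abs(den_b.sum()) < den_tol:
        jk = BlockJackknifeResult(np.nan, np.nan, np.nan, np.nan, 0, degenerate=True)
        return F4RatioResult(f4n, f4den, np.nan, jk, undefined=True)
    keep = counts > 0
    jk = block_jackknife(
        (num_b.sum() - num_b[keep]) / (den_b.sum() - den_b[keep]),
        weights=counts[keep],
        estimate=num_b.sum() / den_b.sum(),
    )
    return F4RatioResult(f4n, f4den, jk.estimate, jk)


# ---------------------------------------------------------------------------
# f-branch


@dataclass
class FbranchResult:
    """f_b matrix over (branch, donor population) with jackknife p and BH flags."""

    fb: pd.DataFrame          # branches x donors, NaN where untestable
    z: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    significant: pd.DataFrame


def _clade_leaves(node):
    return sorted(leaf.taxon.label for leaf in node.leaf_iter())


def f_branch(
    tree,
    aft: AlleleFreqTable,
    outgroup: str,
    n_blocks: int = 20,
    alpha: float = 0.05,
) -> FbranchResult:
    """Branch-specific excess allele sharing f_b(C).

    For each non-root branch b: f_b(C) = median over A in the sister clade of
    [min over B below b of f-hat(A,B;C,O)], with
    f-hat = sum (pB-pA)(pC-pO) / sum (pC-pA)(pC-pO).  C ranges over
    populations outside b's parent clade (never the outgroup).  Significance
    is a delete-one-block jackknife of the full median-of-minima, BH-corrected
    across testable (b, C) cells.

    ``tree`` is a rooted, fully bifurcating dendropy Tree whose leaf labels
    are populations in ``aft`` (the outgroup leaf may be present or absent).
    """
    import dendropy

    if not isinstance(tree, dendropy.Tree):
        raise TypeError("tree must be a dendropy Tree")
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and len(node.child_nodes()) != 2:
            raise ValueError(
                "tree must be fully bifurcating: resolve polytomies before calling"
            )
    pops = [t.label for t in tree.taxon_namespace if t.label != outgroup]
    chrom = aft.sites["chrom"].to_numpy()
    pos = aft.sites["pos"].to_numpy()
    po = aft.p(outgroup)

    # per-trio per-block sums, computed lazily and cached
    cache: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] = {}

    def trio_sums(a, b, c):
        key = (a, b, c)
        if key not in cache:
            pa, pb, pc = aft.p(a), aft.p(b), aft.p(c)
            used = aft.mask_for([a, b, c, outgroup])
            num = (pb - pa) * (pc - po)
            den = (pc - pa) * (pc - po)
            (nb, db), _ = _block_sums([num, den], chrom, pos, used, n_blocks)
            cache[key] = (nb, db)
        return cache[key]

    branches = []  # (branch label, leaves below, leaves in sister, donors)
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        sibs = [ch for ch in parent.child_nodes() if ch is not node]
        if len(sibs) != 1:
            continue
        below = [x for x in _clade_leaves(node) if x != outgroup]
        sister = [x for x in _clade_leaves(sibs[0]) if x != outgroup]
        if not below or not sister:
            continue
        donors = [c for c in pops if c not in below and c not in sister]
        label = below[0] if len(below) == 1 else "(" + ",".join(below) + ")"
        branches.append((label, below, sister, donors))

    labels = [b[0] for b in branches]
    fb = pd.DataFrame(np.nan, index=labels, columns=pops)
    zmat = fb.copy()
    pmat = fb.copy()

    def median_min(delete_block=None):
        """f_b for every (branch, donor) with one block optionally removed."""
        out = {}
        for label, below, sister, donors in branches:
            for c in donors:
                vals = []
                for a in sister:
                    mins = []
                    for b in below:
                        nb, db = trio_sums(a, b, c)
                        if delete_block is None:
                            n, d = nb.sum(), db.sum()
                        else:
                            n = nb.sum() - nb[delete_block]
                            d = db.sum() - db[delete_block]
                        mins.append(n / d if d != 0 else np.nan)
                    vals.append(np.nanmin(mins) if mins else np.nan)
                out[(label, c)] = float(np.nanmedian(vals)) if vals else np.nan
        return out

    full = median_min()
    loo = [median_min(delete_block=j) for j in range(n_blocks)]
    for (label, c), est in full.items():
        loo_vals = np.array([loo[j][(label, c)] for j in range(n_blocks)])
        if np.isnan(est) or np.isnan(loo_vals).any():
            continue
        jk = block_jackknife(loo_vals, estimate=est)
        fb.loc[label, c] = est
        zmat.loc[label, c] = jk.z
        pmat.loc[label, c] = jk.p
    flat = pmat.to_numpy().ravel()
    qflat = bh_fdr(flat)
    qmat = pd.DataFrame(qflat.reshape(pmat.shape), index=labels, columns=pops)
    # one-sided interest: only positive f_b can indicate donor->branch flow
    sig = (qmat < alpha) & (fb > 0)
    return FbranchResult(fb, zmat, pmat, qmat, sig)


# ---------------------------------------------------------------------------
# divergence


def d_xy(
    aft: AlleleFreqTable,
    pop_x: str,
    pop_y: str,
    windows: pd.DataFrame,
    accessible_sites=None,
) -> pd.DataFrame:
    """Windowed mean pairwise divergence.

    Per site, d = p_x (1-p_y) + p_y (1-p_x); the window value divides the sum
    of d by ``accessible_sites`` for that window (array aligned with
    ``windows``), else by the window's bp span.  The output carries a
    ``denominator`` column naming which convention was used.
    """
    px, py = aft.p(pop_x), aft.p(pop_y)
    used = aft.mask_for([pop_x, pop_y])
    d = px * (1 - py) + py * (1 - px)
    chrom = aft.sites["chrom"].to_numpy()
    pos = aft.sites["pos"].to_numpy()
    rows = []
    for i, sel in assign_to_windows(windows, chrom, pos):
        sel = sel[used[sel]]
        w = windows.iloc[i]
        acc = (w.end - w.start) if accessible_sites is None else accessible_sites[i]
        val = float(np.nansum(d[sel]) / acc) if acc > 0 else np.nan
        rows.append((w.chrom, w.start, w.end, len(sel), val))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites_used", "d_xy"])
    out.attrs["denominator"] = "window_bp" if accessible_sites is None else "accessible_sites"
    return out


# ---------------------------------------------------------------------------
# diagnostic markers & ancestry


@dataclass
class AncestryProfile:
    total: pd.Series                # per sample donor-ancestry proportion
    window_fraction: pd.DataFrame   # windows x samples donor fraction
    fragments: pd.DataFrame         # sample, chrom, start, end


def diagnostic_markers(
    aft: AlleleFreqTable,
    donor_pop: str,
    other_pop: str,
    min_delta: float = 1.0,
) -> pd.DataFrame:
    """Sites distinguishing donor from other reference panel.

    Returns (site_index, chrom, pos, donor_is_derived) for sites with
    |p_donor - p_other| >= min_delta; min_delta = 1 keeps fixed differences.
    """
    pa, pb = aft.p(donor_pop), aft.p(other_pop)
    ok = aft.mask_for([donor_pop, other_pop])
    sel = np.flatnonzero(ok & (np.abs(pa - pb) >= min_delta))
    if sel.size == 0:
        raise ValueError(
            f"no diagnostic markers at min_delta={min_delta}; lower min_delta"
        )
    return pd.DataFrame(
        {
            "site_index": sel,
            "chrom": aft.sites["chrom"].to_numpy()[sel],
            "pos": aft.sites["pos"].to_numpy()[sel],
            "donor_is_derived": pa[sel] > pb[sel],
        }
    )


def ancestry_profile(
    gm: GenotypeMatrix,
    vt: VariantTable,
    markers: pd.DataFrame,
    windows: pd.DataFrame,
    frag_threshold: float = 0.5,
) -> AncestryProfile:
    """Per-sample donor-ancestry from diagnostic-marker dosages.

    total = sum of donor-allele dosages / (2 x markers genotyped); fragments
    are maximal runs of windows with donor fraction >= ``frag_threshold``
    (0.5 = a heterozygous donor tract in a diploid).
    """
    dd = derived_dosage(vt, gm)[:, markers["site_index"].to_numpy()]
    flip = ~markers["donor_is_derived"].to_numpy()
    dd[:, flip] = 2.0 - dd[:, flip]
    called = ~np.isnan(dd)
    with np.errstate(invalid="ignore"):
        total = np.nansum(dd, axis=1) / (2.0 * called.sum(axis=1))
    total = pd.Series(total, index=gm.samples, name="donor_proportion")
    mc = markers["chrom"].to_numpy()
    mp = markers["pos"].to_numpy()
    frac_rows = np.full((len(windows), len(gm.samples)), np.nan)
    for i, sel in assign_to_windows(windows, mc, mp):
        if sel.size == 0:
            continue
        sub = dd[:, sel]
        with np.errstate(invalid="ignore"):
            frac_rows[i] = np.nansum(sub, axis=1) / (2.0 * np.sum(~np.isnan(sub), axis=1))
    wf = pd.DataFrame(frac_rows, columns=gm.samples)
    wf.insert(0, "chrom", windows["chrom"].to_numpy())
    wf.insert(1, "start", windows["start"].to_numpy())
    wf.insert(2, "end", windows["end"].to_numpy())
    frag_rows = []
    for s in gm.samples:
        vals = wf[s].to_numpy()
        hot = vals >= frag_threshold
        for chrom_name in pd.unique(wf["chrom"]):
            on_chrom = wf["chrom"].to_numpy() == chrom_name
            idx = np.flatnonzero(on_chrom & hot)
            if idx.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(idx) > 1)
            starts = np.r_[idx[0], idx[breaks + 1]]
            ends = np.r_[idx[breaks], idx[-1]]
            for a, b in zip(starts, ends):
                frag_rows.append((s, chrom_name, int(wf["start"].iloc[a]), int(wf["end"].iloc[b])))
    fragments = pd.DataFrame(frag_rows, columns=["sample", "chrom", "start", "end"])
    return AncestryProfile(total, wf, fragments)
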