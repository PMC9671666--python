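"""Bulked-segregant QTL scan and segregation test.

From per-marker allele read counts in two phenotype bulks (high = apomictic,
low = sexual), the scan computes per-bulk SNP-indices and their difference,
the 2x2 G statistic, a tricube-smoothed G' over a physical window, and
p/q-values from a log-normal null fitted robustly (median/MAD, optionally
Hampel) to the bulk of the G' distribution, then calls FDR-thresholded
significant intervals.  The companion segregation test is the 1-df Pearson
chi-squared for a 1:1 (pseudo-testcross) phenotype ratio, uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import bh_fdr


def snp_index(counts: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Per-bulk SNP-index (alt read fraction) and delta.

    ``counts`` columns: chrom, pos, ref_high, alt_high, ref_low, alt_low.
    Markers with depth < min_depth in either bulk are masked (NaN).
    """
    out = counts[["chrom", "pos"]].copy()
    dh = counts["ref_high"] + counts["alt_high"]
    dl = counts["ref_low"] + counts["alt_low"]
    with np.errstate(invalid="ignore", divide="ignore"):
        ih = counts["alt_high"] / dh
        il = counts["alt_low"] / dl
    masked = (dh < min_depth) | (dl < min_depth)
    out["snp_index_high"] = ih.where(~masked)
    out["snp_index_low"] = il.where(~masked)
    out["delta_snp_index"] = out["snp_index_high"] - out["snp_index_low"]
    out["depth_high"] = dh
    out["depth_low"] = dl
    return out


def g_statistic(counts: pd.DataFrame, min_depth: int = 10) -> np.ndarray:
    """Per-marker G = 2 sum n ln(n/e) over the 2x2 bulk x allele table, with
    expected counts from the margins and 0*ln(0) = 0.  NaN where masked."""
    n = counts[["ref_high", "alt_high", "ref_low", "alt_low"]].to_numpy(dtype=float)
    obs = n.reshape(-1, 2, 2)  # bulk x allele
    row = obs.sum(axis=2, keepdims=True)
    col = obs.sum(axis=1, keepdims=True)
    tot = obs.sum(axis=(1, 2), keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        exp = row * col / tot
        term = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = 2.0 * term.sum(axis=(1, 2))
    g = np.maximum(g, 0.0)  # clip tiny negative round-off
    masked = (row[:, 0, 0] < min_depth) | (row[:, 1, 0] < min_depth)
    g[masked] = np.nan
    return g


def g_prime(g: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
            half_window_bp: float = 1e6) -> np.ndarray:
    """Tricube-weighted local mean of G within +-half_window_bp on the same
    chromosome: w = (1 - (d/W)^3)^3, renormalised over non-NaN neighbours.
    An isolated marker keeps G' = G."""
    g = np.asarray(g, dtype=float)
    pos = np.asarray(pos, dtype=float)
    out = np.full_like(g, np.nan)
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        p = pos[sel]
        order = np.argsort(p)
        p, gs = p[order], g[sel][order]
        res = np.full_like(gs, np.nan)
        lo = np.searchsorted(p, p - half_window_bp, side="left")
        hi = np.searchsorted(p, p + half_window_bp, side="right")
        for k in range(len(p)):
            if np.isnan(gs[k]):
                continue
            idx = np.arange(lo[k], hi[k])
            d = np.abs(p[idx] - p[k]) / half_window_bp
            w = (1.0 - d**3) ** 3
            ok = ~np.isnan(gs[idx]) & (w > 0)
            res[k] = np.sum(w[ok] * gs[idx][ok]) / np.sum(w[ok])
        out[sel[order]] = res
    return out


def gprime_pvalues(gprime: np.ndarray, method: str = "median_mad"):
    """(p, q) from a log-normal null fitted robustly to the bulk of G'.

    ``median_mad``: mu = median(ln G'), sigma = 1.4826 * MAD(ln G').
    ``hampel``: trims markers above the Hampel outlier bound
    (median + 5.2 * MAD on the log scale) before a plain normal fit.
    p = upper tail of the fitted log-normal; q = Benjamini-Hochberg.
    """
    gp = np.asarray(gprime, dtype=float)
    ok = ~np.isnan(gp) & (gp > 0)
    lg = np.log(gp[ok])
    if lg.size < 2 or np.allclose(lg, lg[0]):
        raise ValueError("degenerate (constant) G' distribution: cannot fit null")
    med = np.median(lg)
    mad = np.median(np.abs(lg - med))
    if mad == 0:
        raise ValueError("degenerate G' distribution (zero MAD)")
    if method == "median_mad":
        mu, sigma = med, 1.4826 * mad
    elif method == "hampel":
        keep = lg <= med + 5.2 * mad
        mu, sigma = float(np.mean(lg[keep])), float(np.std(lg[keep], ddof=1))
    else:
        raise ValueError(f"unknown null-fit method {method!r}")
    p = np.full(gp.shape, np.nan)
    p[ok] = stats.norm.sf((np.log(gp[ok]) - mu) / sigma)
    return p, bh_fdr(p)


@dataclass
class QtlScanResult:
    markers: pd.DataFrame   # per-marker indices, G, Gprime, p, q
    regions: pd.DataFrame   # chrom, start, end, n_markers, min_q


def significant_regions(markers: pd.DataFrame, q_threshold: float = 0.01,
                        min_markers: int = 3, gap_bp: float = 5e5) -> pd.DataFrame:
    """Maximal runs of q < threshold markers, merged across gaps < gap_bp and
    filtered to runs of at least ``min_markers`` markers."""
    rows = []
    sig = markers[markers["q"] < q_threshold]
    for c, sub in sig.groupby("chrom", sort=False):
        p = sub["pos"].to_numpy()
        q = sub["q"].to_numpy()
        order = np.argsort(p)
        p, q = p[order], q[order]
        start_i = 0
        for k in range(1, len(p) + 1):
            if k == len(p) or p[k] - p[k - 1] >= gap_bp:
                run = slice(start_i, k)
                if k - start_i >= min_markers:
                    rows.append((c, int(p[run][0]), int(p[run][-1]) + 1,
                                 k - start_i, float(q[run].min())))
                start_i = k
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_markers", "min_q"])


def qtl_scan(counts: pd.DataFrame, min_depth: int = 10, half_window_bp: float = 1e6,
             q_threshold: float = 0.01, min_markers: int = 3,
             gap_bp: float = 5e5) -> QtlScanResult:
    """Full scan: SNP-indices, G, G', p/q, significant regions."""
    m = snp_index(counts, min_depth=min_depth)
    m["G"] = g_statistic(counts, min_depth=min_depth)
    m["Gprime"] = g_prime(m["G"].to_numpy(), m["chrom"].to_numpy(),
                          m["pos"].to_numpy(), half_window_bp)
    m["p"], m["q"] = gprime_pvalues(m["Gprime"].to_numpy())
    regions = significant_regions(m, q_threshold, min_markers, gap_bp)
    return QtlScanResult(m, regions)


@dataclass
class SegregationTest:
    n_class1: int
    n_class2: int
    expected_ratio: tuple
    chi2: float
    p: float


def segregation_test(n1: int, n2: int, ratio=(1, 1)) -> SegregationTest:
    """Pearson chi-squared (1 df, no continuity correction) of observed class
    counts against an expected segregation ratio."""
    total = n1 + n2
    if total <= 0:
        raise ValueError("zero total count")
    frac = ratio[0] / (ratio[0] + ratio[1])
    exp = np.array([total * frac, total * (1 - frac)])
    obs = np.array([n1, n2], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationTest(n1, n2, tuple(ratio), chi2, p)
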