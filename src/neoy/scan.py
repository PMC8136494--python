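"""Windowed population-genomic degeneration scans.

Between-sex differentiation uses the Weir & Cockerham (1984) two-level
estimator: per-site variance components a (among populations), b (among
individuals within populations) and c (within individuals) computed from
genotype counts, summarised per window in the weighted ratio-of-sums form
``F_ST = sum(a) / sum(a + b + c)`` (the vcftools windowed convention;
negative per-site components are retained, not clamped).  Nucleotide
diversity is the allele-frequency-unbiased form ``sum 2 p q n/(n-1)`` per
window bp.  The depth-ratio track normalises the male:female coverage ratio
so autosomes sit at 1; a single-copy X region with no Y cross-mapping then
sits at 0.5 and a partially diverged region between 0.5 and 1.  High
divergence regions (HDRs) are called by thresholding differentiation and
depth jointly and merging flagged runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    FEMALE,
    MALE,
    GT_HET,
    GenotypeMatrix,
    Region,
    WindowTrack,
    merge_flagged_windows,
)


# ------------------------------------------------------- Weir & Cockerham
def wc_site_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site variance components for r = 2
    populations.

    Parameters are per-population arrays (last axis = population): ``n``
    called diploid counts, ``p`` alternate-allele frequencies, ``h``
    heterozygote frequencies.  Returns (a, b, c) per site.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[-1]
    nbar = n.mean(axis=-1)
    nc = (r * nbar - (n**2).sum(axis=-1) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=-1) / (r * nbar)
    s2 = (n * (p - pbar[..., None]) ** 2).sum(axis=-1) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=-1) / (r * nbar)
    a = (nbar / nc) * (
        s2
        - 1.0
        / (nbar - 1.0)
        * (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar)
        - (r - 1.0) / r * s2
        - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def _sex_counts(gm: GenotypeMatrix):
    """Per-site (n, p, h) stacked over (female, male)."""
    out_n, out_p, out_h = [], [], []
    for sel in (gm.is_female, gm.is_male):
        g = gm.geno[:, sel]
        called = g >= 0
        n = np.count_nonzero(called, axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        het = np.count_nonzero(g == GT_HET, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
            h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
        out_n.append(n)
        out_p.append(p)
        out_h.append(h)
    return (np.stack(out_n, axis=-1), np.stack(out_p, axis=-1), np.stack(out_h, axis=-1))


def wc_fst_window(gm: GenotypeMatrix, windows: WindowTrack, min_per_sex: int = 2) -> WindowTrack:
    """Windowed weighted Weir & Cockerham F_ST between the sexes:
    ``sum(a) / sum(a+b+c)`` over usable sites per window.

    Sites with fewer than ``min_per_sex`` called diploids in either sex, and
    monomorphic sites, are skipped; windows with no usable site are masked.
    """
    on_chrom = gm.sites["chrom"].to_numpy() == windows.chrom
    n, p, h = _sex_counts(gm)
    usable = on_chrom & (n >= min_per_sex).all(axis=-1)
    # skip sites with no variation in the pooled sample
    with np.errstate(invalid="ignore"):
        pooled = (n * p).sum(axis=-1) / np.maximum(n.sum(axis=-1), 1)
    usable &= (pooled > 0) & (pooled < 1)
    a = np.zeros(gm.n_sites)
    bc = np.zeros(gm.n_sites)
    if np.any(usable):
        aa, bb, cc = wc_site_components(n[usable], p[usable], h[usable])
        a[usable] = aa
        bc[usable] = aa + bb + cc
    pos0 = gm.sites["pos"].to_numpy() - 1
    idx = windows.window_index(pos0)
    ok = usable & (idx >= 0)
    num = np.bincount(idx[ok], weights=a[ok], minlength=windows.n)
    den = np.bincount(idx[ok], weights=bc[ok], minlength=windows.n)
    valid = np.bincount(idx[ok], minlength=windows.n) > 0
    valid &= den != 0
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(valid, num / np.where(den == 0, 1.0, den), np.nan)
    out = WindowTrack(windows.chrom, windows.starts, windows.ends, span=windows.span)
    out.mask = windows.mask & valid
    out.set_stat("fst", fst)
    return out


# ------------------------------------------------------------ diversity
def pi_window(gm: GenotypeMatrix, windows: WindowTrack, sex: str | None = None) -> WindowTrack:
    """Per-window nucleotide diversity per bp: sum over sites of
    ``2 p q n/(n-1)`` (n = called allele count) divided by window span,
    optionally for one sex."""
    sel = np.ones(gm.n_samples, dtype=bool)
    if sex == MALE:
        sel = gm.is_male
    elif sex == FEMALE:
        sel = gm.is_female
    g = gm.geno[:, sel]
    called = g >= 0
    n_allele = 2 * np.count_nonzero(called, axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pfreq = np.where(n_allele > 0, alt / np.maximum(n_allele, 1), 0.0)
        site_pi = np.where(
            n_allele > 1,
            2.0 * pfreq * (1.0 - pfreq) * n_allele / np.maximum(n_allele - 1, 1),
            0.0,
        )
    on_chrom = gm.sites["chrom"].to_numpy() == windows.chrom
    pos0 = gm.sites["pos"].to_numpy() - 1
    idx = windows.window_index(pos0)
    ok = on_chrom & (idx >= 0)
    tot = np.bincount(idx[ok], weights=site_pi[ok], minlength=windows.n)
    spans = (windows.ends - windows.starts).astype(float)
    out = WindowTrack(windows.chrom, windows.starts, windows.ends, span=windows.span)
    name = "pi" if sex is None else f"pi_{sex}"
    out.set_stat(name, tot / spans)
    return out


# ------------------------------------------------------------ depth ratio
def depth_ratio_track(
    depth_m: WindowTrack,
    depth_f: WindowTrack,
    male_auto_mean: float,
    female_auto_mean: float,
    stat: str = "mean_depth",
    orient: str = "mf",
) -> WindowTrack:
    """Autosome-normalised male:female depth ratio per window:
    ``(male depth / male autosomal mean) / (female depth / female autosomal
    mean)``.  Windows with zero female depth are masked (undefined).
    ``orient="fm"`` flips the ratio to female:male."""
    if depth_m.n != depth_f.n or depth_m.chrom != depth_f.chrom:
        raise ValueError("depth tracks must share a window scaffold")
    if male_auto_mean <= 0 or female_auto_mean <= 0:
        raise ValueError("autosomal normalisation means must be positive")
    if orient not in ("mf", "fm"):
        raise ValueError("orient must be 'mf' or 'fm'")
    m = depth_m.stat(stat) / male_auto_mean
    f = depth_f.stat(stat) / female_auto_mean
    if orient == "fm":
        m, f = f, m
    valid = depth_m.mask & depth_f.mask & (f > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(valid, m / np.where(f == 0, 1.0, f), np.nan)
    out = WindowTrack(depth_m.chrom, depth_m.starts, depth_m.ends, span=depth_m.span)
    out.mask = valid
    out.set_stat("depth_ratio", ratio)
    return out


def autosomal_mean_depth(tracks: dict[str, WindowTrack], auto_chroms, stat="mean_depth") -> float:
    vals = [tracks[c].stat(stat)[tracks[c].mask] for c in auto_chroms if c in tracks]
    if not vals:
        raise ValueError("no autosomal depth windows available for normalisation")
    return float(np.nanmean(np.concatenate(vals)))


# -------------------------------------------------------------------- LD
def ld_r2(
    gm: GenotypeMatrix,
    region: Region,
    max_dist: int = 100_000,
    max_sites: int | None = 200,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, float]:
    """Composite genotype-correlation r^2 for site pairs within ``max_dist``.

    Returns a per-pair table (pos1, pos2, r2) and the mean r^2.  Monomorphic
    or all-missing pairs are skipped.  ``max_sites`` caps the number of sites
    (evenly subsampled; pass a generator for random subsampling).
    """
    sub = gm.subset_region(region)
    from .snpsex import segregating_mask

    sub = sub.subset_sites(segregating_mask(sub))
    if sub.n_sites < 2:
        raise ValueError("need at least two segregating sites for LD")
    if max_sites is not None and sub.n_sites > max_sites:
        if rng is not None:
            pick = np.sort(rng.choice(sub.n_sites, size=max_sites, replace=False))
        else:
            pick = np.linspace(0, sub.n_sites - 1, max_sites).astype(int)
        sub = sub.subset_sites(np.isin(np.arange(sub.n_sites), pick))
    pos = sub.sites["pos"].to_numpy()
    g = sub.geno.astype(float)
    g[g < 0] = np.nan
    rows = []
    for i in range(sub.n_sites - 1):
        for j in range(i + 1, sub.n_sites):
            if pos[j] - pos[i] > max_dist:
                break
            both = ~np.isnan(g[i]) & ~np.isnan(g[j])
            gi, gj = g[i][both], g[j][both]
            if gi.size < 2 or np.var(gi) == 0 or np.var(gj) == 0:
                continue
            r = np.corrcoef(gi, gj)[0, 1]
            rows.append((int(pos[i]), int(pos[j]), float(r * r)))
    table = pd.DataFrame(rows, columns=["pos1", "pos2", "r2"])
    mean = float(table["r2"].mean()) if len(table) else float("nan")
    return table, mean


# ------------------------------------------------------------- HDR calling
def autosomal_fst_threshold(
    fst_tracks: dict[str, WindowTrack], auto_chroms, k_sd: float = 5.0
) -> float:
    """Default F_ST flag threshold: autosomal mean + k_sd standard
    deviations over autosomal windows."""
    vals = np.concatenate(
        [fst_tracks[c].stat("fst")[fst_tracks[c].mask] for c in auto_chroms if c in fst_tracks]
    )
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no autosomal F_ST windows to derive a threshold")
    return float(vals.mean() + k_sd * vals.std())


def call_hdr(
    fst: WindowTrack,
    depth_ratio: WindowTrack,
    fst_threshold: float,
    depth_max: float = 0.9,
    max_gap: int = 1,
) -> list[Region]:
    """Call high-divergence regions on one chromosome.

    A window is flagged when F_ST >= ``fst_threshold`` AND depth ratio <=
    ``depth_max``; flagged runs are merged across gaps of at most
    ``max_gap`` windows.  Idempotent and invariant to window order.
    """
    if fst.n != depth_ratio.n or fst.chrom != depth_ratio.chrom:
        raise ValueError("tracks must share a window scaffold")
    if not (
        np.array_equal(fst.starts, depth_ratio.starts)
        and np.array_equal(fst.ends, depth_ratio.ends)
    ):
        raise ValueError("tracks must share a window scaffold")
    f = fst.stat("fst")
    d = depth_ratio.stat("depth_ratio")
    with np.errstate(invalid="ignore"):
        flags = (
            fst.mask
            & depth_ratio.mask
            & (np.nan_to_num(f, nan=-np.inf) >= fst_threshold)
            & (np.nan_to_num(d, nan=np.inf) <= depth_max)
        )
    return merge_flagged_windows(fst, flags, max_gap=max_gap)
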