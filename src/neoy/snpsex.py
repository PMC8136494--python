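"""Sex-genotype-pattern analysis.

A sex-chromosome-specific SNP (scsSNP) is a site showing female homogamety
and male heterogamety: all called females homozygous for one shared allele
and all called males heterozygous.  In an X1X2Y system every fixed X--Y
difference inside the non-recombining region produces exactly this pattern
when genotypes are called against the female (X) reference.  "Female
homogamety" is read as all females homozygous for the *same* allele — a
Y-specific allele implies one shared X allele — so either hom-ref or
hom-alt females qualify.  A tolerance parameter absorbs genotyping error;
the default (0) keeps the strict rule.
"""

from __future__ import annotations

import numpy as np

from .core import GT_HET, GT_HOM_ALT, GT_HOM_REF, GenotypeMatrix, Region, WindowTrack

SCS = "scsSNP"
NOT_SCS = "not"
UNCLASSIFIABLE = "not-classifiable"


def classify_scs_snp(
    genos,
    is_male,
    tolerance: float = 0.0,
    min_call_rate: float = 0.8,
) -> str:
    """Classify one biallelic site from genotype codes and sex labels.

    scsSNP iff (a) call rate >= ``min_call_rate`` in each sex, (b) at least
    ``1 - tolerance`` of called females are homozygous for one common allele,
    and (c) at least ``1 - tolerance`` of called males are heterozygous.
    A site with one sex entirely missing is not classifiable.
    """
    genos = np.asarray(genos)
    is_male = np.asarray(is_male, dtype=bool)
    fg = genos[~is_male]
    mg = genos[is_male]
    if fg.size == 0 or mg.size == 0:
        return UNCLASSIFIABLE
    f_called = fg[fg >= 0]
    m_called = mg[mg >= 0]
    if f_called.size == 0 or m_called.size == 0:
        return UNCLASSIFIABLE
    if f_called.size < min_call_rate * fg.size or m_called.size < min_call_rate * mg.size:
        return NOT_SCS
    need_f = (1.0 - tolerance) * f_called.size
    need_m = (1.0 - tolerance) * m_called.size
    hom_ref = np.count_nonzero(f_called == GT_HOM_REF)
    hom_alt = np.count_nonzero(f_called == GT_HOM_ALT)
    het_m = np.count_nonzero(m_called == GT_HET)
    if max(hom_ref, hom_alt) >= need_f and het_m >= need_m:
        return SCS
    return NOT_SCS


def classify_scs_sites(
    gm: GenotypeMatrix, tolerance: float = 0.0, min_call_rate: float = 0.8
) -> np.ndarray:
    """Vectorised scsSNP classification of every site; returns an array of
    class strings aligned with ``gm.sites``."""
    male = gm.is_male
    fg = gm.geno[:, ~male]
    mg = gm.geno[:, male]
    f_called = np.count_nonzero(fg >= 0, axis=1)
    m_called = np.count_nonzero(mg >= 0, axis=1)
    f_hom_ref = np.count_nonzero(fg == GT_HOM_REF, axis=1)
    f_hom_alt = np.count_nonzero(fg == GT_HOM_ALT, axis=1)
    m_het = np.count_nonzero(mg == GT_HET, axis=1)
    out = np.full(gm.n_sites, NOT_SCS, dtype=object)
    unclass = (f_called == 0) | (m_called == 0)
    callable_ = (
        (f_called >= min_call_rate * fg.shape[1])
        & (m_called >= min_call_rate * mg.shape[1])
        & ~unclass
    )
    is_scs = (
        callable_
        & (np.maximum(f_hom_ref, f_hom_alt) >= (1.0 - tolerance) * f_called)
        & (m_het >= (1.0 - tolerance) * m_called)
    )
    out[is_scs] = SCS
    out[unclass] = UNCLASSIFIABLE
    return out


def segregating_mask(gm: GenotypeMatrix) -> np.ndarray:
    """Sites whose called alternate-allele frequency is strictly between 0
    and 1."""
    called = gm.geno >= 0
    n_called = np.count_nonzero(called, axis=1)
    alt = np.where(called, gm.geno, 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return (n_called > 0) & (alt > 0) & (alt < 2 * n_called)


def male_specific_het_fraction(
    gm: GenotypeMatrix,
    region: Region,
    tolerance: float = 0.0,
    min_call_rate: float = 0.8,
) -> float:
    """Share of segregating sites in ``region`` that are scsSNPs.

    NaN (undefined marker) when the region holds no segregating site.
    """
    sub = gm.subset_region(region)
    if sub.n_sites == 0:
        raise ValueError(f"region {region} overlaps no site")
    seg = segregating_mask(sub)
    n_seg = int(np.count_nonzero(seg))
    if n_seg == 0:
        return float("nan")
    cls = classify_scs_sites(sub, tolerance=tolerance, min_call_rate=min_call_rate)
    n_scs = int(np.count_nonzero((cls == SCS) & seg))
    return n_scs / n_seg


def observed_heterozygosity(gm: GenotypeMatrix, region: Region) -> dict[str, float]:
    """Per-individual observed heterozygosity (het calls / called sites) in
    ``region``; individuals with no called site map to NaN."""
    sub = gm.subset_region(region)
    called = np.count_nonzero(sub.geno >= 0, axis=0)
    het = np.count_nonzero(sub.geno == GT_HET, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    return dict(zip(gm.samples, frac.astype(float)))


def snp_density_track(
    gm: GenotypeMatrix, windows: WindowTrack, sex: str | None = None
) -> WindowTrack:
    """Segregating sites per bp per window (optionally restricted to the
    genotypes of one sex)."""
    sub = gm
    if sex is not None:
        keep = gm.sex == sex
        sub = GenotypeMatrix(
            [s for s, k in zip(gm.samples, keep) if k],
            gm.sex[keep],
            gm.sites,
            gm.geno[:, keep],
        )
    on_chrom = sub.sites["chrom"].to_numpy() == windows.chrom
    seg = segregating_mask(sub) & on_chrom
    pos0 = sub.sites["pos"].to_numpy()[seg] - 1
    idx = windows.window_index(pos0)
    counts = np.bincount(idx[idx >= 0], minlength=windows.n)
    spans = (windows.ends - windows.starts).astype(float)
    out = WindowTrack(windows.chrom, windows.starts, windows.ends, span=windows.span)
    name = "snp_density" if sex is None else f"snp_density_{sex}"
    out.set_stat(name, counts / spans)
    return out
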