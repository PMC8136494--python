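"""Sex-specific expression filtering on TPM matrices.

A gene is called male-gonad-specific when its TPM is exactly zero in at
least ``min_zero_females`` ovaries, below ``female_ceiling`` in every other
ovary, and above ``male_floor`` in the testes.  The male condition is read
strictly — every testis sample must exceed the floor — which is what
guarantees "detected only in males"; a ``male_mode="mean"`` variant tests
the male mean instead.  TPM values below 1e-12 count as exact zeros (text
-format noise absorption).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FEMALE, MALE, Region

ZERO_EPS = 1e-12


def filter_male_specific_degs(
    tpm: pd.DataFrame,
    sex_map: dict[str, str],
    min_zero_females: int = 2,
    female_ceiling: float = 0.1,
    male_floor: float = 1.0,
    male_mode: str = "all",
) -> pd.DataFrame:
    """Male-gonad-specific genes from a genes x samples TPM table.

    Returns the passing rows (per-sample values echoed), ordered by gene
    id.  Every column must have a sex label; ``male_mode`` is ``"all"``
    (every male sample > male_floor) or ``"mean"``.
    """
    missing = [c for c in tpm.columns if c not in sex_map]
    if missing:
        raise ValueError(f"samples without sex label: {missing}")
    fcols = [c for c in tpm.columns if sex_map[c] == FEMALE]
    mcols = [c for c in tpm.columns if sex_map[c] == MALE]
    if len(fcols) < min_zero_females:
        raise ValueError("fewer female samples than required zero count")
    if not mcols:
        raise ValueError("need at least one male sample")
    if male_mode not in ("all", "mean"):
        raise ValueError("male_mode must be 'all' or 'mean'")
    f = tpm[fcols].to_numpy(dtype=float)
    m = tpm[mcols].to_numpy(dtype=float)
    if (f < 0).any() or (m < 0).any():
        raise ValueError("TPM values must be non-negative")
    is_zero = f <= ZERO_EPS
    cond_zero = is_zero.sum(axis=1) >= min_zero_females
    cond_low = np.where(is_zero, 0.0, f).max(axis=1, initial=0.0) < female_ceiling
    if male_mode == "all":
        cond_male = (m > male_floor).all(axis=1)
    else:
        cond_male = m.mean(axis=1) > male_floor
    passing = tpm.loc[cond_zero & cond_low & cond_male]
    return passing.sort_index()


def count_sex_specific(
    gene_ids,
    gene_regions: dict[str, Region],
    region_classes: list[tuple[Region, str]],
) -> dict[str, int]:
    """Count passing genes per annotated region class.

    ``gene_regions`` maps gene id -> locus; ``region_classes`` is an
    ordered list of (Region, class name) — the first overlapping class
    wins.  Genes without a locus are counted under ``"unplaced"``.
    """
    counts: dict[str, int] = {name: 0 for _, name in region_classes}
    counts["unplaced"] = 0
    for gid in gene_ids:
        locus = gene_regions.get(gid)
        if locus is None:
            counts["unplaced"] += 1
            continue
        for region, name in region_classes:
            if region.overlaps(locus):
                counts[name] += 1
                break
        else:
            counts["unplaced"] += 1
    return counts
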