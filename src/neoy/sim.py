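"""Forward simulator of X1X2Y sex-chromosome evolution.

The simulated karyotype mirrors a neo-Y system: females are X1X1 X2X2,
males X1 X2 Y, where the Y arose from an ancestral Y (homologous to X1)
fused by Robertsonian translocation to the proto-X2.  The Y is laid out as

    [ PAR1 | strata of the X1-homologous arm | repeat spacer |
      X2-homologous flat stratum | age gradient | PAR2 ]

Each stratum carries one recombination-suppression age T; within it the X
and Y copies evolve independently from a common ancestor under a
continuous-time Kimura two-parameter substitution process at rate ``mu``
per site per year, so the expected K2P distance between the copies is
2*mu*T.  The fused arm ends in a gradient whose per-position age declines
linearly from ``gradient_age`` to zero at the distal tip (the simplest
monotone model of gradually spreading recombination suppression).  PARs
recombine, so X--Y mismatches there occur at the polymorphism level
``theta`` only.  An inversion spanning the X1-arm strata is
reverse-complemented on the Y.

Gene loci are embedded in the chromosome sequences and evolve at a reduced
rate (purifying selection, ``cds_constraint``); substitutions creating
in-frame stop codons in non-pseudogenized copies are rejected.  Planted
gene fates: pseudogenes (>= 3 internal stops on the Y copy), HD-XY genes
(Y copy additionally diverged to ~``hdxy_identity``), Y+X- genes (X locus
replaced by unrelated sequence), lost-on-Y genes (Y locus replaced).
Non-homologous loci are excluded from the alignment-block table, as an
aligner would not report them as collinear blocks.

Sequencing depth follows the cross-mapping model: on the female (X)
reference, male expected depth is ``mean_depth * (1 + c(d))`` with
``c(d) = exp(-crossmap_lambda * d)`` the probability that a Y-derived read
still maps at local X--Y divergence ``d``; female depth is ``2 *
mean_depth``.  The autosome-normalised male:female ratio therefore sits at
1 on autosomes, at (1 + c)/2 inside differentiated regions — strictly
between 0.5 and 1 for any positive cross-mapping constant — and at the
single-copy floor 0.5 only when cross-mapping vanishes.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .core import (
    FEMALE,
    MALE,
    GenotypeMatrix,
    Region,
    SimTruth,
    WindowTrack,
    make_windows,
    substream,
)
from .dating import AlignmentBlock

log = logging.getLogger("neoy")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

Y_CHROM = "chrY"
X1_CHROM = "chrX1"
X2_CHROM = "chrX2"
AUTO_CHROM = "chrA"

_SENSE_CODONS: list[str] = []


def _sense_codons() -> list[str]:
    if not _SENSE_CODONS:
        from Bio.Data import CodonTable

        tbl = CodonTable.unambiguous_dna_by_id[1]
        _SENSE_CODONS.extend(sorted(tbl.forward_table))
    return _SENSE_CODONS


@dataclasses.dataclass
class SimConfig:
    """All simulator knobs; defaults are the study conditions.

    ``strata_x1`` lists (length bp, age years) distal-to-proximal for the
    X1-homologous arm; ``strata_x2`` for the flat part of the fused arm,
    followed by the linear ``gradient_len``/``gradient_age`` ramp.
    """

    mu: float = 8.18e-10
    strata_x1: tuple = ((1_000_000, 55e6), (1_000_000, 28e6), (1_000_000, 55e6))
    strata_x2: tuple = ((1_000_000, 48e6),)
    gradient_len: int = 1_500_000
    gradient_age: float = 48e6
    par_lengths: tuple = (300_000, 300_000)
    fusion_spacer: int = 50_000
    inversion: tuple | None | str = "auto"  # (start, end) on Y, None, or "auto"
    theta: float = 0.003
    ts_tv: float = 2.0
    n_males: int = 20
    n_females: int = 28
    geno_error: float = 0.0
    missing_rate: float = 0.0
    mean_depth: float = 5.5
    crossmap_lambda: float = 15.0
    read_len: int = 150
    autosome_len: int = 1_500_000
    n_genes: int = 300
    n_auto_genes: int = 60
    gene_cds_len: int = 900
    intron_len: int = 60
    hdxy_count: int = 10
    yxminus_count: int = 6
    lost_count: int = 12
    pseudo_rate: float = 0.08
    hdxy_identity: float = 0.70
    cds_constraint: float = 0.5
    deg_count: int = 87
    n_female_rna: int = 6
    n_male_rna: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if any(age < 0 for _, age in list(self.strata_x1) + list(self.strata_x2)):
            raise ValueError("stratum ages must be non-negative")
        if self.gradient_age < 0:
            raise ValueError("gradient age must be non-negative")
        if min(
            self.n_males,
            self.n_females,
            self.n_genes,
            self.n_auto_genes,
            self.hdxy_count,
            self.yxminus_count,
            self.lost_count,
        ) < 0:
            raise ValueError("counts must be non-negative")
        if self.mean_depth < 0:
            raise ValueError("mean depth must be non-negative")

    # -- layout ----------------------------------------------------------
    @property
    def par1(self) -> int:
        return int(self.par_lengths[0])

    @property
    def par2(self) -> int:
        return int(self.par_lengths[1])

    @property
    def x1_len(self) -> int:
        return self.par1 + sum(int(l) for l, _ in self.strata_x1)

    @property
    def x2_len(self) -> int:
        return (
            sum(int(l) for l, _ in self.strata_x2)
            + int(self.gradient_len)
            + self.par2
        )

    @property
    def fusion_point(self) -> int:
        return self.x1_len + int(self.fusion_spacer)

    @property
    def y_len(self) -> int:
        return self.x1_len + int(self.fusion_spacer) + self.x2_len

    def inversion_region(self) -> Region | None:
        if self.inversion == "auto":
            if not self.strata_x1:
                return None
            return Region(Y_CHROM, self.par1, self.x1_len, label="inversion")
        if self.inversion is None:
            return None
        s, e = self.inversion
        r = Region(Y_CHROM, int(s), int(e), label="inversion")
        if r.start < self.par1 or r.end > self.x1_len:
            raise ValueError("inversion must lie within the X1-homologous non-PAR")
        return r


def single_stratum_config(length: int, age: float, **kw) -> SimConfig:
    """A minimal configuration: one X1-arm stratum, no PARs, no fusion, no
    genes — the setup for stratum-age recovery experiments."""
    defaults = dict(
        strata_x1=((int(length), float(age)),),
        strata_x2=(),
        gradient_len=0,
        par_lengths=(0, 0),
        fusion_spacer=0,
        inversion=None,
        theta=0.0,
        n_genes=0,
        n_auto_genes=0,
        hdxy_count=0,
        yxminus_count=0,
        lost_count=0,
        pseudo_rate=0.0,
        deg_count=0,
        autosome_len=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


# --------------------------------------------------------------- sequences
def random_codes(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def codes_to_str(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def str_to_codes(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for c, b in zip("ACGT", range(4)):
        lut[ord(c)] = b
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return codes ^ 3  # A<->T, C<->G under 0..3 = A,C,G,T


def evolve(
    codes: np.ndarray,
    ages: np.ndarray,
    mu: float,
    ts_tv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One lineage of K2P evolution: per-site substitution over time
    ``ages`` (years) at total rate ``mu``/site/year with transition:
    transversion ratio ``ts_tv``.

    Uses the exact K2P transition probabilities, so multiple hits and back
    substitutions are modelled and the K2P distance estimator is consistent.
    """
    R = ts_tv
    beta = mu / (2.0 * (R + 1.0))
    alpha = R * mu / (R + 1.0)
    t = np.asarray(ages, dtype=float)
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    u = rng.random(codes.size)
    out = codes.copy()
    m_ts = u < p_ts
    m_tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    m_tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2.0 * p_tv)
    out[m_ts] ^= 2  # A<->G, C<->T
    out[m_tv1] ^= 1
    out[m_tv2] ^= 3
    return out


def expected_mismatch(age: float, mu: float, ts_tv: float) -> float:
    """Expected raw mismatch fraction between two copies separated by
    2*age of K2P evolution (used by concentration tests)."""
    R = ts_tv
    beta = mu / (2.0 * (R + 1.0))
    alpha = R * mu / (R + 1.0)
    t = 2.0 * age
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return float(p_ts + 2.0 * p_tv)


# ------------------------------------------------------------------- genes
@dataclasses.dataclass
class _GeneSpec:
    """Simulator bookkeeping for one gene locus (X-arm coordinates)."""

    index: int
    arm: str  # "x1", "x2" or "auto"
    start: int  # arm coordinates
    exon_bounds: list  # [(s, e), ...] arm coordinates
    label: str = "gametolog"  # truth fate of the Y copy

    @property
    def end(self) -> int:
        return self.exon_bounds[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exon_bounds)


def _make_cds_codes(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    codons = _sense_codons()
    picks = rng.integers(0, len(codons), size=n_codons)
    seq = "ATG" + "".join(codons[i] for i in picks[1:])
    return str_to_codes(seq)


def _place_genes(
    arm: str,
    lo: int,
    hi: int,
    count: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    start_index: int,
) -> list[_GeneSpec]:
    """Place ``count`` non-overlapping gene loci in [lo, hi); overlapping
    draws are re-drawn (logged)."""
    genes: list[_GeneSpec] = []
    taken: list[tuple[int, int]] = []
    n_exons_draw = lambda: int(np.clip(1 + rng.poisson(2.2), 1, 6))
    for i in range(count):
        n_ex = n_exons_draw()
        glen = cfg.gene_cds_len + (n_ex - 1) * cfg.intron_len
        for attempt in range(200):
            s = int(rng.integers(lo, max(lo + 1, hi - glen)))
            if all(s + glen <= a or s >= b for a, b in taken):
                break
            if attempt == 0:
                log.debug("gene placement overlap; re-drawing")
        else:
            raise RuntimeError("could not place genes without overlap")
        taken.append((s, s + glen))
        # split the CDS into n_ex exon chunks separated by introns
        cuts = np.sort(rng.choice(np.arange(1, cfg.gene_cds_len), size=n_ex - 1, replace=False)) if n_ex > 1 else np.array([], dtype=int)
        bounds = []
        cds_pos = 0
        cursor = s
        for cut in list(cuts) + [cfg.gene_cds_len]:
            ex_len = cut - cds_pos
            bounds.append((cursor, cursor + ex_len))
            cursor += ex_len + cfg.intron_len
            cds_pos = cut
        genes.append(_GeneSpec(start_index + i, arm, s, bounds))
    genes.sort(key=lambda g: g.start)
    return genes


def _gene_cds_slices(g: _GeneSpec) -> list[slice]:
    return [slice(s, e) for s, e in g.exon_bounds]


def _extract_cds(arm_codes: np.ndarray, g: _GeneSpec) -> np.ndarray:
    return np.concatenate([arm_codes[s] for s in _gene_cds_slices(g)])


def _repair_stops(
    arm_codes: np.ndarray, anc_codes: np.ndarray, g: _GeneSpec
) -> None:
    """Revert substitutions that created in-frame internal stop codons
    (purifying selection against nonsense)."""
    cds = _extract_cds(arm_codes, g)
    anc = _extract_cds(anc_codes, g)
    offsets = np.concatenate(
        [np.arange(s.start, s.stop) for s in _gene_cds_slices(g)]
    )
    seq = codes_to_str(cds)
    for i in range(0, len(seq) - 3, 3):  # internal codons only
        if seq[i : i + 3] in ("TAA", "TAG", "TGA"):
            arm_codes[offsets[i : i + 3]] = anc[i : i + 3]


def _inject_stops(arm_codes: np.ndarray, g: _GeneSpec, k: int, rng) -> None:
    """Mutate ``k`` distinct internal codons of the gene to TAA."""
    offsets = np.concatenate(
        [np.arange(s.start, s.stop) for s in _gene_cds_slices(g)]
    )
    n_codons = offsets.size // 3
    picks = rng.choice(np.arange(1, n_codons - 1), size=k, replace=False)
    taa = str_to_codes("TAA")
    for c in picks:
        arm_codes[offsets[3 * c : 3 * c + 3]] = taa


# ----------------------------------------------------------------- history
@dataclasses.dataclass
class SimHistory:
    """Everything simulate_history produced, in X(-reference) coordinates
    plus the assembled Y."""

    cfg: SimConfig
    seqs: dict  # chrom -> str (chrX1, chrX2, chrY, chrA)
    x1_codes: np.ndarray
    x2_codes: np.ndarray
    y_on_x1: np.ndarray  # Y allele codes in X1 coordinates (pre-inversion)
    y_on_x2: np.ndarray
    ages_x1: np.ndarray  # per-site suppression age, X1 coordinates
    ages_x2: np.ndarray
    blocks: list
    truth: SimTruth
    genes: list  # list[_GeneSpec]

    def nonpar_x1(self) -> Region | None:
        cfg = self.cfg
        if cfg.x1_len <= cfg.par1:
            return None
        return Region(X1_CHROM, cfg.par1, cfg.x1_len, label="X1HDR")

    def nonpar_x2(self) -> Region | None:
        cfg = self.cfg
        end = cfg.x2_len - cfg.par2
        if end <= 0:
            return None
        return Region(X2_CHROM, 0, end, label="X2HDR")


def _stratum_ages_y(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, list]:
    """Per-site age arrays for the X1 arm (Y layout) and X2 arm, plus the
    truth stratum list (Y coordinates)."""
    ages_x1arm = np.zeros(cfg.x1_len)
    strata: list[tuple[Region, float]] = []
    pos = cfg.par1
    labels = [f"S{chr(ord('A') + i)}" for i in range(26)]
    li = 0
    for length, age in cfg.strata_x1:
        ages_x1arm[pos : pos + int(length)] = float(age)
        strata.append(
            (Region(Y_CHROM, pos, pos + int(length), label=labels[li]), float(age))
        )
        pos += int(length)
        li += 1
    ages_x2arm = np.zeros(cfg.x2_len)
    pos = 0
    for length, age in cfg.strata_x2:
        ages_x2arm[pos : pos + int(length)] = float(age)
        strata.append(
            (
                Region(
                    Y_CHROM,
                    cfg.fusion_point + pos,
                    cfg.fusion_point + pos + int(length),
                    label=labels[li],
                ),
                float(age),
            )
        )
        pos += int(length)
        li += 1
    if cfg.gradient_len > 0:
        i = np.arange(int(cfg.gradient_len))
        ages_x2arm[pos : pos + int(cfg.gradient_len)] = cfg.gradient_age * (
            1.0 - (i + 0.5) / cfg.gradient_len
        )
        strata.append(
            (
                Region(
                    Y_CHROM,
                    cfg.fusion_point + pos,
                    cfg.fusion_point + pos + int(cfg.gradient_len),
                    label=labels[li],
                ),
                float(cfg.gradient_age) / 2.0,
            )
        )
    return ages_x1arm, ages_x2arm, strata


def _mirror_inversion(arr: np.ndarray, inv: Region | None) -> np.ndarray:
    out = arr.copy()
    if inv is not None:
        out[inv.start : inv.end] = out[inv.start : inv.end][::-1]
    return out


def _cut_blocks(
    pieces: list,
    rng: np.random.Generator,
    small_prob: float = 0.08,
) -> list:
    """Subdivide homologous (x_lo, x_hi) pieces into aligner-like block
    lengths; occasionally emit a sub-kb block (filtered later by the
    min_block rule)."""
    out = []
    for lo, hi, meta in pieces:
        pos = lo
        while pos < hi:
            if rng.random() < small_prob:
                ln = int(rng.integers(300, 900))
            else:
                ln = int(rng.integers(20_000, 80_000))
            end = min(pos + ln, hi)
            out.append((pos, end, meta))
            pos = end
    return out


def simulate_history(cfg: SimConfig) -> SimHistory:
    """Evolve the X1, X2, Y and autosome sequences and emit alignment
    blocks plus the ground-truth sidecar."""
    if cfg.x1_len + cfg.x2_len <= 0:
        raise ValueError("empty chromosome layout")
    for arm_len, strata, par in (
        (cfg.x1_len, cfg.strata_x1, cfg.par1),
        (cfg.x2_len, cfg.strata_x2, cfg.par2),
    ):
        if sum(int(l) for l, _ in strata) > arm_len:
            raise ValueError("stratum lengths exceed arm length")
    rng = substream(cfg.seed, "history")
    inv = cfg.inversion_region()
    ages_y_x1, ages_x2, strata = _stratum_ages_y(cfg)
    ages_x1 = _mirror_inversion(ages_y_x1, inv)  # locus age in X1 coordinates

    # gene loci first: they modulate the local substitution rate
    genes: list[_GeneSpec] = []
    if cfg.n_genes > 0:
        non_par_x1 = cfg.x1_len - cfg.par1
        non_par_x2 = cfg.x2_len - cfg.par2
        tot = max(non_par_x1 + non_par_x2, 1)
        n_x1 = int(round(cfg.n_genes * non_par_x1 / tot))
        genes += _place_genes("x1", cfg.par1, cfg.x1_len, n_x1, cfg, rng, 0)
        genes += _place_genes(
            "x2", 0, cfg.x2_len - cfg.par2, cfg.n_genes - n_x1, cfg, rng, n_x1
        )
    if cfg.n_auto_genes > 0 and cfg.autosome_len > 0:
        genes += _place_genes(
            "auto", 0, cfg.autosome_len, cfg.n_auto_genes, cfg, rng, cfg.n_genes
        )

    rate_mod_x1 = np.ones(cfg.x1_len)
    rate_mod_x2 = np.ones(cfg.x2_len)
    anc_x1 = random_codes(cfg.x1_len, rng)
    anc_x2 = random_codes(cfg.x2_len, rng)
    for g in genes:
        if g.arm == "auto":
            continue
        anc = anc_x1 if g.arm == "x1" else anc_x2
        mod = rate_mod_x1 if g.arm == "x1" else rate_mod_x2
        cds = _make_cds_codes(cfg.gene_cds_len // 3, rng)
        pos = 0
        for s in _gene_cds_slices(g):
            anc[s] = cds[pos : pos + (s.stop - s.start)]
            mod[s] = cfg.cds_constraint
            pos += s.stop - s.start

    # per-lineage K2P evolution (X and Y independently from the ancestor)
    x1 = evolve(anc_x1, ages_x1 * rate_mod_x1, cfg.mu, cfg.ts_tv, rng)
    y1 = evolve(anc_x1, ages_x1 * rate_mod_x1, cfg.mu, cfg.ts_tv, rng)
    x2 = evolve(anc_x2, ages_x2 * rate_mod_x2, cfg.mu, cfg.ts_tv, rng)
    y2 = evolve(anc_x2, ages_x2 * rate_mod_x2, cfg.mu, cfg.ts_tv, rng)

    # PARs: polymorphism-level mismatches only
    if cfg.theta > 0:
        for arr, lo, hi in (
            (y1, 0, cfg.par1),
            (y2, cfg.x2_len - cfg.par2, cfg.x2_len),
        ):
            n = hi - lo
            if n <= 0:
                continue
            hit = rng.random(n) < cfg.theta
            shift = rng.integers(1, 4, size=n).astype(np.uint8)
            arr[lo:hi][hit] = (arr[lo:hi][hit] + shift[hit]) % 4

    # gene-fate planting
    exclude_x1: list[tuple[int, int]] = []
    exclude_x2: list[tuple[int, int]] = []
    sex_genes = [g for g in genes if g.arm in ("x1", "x2")]
    multi = [g for g in sex_genes if g.n_exons >= 2]
    rng_f = substream(cfg.seed, "gene-fates")
    n_pseudo = int(round(cfg.pseudo_rate * len(sex_genes)))
    picks = list(
        rng_f.choice(
            len(sex_genes),
            size=min(
                len(sex_genes),
                cfg.hdxy_count + cfg.yxminus_count + cfg.lost_count,
            ),
            replace=False,
        )
    )
    fate_of: dict[int, str] = {}
    for _ in range(cfg.hdxy_count):
        if picks:
            fate_of[picks.pop()] = "HD-XY"
    for _ in range(cfg.yxminus_count):
        if picks:
            fate_of[picks.pop()] = "Y+X-"
    for _ in range(cfg.lost_count):
        if picks:
            fate_of[picks.pop()] = "lost-on-Y"
    pseudo_pool = [
        i
        for i, g in enumerate(sex_genes)
        if i not in fate_of and g.n_exons >= 2
    ]
    for i in rng_f.choice(
        pseudo_pool, size=min(n_pseudo, len(pseudo_pool)), replace=False
    ):
        fate_of[int(i)] = "pseudogene"

    for i, g in enumerate(sex_genes):
        ycopy = y1 if g.arm == "x1" else y2
        xcopy = x1 if g.arm == "x1" else x2
        anc = anc_x1 if g.arm == "x1" else anc_x2
        excl = exclude_x1 if g.arm == "x1" else exclude_x2
        fate = fate_of.get(i, "gametolog")
        g.label = fate
        if fate in ("gametolog", "HD-XY", "Y+X-"):
            _repair_stops(ycopy, anc, g)
        _repair_stops(xcopy, anc, g)
        if fate == "pseudogene":
            _inject_stops(ycopy, g, 3, rng_f)
        elif fate == "HD-XY":
            span = slice(g.start, g.end)
            n = g.end - g.start
            hit = rng_f.random(n) < (1.0 - cfg.hdxy_identity)
            shift = rng_f.integers(1, 4, size=n).astype(np.uint8)
            seg = ycopy[span].copy()
            seg[hit] = (seg[hit] + shift[hit]) % 4
            ycopy[span] = seg
            # still a (highly diverged) protein-coding gene: no nonsense
            _repair_stops(ycopy, anc, g)
        elif fate == "Y+X-":
            xcopy[g.start : g.end] = random_codes(g.end - g.start, rng_f)
            excl.append((g.start, g.end))
        elif fate == "lost-on-Y":
            ycopy[g.start : g.end] = random_codes(g.end - g.start, rng_f)
            excl.append((g.start, g.end))

    # assemble the Y: inverted X1 arm + repeat-like spacer + X2 arm
    y_arm1 = y1.copy()
    if inv is not None:
        y_arm1[inv.start : inv.end] = complement_codes(
            y_arm1[inv.start : inv.end][::-1]
        )
    spacer_unit = str_to_codes("GGAATGGAATGGAAT")  # satellite-like repeat
    spacer = np.tile(spacer_unit, int(cfg.fusion_spacer) // spacer_unit.size + 1)[
        : int(cfg.fusion_spacer)
    ]
    y_codes = np.concatenate([y_arm1, spacer, y2])

    # alignment blocks: homologous pieces minus disrupted loci,
    # cut at orientation/stratum boundaries
    def _pieces(arm_len, exclude, cuts):
        bounds = sorted({0, arm_len, *cuts, *(b for seg in exclude for b in seg)})
        out = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if any(lo >= s and hi <= e for s, e in exclude):
                continue
            if lo < hi:
                out.append((lo, hi, None))
        return out

    rng_b = substream(cfg.seed, "blocks")
    blocks: list[AlignmentBlock] = []
    if cfg.x1_len > 0:
        cuts = {cfg.par1}
        if inv is not None:
            cuts |= {inv.start, inv.end}
        for lo, hi, _ in _cut_blocks(_pieces(cfg.x1_len, exclude_x1, cuts), rng_b):
            inside = inv is not None and lo >= inv.start and hi <= inv.end
            if inside:
                ys = inv.start + inv.end - hi
                ye = inv.start + inv.end - lo
                orient = "-"
            else:
                ys, ye, orient = lo, hi, "+"
            blocks.append(
                AlignmentBlock(
                    y_region=Region(Y_CHROM, ys, ye),
                    x_region=Region(X1_CHROM, lo, hi),
                    orient=orient,
                )
            )
    if cfg.x2_len > 0:
        for lo, hi, _ in _cut_blocks(
            _pieces(cfg.x2_len, exclude_x2, {cfg.x2_len - cfg.par2}), rng_b
        ):
            blocks.append(
                AlignmentBlock(
                    y_region=Region(
                        Y_CHROM, cfg.fusion_point + lo, cfg.fusion_point + hi
                    ),
                    x_region=Region(X2_CHROM, lo, hi),
                    orient="+",
                )
            )
    blocks.sort(key=lambda b: b.y_region.start)

    seqs = {
        X1_CHROM: codes_to_str(x1),
        X2_CHROM: codes_to_str(x2),
        Y_CHROM: codes_to_str(y_codes),
    }
    if cfg.autosome_len > 0:
        seqs[AUTO_CHROM] = codes_to_str(random_codes(cfg.autosome_len, rng))
    for b in blocks:
        b.attach_seqs({Y_CHROM: seqs[Y_CHROM]}, seqs)

    # fixed X/Y differences = planted scsSNP sites (1-based VCF positions)
    scs: list[str] = []
    if cfg.x1_len > cfg.par1:
        d = np.flatnonzero(x1[cfg.par1 :] != y1[cfg.par1 :]) + cfg.par1
        scs += [f"{X1_CHROM}:{p + 1}" for p in d]
    if cfg.x2_len > cfg.par2:
        d = np.flatnonzero(x2[: cfg.x2_len - cfg.par2] != y2[: cfg.x2_len - cfg.par2])
        scs += [f"{X2_CHROM}:{p + 1}" for p in d]

    par_regions = []
    if cfg.par1 > 0:
        par_regions.append(Region(Y_CHROM, 0, cfg.par1, label="PAR1"))
    if cfg.par2 > 0:
        par_regions.append(
            Region(Y_CHROM, cfg.y_len - cfg.par2, cfg.y_len, label="PAR2")
        )
    truth = SimTruth(
        strata=strata,
        inversion=inv,
        fusion_point=cfg.fusion_point,
        par=par_regions,
        planted_scs_sites=scs,
        planted_degs=[],
        planted_pseudogenes=[
            _gene_id(g) for g in sex_genes if g.label == "pseudogene"
        ],
        planted_yxminus=[_gene_id(g) for g in sex_genes if g.label == "Y+X-"],
        seed=cfg.seed,
        extras={
            "gradient": {"start_age": float(cfg.gradient_age), "end_age": 0.0},
            "gene_labels": {_gene_id(g): g.label for g in genes},
        },
    )
    return SimHistory(
        cfg=cfg,
        seqs=seqs,
        x1_codes=x1,
        x2_codes=x2,
        y_on_x1=y1,
        y_on_x2=y2,
        ages_x1=ages_x1,
        ages_x2=ages_x2,
        blocks=blocks,
        truth=truth,
        genes=genes,
    )


def _gene_id(g: _GeneSpec) -> str:
    prefix = {"x1": "Yg", "x2": "Yg", "auto": "Ag"}[g.arm]
    return f"{prefix}{g.index:04d}"


# -------------------------------------------------------------- population
def _poly_positions(rng, length: int, rho: float, forbid: set) -> np.ndarray:
    n = rng.poisson(rho * length)
    if n == 0 or length == 0:
        return np.array([], dtype=np.int64)
    pos = np.unique(rng.integers(0, length, size=n))
    return np.array([p for p in pos if p not in forbid], dtype=np.int64)


def simulate_population(
    cfg: SimConfig, history: SimHistory
) -> GenotypeMatrix:
    """Draw diploid genotypes for the sexed sample against the female (X)
    reference.

    Fixed X/Y differences in the non-PAR make all females hom-ref and all
    males het (before any genotyping error).  Polymorphic sites appear at a
    density tuned so the expected per-bp diversity is ``theta``; allele
    frequencies are drawn uniform on (0.1, 0.9).
    """
    if cfg.n_males + cfg.n_females == 0:
        raise ValueError("need at least one sampled individual")
    rng = substream(cfg.seed, "population")
    nf, nm = cfg.n_females, cfg.n_males
    samples = [f"F{i + 1:03d}" for i in range(nf)] + [
        f"M{i + 1:03d}" for i in range(nm)
    ]
    sex = [FEMALE] * nf + [MALE] * nm
    male_cols = np.arange(nf, nf + nm)

    # E[2pq] for p ~ U(0.1, 0.9): density of segregating sites so that the
    # expected per-bp diversity equals theta
    e2pq = 2.0 * (0.5 - (0.8**2 / 12.0 + 0.25))
    rho = cfg.theta / e2pq if cfg.theta > 0 else 0.0

    chrom_plan = []
    if cfg.x1_len > 0:
        chrom_plan.append(
            (X1_CHROM, history.x1_codes, history.y_on_x1, cfg.par1, cfg.x1_len)
        )
    if cfg.x2_len > 0:
        chrom_plan.append(
            (X2_CHROM, history.x2_codes, history.y_on_x2, 0, cfg.x2_len - cfg.par2)
        )
    if cfg.autosome_len > 0:
        chrom_plan.append((AUTO_CHROM, None, None, 0, 0))

    frames = []
    genos = []
    for chrom, xcodes, ycodes, np_lo, np_hi in chrom_plan:
        length = len(xcodes) if xcodes is not None else cfg.autosome_len
        rows = []
        # fixed X/Y differences (non-PAR of the sex chromosomes)
        fixed = np.array([], dtype=np.int64)
        if xcodes is not None and np_hi > np_lo:
            fixed = (
                np.flatnonzero(xcodes[np_lo:np_hi] != ycodes[np_lo:np_hi]) + np_lo
            )
        forbid = set(fixed.tolist())
        xpoly = _poly_positions(rng, length, rho, forbid)
        forbid |= set(xpoly.tolist())
        ypoly = np.array([], dtype=np.int64)
        if xcodes is not None and np_hi > np_lo:
            yp = _poly_positions(rng, np_hi - np_lo, rho, set()) + np_lo
            ypoly = np.array([p for p in yp if p not in forbid], dtype=np.int64)

        n_sites = fixed.size + xpoly.size + ypoly.size
        if n_sites == 0:
            continue
        letters = np.array(["A", "C", "G", "T"], dtype=object)
        G = np.zeros((n_sites, nf + nm), dtype=np.int8)
        pos_all: list = []
        ref_all: list = []
        alt_all: list = []
        r = 0
        # 1) fixed differences: females 0, males 1
        if fixed.size:
            G[np.ix_(np.arange(fixed.size), male_cols)] = 1
            pos_all += list(fixed)
            ref_all += list(letters[xcodes[fixed]])
            alt_all += list(letters[ycodes[fixed]])
            r += fixed.size
        # 2) X-background polymorphism
        if xpoly.size:
            freqs = rng.uniform(0.1, 0.9, size=xpoly.size)
            fem = rng.binomial(2, freqs[:, None], size=(xpoly.size, nf))
            in_nonpar = (
                (xpoly >= np_lo) & (xpoly < np_hi)
                if xcodes is not None
                else np.zeros(xpoly.size, dtype=bool)
            )
            mal_dip = rng.binomial(2, freqs[:, None], size=(xpoly.size, nm))
            mal_hap = rng.binomial(1, freqs[:, None], size=(xpoly.size, nm))
            mal = np.where(in_nonpar[:, None], mal_hap, mal_dip)
            blockG = np.concatenate([fem, mal], axis=1).astype(np.int8)
            G[r : r + xpoly.size] = blockG
            base = (
                xcodes[xpoly]
                if xcodes is not None
                else random_codes(xpoly.size, rng)
            )
            alt_shift = rng.integers(1, 4, size=xpoly.size).astype(np.uint8)
            pos_all += list(xpoly)
            ref_all += list(letters[base])
            alt_all += list(letters[(base + alt_shift) % 4])
            r += xpoly.size
        # 3) Y-background polymorphism (males only, het when carrying the
        #    derived Y allele)
        if ypoly.size:
            freqs = rng.uniform(0.1, 0.9, size=ypoly.size)
            mal = rng.binomial(1, freqs[:, None], size=(ypoly.size, nm))
            G[r : r + ypoly.size, male_cols] = mal.astype(np.int8)
            base = xcodes[ypoly]
            alt_shift = rng.integers(1, 4, size=ypoly.size).astype(np.uint8)
            pos_all += list(ypoly)
            ref_all += list(letters[base])
            alt_all += list(letters[(base + alt_shift) % 4])
            r += ypoly.size

        order = np.argsort(np.asarray(pos_all), kind="stable")
        G = G[order]
        pos_arr = np.asarray(pos_all, dtype=np.int64)[order]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos_arr + 1,
                    "ref": np.asarray(ref_all, dtype=object)[order],
                    "alt": np.asarray(alt_all, dtype=object)[order],
                }
            )
        )
        genos.append(G)

    if not frames:
        raise ValueError("simulation produced no segregating sites")
    sites = pd.concat(frames, ignore_index=True)
    G = np.concatenate(genos, axis=0)
    if cfg.geno_error > 0:
        hit = rng.random(G.shape) < cfg.geno_error
        G = np.where(hit, rng.integers(0, 3, size=G.shape, dtype=np.int8), G)
    if cfg.missing_rate > 0:
        G = np.where(rng.random(G.shape) < cfg.missing_rate, np.int8(-1), G)
    return GenotypeMatrix(samples, sex, sites, G)


def sex_map_of(gm: GenotypeMatrix) -> dict[str, str]:
    return dict(zip(gm.samples, gm.sex))


# ------------------------------------------------------------------- depth
def crossmap_fraction(d, lam: float):
    """c(d) = exp(-lambda d): probability a Y-derived read still maps to
    the X reference at local divergence d."""
    return np.exp(-lam * np.asarray(d, dtype=float))


def simulate_depth(
    cfg: SimConfig, history: SimHistory, span: int = 100_000
) -> dict[str, dict[str, WindowTrack]]:
    """Per-window mean depth per sex on the female reference, with Poisson
    read-count noise."""
    if cfg.mean_depth < 0 or cfg.crossmap_lambda < 0:
        raise ValueError("depth parameters must be non-negative")
    rng = substream(cfg.seed, "depth")
    plan = []
    if cfg.x1_len > 0:
        plan.append((X1_CHROM, history.ages_x1))
    if cfg.x2_len > 0:
        plan.append((X2_CHROM, history.ages_x2))
    if cfg.autosome_len > 0:
        plan.append((AUTO_CHROM, np.zeros(cfg.autosome_len)))
    out: dict[str, dict[str, WindowTrack]] = {FEMALE: {}, MALE: {}}
    for chrom, ages in plan:
        windows = make_windows(Region(chrom, 0, ages.size), span)
        d = 2.0 * cfg.mu * ages
        c = crossmap_fraction(d, cfg.crossmap_lambda)
        male_site = cfg.mean_depth * (1.0 + c)
        female_site = np.full(ages.size, 2.0 * cfg.mean_depth)
        for sexname, site_depth in ((FEMALE, female_site), (MALE, male_site)):
            exp_win = np.array(
                [
                    site_depth[s:e].mean()
                    for s, e in zip(windows.starts, windows.ends)
                ]
            )
            spans = (windows.ends - windows.starts).astype(float)
            n_eff = spans / cfg.read_len  # expected reads per unit depth
            noisy = rng.poisson(exp_win * n_eff) / n_eff
            t = WindowTrack(chrom, windows.starts, windows.ends, span=span)
            t.set_stat("mean_depth", noisy)
            out[sexname][chrom] = t
    return out


# -------------------------------------------------------------- expression
def simulate_expression(
    cfg: SimConfig, history: SimHistory
) -> tuple[pd.DataFrame, dict[str, str], list[str]]:
    """Gonad TPM table for the RNA panel; ``deg_count`` planted genes
    satisfy the male-specific rule exactly (>=2 female zeros, other females
    < 0.1, every male > 1)."""
    rng = substream(cfg.seed, "expression")
    sex_genes = [g for g in history.genes if g.arm in ("x1", "x2")]
    expressed = [g for g in sex_genes if g.label in ("gametolog", "HD-XY", "Y+X-")]
    if cfg.deg_count > len(expressed) + len(
        [g for g in history.genes if g.arm == "auto"]
    ):
        raise ValueError("deg_count exceeds the number of simulated genes")
    if cfg.deg_count > len(expressed):
        raise ValueError("deg_count exceeds the number of expressed Y genes")
    gene_ids = [_gene_id(g) for g in history.genes]
    nf, nm = cfg.n_female_rna, cfg.n_male_rna
    cols = [f"OV{i + 1}" for i in range(nf)] + [f"TE{i + 1}" for i in range(nm)]
    sexmap = {c: FEMALE for c in cols[:nf]} | {c: MALE for c in cols[nf:]}

    base = rng.lognormal(mean=1.2, sigma=1.1, size=len(gene_ids))
    noise = rng.lognormal(mean=0.0, sigma=0.3, size=(len(gene_ids), nf + nm))
    tpm = base[:, None] * noise

    deg_idx = rng.choice(
        [gene_ids.index(_gene_id(g)) for g in expressed],
        size=cfg.deg_count,
        replace=False,
    )
    for i in deg_idx:
        k_zero = int(rng.integers(2, nf + 1))
        fvals = rng.uniform(0.0, 0.08, size=nf)
        zero_at = rng.choice(nf, size=k_zero, replace=False)
        fvals[zero_at] = 0.0
        mvals = 2.0 ** rng.uniform(1.0, 6.0, size=nm)  # 2..64 TPM
        tpm[i, :nf] = fvals
        tpm[i, nf:] = mvals
    df = pd.DataFrame(tpm, index=pd.Index(gene_ids, name="gene_id"), columns=cols)
    degs = sorted(gene_ids[i] for i in deg_idx)
    history.truth.planted_degs = degs
    return df, sexmap, degs


# ------------------------------------------------------------------- genes
def simulate_genes(cfg: SimConfig, history: SimHistory):
    """Materialise gene models and CDS for the Y and X gene sets (plus
    autosomal background genes) from the evolved chromosomes."""
    from .genevo import GeneModel

    inv = history.truth.inversion
    y_genes: list[GeneModel] = []
    x_genes: list[GeneModel] = []
    auto_genes: list[GeneModel] = []
    y_seq = history.seqs[Y_CHROM]
    for g in history.genes:
        gid = _gene_id(g)
        if g.arm == "auto":
            exons = [
                Region(AUTO_CHROM, s, e) for s, e in g.exon_bounds
            ]
            auto_genes.append(
                GeneModel(
                    id=gid,
                    chrom=AUTO_CHROM,
                    strand="+",
                    region=Region(AUTO_CHROM, g.start, g.end),
                    exons=exons,
                    cds="",
                    class_label="autosomal",
                )
            )
            continue
        x_chrom = X1_CHROM if g.arm == "x1" else X2_CHROM
        x_codes = history.x1_codes if g.arm == "x1" else history.x2_codes
        # X copy
        if g.label != "Y+X-":
            cds_x = codes_to_str(_extract_cds(x_codes, g))
            x_genes.append(
                GeneModel(
                    id=gid.replace("Yg", "X1g" if g.arm == "x1" else "X2g"),
                    chrom=x_chrom,
                    strand="+",
                    region=Region(x_chrom, g.start, g.end),
                    exons=[Region(x_chrom, s, e) for s, e in g.exon_bounds],
                    cds=cds_x,
                    class_label=g.label,
                )
            )
        # Y copy (coordinates mapped through the inversion where applicable)
        if g.label != "lost-on-Y":
            on_x1 = g.arm == "x1"
            inside_inv = (
                on_x1
                and inv is not None
                and g.start >= inv.start
                and g.end <= inv.end
            )
            if on_x1:
                if inside_inv:
                    ys = inv.start + inv.end - g.end
                    ye = inv.start + inv.end - g.start
                    strand = "-"
                    exon_pairs = [
                        (inv.start + inv.end - e, inv.start + inv.end - s)
                        for s, e in reversed(g.exon_bounds)
                    ]
                else:
                    ys, ye, strand = g.start, g.end, "+"
                    exon_pairs = list(g.exon_bounds)
            else:
                off = cfg.fusion_point
                ys, ye, strand = off + g.start, off + g.end, "+"
                exon_pairs = [(off + s, off + e) for s, e in g.exon_bounds]
            exons = [Region(Y_CHROM, s, e) for s, e in exon_pairs]
            spliced = "".join(y_seq[e.start : e.end] for e in exons)
            if strand == "-":
                from .dating import revcomp

                spliced = revcomp(spliced)
            y_genes.append(
                GeneModel(
                    id=gid,
                    chrom=Y_CHROM,
                    strand=strand,
                    region=Region(Y_CHROM, ys, ye),
                    exons=exons,
                    cds=spliced,
                    class_label=g.label,
                )
            )
    return y_genes, x_genes, auto_genes
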