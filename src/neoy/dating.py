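"""Gametolog divergence dating and evolutionary-stratum segmentation.

The dating chain is: Kimura two-parameter (K2P) distances on collinear
X--Y alignment blocks, aggregated into fixed-span windows along the Y
(blocks shorter than ``min_block`` aligned bp are discarded, surviving
blocks are clipped to window bounds and weighted by aligned length), then
converted to time through ``T = D / (2 mu)``.  A Ks-based route
(``r = Ks / 2t`` and its inverse) provides an independent coding-sequence
calibration, with Ks computed by the Nei--Gojobori (1986) proportion method
under a Jukes--Cantor correction.

Strata — contiguous Y segments that stopped recombining at one time — are
recovered from the windowed age series by exact dynamic-programming
changepoint segmentation.  The default per-segment cost is the residual sum
of squares of a linear fit, which treats both constant-age strata and the
linearly decaying divergence ramp of a recently fused arm as single
segments; a piecewise-constant cost is available via ``cost="constant"``.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .core import Region, WindowTrack

log = logging.getLogger("neoy")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclasses.dataclass
class AlignmentBlock:
    """A collinear aligned segment between the Y and an X chromosome.

    ``orient == "-"`` means X coordinates descend as Y coordinates ascend
    (the block lies in an inverted region).  ``y_seq``/``x_seq`` are the
    aligned sequences in Y-forward orientation (the X side already
    reverse-complemented for ``-`` blocks); they may be attached lazily from
    FASTA after reading a block table.
    """

    y_region: Region
    x_region: Region
    orient: str = "+"
    y_seq: str | None = None
    x_seq: str | None = None

    def __post_init__(self) -> None:
        if self.orient not in "+-":
            raise ValueError("orient must be '+' or '-'")
        if self.y_seq is not None and self.x_seq is not None:
            if len(self.y_seq) != len(self.x_seq):
                raise ValueError("aligned sequences must have equal length")

    @property
    def length(self) -> int:
        if self.y_seq is not None:
            return len(self.y_seq)
        return self.y_region.span

    def attach_seqs(self, y_fasta: dict[str, str], x_fasta: dict[str, str]) -> None:
        """Fill aligned sequences from chromosome sequences (gapless blocks)."""
        y = y_fasta[self.y_region.chrom][self.y_region.start : self.y_region.end]
        x = x_fasta[self.x_region.chrom][self.x_region.start : self.x_region.end]
        if self.orient == "-":
            x = revcomp(x)
        self.y_seq, self.x_seq = y, x


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtN", "TGCAtgcaN"))[::-1]


# ----------------------------------------------------------------- distances
def _pair_codes(a: str, b: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Byte codes for two aligned sequences and the valid-column mask
    (both sides unambiguous A/C/G/T, no gaps)."""
    ca = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    cb = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    if ca.size != cb.size:
        raise ValueError("aligned pair must have equal length")
    lut = np.full(256, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        lut[ord(base)] = code
    xa, xb = lut[ca], lut[cb]
    valid = (xa != 255) & (xb != 255)
    return xa, xb, valid


def k2p_counts(a: str, b: str) -> tuple[int, int, int]:
    """(transitions, transversions, compared sites) for an aligned pair.

    Ambiguous bases and gap characters are excluded from both numerator and
    denominator.  With bases coded A=0, C=1, G=2, T=3, a transition is an
    XOR-by-2 (A<->G, C<->T); any other difference is a transversion.
    """
    xa, xb, valid = _pair_codes(a, b)
    diff = valid & (xa != xb)
    ts = int(np.count_nonzero(diff & ((xa ^ xb) == 2)))
    tv = int(np.count_nonzero(diff)) - ts
    return ts, tv, int(np.count_nonzero(valid))


def kimura2p_distance(a: str, b: str) -> float:
    """Kimura (1980) two-parameter distance of an aligned, gap-stripped pair.

    D = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P/Q the transition and
    transversion fractions.  Saturated pairs (log argument <= 0) return NaN,
    the saturation marker, rather than raising; NaN propagates as a masked
    window downstream.
    """
    ts, tv, n = k2p_counts(a, b)
    if n == 0:
        return math.nan
    p, q = ts / n, tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def windowed_divergence(
    blocks: list[AlignmentBlock],
    windows: WindowTrack,
    min_block: int = 1000,
    stat: str = "D",
) -> WindowTrack:
    """Aligned-length-weighted mean K2P distance per window along the Y.

    ``min_block`` applies to a block's total aligned length *before*
    clipping (a 1.5-kb block still contributes a 200-bp overlap).  Windows
    with no qualifying aligned bp — or containing a saturated fragment — are
    masked.
    """
    num = np.zeros(windows.n)
    den = np.zeros(windows.n, dtype=np.int64)
    saturated = np.zeros(windows.n, dtype=bool)
    for b in blocks:
        if b.y_seq is None or b.x_seq is None:
            raise ValueError("blocks need aligned sequences; call attach_seqs first")
        if b.length <= min_block:
            continue
        if b.y_region.chrom != windows.chrom:
            continue
        ys, ye = b.y_region.start, b.y_region.end
        if ye <= windows.starts[0] or ys >= windows.ends[-1]:
            log.info("block %s outside all windows; ignored", b.y_region)
            continue
        lo = int(windows.window_index(max(ys, int(windows.starts[0]))))
        hi = int(windows.window_index(min(ye, int(windows.ends[-1])) - 1))
        for w in range(lo, hi + 1):
            s = max(ys, int(windows.starts[w]))
            e = min(ye, int(windows.ends[w]))
            if s >= e:
                continue
            frag_a = b.y_seq[s - ys : e - ys]
            frag_b = b.x_seq[s - ys : e - ys]
            d = kimura2p_distance(frag_a, frag_b)
            _, _, nvalid = k2p_counts(frag_a, frag_b)
            if nvalid == 0:
                continue
            if math.isnan(d):
                saturated[w] = True
                continue
            num[w] += d * nvalid
            den[w] += nvalid
    valid = (den > 0) & ~saturated
    with np.errstate(invalid="ignore"):
        d = np.where(valid, num / np.maximum(den, 1), np.nan)
    out = WindowTrack(windows.chrom, windows.starts, windows.ends, span=windows.span)
    out.mask = windows.mask & valid
    out.set_stat(stat, d)
    return out


# ------------------------------------------------------------------- timing
def divergence_time(d, mu: float):
    """T = D / (2 mu), in years. Linear and monotone in D."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    return np.asarray(d, dtype=float) / (2.0 * mu) if np.ndim(d) else float(d) / (2.0 * mu)


def rate_from_ks(ks: float, t: float) -> float:
    """Substitution rate per site per year from synonymous divergence:
    r = Ks / (2 t)."""
    if t <= 0:
        raise ValueError("calibration time must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * t)


def time_from_ks(ks: float, r: float) -> float:
    """Inverse calibration: t = Ks / (2 r)."""
    if r <= 0:
        raise ValueError("rate must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * r)


# ---------------------------------------------------------------- NG86 Ks
_STANDARD_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _STANDARD_TABLE:
        from Bio.Data import CodonTable

        tbl = CodonTable.unambiguous_dna_by_id[1]
        _STANDARD_TABLE.update(tbl.forward_table)
        for stop in tbl.stop_codons:
            _STANDARD_TABLE[stop] = "*"
    return _STANDARD_TABLE


def _syn_sites(codon: str) -> float:
    """NG86 synonymous site count of one codon: at each position, the
    fraction of the three alternative bases that leave the amino acid
    unchanged. Changes to stop codons count as nonsynonymous."""
    tbl = _codon_table()
    aa = tbl[codon]
    s = 0.0
    for i in range(3):
        for alt in "ACGT":
            if alt == codon[i]:
                continue
            mut = codon[:i] + alt + codon[i + 1 :]
            if tbl[mut] == aa and tbl[mut] != "*":
                s += 1.0 / 3.0
    return s


def _path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all mutational
    orderings between two codons; paths through stop codons are excluded
    (all paths are used if every ordering is blocked)."""
    import itertools

    tbl = _codon_table()
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    results = []
    blocked = []
    for order in itertools.permutations(pos):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if tbl[nxt] == "*" or tbl[cur] == "*":
                through_stop = True
            if tbl[nxt] == tbl[cur] and tbl[nxt] != "*":
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (blocked if through_stop else results).append((sd, nd))
    use = results if results else blocked
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


def ks_ng86(cds_a: str, cds_b: str) -> float:
    """Nei--Gojobori (1986) synonymous divergence with Jukes--Cantor
    correction: Ks = -3/4 ln(1 - 4/3 pS), pS = Sd / S.

    S is the synonymous site count averaged over both sequences; codon pairs
    with ambiguity, gaps, or stop codons are skipped.  Returns NaN when S is
    zero (undefined) or pS >= 0.75 (saturation).
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDS pair must have equal length")
    if len(cds_a) % 3:
        raise ValueError("aligned CDS length must be divisible by 3")
    tbl = _codon_table()
    S = 0.0
    Sd = 0.0
    for i in range(0, len(cds_a), 3):
        c1, c2 = cds_a[i : i + 3].upper(), cds_b[i : i + 3].upper()
        if any(ch not in "ACGT" for ch in c1 + c2):
            continue
        if tbl[c1] == "*" or tbl[c2] == "*":
            continue
        S += 0.5 * (_syn_sites(c1) + _syn_sites(c2))
        sd, _ = _path_diffs(c1, c2)
        Sd += sd
    if S <= 0:
        return math.nan
    ps = Sd / S
    if ps >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - ps * 4.0 / 3.0)


# ------------------------------------------------------------- segmentation
@dataclasses.dataclass
class StratumCall:
    """A contiguous Y segment with one assigned divergence age."""

    region: Region
    mean_age: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.mean_age < 0:
            raise ValueError("mean_age must be non-negative")


def _segment_costs(x: np.ndarray, y: np.ndarray, cost: str) -> np.ndarray:
    """C[i, j] = fit cost of points i..j inclusive (SSE about the best
    constant or the best least-squares line)."""
    n = y.size
    one = np.ones(n)
    cs1 = np.concatenate([[0.0], np.cumsum(one)])
    csy = np.concatenate([[0.0], np.cumsum(y)])
    csyy = np.concatenate([[0.0], np.cumsum(y * y)])
    csx = np.concatenate([[0.0], np.cumsum(x)])
    csxx = np.concatenate([[0.0], np.cumsum(x * x)])
    csxy = np.concatenate([[0.0], np.cumsum(x * y)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    m = cs1[j + 1] - cs1[i]
    sy = csy[j + 1] - csy[i]
    syy = csyy[j + 1] - csyy[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        sse_const = syy - sy * sy / m
        if cost == "constant":
            C = sse_const
        else:
            sx = csx[j + 1] - csx[i]
            sxx = csxx[j + 1] - csxx[i]
            sxy = csxy[j + 1] - csxy[i]
            sxx_c = sxx - sx * sx / m
            sxy_c = sxy - sx * sy / m
            slope_term = np.where(sxx_c > 1e-12, sxy_c**2 / np.where(sxx_c > 1e-12, sxx_c, 1.0), 0.0)
            C = sse_const - slope_term
    C = np.where(j >= i, np.maximum(C, 0.0), np.inf)
    return C


def _dp_fixed_k(C: np.ndarray, k: int) -> list[int]:
    """Exact DP for k segments; ties broken toward earlier boundaries.
    Returns segment start indices (length k, first is 0)."""
    n = C.shape[0]
    INF = np.inf
    best = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    best[0, 0] = 0.0
    for seg in range(1, k + 1):
        for end in range(seg, n + 1):
            lo = seg - 1
            cand = best[seg - 1, lo:end] + C[lo:end, end - 1]
            a = int(np.argmin(cand))  # first minimum -> earliest boundary
            best[seg, end] = cand[a]
            back[seg, end] = lo + a
    starts = []
    end = n
    for seg in range(k, 0, -1):
        s = back[seg, end]
        starts.append(s)
        end = s
    return starts[::-1]


def _dp_penalty(C: np.ndarray, penalty: float) -> list[int]:
    """Penalized DP (cost + penalty per segment); ties toward fewer/earlier
    boundaries."""
    n = C.shape[0]
    best = np.full(n + 1, np.inf)
    nseg = np.zeros(n + 1, dtype=int)
    back = np.zeros(n + 1, dtype=int)
    best[0] = 0.0
    for end in range(1, n + 1):
        cand = best[:end] + C[:end, end - 1] + penalty
        a = 0
        for s in range(end):
            if cand[s] < cand[a] - 1e-12 or (
                abs(cand[s] - cand[a]) <= 1e-12 and nseg[s] < nseg[a]
            ):
                a = s
        best[end] = cand[a]
        nseg[end] = nseg[a] + 1
        back[end] = a
    starts = []
    end = n
    while end > 0:
        s = back[end]
        starts.append(s)
        end = s
    return starts[::-1]


def segment_strata(
    track: WindowTrack,
    k: int | None = None,
    penalty: float | None = None,
    stat: str = "T",
    cost: str = "linear",
) -> list[StratumCall]:
    """Segment a windowed age series into contiguous strata.

    Exact dynamic-programming changepoint segmentation over the unmasked
    windows; masked windows are bridged (excluded from the cost, segments may
    span them).  Either ``k`` fixes the number of segments, or ``penalty``
    adds a per-segment cost; with neither, a BIC-like default penalty
    ``2 * sigma^2 * ln(n)`` is used with sigma estimated from first
    differences.  Deterministic: ties break toward fewer, earlier boundaries.
    """
    vals = track.stat(stat)
    keep = track.mask & ~np.isnan(vals)
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        raise ValueError("need at least two unmasked windows to segment")
    y = vals[idx]
    x = 0.5 * (track.starts[idx] + track.ends[idx]).astype(float)
    xs = (x - x.mean()) / max(track.span, 1)  # centered, window-sized units
    C = _segment_costs(xs, y, cost)
    if k is not None:
        if not (1 <= k <= idx.size):
            raise ValueError("k must be between 1 and the number of windows")
        seg_starts = _dp_fixed_k(C, k)
    else:
        if penalty is None:
            d = np.diff(y)
            sigma = np.median(np.abs(d)) / (math.sqrt(2.0) * 0.6745) if d.size else 0.0
            penalty = max(2.0 * sigma**2 * math.log(idx.size), 1e-12)
        seg_starts = _dp_penalty(C, penalty)
    calls: list[StratumCall] = []
    bounds = seg_starts + [idx.size]
    for s_i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        member = idx[a:b]
        start = int(track.starts[member[0]])
        # extend each call to the start of the next segment's first window so
        # the calls tile the segmented span even across masked gaps
        end = int(track.starts[idx[bounds[s_i + 1]]]) if b < idx.size else int(
            track.ends[member[-1]]
        )
        label = f"S{chr(ord('A') + s_i)}" if s_i < 26 else f"S{s_i}"
        calls.append(
            StratumCall(
                region=Region(track.chrom, start, end, label=label),
                mean_age=float(np.mean(y[a:b])),
                label=label,
            )
        )
    return calls
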