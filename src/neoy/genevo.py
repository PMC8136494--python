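"""Gene-fate analysis between the Y and its X gametolog arms.

Homologous gene pairs are found by reciprocal best hits (RBH) on CDS k-mer
containment and chained into collinear runs; inversion breakpoints fall
where block/chain orientation flips.  A Y gene without an RBH partner on
the corresponding arm is a highly diverged (HD-XY) candidate; it is
promoted to Y+X- (no homologous X sequence at all) only when a
liftover-style local sequence search of the gene — and, as a second,
annotation-like pass, of each of its exons — finds nothing on the arm.

The search floor is length-dependent: the best infix edit-similarity of an
*unrelated* query against a multi-Mb arm concentrates near
``0.484 + 1.44/sqrt(L)`` (the null of random DNA under edit distance), so
a hit requires identity above that null plus a margin.  Pseudogenes follow
the frame-error rule: more than two frameshift indels (length not a
multiple of 3) plus in-frame internal stop codons, applied to multi-exon
genes; single-exon genes are reported but not flagged.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter

import edlib

from .core import Region
from .dating import revcomp

GAMETOLOG = "gametolog"
HD_XY = "HD-XY"
Y_PLUS_X_MINUS = "Y+X-"
LOST = "lost-on-Y"
PSEUDOGENE = "pseudogene"
UNCLASSIFIABLE = "not-classifiable"

_STOPS = {"TAA", "TAG", "TGA"}


@dataclasses.dataclass
class GeneModel:
    """A gene with its exon structure and (spliced) coding sequence."""

    id: str
    chrom: str
    strand: str
    region: Region
    exons: list
    cds: str
    class_label: str | None = None

    def __post_init__(self) -> None:
        prev_end = self.region.start
        for e in self.exons:
            if e.start < prev_end or e.end > self.region.end:
                raise ValueError(f"exons of {self.id} must be ordered within the gene")
            prev_end = e.end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_seqs(self) -> list[str]:
        """CDS chunks per exon (5'->3' in CDS order)."""
        lens = [e.span for e in self.exons]
        if self.strand == "-":
            lens = lens[::-1]
        out, pos = [], 0
        for ln in lens:
            out.append(self.cds[pos : pos + ln])
            pos += ln
        return out


# ----------------------------------------------------------- RBH synteny
def _kmers(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_similarity(a: str, b: str, k: int = 8) -> tuple[float, float]:
    """(identity proxy, coverage) from shared k-mer containment: the shared
    distinct k-mers over the smaller / larger set."""
    A, B = _kmers(a, k), _kmers(b, k)
    if not A or not B:
        return 0.0, 0.0
    inter = len(A & B)
    return inter / min(len(A), len(B)), inter / max(len(A), len(B))


@dataclasses.dataclass
class SyntenyResult:
    pairs: dict  # y gene id -> x gene id
    pairs_rev: dict  # x gene id -> y gene id
    chains: list  # list of (orient, [(y_id, x_id), ...])


def rbh_synteny(
    y_genes: list,
    x_genes: list,
    similarity=None,
    min_ident: float = 0.5,
    min_cov: float = 0.5,
    min_chain: int = 3,
    k: int = 8,
) -> SyntenyResult:
    """Reciprocal-best-hit homolog pairs chained into collinear runs.

    ``similarity(a, b) -> (ident, cov)`` defaults to CDS k-mer containment.
    Chains are maximal runs of pairs consecutive in both gene orders
    (uniformly forward or uniformly reversed) of length >= ``min_chain``.
    """
    if not y_genes or not x_genes:
        return SyntenyResult({}, {}, [])
    sim = similarity or (lambda a, b: kmer_similarity(a, b, k=k))

    # inverted k-mer index over X CDS restricts candidate pairs
    index: dict[str, list[int]] = {}
    xk = []
    for j, xg in enumerate(x_genes):
        ks = _kmers(xg.cds, k)
        xk.append(ks)
        for m in ks:
            index.setdefault(m, []).append(j)
    best_y: dict[int, tuple[float, float, int]] = {}
    scores: dict[tuple[int, int], tuple[float, float]] = {}
    for i, yg in enumerate(y_genes):
        if not yg.cds:
            continue
        cand = Counter()
        for m in _kmers(yg.cds, k):
            for j in index.get(m, ()):
                cand[j] += 1
        for j, shared in cand.items():
            # cheap pre-filter before the full similarity call
            if shared < min_ident * min(len(_kmers(yg.cds, k)), len(xk[j])) * 0.5:
                continue
            ident, cov = sim(yg.cds, x_genes[j].cds)
            if ident >= min_ident and cov >= min_cov:
                scores[(i, j)] = (ident, cov)
                if i not in best_y or ident > best_y[i][0]:
                    best_y[i] = (ident, cov, j)
    best_x: dict[int, tuple[float, int]] = {}
    for (i, j), (ident, _) in scores.items():
        if j not in best_x or ident > best_x[j][0]:
            best_x[j] = (ident, i)
    pairs = {}
    pairs_rev = {}
    for i, (ident, cov, j) in best_y.items():
        if best_x.get(j, (None, None))[1] == i:
            pairs[y_genes[i].id] = x_genes[j].id
            pairs_rev[x_genes[j].id] = y_genes[i].id

    # collinear chaining on coordinate order (ranks among paired genes only,
    # so unpaired interlopers do not break a collinear run)
    y_order = sorted(
        (g for g in y_genes if g.id in pairs), key=lambda g: (g.chrom, g.region.start)
    )
    x_by_id = {g.id: g for g in x_genes}
    x_rank = {
        g.id: r
        for r, g in enumerate(
            sorted(
                (g for g in x_genes if g.id in pairs_rev),
                key=lambda g: (g.chrom, g.region.start),
            )
        )
    }
    chains = []
    run: list = []
    run_dir = 0
    prev_rank = None
    for g in y_order:
        xid = pairs[g.id]
        rank = x_rank[xid]
        if run and prev_rank is not None:
            step = rank - prev_rank
            same_chrom = x_by_id[run[-1][1]].chrom == x_by_id[xid].chrom
            if step in (1, -1) and (run_dir in (0, step)) and same_chrom:
                run.append((g.id, xid))
                run_dir = step
                prev_rank = rank
                continue
            if len(run) >= min_chain:
                chains.append(("-" if run_dir < 0 else "+", run))
            run = []
            run_dir = 0
        run.append((g.id, xid))
        prev_rank = rank
    if len(run) >= min_chain:
        chains.append(("-" if run_dir < 0 else "+", run))
    return SyntenyResult(pairs, pairs_rev, chains)


# -------------------------------------------------- inversion breakpoints
def detect_inversion_breakpoints(blocks) -> tuple[list, list]:
    """Breakpoints and reversed spans from oriented blocks sorted by Y
    coordinate.

    Returns ``(breakpoints, reversed_spans)``: a breakpoint Region at every
    adjacency where orientation flips, and the ``[first, last]`` span of
    each maximal reversed run.
    """
    blocks = sorted(blocks, key=lambda b: (b.y_region.chrom, b.y_region.start))
    breakpoints: list[Region] = []
    spans: list[Region] = []
    if len(blocks) < 2:
        return breakpoints, spans
    run_start = None
    for prev, nxt in zip(blocks[:-1], blocks[1:]):
        if prev.y_region.chrom != nxt.y_region.chrom:
            continue
        if prev.orient != nxt.orient:
            bp_start = prev.y_region.end
            bp_end = max(nxt.y_region.start, bp_start + 1)
            breakpoints.append(Region(prev.y_region.chrom, bp_start, bp_end))
    for b in blocks:
        if b.orient == "-":
            if run_start is None:
                run_start = b
            run_end = b
        else:
            if run_start is not None:
                spans.append(
                    Region(
                        run_start.y_region.chrom,
                        run_start.y_region.start,
                        run_end.y_region.end,
                        label="inversion",
                    )
                )
                run_start = None
    if run_start is not None:
        spans.append(
            Region(
                run_start.y_region.chrom,
                run_start.y_region.start,
                run_end.y_region.end,
                label="inversion",
            )
        )
    return breakpoints, spans


# ------------------------------------------------------- sequence search
def search_null_identity(length: int, base: float = 0.484, slope: float = 1.44) -> float:
    """Expected best infix edit-similarity of an unrelated query of this
    length against a multi-Mb target (the random-DNA null)."""
    return base + slope / math.sqrt(max(length, 1))


def sequence_search_hit(
    query: str,
    target: str,
    margin: float = 0.05,
    null_base: float = 0.484,
    null_slope: float = 1.44,
) -> bool:
    """Liftover-style local search: True when the best infix alignment of
    the query (either strand) beats the random-DNA null by ``margin``."""
    if not query or not target or len(query) > len(target):
        return False
    floor = search_null_identity(len(query), null_base, null_slope) + margin
    for q in (query, revcomp(query)):
        d = edlib.align(q, target, mode="HW", task="distance")["editDistance"]
        if 1.0 - d / len(query) >= floor:
            return True
    return False


def classify_y_gene(
    y_gene: GeneModel,
    x_arm_seq: str,
    synteny: SyntenyResult,
    margin: float = 0.05,
    min_exon: int = 100,
) -> str:
    """Fate of one Y gene against its corresponding X arm.

    gametolog if it has an RBH/synteny homolog; otherwise an HD-XY
    candidate, promoted to Y+X- only when neither the whole CDS nor any
    exon (>= ``min_exon`` bp, homology-annotation pass) finds homologous
    sequence on the arm.
    """
    if not y_gene.cds:
        return UNCLASSIFIABLE
    if y_gene.id in synteny.pairs:
        return GAMETOLOG
    if sequence_search_hit(y_gene.cds, x_arm_seq, margin=margin):
        return HD_XY
    for ex in y_gene.exon_seqs():
        if len(ex) >= min_exon and sequence_search_hit(ex, x_arm_seq, margin=margin):
            return HD_XY
    return Y_PLUS_X_MINUS


def gene_loss_fraction(
    x_genes: list,
    region: Region,
    y_seq: str,
    synteny: SyntenyResult,
    margin: float = 0.05,
) -> float:
    """Fraction of X genes in ``region`` with no Y homolog (unpaired and
    not found by sequence search on the Y)."""
    in_region = [
        g
        for g in x_genes
        if g.chrom == region.chrom and g.region.overlaps(region)
    ]
    if not in_region:
        raise ValueError(f"no X genes in {region}")
    lost = 0
    for g in in_region:
        if g.id in synteny.pairs_rev:
            continue
        if sequence_search_hit(g.cds, y_seq, margin=margin):
            continue
        lost += 1
    return lost / len(in_region)


# ----------------------------------------------------------- pseudogenes
_ALIGNER = None


def _affine_aligner():
    # affine gap costs: substitution-diverged homologs align gap-free, so
    # only genuine indels count as candidate frameshifts
    global _ALIGNER
    if _ALIGNER is None:
        from Bio import Align

        a = Align.PairwiseAligner(
            mode="global",
            match_score=1,
            mismatch_score=-1,
            open_gap_score=-4,
            extend_gap_score=-0.5,
        )
        _ALIGNER = a
    return _ALIGNER


def count_frame_errors(cds: str, homolog_cds: str | None = None) -> int | None:
    """Frame errors of a coding sequence.

    Without a homolog: in-frame internal stop codons of the CDS itself.
    With an intact homolog: indel runs of net length not divisible by 3 in
    an affine-gap global alignment (frameshifts), plus internal stop codons
    read in the *homolog-restored* frame — counting stops in the raw frame
    of a frameshifted sequence would misread every downstream codon.
    Returns None when the frame is undeterminable (empty or sub-codon CDS).
    """
    cds = cds.upper()
    if len(cds) < 6:
        return None
    errors = 0
    if not homolog_cds:
        for i in range(0, len(cds) - len(cds) % 3 - 3, 3):
            if cds[i : i + 3] in _STOPS:
                errors += 1
        return errors
    homolog_cds = homolog_cds.upper()
    aln = _affine_aligner().align(cds, homolog_cds)[0]
    seg_a, seg_b = aln.aligned
    # frameshifts: unaligned stretches with a net length indivisible by 3
    prev_a = prev_b = 0
    boundaries = list(zip(seg_a, seg_b)) + [
        ((len(cds), len(cds)), (len(homolog_cds), len(homolog_cds)))
    ]
    for (a_s, a_e), (b_s, b_e) in boundaries:
        gap = abs((a_s - prev_a) - (b_s - prev_b))
        if gap % 3 != 0:
            errors += 1
        prev_a, prev_b = a_e, b_e
    # internal stops, codon grid taken from the homolog coordinates
    last_codon = (len(homolog_cds) // 3 - 1) * 3
    for (a_s, a_e), (b_s, b_e) in zip(seg_a, seg_b):
        b0 = ((b_s + 2) // 3) * 3
        while b0 + 3 <= b_e:
            if b0 < last_codon:
                a0 = a_s + (b0 - b_s)
                if cds[a0 : a0 + 3] in _STOPS:
                    errors += 1
            b0 += 3
    return errors


def flag_pseudogene(
    gene: GeneModel,
    homolog_cds: str | None = None,
    max_frame_errors: int = 2,
) -> tuple[bool | None, int | None]:
    """Pseudogene flag: multi-exon gene with more than ``max_frame_errors``
    frame errors.  Single-exon genes are never flagged (their error count
    is still reported).  Returns ``(flag, n_frame_errors)``; ``(None,
    None)`` when the frame is undeterminable."""
    errors = count_frame_errors(gene.cds, homolog_cds)
    if errors is None:
        return None, None
    if gene.n_exons < 2:
        return False, errors
    return errors > max_frame_errors, errors
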