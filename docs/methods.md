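# Methods

This note documents the models, estimators and numerical choices behind
`neoy`, and what the simulator does and does not emulate.

## The system being modelled

A neo-Y chromosome arises when an ancestral Y — already recombinationally
isolated from its X1 gametolog — fuses with an autosome (Robertsonian
translocation), turning the autosome's free homolog into a new X2. Males
are X1 X2 Y, females X1X1 X2X2. The non-recombining Y then accumulates
divergence from both X partners in *strata*: contiguous segments that
stopped recombining at one time and therefore share one X–Y divergence
age. The default simulated Y carries, in order: a pseudoautosomal region
(PAR1), three X1-homologous strata of 55 / 28 / 55 Ma spanned by an
inversion, a repeat-like fusion spacer, a flat 48-Ma stratum on the fused
arm, a gradient segment whose age declines linearly from 48 Ma to zero at
the distal tip, and PAR2.

## Dating

**Distances.** Aligned X–Y blocks are scored with the Kimura (1980)
two-parameter distance, D = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), separating
transition (P) and transversion (Q) fractions; ambiguous bases are removed
from numerator and denominator. Pairs with a non-positive log argument
return NaN (saturation marker) and propagate as masked windows rather
than exceptions. Blocks with total aligned length ≤ `min_block` (default
1000 bp, a block-level property applied before clipping) are discarded;
surviving blocks are clipped to 100-kb window bounds and each window takes
the aligned-length-weighted mean of its fragment distances. Windows with
no qualifying base, or containing a saturated fragment, are masked.

**Times.** T = D/(2μ) with μ = 8.18 × 10⁻¹⁰ substitutions/site/year by
default, treated as a given constant (estimating μ from cross-species
orthology is out of scope). The coding route uses NG86: synonymous site
counts averaged over both sequences, multi-difference codons averaged over
all mutational orderings (orderings passing through stop codons are
excluded; if all are blocked, all are used), and the Jukes–Cantor
correction Ks = −¾ ln(1 − 4/3 pS). pS ≥ 0.75 and S = 0 return NaN
markers. Rate calibration is r = Ks/(2t) and its inverse t = Ks/(2r).

**Why the simulator uses the full K2P process.** Each lineage evolves by
the exact continuous-time K2P transition probabilities (transition:
transversion rate ratio 2:1 by default), not by at-most-one-change
draws. At a 55-Ma stratum the expected distance 2μT ≈ 0.090 is large
enough that applying the K2P multiple-hit correction to single-hit data
would overestimate ages by ~7%; under the true process the K2P estimator
is consistent and windowed dating recovers planted ages essentially
unbiased (the acceptance run measures 55.0 / 28.0 / 48.0 Ma on planted
55 / 28 / 48). PAR sequences differ only at the polymorphism level θ.

## Stratum segmentation

The windowed age series is segmented by exact dynamic programming over
changepoints. The per-segment cost is the residual sum of squares of a
*linear* fit (a constant-cost mode exists as `cost="constant"`). The
linear cost is deliberate: the fused arm's gradient segment is, by
construction, a linear ramp in age, and a piecewise-constant objective
provably prefers to split a long ramp into multiple flat pieces while
merging the adjacent 55- and 48-Ma strata — a mis-segmentation no penalty
choice can fix at fixed k = 5. With linear segment costs, constant strata
and the ramp each fit one segment with near-zero residual, and the four
true boundaries are recovered to within ±2 windows in ≥ 9/10 seeds.
Masked windows (the fusion spacer, unaligned gaps) are excluded from the
cost and bridged. Either k (number of segments) is fixed, or a per-segment
penalty is added (default 2σ̂² ln n with σ̂ from median absolute first
differences). Ties break toward fewer, earlier boundaries, making the
segmentation deterministic. The gradient section is reported as a single
call whose `mean_age` is the segment mean; per-window ages remain in the
track.

## Sex-linked genotype patterns

A site is an scsSNP iff call rate ≥ 0.8 in each sex (mirroring a
`max-missing 0.8` VCF filter), all called females are homozygous for one
*shared* allele (a Y-specific allele implies one common X allele — either
hom-ref or hom-alt qualifies), and all called males are heterozygous. A
`tolerance` parameter relaxes "all" to a fraction for genotyping error;
the default keeps the strict rule. Fixed X–Y differences produce exactly
this pattern on an X reference; Y-linked polymorphisms that drifted near
fixation also can, which is why the male-specific-het fraction of a
region brackets the planted fixed-difference share from above in
simulation tests.

## Degeneration scans

**F_ST.** Per-site Weir & Cockerham (1984) two-level variance components
a, b, c from genotype counts of the two sexes (r = 2; unequal sample
sizes handled through n̄ and n_c), summarised per window as Σa/Σ(a+b+c)
with negative components retained. Sites with fewer than two called
diploids in either sex, and sites monomorphic in the pooled sample, are
skipped; windows with no usable site are masked. The implementation is
vectorised and verified against an independently coded per-site oracle to
1e-10.

**Diversity.** π per window bp as Σ 2p̂q̂·n/(n−1) over sites, n the
called allele count.

**Depth ratio.** The simulator's mapping model: a Y-derived read still
maps to the X reference with probability c(d) = exp(−λ d) at local X–Y
divergence d, so male expected depth on X is m(1 + c(d)) against a female
2m. Normalising each sex by its autosomal mean puts autosomes at 1,
differentiated regions at (1 + c)/2 ∈ (0.5, 1) for any positive λ, and
the single-copy floor 0.5 only in the no-cross-mapping limit. λ defaults
to 15, which reproduces a ~0.65 ratio at 9% divergence — the visual level
of published sexed-coverage scans. The ratio orientation is
heterogametic:homogametic on the X reference; windows with zero female
depth are masked.

**HDR calling.** A window is flagged when F_ST ≥ (autosomal mean + 5 SD)
AND depth ratio ≤ 0.9; flagged runs merge across gaps ≤ 1 window. This
threshold-plus-merge rule stands in for an association scan. A
consequence of the AND-rule: on the fused arm's age gradient, windows
younger than ln(1/0.9)/(2μλ) ≈ 9 Ma (at default λ) have expected depth
ratio above 0.9 and cannot be flagged, so the called X2 HDR ends a few
windows short of the planted non-PAR — matching the biological situation
in which the youngest, least diverged tail of a fused arm is
indistinguishable from a PAR by coverage. The X1 call is exact at window
resolution.

## Gene fates

Homolog pairs are reciprocal best hits on CDS 8-mer containment (floors
0.5 identity-proxy/coverage), chained into collinear runs (uniform
direction, ranks among paired genes, min chain 3). Y genes without an RBH
partner on the corresponding arm are HD-XY candidates; a liftover-style
search decides Y⁺X⁻: the whole CDS, and then each exon ≥ 100 bp
(an annotation-like second pass), is infix-aligned to the arm on both
strands with edlib. A hit requires edit-similarity above a
length-dependent null plus margin: the best infix edit-similarity of an
*unrelated* query against a multi-Mb arm concentrates near
0.484 + 1.44/√L (measured on random DNA), so the floor is that null +
0.05. A flat low floor would classify every deleted gene as HD-XY; a flat
high floor would miss genuinely diverged copies. Gene-loss fractions
apply the mirrored logic to X genes against the Y sequence.

Pseudogene flagging follows the frame-error rule: frameshifts (indel runs
of net length ≢ 0 mod 3 in an affine-gap global alignment to the intact
homolog — affine costs so substitution divergence does not fake indels)
plus internal stop codons read in the homolog-restored frame (counting
stops in the raw frame of a frameshifted sequence would misread every
downstream codon). A multi-exon gene with more than two frame errors is
flagged; single-exon genes are reported but never flagged, and their
counts are kept separate.

## The simulator: what it does and does not emulate

Generated: per-stratum K2P divergence with per-site age arrays (linear
gradient on the fused arm), an inversion (reverse-complemented on the Y,
emitting `-`-oriented blocks), PARs at polymorphism-level divergence,
population genotypes for sexed samples on the female reference (fixed X–Y
differences → all-female-hom / all-male-het; polymorphic sites at a
density tuned so per-bp diversity equals θ, allele frequencies uniform on
(0.1, 0.9), optional genotyping error and missingness), sexed Poisson
read depth under the cross-mapping model, embedded gene loci evolving at
half the neutral rate (purifying selection) with nonsense substitutions
rejected in functional copies, planted gene fates (pseudogenes = 3
injected internal stops; HD-XY = Y copy diverged to ~70% identity;
Y⁺X⁻ / lost-on-Y = the X or Y locus replaced by unrelated sequence and
excluded from alignment blocks, as an aligner would not report
non-homologous segments), and a 6+6 gonad TPM table in which planted
genes satisfy the male-specific rule exactly.

Not modelled: coalescent genealogies and linked selection, recombination
maps, indels in chromosomal alignments, transposable-element sequence
evolution, read-level artefacts (mapping quality, GC bias), and
expression count noise beyond log-normal scatter. Passing recovery tests
therefore demonstrates the *estimators and decision rules* are correct
under the stated generative assumptions, not that real data meet those
assumptions.

## Default study conditions

μ = 8.18e-10 /site/year; strata 1 Mb each (gradient 1.5 Mb), PARs 0.3 Mb,
spacer 50 kb, autosome 1.5 Mb; θ = 0.003 (autosomal SNP density ~0.3%);
20 males + 28 females; mean depth 5.5 per haploid copy (~11× diploid);
λ = 15; 300 sex-chromosome genes (CDS 900 bp, ≤ 6 exons) + 60 autosomal;
8% pseudogene rate, 10 HD-XY, 6 Y⁺X⁻, 12 lost-on-Y; 87 planted
male-specific genes among 6 ovary + 6 testis samples. Desk-scale runs
(full pipeline ~1–2 min on one CPU) use these sizes; the acceptance
script uses single 2-Mb strata averaged over 10 seeds.

## Numerical conventions

Regions and windows are 0-based half-open; VCF positions 1-based,
converted at the reader boundary. "Sliding" windows are non-overlapping
tiling windows (step = span) by default, with an optional step. All
randomness derives from one seed through named substreams (CRC-keyed
`SeedSequence` spawns), so identical configs give byte-identical outputs;
floats are written with a fixed `%.10g` format. Undefined statistics
(zero denominators, saturation) are NaN markers plus window masks, never
exceptions, except where a precondition is violated outright.
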