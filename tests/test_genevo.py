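"""RBH synteny, inversion breakpoints, gene fates and pseudogene flags."""

import numpy as np
import pytest

from neoy.core import Region
from neoy.dating import AlignmentBlock, revcomp
from neoy.genevo import (
    GAMETOLOG,
    HD_XY,
    LOST,
    UNCLASSIFIABLE,
    Y_PLUS_X_MINUS,
    GeneModel,
    SyntenyResult,
    classify_y_gene,
    count_frame_errors,
    detect_inversion_breakpoints,
    flag_pseudogene,
    gene_loss_fraction,
    rbh_synteny,
    sequence_search_hit,
)

_EMPTY = SyntenyResult({}, {}, [])


_SENSE = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _random_cds(rng, n=900):
    """Random coding sequence without internal stop codons."""
    n_codons = n // 3
    return "ATG" + "".join(
        _SENSE[i] for i in rng.integers(0, len(_SENSE), n_codons - 1)
    )


def _mutate(seq, rng, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[(("ACGT".index(out[i])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def _gene(gid, chrom, start, cds, n_exons=1, strand="+"):
    glen = len(cds)
    exons = []
    if n_exons == 1:
        exons = [Region(chrom, start, start + glen)]
    else:
        step = glen // n_exons
        pos = start
        for i in range(n_exons):
            ln = step if i < n_exons - 1 else glen - step * (n_exons - 1)
            exons.append(Region(chrom, pos, pos + ln))
            pos += ln + 10
    return GeneModel(
        id=gid,
        chrom=chrom,
        strand=strand,
        region=Region(chrom, start, exons[-1].end),
        exons=exons,
        cds=cds,
    )


def _gene_set(rng, n, chrom, mutate_rate=0.0):
    y, x = [], []
    for i in range(n):
        cds = _random_cds(rng)
        y.append(_gene(f"Yg{i:03d}", "chrY", i * 2000, cds))
        x.append(_gene(f"Xg{i:03d}", chrom, i * 2000, _mutate(cds, rng, mutate_rate)))
    return y, x


class TestRBHSynteny:
    def test_identical_complements_pair_fully_in_one_forward_chain(self, rng):
        y, x = _gene_set(rng, 8, "chrX1")
        syn = rbh_synteny(y, x)
        assert len(syn.pairs) == 8
        assert len(syn.chains) == 1
        orient, run = syn.chains[0]
        assert orient == "+" and len(run) == 8

    def test_reversed_run_forms_a_reversed_chain(self, rng):
        y, x = _gene_set(rng, 10, "chrX1")
        # reverse the X order of genes 3..7 (Y order kept)
        starts = [g.region.start for g in x]
        blockidx = list(range(3, 8))
        originals = {j: x[j] for j in blockidx}
        for slot, j in zip(blockidx, reversed(blockidx)):
            src = originals[j]
            x[slot] = _gene(src.id, src.chrom, starts[slot], src.cds)
        x.sort(key=lambda g: g.region.start)
        syn = rbh_synteny(y, x, min_chain=2)
        orients = sorted(o for o, _ in syn.chains)
        assert orients == ["+", "+", "-"]
        rev = [run for o, run in syn.chains if o == "-"]
        assert len(rev) == 1 and len(rev[0]) == 5
        assert [yid for yid, _ in rev[0]] == [f"Yg{i:03d}" for i in range(3, 8)]

    def test_diverged_gene_stays_unpaired(self, rng):
        y, x = _gene_set(rng, 5, "chrX1")
        x[2] = _gene(x[2].id, x[2].chrom, x[2].region.start, _mutate(x[2].cds, rng, 0.4))
        syn = rbh_synteny(y, x)
        assert "Yg002" not in syn.pairs
        assert len(syn.pairs) == 4

    def test_empty_gene_set_gives_empty_result(self):
        syn = rbh_synteny([], [])
        assert syn.pairs == {} and syn.chains == []


def _block(ys, ye, orient, chrom="chrY"):
    return AlignmentBlock(
        y_region=Region(chrom, ys, ye),
        x_region=Region("chrX1", ys, ye),
        orient=orient,
    )


class TestInversionBreakpoints:
    def test_all_forward_blocks_give_no_breakpoints(self):
        bps, spans = detect_inversion_breakpoints(
            [_block(0, 10, "+"), _block(10, 20, "+")]
        )
        assert bps == [] and spans == []

    def test_flanking_breakpoints_of_a_reversed_run(self):
        blocks = [
            _block(0, 10, "+"),
            _block(10, 20, "-"),
            _block(20, 30, "-"),
            _block(30, 40, "-"),
            _block(40, 50, "+"),
        ]
        bps, spans = detect_inversion_breakpoints(blocks)
        assert len(bps) == 2
        assert bps[0].start == 10 and bps[1].start == 40
        assert len(spans) == 1
        assert (spans[0].start, spans[0].end) == (10, 40)

    def test_invariant_under_global_orientation_flip(self):
        blocks = [_block(0, 10, "+"), _block(10, 20, "-"), _block(20, 30, "+")]
        flipped = [
            _block(b.y_region.start, b.y_region.end, "-" if b.orient == "+" else "+")
            for b in blocks
        ]
        bps1, _ = detect_inversion_breakpoints(blocks)
        bps2, _ = detect_inversion_breakpoints(flipped)
        assert [(b.start, b.end) for b in bps1] == [(b.start, b.end) for b in bps2]

    def test_fewer_than_two_blocks_gives_nothing(self):
        bps, _ = detect_inversion_breakpoints([_block(0, 10, "-")])
        assert bps == []

    def test_recovers_simulated_inversion_span(self, small_history):
        inv = small_history.truth.inversion
        _, spans = detect_inversion_breakpoints(small_history.blocks)
        assert len(spans) == 1
        assert spans[0].start == inv.start
        assert spans[0].end == inv.end


class TestClassifyYGene:
    def _arm(self, rng, n=200_000):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    def test_paired_gene_is_gametolog(self, rng):
        g = _gene("Yg000", "chrY", 0, _random_cds(rng))
        syn = SyntenyResult({"Yg000": "Xg000"}, {"Xg000": "Yg000"}, [])
        assert classify_y_gene(g, self._arm(rng), syn) == GAMETOLOG

    def test_deleted_x_copy_gives_y_plus_x_minus(self, rng):
        g = _gene("Yg000", "chrY", 0, _random_cds(rng), n_exons=3)
        assert classify_y_gene(g, self._arm(rng), _EMPTY) == Y_PLUS_X_MINUS

    def test_sixty_percent_copy_is_hd_xy(self, rng):
        cds = _random_cds(rng)
        arm = self._arm(rng, 100_000)
        arm = arm[:50_000] + _mutate(cds, rng, 0.4) + arm[50_000:]
        g = _gene("Yg000", "chrY", 0, cds)
        assert classify_y_gene(g, arm, _EMPTY) == HD_XY

    def test_copy_on_reverse_strand_is_found(self, rng):
        cds = _random_cds(rng)
        arm = self._arm(rng, 100_000)
        arm = arm[:50_000] + revcomp(_mutate(cds, rng, 0.2)) + arm[50_000:]
        g = _gene("Yg000", "chrY", 0, cds)
        assert classify_y_gene(g, arm, _EMPTY) == HD_XY

    def test_gene_without_cds_is_not_classifiable(self, rng):
        g = GeneModel(
            id="Yg000",
            chrom="chrY",
            strand="+",
            region=Region("chrY", 0, 100),
            exons=[Region("chrY", 0, 100)],
            cds="",
        )
        assert classify_y_gene(g, self._arm(rng), _EMPTY) == UNCLASSIFIABLE

    def test_classification_is_a_partition_on_simulation(self, small_history):
        from neoy.sim import simulate_genes

        cfg = small_history.cfg
        y_genes, x_genes, _ = simulate_genes(cfg, small_history)
        syn = rbh_synteny(y_genes, x_genes)
        labels = small_history.truth.extras["gene_labels"]
        seen = set()
        for g in y_genes:
            arm = "chrX1" if g.region.end <= cfg.x1_len else "chrX2"
            if g.id in syn.pairs:
                fate = GAMETOLOG
            else:
                fate = classify_y_gene(g, small_history.seqs[arm], _EMPTY)
            assert fate in (GAMETOLOG, HD_XY, Y_PLUS_X_MINUS, UNCLASSIFIABLE)
            seen.add(fate)
            truth = labels[g.id]
            expect = {"pseudogene": GAMETOLOG}.get(truth, truth)
            assert fate == expect
        assert {GAMETOLOG, HD_XY, Y_PLUS_X_MINUS} <= seen


class TestGeneLoss:
    def test_loss_fraction_on_toys(self, rng):
        y, x = _gene_set(rng, 10, "chrX1")
        y_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 50_000))
        syn = rbh_synteny(y, x)
        region = Region("chrX1", 0, 1_000_000)
        assert gene_loss_fraction(x, region, y_seq, syn) == 0.0
        # delete two Y copies entirely: unpaired and unsearchable
        y2 = y[:8]
        syn2 = rbh_synteny(y2, x)
        assert gene_loss_fraction(x, region, y_seq, syn2) == pytest.approx(0.2)
        syn3 = rbh_synteny([], x)
        assert gene_loss_fraction(x, region, y_seq, syn3) == 1.0

    def test_empty_region_is_an_error(self, rng):
        with pytest.raises(ValueError):
            gene_loss_fraction([], Region("chrX1", 0, 10), "ACGT", _EMPTY)

    def test_planted_losses_recovered_on_simulation(self, small_history):
        from neoy.sim import simulate_genes

        cfg = small_history.cfg
        y_genes, x_genes, _ = simulate_genes(cfg, small_history)
        syn = rbh_synteny(y_genes, x_genes)
        labels = small_history.truth.extras["gene_labels"]
        y_seq = small_history.seqs["chrY"]
        lost_truth = {
            gid.replace("Yg", "X1g"): lab
            for gid, lab in labels.items()
            if lab == LOST
        } | {
            gid.replace("Yg", "X2g"): lab
            for gid, lab in labels.items()
            if lab == LOST
        }
        n_lost = 0
        for g in x_genes:
            if g.id in syn.pairs_rev:
                continue
            if not sequence_search_hit(g.cds, y_seq):
                n_lost += 1
                assert g.id in lost_truth
        assert n_lost == cfg.lost_count


class TestPseudogeneFlag:
    def _multi(self, cds, rng):
        return _gene("Yg0", "chrY", 0, cds, n_exons=3)

    def test_three_frameshifts_flag_a_multi_exon_gene(self, rng):
        intact = _random_cds(rng)
        broken = intact[:100] + intact[101:400] + intact[401:700] + intact[701:]
        g = self._multi(broken, rng)
        flag, errors = flag_pseudogene(g, homolog_cds=intact)
        assert errors >= 3
        assert flag is True

    def test_two_frame_errors_do_not_flag(self, rng):
        intact = _random_cds(rng)
        broken = intact[:100] + intact[101:400] + intact[401:]
        g = self._multi(broken, rng)
        flag, errors = flag_pseudogene(g, homolog_cds=intact)
        assert errors == 2
        assert flag is False

    def test_in_frame_indel_is_not_a_frame_error(self, rng):
        intact = _random_cds(rng)
        broken = intact[:300] + intact[303:]
        g = self._multi(broken, rng)
        flag, errors = flag_pseudogene(g, homolog_cds=intact)
        assert errors == 0 and flag is False

    def test_internal_stops_count_but_single_exon_is_never_flagged(self):
        cds = "ATG" + "TAA" * 5 + "GGC" * 20 + "TGA"
        single = _gene("Yg0", "chrY", 0, cds, n_exons=1)
        flag, errors = flag_pseudogene(single)
        assert errors == 5
        assert flag is False
        multi = _gene("Yg1", "chrY", 0, cds, n_exons=2)
        assert flag_pseudogene(multi)[0] is True

    def test_undeterminable_frame(self):
        g = _gene("Yg0", "chrY", 0, "ATG", n_exons=1)
        assert flag_pseudogene(g) == (None, None)

    def test_planted_pseudogene_recall_and_precision(self, small_history):
        from neoy.sim import simulate_genes

        y_genes, x_genes, _ = simulate_genes(small_history.cfg, small_history)
        x_cds = {g.id: g.cds for g in x_genes}
        syn = rbh_synteny(y_genes, x_genes)
        flagged = set()
        for g in y_genes:
            homolog = x_cds.get(syn.pairs.get(g.id, ""))
            if flag_pseudogene(g, homolog)[0]:
                flagged.add(g.id)
        assert flagged == set(small_history.truth.planted_pseudogenes)
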