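"""K2P distances, windowed dating, Ks calibration and segmentation."""

import itertools
import math

import numpy as np
import pytest

from neoy.core import Region, make_windows
from neoy.dating import (
    AlignmentBlock,
    divergence_time,
    k2p_counts,
    kimura2p_distance,
    ks_ng86,
    rate_from_ks,
    segment_strata,
    time_from_ks,
    windowed_divergence,
)

MU = 8.18e-10


# ------------------------------------------------------------- K2P oracle
_TS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def k2p_bruteforce(a: str, b: str) -> float:
    """Independent count-and-correct K2P evaluation (per-character loop)."""
    ts = tv = n = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x, y) in _TS:
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


def _mutated_pair(rng, n=500):
    bases = np.array(list("ACGT"))
    a = bases[rng.integers(0, 4, n)]
    b = a.copy()
    p = rng.uniform(0, 0.12)
    q = rng.uniform(0, 0.08)
    u = rng.random(n)
    ts_map = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv_map = {"A": "C", "G": "T", "C": "A", "T": "G"}
    for i in range(n):
        if u[i] < p:
            b[i] = ts_map[b[i]]
        elif u[i] < p + q:
            b[i] = tv_map[b[i]]
    return "".join(a), "".join(b)


class TestKimura2P:
    def test_identical_pair_has_zero_distance(self):
        assert kimura2p_distance("ACGT" * 25, "ACGT" * 25) == 0.0

    def test_closed_form_examples(self):
        # 100 sites, 10 transitions, 0 transversions
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        assert kimura2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)
        assert kimura2p_distance(a, b) == pytest.approx(0.111572, abs=5e-7)
        # P = 0.1, Q = 0.05 on 100 sites
        c = "G" * 10 + "C" * 5 + "A" * 85
        d = kimura2p_distance(a, c)
        expect = -0.5 * math.log(0.75) - 0.25 * math.log(0.9)
        assert d == pytest.approx(expect, abs=1e-12)
        assert d == pytest.approx(0.170181, abs=5e-7)

    def test_saturation_returns_marker_not_exception(self):
        a = "A" * 10
        b = "G" * 10  # P = 1 -> 1 - 2P - Q < 0
        assert math.isnan(kimura2p_distance(a, b))

    def test_ambiguous_bases_excluded_from_both_counts(self):
        ts, tv, n = k2p_counts("ANGT", "AAGT")
        assert (ts, tv, n) == (0, 0, 3)

    def test_matches_bruteforce_oracle_on_random_pairs(self, rng):
        for _ in range(1000):
            a, b = _mutated_pair(rng, n=300)
            assert kimura2p_distance(a, b) == pytest.approx(
                k2p_bruteforce(a, b), abs=1e-12
            )


class TestWindowedDivergence:
    def _block(self, ystart, a, b, orient="+"):
        return AlignmentBlock(
            y_region=Region("chrY", ystart, ystart + len(a)),
            x_region=Region("chrX1", ystart, ystart + len(a)),
            orient=orient,
            y_seq=a,
            x_seq=b,
        )

    def test_window_value_is_aligned_length_weighted_mean(self, rng):
        w = make_windows(Region("chrY", 0, 10_000), 10_000)
        a1, b1 = _mutated_pair(rng, 1500)
        a2, b2 = _mutated_pair(rng, 2000)
        d1, d2 = kimura2p_distance(a1, b1), kimura2p_distance(a2, b2)
        track = windowed_divergence(
            [self._block(0, a1, b1), self._block(3000, a2, b2)], w, min_block=1000
        )
        expect = (1500 * d1 + 2000 * d2) / 3500
        assert track.stat("D")[0] == pytest.approx(expect, rel=1e-12)

    def test_short_blocks_are_discarded_and_window_masked(self, rng):
        w = make_windows(Region("chrY", 0, 10_000), 10_000)
        a, b = _mutated_pair(rng, 900)
        track = windowed_divergence([self._block(0, a, b)], w, min_block=1000)
        assert not track.mask[0]
        assert math.isnan(track.stat("D")[0])

    def test_single_qualifying_block_sets_the_window_value(self, rng):
        w = make_windows(Region("chrY", 0, 10_000), 10_000)
        a, b = _mutated_pair(rng, 2000)
        track = windowed_divergence([self._block(100, a, b)], w)
        assert track.stat("D")[0] == pytest.approx(kimura2p_distance(a, b), rel=1e-12)

    def test_min_block_applies_before_clipping(self, rng):
        # a 1.5 kb block overlapping a window by 200 bp still contributes
        w = make_windows(Region("chrY", 0, 2000), 1000)
        a, b = _mutated_pair(rng, 1500)
        track = windowed_divergence([self._block(800, a, b)], w, min_block=1000)
        assert track.mask[0] and track.mask[1]
        frag_d = kimura2p_distance(a[:200], b[:200])
        assert track.stat("D")[0] == pytest.approx(frag_d, rel=1e-12)


class TestDivergenceTime:
    def test_examples_and_linearity(self):
        assert divergence_time(0.0, MU) == 0.0
        assert divergence_time(0.089980, MU) == pytest.approx(5.50e7, rel=1e-4)
        assert divergence_time(0.078528, MU) == pytest.approx(4.80e7, rel=1e-4)
        # exact inverse of D = 2 mu T
        for T in (1e6, 2.8e7, 5.5e7):
            assert divergence_time(2 * MU * T, MU) == pytest.approx(T, rel=1e-12)

    def test_non_positive_rate_is_an_error(self):
        with pytest.raises(ValueError):
            divergence_time(0.1, 0.0)


class TestKsCalibration:
    def test_rate_from_ks_reproduces_published_calibration(self):
        # Ks 0.03 at a 11.5 Ma split -> ~1.3e-9 per site per year
        assert rate_from_ks(0.03, 1.15e7) == pytest.approx(1.3043e-9, rel=1e-4)
        assert rate_from_ks(0.0, 1.15e7) == 0.0

    def test_time_from_ks_inverse(self):
        r = rate_from_ks(0.03, 1.15e7)
        assert time_from_ks(0.157, r) == pytest.approx(6.018e7, rel=1e-3)
        assert time_from_ks(rate_from_ks(0.2, 5e6) * 2 * 5e6, r) > 0

    def test_non_positive_denominators_are_errors(self):
        with pytest.raises(ValueError):
            rate_from_ks(0.03, 0.0)
        with pytest.raises(ValueError):
            time_from_ks(0.03, 0.0)


# ------------------------------------------------------------ NG86 oracle
def _code():
    from Bio.Seq import Seq

    return {
        "".join(c): str(Seq("".join(c)).translate())
        for c in itertools.product("ACGT", repeat=3)
    }


def ks_oracle(a: str, b: str) -> float:
    """Exhaustive-codon-path NG86 re-derivation (independent code path)."""
    code = _code()
    S = 0.0
    Sd = 0.0
    for i in range(0, len(a), 3):
        c1, c2 = a[i : i + 3], b[i : i + 3]
        if code[c1] == "*" or code[c2] == "*":
            continue
        for c in (c1, c2):
            syn = 0
            for pos in range(3):
                for alt in "ACGT":
                    if alt != c[pos]:
                        mut = c[:pos] + alt + c[pos + 1 :]
                        if code[mut] == code[c] and code[mut] != "*":
                            syn += 1
            S += syn / 6.0  # averaged over the two sequences, /3 per site
        diff_pos = [p for p in range(3) if c1[p] != c2[p]]
        if not diff_pos:
            continue
        paths = []
        stop_free = []
        for order in itertools.permutations(diff_pos):
            cur, sd = c1, 0.0
            ok = True
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if code[nxt] == "*":
                    ok = False
                if code[nxt] == code[cur] and code[nxt] != "*":
                    sd += 1
                cur = nxt
            (stop_free if ok else paths).append(sd)
        use = stop_free if stop_free else paths
        Sd += sum(use) / len(use)
    ps = Sd / S
    return -0.75 * math.log(1 - ps * 4 / 3)


def _random_cds(rng, n_codons=30):
    code = _code()
    sense = [c for c, aa in code.items() if aa != "*"]
    return "".join(sense[i] for i in rng.integers(0, len(sense), n_codons))


class TestKsNG86:
    def test_identical_cds_has_zero_ks(self, rng):
        cds = _random_cds(rng)
        assert ks_ng86(cds, cds) == 0.0

    def test_single_synonymous_change_matches_site_counting(self, rng):
        cds = "ATG" + "GGT" + _random_cds(rng, 28)
        other = cds[:3] + "GGC" + cds[6:]
        got = ks_ng86(cds, other)
        oracle = ks_oracle(cds, other)
        assert got == pytest.approx(oracle, abs=1e-12)
        assert got > 0

    def test_purely_nonsynonymous_pair_has_zero_ks(self):
        a = "ATGGCTGCTGCTGCTGCT"  # M A A A A A
        b = "ATGGATGATGATGATGAT"  # M D D D D D (GCT->GAT is nonsynonymous)
        assert ks_ng86(a, b) == 0.0

    def test_matches_exhaustive_path_oracle_on_toy_pairs(self, rng):
        for _ in range(50):
            a = _random_cds(rng, 25)
            b = list(a)
            for j in rng.choice(len(b), size=6, replace=False):
                b[j] = "ACGT"[int(rng.integers(0, 4))]
            b = "".join(b)
            ka, kb = ks_ng86(a, b), ks_oracle(a, b)
            if math.isnan(ka):
                assert math.isnan(kb)
            else:
                assert ka == pytest.approx(kb, abs=1e-12)

    def test_bad_frame_is_an_error(self):
        with pytest.raises(ValueError):
            ks_ng86("ATGA", "ATGA")


# ------------------------------------------------------------ segmentation
def _track_from_values(values, mask=None, span=100):
    t = make_windows(Region("chrY", 0, span * len(values)), span)
    t.set_stat("T", values, valid=mask)
    return t


class TestSegmentation:
    def test_noise_free_three_strata_recovered_exactly(self):
        vals = [55.0] * 20 + [28.0] * 10 + [55.0] * 15
        calls = segment_strata(_track_from_values(vals), k=3)
        assert [c.region.start for c in calls] == [0, 2000, 3000]
        assert [c.mean_age for c in calls] == [55.0, 28.0, 55.0]

    def test_constant_series_is_one_segment(self):
        calls = segment_strata(_track_from_values([40.0] * 30))
        assert len(calls) == 1
        assert calls[0].mean_age == 40.0

    def test_linear_gradient_is_one_segment_under_linear_cost(self):
        vals = list(np.linspace(48.0, 0.0, 25))
        calls = segment_strata(_track_from_values(vals), k=1)
        two = segment_strata(_track_from_values([48.0] * 10 + vals), k=2)
        assert len(calls) == 1
        assert [c.region.start for c in two] == [0, 1000]

    def test_masked_windows_are_bridged(self):
        vals = [55.0] * 10 + [0.0, 0.0] + [28.0] * 10
        mask = [True] * 10 + [False, False] + [True] * 10
        calls = segment_strata(_track_from_values(vals, mask), k=2)
        assert len(calls) == 2
        assert calls[0].mean_age == 55.0
        assert calls[1].mean_age == 28.0

    def test_all_masked_is_an_error(self):
        with pytest.raises(ValueError):
            segment_strata(_track_from_values([1.0] * 5, [False] * 5), k=1)

    def test_segment_count_monotone_in_penalty(self, rng):
        vals = np.concatenate(
            [rng.normal(m, 0.5, 12) for m in (55, 28, 55, 48)]
        )
        t = _track_from_values(list(vals))
        counts = [
            len(segment_strata(t, penalty=p, cost="constant"))
            for p in (1e-6, 1.0, 10.0, 1e3, 1e6)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == t.n  # penalty -> 0: one segment per window
        assert counts[-1] == 1  # penalty -> inf: a single segment
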