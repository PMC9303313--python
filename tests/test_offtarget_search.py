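"""Semi-global distance scan, per-gene distance classes, exclusion screen."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapmertox import (
    classify_offtargets,
    exclusion_screen,
    parse_gapmer,
    reverse_complement,
    scan_transcript,
    semi_global_distance,
)
from gapmertox.offtarget import GeneDistanceMap, d_class, hamming_min
from gapmertox.simulate import plant_site

from oracle_utils import (
    brute_force_min_substring_distance,
    edlib_infix,
    naive_semi_global,
    random_dna,
)

pattern_st = st.text(alphabet="ACGT", min_size=8, max_size=14)
text_st = st.text(alphabet="ACGT", min_size=0, max_size=120)


class TestSemiGlobalDistance:
    @pytest.mark.parametrize(
        "pattern,text,expected",
        [
            ("ACGT", "TTACGTTT", 0),  # exact substring
            ("ACGT", "TTAGGTTT", 1),  # single mismatch
            ("ACGT", "TTACGGTTT", 1),  # one edit (no exact copy present)
            ("ACGT", "", 4),  # empty text: all deleted
        ],
    )
    def test_known_values(self, pattern, text, expected):
        assert semi_global_distance(pattern, text) == expected

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            semi_global_distance("", "ACGT")

    @given(pattern_st, text_st)
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_naive_dp_and_edlib(self, pattern, text):
        ours = semi_global_distance(pattern, text)
        assert ours == naive_semi_global(pattern, text)
        assert ours == edlib_infix(pattern, text)

    @given(pattern_st, st.text(alphabet="ACGT", min_size=0, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_substring_brute_force(self, pattern, text):
        assert semi_global_distance(pattern, text) == brute_force_min_substring_distance(
            pattern, text
        )


class TestScanTranscript:
    def test_planted_exact_site(self, ts1):
        site = reverse_complement(ts1.sequence)
        text = "A" * 50 + site + "A" * 30
        hits = scan_transcript(ts1, ("tx", text), d_max=0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.d) == (50, 50 + len(site), 0)
        assert h.aligned_query == h.aligned_target == site

    def test_planted_two_edit_site_roundtrip(self, ts1, rng):
        base = random_dna(rng, 120)
        # keep drawing backgrounds until one is clean enough to plant into
        seq, (start, end) = plant_site(base, ts1, d=2, seed=rng)
        hits = scan_transcript(ts1, ("tx", seq), d_max=2)
        assert hits and min(h.d for h in hits) == 2

    def test_threshold_excludes(self, ts1, rng):
        base = random_dna(rng, 120)
        seq, _ = plant_site(base, ts1, d=2, seed=rng)
        assert scan_transcript(ts1, ("tx", seq), d_max=1) == []

    def test_empty_transcript(self, ts1):
        assert scan_transcript(ts1, ("tx", ""), d_max=3) == []

    def test_edit_decomposition_sums_to_d(self, ts1, rng):
        for d in range(4):
            seq, _ = plant_site(random_dna(rng, 100), ts1, d=d, seed=rng)
            for h in scan_transcript(ts1, ("tx", seq), d_max=3):
                assert h.d == h.n_mismatch + h.n_ins + h.n_del
                assert h.end - h.start == len(ts1.sequence) - h.n_del + h.n_ins

    def test_hit_set_monotone_in_dmax(self, ts1, rng):
        seq, _ = plant_site(random_dna(rng, 150), ts1, d=1, seed=rng)
        for k in range(3):
            lo = {(h.start, h.end) for h in scan_transcript(ts1, ("tx", seq), d_max=k)}
            hi_hits = scan_transcript(ts1, ("tx", seq), d_max=k + 1)
            # every low-threshold site is still covered at the looser threshold
            for s, e in lo:
                assert any(h.start < e and s < h.end for h in hi_hits)


class TestClassifyOfftargets:
    def test_min_over_transcripts(self, ts1, rng):
        t1, _ = plant_site(random_dna(rng, 100), ts1, d=2, seed=rng)
        t2, _ = plant_site(random_dna(rng, 100), ts1, d=1, seed=rng)
        dist = classify_offtargets(
            ts1, {"txA": t1, "txB": t2}, {"txA": "g1", "txB": "g1"}, d_max=3
        )
        assert dist.min_d["g1"] == 1
        assert dist.class_of("g1") == "d1"

    def test_planted_classes_recovered(self, ts1, rng):
        transcripts, tx2gene = {}, {}
        for d in range(3):
            seq, _ = plant_site(random_dna(rng, 150), ts1, d=d, seed=rng)
            transcripts[f"tx{d}"] = seq
            tx2gene[f"tx{d}"] = f"g{d}"
        dist = classify_offtargets(ts1, transcripts, tx2gene, d_max=3)
        assert {g: d_class(d) for g, d in dist.min_d.items()} == {
            "g0": "d0",
            "g1": "d1",
            "g2": "d2",
        }

    def test_empty_transcriptome(self, ts1):
        assert classify_offtargets(ts1, {}, {}, d_max=3).min_d == {}

    def test_missing_mapping_listed(self, ts1):
        with pytest.raises(KeyError, match="txZ"):
            classify_offtargets(ts1, {"txZ": "ACGT" * 10}, {}, d_max=3)

    def test_frame_roundtrip(self, ts1):
        dist = GeneDistanceMap(aso_id="TS1", min_d={"gA": 0, "gB": 3})
        back = GeneDistanceMap.from_frame(dist.to_frame())
        assert back == dist


class TestDClass:
    def test_pooling(self):
        assert [d_class(d) for d in [0, 1, 2, 3, 7]] == ["d0", "d1", "d2", "d3plus", "d3plus"]


class TestExclusionScreen:
    def test_verbatim_complement_fails(self, rng):
        cand = random_dna(rng, 14)
        tx = random_dna(rng, 60) + reverse_complement(cand) + random_dna(rng, 60)
        result = exclusion_screen([cand], {"t": tx})
        assert not result["passed"].iloc[0]
        assert result["best_d"].iloc[0] == 0

    def test_d2_planted_passes(self, ts1, rng):
        seq, _ = plant_site(random_dna(rng, 150), ts1, d=2, seed=rng)
        result = exclusion_screen([ts1.sequence], {"t": seq})
        assert result["passed"].iloc[0]
        assert result["best_d"].iloc[0] == 2

    def test_empty_transcriptome_all_pass(self, rng):
        cands = [random_dna(rng, 14) for _ in range(5)]
        result = exclusion_screen(cands, {})
        assert result["passed"].all()
        assert (result["best_d"] == math.inf).all()

    @given(pattern_st, st.text(alphabet="ACGT", min_size=14, max_size=120))
    @settings(max_examples=150, deadline=None)
    def test_hamming_never_below_edit(self, pattern, text):
        assert hamming_min(pattern, text) >= semi_global_distance(pattern, text)

    def test_mismatch_only_mode(self):
        # one insertion: edit distance 1 (excluded), Hamming distance larger
        cand = "GTTATGCCACCCTA"
        site = reverse_complement(cand)  # TAGGGTGGCATAAC
        broken = site[:7] + "A" + site[7:]
        tx = "C" * 40 + broken + "C" * 40
        assert semi_global_distance(site, tx) == 1
        assert hamming_min(site, tx) > 1
        assert not exclusion_screen([cand], {"t": tx}, mode="edit")["passed"].iloc[0]
        assert exclusion_screen([cand], {"t": tx}, mode="mismatch_only")["passed"].iloc[0]


def test_hamming_min_short_text():
    assert hamming_min("ACGTACGT", "ACG") == math.inf
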