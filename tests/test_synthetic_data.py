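"""Synthetic transcriptome/expression/toxicity generator."""

import json

import numpy as np
import pytest

from gapmertox import (
    SimConfig,
    classify_offtargets,
    make_fixture_bundle,
    make_transcriptome,
    parse_gapmer,
    plant_site,
    reverse_complement,
    scan_transcript,
    simulate_expression,
    simulate_toxicity,
)
from gapmertox.expression import compute_offtarget_index, index_ratio
from gapmertox.offtarget import GeneDistanceMap, exclusion_screen

from oracle_utils import naive_semi_global, random_dna


class TestSimConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"delta0": -0.1},
            {"gamma": 0.0},
            {"gamma": 1.5},
            {"sigma_expr": -1.0},
            {"tx_len": (500, 200)},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestMakeTranscriptome:
    def test_deterministic_per_seed(self, ts1):
        cfg = SimConfig(seed=3, n_genes=5, tx_len=(100, 200))
        assert make_transcriptome(cfg, [ts1]) == make_transcriptome(cfg, [ts1])

    def test_lengths_in_range(self):
        cfg = SimConfig(seed=1, n_genes=10, tx_len=(200, 500))
        transcripts, _ = make_transcriptome(cfg)
        assert all(200 <= len(s) <= 500 for s in transcripts.values())

    def test_clean_background_passes_exclusion_screen(self, ts1):
        cfg = SimConfig(seed=2, n_genes=15, tx_len=(150, 250))
        transcripts, _ = make_transcriptome(cfg, [ts1])
        result = exclusion_screen([ts1.sequence], transcripts)
        assert result["passed"].all()

    def test_planted_sites_give_requested_classes(self, ts1):
        plants = tuple(("TS1", f"gene{i + 1:04d}", d) for i, d in enumerate([0, 1, 2]))
        cfg = SimConfig(seed=5, n_genes=10, tx_len=(150, 250), planted_sites=plants)
        transcripts, tx2gene = make_transcriptome(cfg, [ts1])
        dist = classify_offtargets(ts1, transcripts, tx2gene, d_max=3)
        for i, d in enumerate([0, 1, 2]):
            assert dist.min_d[f"gene{i + 1:04d}"] == d

    def test_unknown_planted_aso_raises(self, ts1):
        cfg = SimConfig(seed=1, n_genes=3, planted_sites=(("NOPE", "gene0001", 0),))
        with pytest.raises(KeyError, match="NOPE"):
            make_transcriptome(cfg, [ts1])


class TestPlantSite:
    def test_d0_verbatim(self, ts1, rng):
        seq, (start, end) = plant_site(random_dna(rng, 100), ts1, d=0, seed=rng)
        assert seq[start:end] == reverse_complement(ts1.sequence)

    @pytest.mark.parametrize("d", [0, 1, 2, 3])
    def test_roundtrip_via_independent_oracle(self, ts1, rng, d):
        seq, _ = plant_site(random_dna(rng, 120), ts1, d=d, seed=rng)
        pattern = reverse_complement(ts1.sequence)
        assert naive_semi_global(pattern, seq) == d
        hits = scan_transcript(ts1, ("t", seq), d_max=3)
        assert min(h.d for h in hits) == d

    def test_below_threshold_not_found(self, ts1, rng):
        seq, _ = plant_site(random_dna(rng, 120), ts1, d=2, seed=rng)
        assert scan_transcript(ts1, ("t", seq), d_max=1) == []

    def test_invalid_d_rejected(self, ts1, rng):
        with pytest.raises(ValueError):
            plant_site(random_dna(rng, 100), ts1, d=5, seed=rng)


class TestSimulateExpression:
    def test_no_effect_no_noise_gives_unity(self):
        cfg = SimConfig(seed=1, delta0=0.0, sigma_expr=0.0)
        dist = GeneDistanceMap("A", {"g1": 0})
        expr = simulate_expression(cfg, dist, "A", ["g1", "g2"])
        assert np.allclose(expr.data["ratio"], 1.0)

    def test_noise_free_closed_form(self):
        cfg = SimConfig(seed=1, delta0=1.0, gamma=0.5, d_eff=2, sigma_expr=0.0)
        dist = GeneDistanceMap("A", {"g0": 0, "g1": 1, "g3": 3})
        expr = simulate_expression(cfg, dist, "A", ["g0", "g1", "g3"])
        ratios = dict(zip(expr.data["gene_id"], expr.data["ratio"]))
        assert ratios["g0"] == pytest.approx(0.5)
        assert ratios["g1"] == pytest.approx(2.0 ** -0.5)
        assert ratios["g3"] == pytest.approx(1.0)  # beyond d_eff: no knockdown

    def test_d0_class_mean_within_clt_bound(self):
        cfg = SimConfig(seed=7, delta0=1.0, gamma=0.5, sigma_expr=0.1)
        n0 = 400
        dist = GeneDistanceMap("A", {f"g{i}": 0 for i in range(n0)})
        expr = simulate_expression(cfg, dist, "A", [f"g{i}" for i in range(n0)])
        mean_log2 = np.log2(expr.data["ratio"]).mean()
        assert abs(mean_log2 - (-1.0)) < 3 * 0.1 / np.sqrt(n0)

    def test_deterministic_per_seed_and_aso(self):
        cfg = SimConfig(seed=9)
        dist = GeneDistanceMap("A", {"g1": 0})
        a = simulate_expression(cfg, dist, "A", ["g1", "g2"])
        b = simulate_expression(cfg, dist, "A", ["g1", "g2"])
        assert a.data.equals(b.data)


class TestSimulateToxicity:
    def test_noise_free_baseline(self):
        cfg = SimConfig(seed=1, alpha=np.log(50.0), beta_hyb=0.0, sigma_tox=0.0)
        recs = simulate_toxicity(cfg, {"a": 3.0, "b": 7.0})
        assert all(r.ast == pytest.approx(50.0) for r in recs)

    def test_independent_indices_uncorrelated(self):
        # hybridization-independent toxicity only: index carries no signal
        rng = np.random.default_rng(11)
        ids = [f"a{i}" for i in range(100)]
        cfg = SimConfig(
            seed=11,
            beta_hyb=0.0,
            beta_indep={i: float(v) for i, v in zip(ids, rng.normal(0, 1, 100))},
            sigma_tox=0.1,
        )
        indices = {i: float(v) for i, v in zip(ids, rng.uniform(0, 10, 100))}
        recs = simulate_toxicity(cfg, indices)
        from gapmertox import correlate

        r, _, _ = correlate(
            [indices[x.aso_id] for x in recs], [np.log(x.ast) for x in recs]
        )
        assert abs(r) < 0.15

    def test_hybridization_driven_strongly_correlated(self):
        ids = [f"a{i}" for i in range(100)]
        rng = np.random.default_rng(13)
        cfg = SimConfig(seed=13, beta_hyb=0.5, beta_indep={}, sigma_tox=0.05)
        indices = {i: float(v) for i, v in zip(ids, rng.uniform(0, 10, 100))}
        recs = simulate_toxicity(cfg, indices)
        from gapmertox import correlate

        r, _, _ = correlate(
            [indices[x.aso_id] for x in recs], [np.log(x.ast) for x in recs]
        )
        assert r > 0.8


class TestFixtureBundle:
    def test_bundle_deterministic_and_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = make_fixture_bundle("null", 4, d1)
        m2 = make_fixture_bundle("null", 4, d2)
        assert m1 == m2
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_null_scenario_no_hepatotoxic_calls(self):
        from gapmertox import classify_hepatotoxic
        m = make_fixture_bundle("null", 8)
        assert all(v <= 100 for v in m["derived"]["ast"].values())

    def test_paper_like_dissociation(self):
        # index ratio stays near 100% while toxicity collapses
        m = make_fixture_bundle("paper_like", 17)
        ratios = m["derived"]["index_ratio_pct"]
        assert ratios and all(85.0 <= v <= 115.0 for v in ratios.values())
        parent_ast = m["derived"]["ast"][m["parent"]]
        for aso, ast in m["derived"]["ast"].items():
            if aso != m["parent"]:
                assert parent_ast / ast > 10.0

    def test_planted_distances_recovered_in_bundle(self, tmp_path):
        import pandas as pd

        out = tmp_path / "bundle"
        m = make_fixture_bundle("paper_like", 6, out)
        dist = pd.read_csv(out / "distances.tsv", sep="\t")
        parent = dist[dist["aso_id"] == m["parent"]]
        observed = dict(zip(parent["gene_id"], parent["min_d"]))
        for aso_id, gene_id, d in m["planted_sites"]:
            assert observed[gene_id] == d

    def test_bundle_files_reload_cleanly(self, tmp_path):
        from gapmertox.io import (
            read_expression_tsv,
            read_fasta,
            read_gapmer_tsv,
            read_tm_tsv,
            read_tox_tsv,
            read_tx2gene,
        )

        out = tmp_path / "bundle"
        m = make_fixture_bundle("hybridization_driven", 3, out)
        transcripts = read_fasta(out / "transcriptome.fa")
        tx2gene = read_tx2gene(out / "tx2gene.tsv")
        assert set(transcripts) == set(tx2gene)
        asos = read_gapmer_tsv(out / "asos.tsv")
        assert [a.id for a in asos] == m["asos"]
        for aso_id in m["asos"]:
            table = read_expression_tsv(out / f"expression_{aso_id}.tsv", aso_id)
            assert len(table.data) == m["parameters"]["n_genes"]
        assert len(read_tox_tsv(out / "tox.tsv")) == len(m["asos"])
        read_tm_tsv(out / "tm.tsv")
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["scenario"] == "hybridization_driven"

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="scenario"):
            make_fixture_bundle("weird", 0)


class TestParameterRecovery:
    def test_delta0_recovered_within_ten_percent(self):
        # regress -log2(ratio) on gamma**d over planted classes
        cfg = SimConfig(seed=21, delta0=1.0, gamma=0.5, d_eff=2, sigma_expr=0.1)
        n_per = 200
        min_d, gene_ids = {}, []
        for d in range(4):
            for i in range(n_per):
                g = f"g{d}_{i}"
                gene_ids.append(g)
                min_d[g] = d
        gene_ids += [f"bg{i}" for i in range(1200)]  # n_genes = 2000
        dist = GeneDistanceMap("A", min_d)
        expr = simulate_expression(cfg, dist, "A", gene_ids)
        y = -np.log2(expr.data["ratio"].to_numpy())
        x = np.array(
            [
                cfg.gamma ** min_d[g] if g in min_d and min_d[g] <= cfg.d_eff else 0.0
                for g in expr.data["gene_id"]
            ]
        )
        delta0_hat = float(x @ y / (x @ x))
        assert abs(delta0_hat - cfg.delta0) / cfg.delta0 < 0.10
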