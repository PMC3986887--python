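import numpy as np
import pandas as pd
import pytest

from cpglights import profiles, synthetic_data as sd
from cpglights.correlation import spearman
from cpglights.errors import ConfigurationError, InsufficientDataError


class TestConfig:
    def test_invalid_fractions(self):
        with pytest.raises(ConfigurationError):
            sd.SimulationConfig(frac_negative=0.8, frac_positive=0.3)

    def test_invalid_depletion(self):
        with pytest.raises(ConfigurationError):
            sd.SimulationConfig(depletion_factor=0.0)

    def test_normal_exceeds_classes(self):
        with pytest.raises(ConfigurationError):
            sd.SimulationConfig(n_classes=10, n_normal=11)


class TestExpression:
    def test_counts_nonnegative_and_classes_covered(self, tiny_sim_config):
        clusters, counts, sample_map = sd.simulate_expression(tiny_sim_config)
        assert (counts.values >= 0).all()
        assert counts.values.dtype.kind == "i"
        assert sample_map["class_id"].nunique() == tiny_sim_config.n_classes
        assert len(clusters) == tiny_sim_config.n_tss

    def test_deterministic_rerun(self, tiny_sim_config):
        a = sd.simulate_expression(tiny_sim_config)
        b = sd.simulate_expression(tiny_sim_config)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_library_sizes_make_rle_nontrivial(self, tiny_sim_config):
        _, counts, _ = sd.simulate_expression(tiny_sim_config)
        _, size_factors = profiles.rle_normalize(counts)
        assert size_factors.max() / size_factors.min() > 1.2


class TestMethylation:
    def _run(self, **kw):
        config = sd.SimulationConfig(
            n_classes=12, n_normal=8, n_tss=40, n_cpg_per_promoter=5,
            samples_per_class=1, frac_missing=0.0, frac_low_coverage=0.0,
            replica_sd=0.0, seed=77, **kw,
        )
        clusters, counts, sample_map = sd.simulate_expression(config)
        normalized, _ = profiles.rle_normalize(counts)
        class_expr = profiles.average_by_class(normalized, sample_map)
        meth, truth = sd.simulate_methylation(class_expr, sample_map, config)
        return config, class_expr, meth, truth, sample_map

    def test_planted_negative_is_perfectly_anticorrelated_when_noiseless(self):
        config, class_expr, meth, truth, sample_map = self._run(noise_sd=0.0)
        percent = meth.pivot_table(index="cytosine_id", columns="sample", values="percent_meth")
        class_percent = profiles.average_by_class(percent, sample_map)
        neg = truth.cytosines[truth.cytosines["label"] == "negative"]
        assert len(neg) > 0
        for cid, row in neg.iterrows():
            expr = class_expr.iloc[row["promoter"]].to_numpy()
            prof = class_percent.loc[cid, class_expr.columns].to_numpy()
            scc, n = spearman(prof, expr)
            assert scc == pytest.approx(-1.0)
            # amplitude filter passes by construction
            assert profiles.amplitude(prof) > 50

    def test_positive_label_is_monotone_increasing(self):
        config, class_expr, meth, truth, sample_map = self._run(
            noise_sd=0.0, frac_positive=0.3, frac_negative=0.1
        )
        percent = meth.pivot_table(index="cytosine_id", columns="sample", values="percent_meth")
        class_percent = profiles.average_by_class(percent, sample_map)
        pos = truth.cytosines[truth.cytosines["label"] == "positive"]
        for cid, row in pos.iterrows():
            expr = class_expr.iloc[row["promoter"]].to_numpy()
            prof = class_percent.loc[cid, class_expr.columns].to_numpy()
            scc, _ = spearman(prof, expr)
            assert scc == pytest.approx(1.0)

    def test_rerun_is_bit_identical(self):
        _, _, a, _, _ = self._run()
        _, _, b, _, _ = self._run()
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_classes_raises(self):
        config = sd.SimulationConfig(n_tss=5, seed=1)
        expr = pd.DataFrame(np.ones((5, 2)), columns=["a", "b"])
        smap = pd.DataFrame({"class_id": ["a", "b"], "normal": True}, index=["s1", "s2"])
        with pytest.raises(InsufficientDataError):
            sd.simulate_methylation(expr, smap, config)


class TestGeometry:
    def test_occurrences_inside_promoters_and_depletion_ratio(self):
        config = sd.SimulationConfig(
            n_tss=800, n_cpg_per_promoter=20, depletion_factor=0.5, seed=3
        )
        truth = sd.simulate_truth_only(config)
        cyt = truth.cytosines
        span = config.promoter_span
        for row in truth.occurrences.itertuples(index=False):
            prom_idx = int(row.promoter[3:])
            prom_start = config.promoter_start(prom_idx)
            assert prom_start <= row.start and row.end <= prom_start + span
        inside_rate = (cyt.loc[cyt["inside"], "label"] == "negative").mean()
        outside_rate = (cyt.loc[~cyt["inside"], "label"] == "negative").mean()
        ratio = inside_rate / outside_rate
        n_in = int(cyt["inside"].sum())
        se = 3 * np.sqrt(1 / (n_in * outside_rate))
        assert abs(ratio - 0.5) < se

    def test_no_depletion_case(self):
        config = sd.SimulationConfig(
            n_tss=800, n_cpg_per_promoter=20, depletion_factor=1.0, seed=4
        )
        cyt = sd.simulate_truth_only(config).cytosines
        inside_rate = (cyt.loc[cyt["inside"], "label"] == "negative").mean()
        outside_rate = (cyt.loc[~cyt["inside"], "label"] == "negative").mean()
        n_in = int(cyt["inside"].sum())
        assert abs(inside_rate - outside_rate) < 3 * np.sqrt(outside_rate / n_in)

    def test_planted_occurrences_spell_consensus_for_degenerate_pcm(self):
        counts = np.zeros((4, 6))
        for j, base in enumerate("ACGCGT"):
            counts["ACGT".index(base), j] = 50
        pcm = sd.PositionCountMatrix("DEG", counts, 50)
        config = sd.SimulationConfig(
            n_tss=50, n_cpg_per_promoter=2,
            motif_set=[sd.MotifSpec("DEG", pcm, "activator")], seed=5,
        )
        truth = sd.simulate_truth_only(config)
        clusters, counts_tab, sample_map = sd.simulate_expression(config)
        normalized, _ = profiles.rle_normalize(counts_tab)
        class_expr = profiles.average_by_class(normalized, sample_map)
        _, truth2 = sd.simulate_methylation(class_expr, sample_map, config)
        seqs, truth3 = sd.simulate_promoters(truth2, config)
        for row in truth3.occurrences.itertuples(index=False):
            prom_idx = int(row.promoter[3:])
            offset = config.promoter_start(prom_idx)
            word = seqs[row.promoter][row.start - offset : row.end - offset]
            assert word == "ACGCGT"

    def test_cytosine_positions_carry_cpg_dyads(self, tiny_sim_config):
        out = sd.simulate_all(tiny_sim_config)
        truth = out["truth"]
        for row in truth.cytosines.itertuples(index=False):
            prom = f"tss{row.promoter:05d}"
            offset = tiny_sim_config.promoter_start(row.promoter)
            local = row.pos - offset
            assert out["sequences"][prom][local : local + 2] == "CG"


class TestAlignment:
    def test_degenerate_pcm_gives_identical_sequences(self):
        counts = np.zeros((4, 4))
        for j, base in enumerate("ACGT"):
            counts["ACGT".index(base), j] = 15
        pcm = sd.PositionCountMatrix("DEG", counts, 15)
        alignment = sd.simulate_alignment(pcm, 15, seed=0)
        assert alignment.sequences == tuple(["ACGT"] * 15)

    def test_empirical_frequencies_converge(self):
        pcm = sd.PositionCountMatrix("U", np.full((4, 4), 10.0), 40)
        alignment = sd.simulate_alignment(pcm, 40_000, seed=1)
        from cpglights.motif_models import build_pcm

        rebuilt = build_pcm(alignment)
        freqs = rebuilt.counts / rebuilt.n
        assert np.abs(freqs - 0.25).max() < 0.01

    def test_same_seed_identical(self):
        pcm = sd.PositionCountMatrix("U", np.full((4, 3), 10.0), 40)
        a = sd.simulate_alignment(pcm, 50, seed=9)
        b = sd.simulate_alignment(pcm, 50, seed=9)
        assert a.sequences == b.sequences


def test_fasta_roundtrip(tiny_sim_config, tmp_path):
    from cpglights.scanning import read_fasta

    out = sd.simulate_all(tiny_sim_config, outdir=tmp_path)
    back = read_fasta(tmp_path / "promoters.fa")
    assert back == out["sequences"]


def test_simulate_all_is_deterministic(tiny_sim_config, tmp_path):
    a = sd.simulate_all(tiny_sim_config)
    b = sd.simulate_all(tiny_sim_config)
    pd.testing.assert_frame_equal(a["methylation"], b["methylation"])
    assert a["sequences"] == b["sequences"]
    other = sd.simulate_all(sd.SimulationConfig(**{**tiny_sim_config.__dict__, "seed": 999}))
    assert not a["sequences"] == other["sequences"]
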