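import itertools

import numpy as np
import pandas as pd
import pytest

from proxiscore import (
    GroundTruth,
    SimulationConfig,
    evaluate_recovery,
    make_ground_truth,
    simulate_display_screen,
    simulate_interactome_experiment,
    simulate_phosphoproteome,
)
from proxiscore.display import build_counts_matrix
from proxiscore.scoring import raw_score
from proxiscore.simulate import make_dense_energy_matrix, make_energy_matrix


class TestConfigAndTruth:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_proteins=0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(dropout_below_lod=1.5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(replicate_sd=-1).validate()
        with pytest.raises(ValueError):
            SimulationConfig(n_interactors=10, n_proteins=5).validate()

    def test_config_file_round_trip(self, tmp_path, small_config):
        path = tmp_path / "config.tsv"
        small_config.to_file(path)
        assert SimulationConfig.from_file(path) == small_config

    def test_truth_structure(self, small_truth, small_config):
        assert len(small_truth.protein_ids) == small_config.n_proteins
        assert len(small_truth.spike_ins) == small_config.n_interactors
        # effect is zero exactly outside the spike-in set
        effects = pd.Series(small_truth.interactor_effect,
                            index=small_truth.protein_ids)
        assert (effects[~effects.index.isin(small_truth.spike_ins)] == 0).all()
        assert small_truth.energy_matrix.shape == (20, 11)
        # compartments only set for mitochondrial proteins
        ann = small_truth.annotation
        assert (ann.loc[~ann["is_mitochondrial"], "compartment"] == "unknown").all()

    def test_energy_matrix_variants(self):
        rng = np.random.default_rng(0)
        sparse = make_energy_matrix(rng)
        flank = sparse.drop(columns=[0]).to_numpy()
        assert (np.abs(flank[flank != 0]) == 2.0).all()
        assert (flank != 0).sum() == 6
        assert (sparse[0] == 0).all()
        dense = make_dense_energy_matrix(np.random.default_rng(1))
        assert (dense[0] == 0).all()
        assert (dense.drop(columns=[0]) != 0).all().all()

    def test_truth_sidecar_written(self, tmp_path, small_truth):
        path = tmp_path / "truth.tsv"
        small_truth.to_tsv(path)
        back = pd.read_csv(path, sep="\t", index_col=0)
        assert list(back.index) == small_truth.protein_ids
        assert np.allclose(back["interactor_effect"],
                           small_truth.interactor_effect)


class TestInteractomeSimulator:
    def test_seeded_determinism(self, small_truth, small_config):
        m1, d1 = simulate_interactome_experiment(small_truth, small_config, seed=5)
        m2, d2 = simulate_interactome_experiment(small_truth, small_config, seed=5)
        pd.testing.assert_frame_equal(m1.intensity, m2.intensity)
        pd.testing.assert_frame_equal(m1.msms, m2.msms)
        pd.testing.assert_frame_equal(d1, d2)

    def test_zero_effect_zero_noise_means_equal(self, small_config):
        cfg = SimulationConfig(n_proteins=50, n_interactors=1, interactor_effect=0.0,
                               replicate_sd=0.0, dropout_below_lod=0.0, seed=3)
        truth = make_ground_truth(cfg)
        truth.interactor_effect[:] = 0.0
        matrix, design = simulate_interactome_experiment(truth, cfg)
        bait = design.loc[design["bait_label"] == "WT", "sample_id"]
        ctrl = design.loc[design["bait_label"] == "TurboID", "sample_id"]
        assert np.allclose(matrix.intensity[bait].mean(axis=1),
                           matrix.intensity[ctrl].mean(axis=1))

    def test_effect_monotone_in_delta_at_fixed_seed(self, small_config):
        cfg = SimulationConfig(n_proteins=40, n_interactors=1, seed=9)
        truth = make_ground_truth(cfg)
        ratios = []
        for delta in (0.0, 1.0, 2.0, 4.0):
            truth.interactor_effect[:] = 0.0
            truth.interactor_effect[7] = delta
            matrix, design = simulate_interactome_experiment(truth, cfg, seed=11)
            bait = design.loc[design["bait_label"] == "WT", "sample_id"]
            ctrl = design.loc[design["bait_label"] == "TurboID", "sample_id"]
            row = matrix.intensity.iloc[7]
            ratios.append(row[bait].mean() / row[ctrl].mean())
        assert all(b >= a for a, b in itertools.pairwise(ratios))

    def test_size_mismatch_rejected(self, small_truth):
        cfg = SimulationConfig(n_proteins=17)
        with pytest.raises(ValueError, match="proteins"):
            simulate_interactome_experiment(small_truth, cfg)

    def test_msms_scale_with_intensity(self, small_truth, small_config):
        matrix, _ = simulate_interactome_experiment(small_truth, small_config)
        intensity = matrix.intensity.to_numpy().ravel()
        msms = matrix.msms.to_numpy().ravel()
        bright = intensity > np.percentile(intensity, 80)
        dim = (intensity > 0) & (intensity < np.percentile(intensity, 20))
        assert msms[bright].mean() > msms[dim].mean()


class TestDisplaySimulator:
    def test_seeded_determinism(self, small_truth, small_config):
        a = simulate_display_screen(small_truth, small_config, seed=4)
        b = simulate_display_screen(small_truth, small_config, seed=4)
        assert a[0].peptides == b[0].peptides
        assert a[1].peptides == b[1].peptides

    def test_peptide_invariants(self, small_truth, small_config):
        inp, sel = simulate_display_screen(small_truth, small_config)
        for pool in (inp, sel):
            assert all(len(p) == 11 and p[5] == "Y" for p in pool.peptides)
        assert len(inp) == small_config.n_reads_input
        assert len(sel) == small_config.n_reads_selected

    def test_beta_zero_matches_input_frequencies(self, small_truth):
        cfg = SimulationConfig(n_proteins=200, n_interactors=10,
                               n_reads_input=20_000, n_reads_selected=20_000,
                               selection_sharpness=0.0, seed=6)
        inp, sel = simulate_display_screen(small_truth, cfg)
        f_in = build_counts_matrix(inp).counts / len(inp)
        f_sel = build_counts_matrix(sel).counts / len(sel)
        # binomial sampling error: se ~ sqrt(p q / n) ~ 0.0015 at p = 0.05
        flank = [p for p in f_in.columns if p != 0]
        diff = (f_sel[flank] - f_in[flank]).to_numpy()
        assert np.abs(diff).max() < 6 * np.sqrt(0.05 * 0.95 / len(sel))

    def test_selection_prefers_high_energy_peptides(self, small_truth, small_config):
        inp, sel = simulate_display_screen(small_truth, small_config)
        energy = small_truth.energy_matrix

        def mean_score(pool):
            return np.mean([raw_score(p, energy)[0] for p in pool.peptides[:2000]])

        assert mean_score(sel) > mean_score(inp)


class TestPhosphoproteomeSimulator:
    def test_window_invariants(self, small_truth):
        sites = simulate_phosphoproteome(small_truth, 200, seed=2)
        assert len(sites) == 200
        assert sites["window"].str.len().eq(11).all()
        assert sites["window"].str[5].eq("Y").all()

    def test_planted_windows_outscore_random_under_truth(self, small_truth):
        sites = simulate_phosphoproteome(small_truth, 300, seed=3)
        scores = np.array(
            [raw_score(w, small_truth.energy_matrix)[0] for w in sites["window"]]
        )
        top_tier = sites["tier"] > 0.8
        random_tier = ~sites["planted"]
        assert scores[top_tier].mean() > scores[random_tier].mean()

    def test_tier_one_is_argmax_window(self, small_truth):
        from proxiscore.scoring import argmax_window

        sites = simulate_phosphoproteome(small_truth, 100, seed=4)
        full = sites.loc[np.isclose(sites["tier"], 1.0), "window"]
        assert (full == argmax_window(small_truth.energy_matrix)).all()


class TestRecoveryMetrics:
    def test_perfect_calls(self, small_truth):
        report = evaluate_recovery(small_truth.spike_ins, small_truth)
        assert report.sensitivity == 1.0
        assert report.fdr == 0.0

    def test_empty_calls(self, small_truth):
        report = evaluate_recovery(set(), small_truth)
        assert report.sensitivity == 0.0
        assert report.fdr == 0.0

    def test_matches_exhaustive_oracle_on_tiny_universe(self):
        cfg = SimulationConfig(n_proteins=10, n_interactors=3, seed=1)
        truth = make_ground_truth(cfg)
        spikes = truth.spike_ins
        ids = truth.protein_ids
        for r in range(len(ids) + 1):
            for calls in itertools.combinations(ids, r):
                calls = set(calls)
                tp = len(calls & spikes)
                fp = len(calls - spikes)
                report = evaluate_recovery(calls, truth)
                assert report.sensitivity == pytest.approx(tp / 3)
                assert report.fdr == pytest.approx(fp / max(1, fp + tp))
            if r > 3:  # 2^10 subsets in full; cap the enumeration depth
                break

    def test_matrix_correlation_perfect_for_truth_itself(self, small_truth):
        report = evaluate_recovery(set(), small_truth,
                                   recovered_matrix=small_truth.energy_matrix)
        assert report.matrix_r == pytest.approx(1.0)
        assert "Pearson" in report.summary()
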