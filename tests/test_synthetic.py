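import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regulonml import synthetic as syn
from regulonml.motifs import build_pssm, scan
from regulonml.panregulon import build_pan_regulon, map_tu


class TestGeneratePwm:
    def test_maximal_information_forces_point_mass_columns(self):
        pwm = syn.generate_pwm(6, 12.0, seed=0)
        assert np.allclose(pwm.max(axis=1), 1.0)

    def test_zero_information_is_uniform(self):
        pwm = syn.generate_pwm(6, 0.0, seed=0)
        assert np.allclose(pwm, 0.25)

    def test_entropy_recomputation_within_5_percent(self):
        pwm = syn.generate_pwm(8, 10.0, seed=1)
        # independent recomputation: info = sum(2 - H(column))
        with np.errstate(divide="ignore"):
            plogp = np.where(pwm > 0, pwm * np.log2(pwm), 0.0)
        info = (2.0 + plogp.sum(axis=1)).sum()
        assert abs(info - 10.0) <= 0.05 * 10.0
        assert np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9)

    def test_infeasible_information_names_bound(self):
        with pytest.raises(ValueError, match=r"\[0, 12.0\]"):
            syn.generate_pwm(6, 13.0, seed=0)

    def test_deterministic_in_seed(self):
        assert np.array_equal(syn.generate_pwm(8, 9.0, 5), syn.generate_pwm(8, 9.0, 5))


class TestRegulonDataset:
    def test_max_information_plants_consensus_verbatim(self):
        cfg = syn.SyntheticConfig(seed=1, n_promoters=50, n_positives=10,
                                  motif_length=8, motif_information=16.0,
                                  label_noise=0.0)
        promoters, labels, truth = syn.generate_regulon_dataset(cfg)
        consensus = "".join("ACGT"[i] for i in truth.planted_pwm.argmax(axis=1))
        for p in promoters:
            if truth.true_labels[p.tu_id] == 1:
                assert consensus in p.sequence

    def test_no_positives_means_no_planting(self):
        cfg = syn.SyntheticConfig(seed=2, n_promoters=30, n_positives=0)
        _, labels, truth = syn.generate_regulon_dataset(cfg)
        assert labels.sum() == 0 and not truth.planted_positions

    def test_planted_positions_inside_window(self, demo_dataset):
        cfg, promoters, _, truth = demo_dataset
        a, b = cfg.planting_window
        for off in truth.planted_positions.values():
            assert a <= off and off + cfg.motif_length <= b

    def test_planted_sites_outscore_negatives(self, demo_dataset):
        cfg, promoters, _, truth = demo_dataset
        pssm = build_pssm(probabilities=truth.planted_pwm, name="planted")
        pos = [scan(pssm, p).score for p in promoters if truth.true_labels[p.tu_id]]
        neg = [scan(pssm, p).score for p in promoters if not truth.true_labels[p.tu_id]]
        assert np.mean(pos) > np.mean(neg)

    def test_label_noise_flips_expected_count(self):
        cfg = syn.SyntheticConfig(seed=3, n_promoters=100, n_positives=20,
                                  label_noise=0.1)
        _, labels, truth = syn.generate_regulon_dataset(cfg)
        assert (labels != truth.true_labels).sum() == 10

    def test_same_seed_byte_identical(self):
        cfg = syn.SyntheticConfig(seed=11, n_promoters=40, n_positives=5)
        a = syn.generate_regulon_dataset(cfg)
        b = syn.generate_regulon_dataset(cfg)
        assert [p.sequence for p in a[0]] == [p.sequence for p in b[0]]
        assert a[1].equals(b[1])

    def test_group_structure_emitted(self):
        cfg = syn.SyntheticConfig(seed=4, n_promoters=200, n_positives=10)
        promoters, _, _ = syn.generate_regulon_dataset(cfg)
        assert any(len(p.gene_ids) > 1 for p in promoters)
        ids = [g for p in promoters for g in p.gene_ids]
        assert len(ids) == len(set(ids))

    def test_oversized_planting_window_rejected(self):
        with pytest.raises(ValueError, match="planting_window"):
            syn.SyntheticConfig(seed=0, planting_window=(-300, 50))


class TestStrainFamily:
    def test_two_strains_have_no_accessory(self):
        fam = syn.generate_strain_family(syn.SyntheticConfig(seed=5, n_strains=2))
        assert fam.truth.strain_partition["accessory"] == frozenset()

    def test_same_seed_identical_genomes(self):
        cfg = syn.SyntheticConfig(seed=6)
        a = syn.generate_strain_family(cfg)
        b = syn.generate_strain_family(cfg)
        assert {k: g.sequence for k, g in a.genomes.items()} == \
            {k: g.sequence for k, g in b.genomes.items()}

    def test_each_tu_embedded_exactly_once_where_designed(self):
        fam = syn.generate_strain_family(syn.SyntheticConfig(seed=7))
        for tu, seq in fam.tu_sequences.items():
            for strain, genome in fam.genomes.items():
                m = map_tu(seq, genome, tu_id=tu)
                if strain in fam.tu_strains[tu]:
                    assert m.status == "unique-match"
                else:
                    assert m.status == "absent"

    def test_partition_sets_pairwise_disjoint(self):
        fam = syn.generate_strain_family(syn.SyntheticConfig(seed=8))
        p = fam.truth.strain_partition
        assert not (p["core"] & p["accessory"])
        assert not (p["core"] & p["unique"])
        assert not (p["accessory"] & p["unique"])

    def test_round_trip_recovers_designed_partition(self):
        fam = syn.generate_strain_family(syn.SyntheticConfig(seed=9, n_strains=3))
        regulated = {
            s: {tu for tu in fam.tu_sequences if s in fam.tu_strains[tu]}
            for s in fam.genomes
        }
        pan = build_pan_regulon(regulated)
        assert pan.core == fam.truth.strain_partition["core"]
        assert pan.accessory == fam.truth.strain_partition["accessory"]
        assert pan.unique == fam.truth.strain_partition["unique"]


class TestExpressionResponse:
    def test_noiseless_response_perfectly_monotone(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50)
        resp = syn.generate_expression_response(scores, slope=1.0, noise_sd=0.0, seed=1)
        rho, _ = stats.spearmanr(scores, resp)
        assert rho == pytest.approx(1.0)

    def test_null_slope_uncorrelated(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=500)
        resp = syn.generate_expression_response(scores, slope=0.0, noise_sd=1.0, seed=2)
        rho, _ = stats.spearmanr(scores, resp)
        assert abs(rho) <= 0.15

    def test_reference_conditions_reach_rho_0_7(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=500)
        resp = syn.generate_expression_response(scores, slope=1.0, noise_sd=0.5, seed=3)
        rho, _ = stats.spearmanr(scores, resp)
        assert rho >= 0.7

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            syn.generate_expression_response([], 1.0, 0.5, seed=0)


class TestPentamerTable:
    def test_all_13_parameters_finite(self):
        t = syn.generate_pentamer_table(seed=1)
        assert len(t.table) == 1024
        assert t.table.shape[1] == 13
        assert np.isfinite(t.table.to_numpy()).all()

    def test_deterministic(self):
        a = syn.generate_pentamer_table(seed=2).table
        b = syn.generate_pentamer_table(seed=2).table
        pd.testing.assert_frame_equal(a, b)


class TestDatasetExport:
    def test_writes_all_artifacts(self, tmp_path):
        cfg = syn.SyntheticConfig(seed=12, n_promoters=30, n_positives=5)
        promoters, labels, truth = syn.generate_regulon_dataset(cfg)
        syn.write_regulon_dataset(promoters, labels, truth, tmp_path)
        for name in ("promoters.fasta", "tss.gff3", "planted_motif.meme",
                     "regulons.tsv", "labels.tsv", "truth_positions.tsv"):
            assert (tmp_path / name).exists()
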