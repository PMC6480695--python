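"""Synthetic cohort generator: determinism, calibration and round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, pearsonr

from icb_bench.errors import ConfigurationError
from icb_bench.labels import assign_labels
from icb_bench.panel import assemble_scores
from icb_bench.performance import evaluate_marker
from icb_bench.simulate import default_config, generate_cohorts, write_cohort
from icb_bench.io import read_cohort


def single_cohort_config(seed, n, effects, rna=True, dna=False, **overrides):
    return default_config(
        seed=seed,
        n_cohorts=1,
        cohort_ids=["sim"],
        n_patients=[n],
        rna_available=[rna],
        dna_available=[dna],
        responder_fraction=[0.5],
        marker_effects=effects,
        marker_correlations=overrides.pop("marker_correlations", []),
        **overrides,
    )


class TestConfigValidation:
    def test_length_mismatch(self):
        with pytest.raises(ConfigurationError, match="n_patients"):
            default_config(n_patients=[10, 10])

    def test_unknown_marker_effect(self):
        with pytest.raises(ConfigurationError, match="NotAMarker"):
            default_config(marker_effects={"NotAMarker": 1.0})

    def test_rna_effect_in_dna_only_cohort_names_both(self):
        with pytest.raises(ConfigurationError, match="study3.*CD274"):
            default_config(cohort_marker_effects={"study3": {"CD274": 1.0}})

    def test_responder_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            default_config(responder_fraction=[0.5, 0.5, 0.5, 0.5, 1.2])


class TestDefaultShape:
    def test_table_shape(self, default_bundles):
        assert [b.cohort_id for b in default_bundles] == [f"study{i}" for i in range(1, 6)]
        assert [len(b.patient_ids) for b in default_bundles] == [28, 49, 33, 63, 41]
        assert [b.rna_available for b in default_bundles] == [True, True, False, False, True]
        assert all(b.dna_available for b in default_bundles)

    def test_expression_non_negative_and_patients_consistent(self, default_bundles):
        for b in default_bundles:
            if b.expression is not None:
                assert (b.expression.to_numpy() >= 0).all()
                assert list(b.expression.columns) == b.patient_ids
            if b.mutations is not None and len(b.mutations):
                assert set(b.mutations["patient_id"]) <= set(b.patient_ids)

    def test_response_vocabulary(self, default_bundles):
        for b in default_bundles:
            assert set(b.clinical["response_category"]) <= {"CR", "PR", "SD", "PD", "LB", "NB"}

    def test_labels_recover_latent_status(self, default_bundles):
        """The clinical draw is consistent with the survival-rescue rule."""
        cfg = default_config(seed=7)
        for b, frac in zip(default_bundles, cfg.responder_fraction):
            labels = assign_labels(b.clinical)
            observed = (labels["label"] == "responder").mean()
            # binomial noise at n in [28, 63]
            assert abs(observed - frac) < 0.2


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        for run in ("a", "b"):
            bundles = generate_cohorts(default_config(seed=123))
            for b in bundles[:2]:
                write_cohort(b, tmp_path / run)
        for path_a in sorted((tmp_path / "a").iterdir()):
            path_b = tmp_path / "b" / path_a.name
            assert path_a.read_bytes() == path_b.read_bytes()

    def test_different_seeds_differ(self):
        a = generate_cohorts(default_config(seed=1))[0]
        b = generate_cohorts(default_config(seed=2))[0]
        assert not a.clinical.equals(b.clinical)


class TestCalibration:
    def test_responder_fraction_recovered(self):
        cfg = single_cohort_config(seed=5, n=400, effects={})
        cfg.responder_fraction = [0.6]
        bundle = generate_cohorts(cfg)[0]
        labels = assign_labels(bundle.clinical)
        assert (labels["label"] == "responder").mean() == pytest.approx(0.6, abs=0.05)

    def test_configured_correlation_recovered(self):
        cfg = single_cohort_config(
            seed=6, n=300, effects=dict(default_config().marker_effects),
            marker_correlations=[("PDCD1", "IFN-y (reduced set)", 0.6)],
        )
        bundle = generate_cohorts(cfg)[0]
        latent = bundle.latent_scores
        r_latent = pearsonr(latent["PDCD1"], latent["IFN-y (reduced set)"]).statistic
        assert r_latent == pytest.approx(0.6, abs=0.1)

    def test_null_cohorts_have_chance_level_aucs(self):
        """No-signal configuration: downstream AUCs hug 0.5 across markers."""
        outside = 0
        total = 0
        for seed in range(6):
            cfg = single_cohort_config(
                seed=100 + seed, n=500, effects={}, effect_heterogeneity=0.0
            )
            bundle = generate_cohorts(cfg)[0]
            table = assemble_scores(bundle)
            labels = assign_labels(bundle.clinical).set_index("patient_id")["label"]
            for marker in table.scores.columns:
                if table.scores[marker].isna().all():
                    continue
                ev = evaluate_marker(table.scores[marker], labels, marker, "sim")
                total += 1
                if not 0.4 <= ev.auc <= 0.6:
                    outside += 1
        assert total >= 90
        assert outside / total <= 0.10

    def test_strong_single_gene_marker_hits_binormal_auc(self):
        cfg = single_cohort_config(
            seed=9, n=500, effects={"CD274": 2.0}, effect_heterogeneity=0.0
        )
        bundle = generate_cohorts(cfg)[0]
        table = assemble_scores(bundle)
        labels = assign_labels(bundle.clinical).set_index("patient_id")["label"]
        ev = evaluate_marker(table.scores["CD274"], labels, "CD274", "sim")
        assert ev.auc == pytest.approx(norm.cdf(2.0 / np.sqrt(2.0)), abs=0.03)

    def test_signature_scoring_recovers_latent_score(self):
        """Gene back-fill: the mean-of-logs score tracks the latent signature."""
        cfg = single_cohort_config(seed=10, n=250, effects={})
        bundle = generate_cohorts(cfg)[0]
        table = assemble_scores(bundle)
        latent = bundle.latent_scores
        r = pearsonr(
            table.scores["ICB resist. signature 1"], latent["ICB resist. signature 1"]
        ).statistic
        assert r > 0.9

    def test_mutational_load_effect_survives_count_transform(self):
        cfg = single_cohort_config(
            seed=11, n=500, effects={"Mutational load": 0.8},
            rna=False, dna=True, effect_heterogeneity=0.0,
        )
        bundle = generate_cohorts(cfg)[0]
        table = assemble_scores(bundle)
        labels = assign_labels(bundle.clinical).set_index("patient_id")["label"]
        ev = evaluate_marker(table.scores["Mutational load"], labels, "TMB", "sim")
        assert ev.auc == pytest.approx(norm.cdf(0.8 / np.sqrt(2.0)), abs=0.05)


class TestWriteReadRoundTrip:
    def test_generated_cohort_round_trips(self, tmp_path, default_bundles):
        for bundle in default_bundles[:2]:
            write_cohort(bundle, tmp_path)
            back = read_cohort(tmp_path, bundle.cohort_id)
            pd.testing.assert_frame_equal(back.clinical, bundle.clinical)
            pd.testing.assert_frame_equal(back.expression, bundle.expression)
            pd.testing.assert_frame_equal(back.plugin_scores, bundle.plugin_scores)
            pd.testing.assert_frame_equal(
                back.mutations.reset_index(drop=True), bundle.mutations.reset_index(drop=True)
            )

    def test_dna_only_cohort_writes_no_expression(self, tmp_path, default_bundles):
        dna_only = next(b for b in default_bundles if not b.rna_available)
        paths = write_cohort(dna_only, tmp_path)
        names = {p.name for p in paths}
        assert f"{dna_only.cohort_id}_expression.tsv" not in names
        back = read_cohort(tmp_path, dna_only.cohort_id)
        assert back.expression is None
        assert not back.rna_available

    def test_empty_cohort_valid_headers(self, tmp_path):
        cfg = single_cohort_config(seed=12, n=0, effects={}, rna=True, dna=True)
        bundle = generate_cohorts(cfg)[0]
        write_cohort(bundle, tmp_path)
        back = read_cohort(tmp_path, "sim")
        assert len(back.clinical) == 0
        assert back.mutations is not None and len(back.mutations) == 0
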