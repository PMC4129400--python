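"""Normalization and filtering rules for raw array features."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pqtlkit import array_quant as aq
from pqtlkit.datatypes import ProteinMatrix, SimulationConfig
from pqtlkit.synthetic import (
    simulate_array_features,
    simulate_genotypes,
    simulate_true_traits,
)


def _features(rows):
    base = dict(
        array_id="a1", print_id="p1", batch_id="b1", platform="RPPA",
        sample_id="s1", individual_id="i1", bio_rep="bio1", tech_rep="tech1",
        antibody_id="ab", band_mw_kda=50.0, noise_sd=1.0,
    )
    out = []
    for i, r in enumerate(rows):
        rec = {**base, "feature_id": f"f{i}", **r}
        out.append(rec)
    return pd.DataFrame(out)


class TestBackgroundCorrect:
    @pytest.mark.parametrize(
        "raw,bg,expected,excluded",
        [
            (100.0, 20.0, 80.0, False),
            (10.0, 20.0, -10.0, True),  # negative corrected intensity dropped
            (100.0, 0.0, 100.0, False),
        ],
    )
    def test_subtraction_and_exclusion(self, raw, bg, expected, excluded):
        f = _features([{"raw_intensity": raw, "background": bg}])
        out = aq.background_correct(f)
        assert out.loc[0, "corrected_intensity"] == expected
        assert bool(out.loc[0, "excluded"]) is excluded

    def test_missing_background_column_rejected(self):
        f = _features([{"raw_intensity": 1.0, "background": 1.0}]).drop(
            columns="background"
        )
        with pytest.raises(ValueError):
            aq.background_correct(f)


class TestSnrFilter:
    @pytest.mark.parametrize(
        "corrected,noise,threshold,excluded",
        [
            (90.0, 30.0, 3.0, False),  # SNR exactly 3: boundary retained
            (30.0, 30.0, 3.0, True),
            (1.0, 30.0, 0.0, False),  # degenerate threshold excludes nothing
        ],
    )
    def test_threshold(self, corrected, noise, threshold, excluded):
        f = aq.background_correct(
            _features([{"raw_intensity": corrected, "background": 0.0,
                        "noise_sd": noise}])
        )
        out = aq.snr_filter(f, threshold=threshold)
        assert bool(out.loc[0, "excluded"]) is excluded

    def test_nonpositive_noise_rejected(self):
        f = aq.background_correct(
            _features([{"raw_intensity": 10.0, "background": 0.0, "noise_sd": 0.0}])
        )
        with pytest.raises(ValueError):
            aq.snr_filter(f)


class TestClassifyAntibody:
    def test_single_predominant_on_size_band_is_rppa(self):
        p = aq.BandProfile("ab", [(50.0, 100.0, 10.0)], predicted_mw=50.0)
        assert aq.classify_antibody(p) == "RPPA"

    def test_on_size_band_with_extras_is_mwa(self):
        p = aq.BandProfile(
            "ab", [(50.0, 60.0, 5.0), (90.0, 40.0, 4.0)], predicted_mw=50.0
        )
        assert aq.classify_antibody(p) == "MWA"

    def test_only_off_size_bands_fails(self):
        p = aq.BandProfile("ab", [(120.0, 100.0, 8.0)], predicted_mw=50.0)
        assert aq.classify_antibody(p) == "FAIL"

    def test_low_snr_on_size_band_fails(self):
        p = aq.BandProfile("ab", [(50.0, 100.0, 2.0)], predicted_mw=50.0)
        assert aq.classify_antibody(p) == "FAIL"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            aq.BandProfile("ab", [], predicted_mw=50.0)
        p = aq.BandProfile("ab", [(50.0, 1.0, 5.0)], predicted_mw=-1.0)
        with pytest.raises(ValueError):
            aq.classify_antibody(p)


class TestQuantileNormalize:
    def test_hand_oracle_two_arrays(self):
        # sort-average-reassign by hand: sorted means are [1.5, 3.5, 8.5]
        out = aq.quantile_normalize(
            {"a": np.array([2.0, 4.0, 8.0]), "b": np.array([1.0, 3.0, 9.0])},
            log2=False,
        )
        np.testing.assert_allclose(out["a"], [1.5, 3.5, 8.5])
        np.testing.assert_allclose(out["b"], [1.5, 3.5, 8.5])

    def test_identical_arrays_fixed_point(self):
        v = np.array([3.0, 1.0, 2.0])
        out = aq.quantile_normalize({"a": v, "b": v.copy()}, log2=False)
        np.testing.assert_allclose(out["a"], v)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=50)
        perm = rng.permutation(50)
        out = aq.quantile_normalize({"a": v, "b": v[perm]}, log2=False)
        np.testing.assert_allclose(out["b"], out["a"][perm])

    def test_sorted_distributions_identical_after(self):
        rng = np.random.default_rng(1)
        arrays = {f"a{i}": np.abs(rng.normal(5, 2, size=200)) + 0.1 for i in range(5)}
        out = aq.quantile_normalize(arrays)
        ref = np.sort(out["a0"])
        for v in out.values():
            np.testing.assert_allclose(np.sort(v), ref, atol=1e-9)

    def test_ties_receive_average_of_order_statistics(self):
        out = aq.quantile_normalize(
            {"a": np.array([1.0, 1.0, 5.0]), "b": np.array([2.0, 4.0, 6.0])},
            log2=False,
        )
        # means of order stats: [1.5, 2.5, 5.5]; the tie at rank 1-2 averages
        np.testing.assert_allclose(out["a"], [2.0, 2.0, 5.5])

    def test_nonpositive_rejected_before_log(self):
        with pytest.raises(ValueError):
            aq.quantile_normalize({"a": np.array([1.0, -2.0]), "b": np.array([1.0, 2.0])})

    def test_needs_two_arrays(self):
        with pytest.raises(ValueError):
            aq.quantile_normalize({"a": np.array([1.0])})


class TestLoadNormalize:
    def test_median_subtraction(self):
        f = _features(
            [
                {"raw_intensity": 0, "background": 0, "array_id": a, "norm_log2": v}
                for a, v in zip("abc", [1.0, 2.0, 3.0])
            ]
        )
        out = aq.load_normalize(f)
        np.testing.assert_allclose(sorted(out["residual"]), [-1.0, 0.0, 1.0])

    def test_constant_samples_zero_residual(self):
        f = _features(
            [
                {"raw_intensity": 0, "background": 0, "sample_id": s,
                 "array_id": a, "norm_log2": 2.5}
                for s in ("s1", "s2") for a in ("a1", "a2")
            ]
        )
        out = aq.load_normalize(f)
        assert (out["residual"] == 0).all()

    def test_per_sample_median_zero_invariant(self):
        rng = np.random.default_rng(2)
        rows = []
        for s in range(6):
            for a in range(5):
                rows.append(
                    {"raw_intensity": 0, "background": 0, "sample_id": f"s{s}",
                     "array_id": f"a{a}", "norm_log2": rng.normal()}
                )
        out = aq.load_normalize(_features(rows))
        med = out.groupby("sample_id")["residual"].median()
        np.testing.assert_allclose(med, 0.0, atol=1e-9)

    def test_recovers_planted_load_offsets(self):
        cfg = SimulationConfig(
            n_individuals=40, n_variants=20, n_traits=24, seed=21,
            load_effect_sd=1.0, batch_effect_sd=0.0, noise_sd=0.0, bio_rep_sd=0.0,
            mwa_fraction=0.0, dual_platform_fraction=0.0, arrays_per_print=24,
        )
        gm, _ = simulate_genotypes(cfg)
        prot, _ = simulate_true_traits(gm, [], cfg)
        features, truth = simulate_array_features(prot, cfg)
        f = aq.background_correct(features)
        f["norm_log2"] = np.log2(f["corrected_intensity"] / cfg.gain)
        out = aq.load_normalize(f)
        est = out.groupby(["print_id", "individual_id", "bio_rep"])[
            "load_effect"
        ].first()
        planted = truth.load_effects.set_index(
            ["print_id", "individual_id", "bio_rep"]
        )["lam"]
        # lambda-hat = lambda + median of the sample's latent levels across
        # the print's antibodies; with 24 antibodies that error is modest
        resid = (est - planted.loc[est.index]).to_numpy()
        assert np.corrcoef(est, planted.loc[est.index])[0, 1] > 0.9
        assert np.std(resid) < 0.5

    def test_empty_print_rejected(self):
        with pytest.raises((ValueError, KeyError)):
            aq.load_normalize(_features([]))


class TestBatchCorrect:
    def test_offset_batches_equalized(self):
        rows = []
        for b, off in (("g1", 0.0), ("g2", 2.0)):
            for i in range(5):
                rows.append(
                    {"raw_intensity": 0, "background": 0, "platform": "MWA",
                     "batch_id": b, "sample_id": f"s{i}", "residual": i * 0.1 + off}
                )
        out = aq.batch_correct(_features(rows))
        med = out.groupby("batch_id")["residual"].median()
        np.testing.assert_allclose(med["g1"], med["g2"], atol=1e-12)

    def test_single_batch_centered(self):
        rows = [
            {"raw_intensity": 0, "background": 0, "platform": "MWA",
             "batch_id": "g1", "residual": v}
            for v in (1.0, 2.0, 5.0)
        ]
        out = aq.batch_correct(_features(rows))
        np.testing.assert_allclose(sorted(out["residual"]), [-1.0, 0.0, 3.0])

    def test_rppa_rows_untouched(self):
        rows = [
            {"raw_intensity": 0, "background": 0, "platform": "RPPA",
             "residual": v}
            for v in (1.0, 2.0)
        ]
        out = aq.batch_correct(_features(rows))
        assert list(out["residual"]) == [1.0, 2.0]

    def test_planted_batch_variance_removed(self):
        cfg = SimulationConfig(
            n_individuals=40, n_variants=20, n_traits=12, seed=22,
            load_effect_sd=0.0, batch_effect_sd=0.5, noise_sd=0.0, bio_rep_sd=0.0,
            mwa_fraction=1.0, dual_platform_fraction=0.0,
        )
        gm, _ = simulate_genotypes(cfg)
        prot, _ = simulate_true_traits(gm, [], cfg)
        features, _ = simulate_array_features(prot, cfg)
        f = aq.background_correct(features)
        f["residual"] = np.log2(f["corrected_intensity"] / cfg.gain)

        def between(frame):
            g = frame.groupby(["antibody_id", "batch_id"])["residual"].mean()
            return g.groupby("antibody_id").var().mean()

        b0 = between(f)
        out = aq.batch_correct(f)
        b1 = between(out)
        # planted per-(antibody, gel) shifts carry the between-batch
        # variance component; median removal collapses it
        assert b1 < 0.1 * b0
        med = out.groupby(["antibody_id", "batch_id"])["residual"].median()
        np.testing.assert_allclose(med, 0.0, atol=1e-9)


class TestAggregateReplicates:
    def _resid_features(self, rows):
        f = _features(rows)
        f["excluded"] = f.get("excluded", False)
        f["snr"] = f.get("snr", 10.0)
        return f

    def test_technical_mean(self):
        rows = [
            {"raw_intensity": 0, "background": 0, "tech_rep": f"t{i}",
             "corrected_intensity": 100.0, "residual": v}
            for i, v in enumerate([1.0, 1.2, 1.4])
        ]
        pm = aq.aggregate_replicates(self._resid_features(rows))
        assert pm.replicate_values.iloc[0, 0] == pytest.approx(1.2)

    def test_missing_tech_replicate_uses_remaining(self):
        rows = [
            {"raw_intensity": 0, "background": 0, "tech_rep": f"t{i}",
             "corrected_intensity": 100.0, "residual": v}
            for i, v in enumerate([1.0, 1.4])
        ]
        pm = aq.aggregate_replicates(self._resid_features(rows))
        assert pm.replicate_values.iloc[0, 0] == pytest.approx(1.2)

    def test_platform_with_higher_median_intensity_wins(self):
        rows = []
        for plat, inten, val in (("RPPA", 500.0, 1.0), ("MWA", 800.0, 2.0)):
            for i in range(3):
                rows.append(
                    {"raw_intensity": 0, "background": 0, "platform": plat,
                     "tech_rep": f"t{i}", "corrected_intensity": inten,
                     "residual": val}
                )
        pm = aq.aggregate_replicates(self._resid_features(rows))
        assert pm.trait_info.loc["ab", "platform"] == "MWA"
        assert pm.replicate_values.iloc[0, 0] == pytest.approx(2.0)


class TestQcFilter:
    def _matrix(self, info):
        n = len(info)
        rep = pd.DataFrame(
            np.zeros((2, n)),
            index=pd.MultiIndex.from_product(
                [["i1"], ["bio1", "bio2"]], names=["individual_id", "bio_rep"]
            ),
            columns=info.index,
        )
        return ProteinMatrix(rep, info)

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(3)
        info = pd.DataFrame(
            {
                "platform": "RPPA",
                "median_intensity": rng.uniform(100, 1000, 100),
                "median_snr": rng.uniform(1, 50, 100),
                "tech_cv": rng.uniform(0.01, 0.5, 100),
            },
            index=pd.Index([f"ab{i:04d}" for i in range(100)], name="trait_id"),
        )
        pm = aq.qc_filter(self._matrix(info), mode="quartile")
        lo_i = np.quantile(info["median_intensity"], 0.25)
        lo_s = np.quantile(info["median_snr"], 0.25)
        hi_c = np.quantile(info["tech_cv"], 0.75)
        expected = {
            t
            for t in info.index
            if info.loc[t, "median_intensity"] >= lo_i
            and info.loc[t, "median_snr"] >= lo_s
            and info.loc[t, "tech_cv"] <= hi_c
        }
        assert set(pm.traits) == expected
        assert len(pm.traits) <= 100

    def test_all_tied_metrics_drop_nothing(self):
        info = pd.DataFrame(
            {"platform": "RPPA", "median_intensity": 500.0, "median_snr": 10.0,
             "tech_cv": 0.1},
            index=pd.Index([f"ab{i}" for i in range(6)], name="trait_id"),
        )
        pm = aq.qc_filter(self._matrix(info), mode="quartile")
        assert len(pm.traits) == 6

    def test_spiked_high_cv_traits_dropped(self):
        rng = np.random.default_rng(4)
        cv = rng.uniform(0.01, 0.1, 40)
        cv[:5] = rng.uniform(0.5, 1.0, 5)  # 10x CV spike-ins
        info = pd.DataFrame(
            {
                "platform": "RPPA",
                "median_intensity": rng.uniform(400, 600, 40),
                "median_snr": rng.uniform(10, 20, 40),
                "tech_cv": cv,
            },
            index=pd.Index([f"ab{i:04d}" for i in range(40)], name="trait_id"),
        )
        pm = aq.qc_filter(self._matrix(info), mode="quartile")
        dropped = set(info.index) - set(pm.traits)
        assert {f"ab{i:04d}" for i in range(5)} <= dropped

    def test_too_few_traits_rejected(self):
        info = pd.DataFrame(
            {"platform": "RPPA", "median_intensity": [1.0], "median_snr": [1.0],
             "tech_cv": [0.1]},
            index=pd.Index(["ab0"], name="trait_id"),
        )
        with pytest.raises(ValueError):
            aq.qc_filter(self._matrix(info))


class TestAntibodyPairConcordance:
    def _pm(self, cols: dict) -> ProteinMatrix:
        rep = pd.DataFrame(
            cols,
            index=pd.MultiIndex.from_product(
                [[f"i{k}" for k in range(len(next(iter(cols.values()))))], ["bio1"]],
                names=["individual_id", "bio_rep"],
            ),
        )
        info = pd.DataFrame(index=rep.columns)
        return ProteinMatrix(rep, info)

    def test_identity_and_reversal(self):
        v = np.arange(10.0)
        pm = self._pm({"a": v, "b": v, "c": v[::-1]})
        out = aq.antibody_pair_concordance(pm, [("a", "b"), ("a", "c")])
        assert out["rho"].tolist() == pytest.approx([1.0, -1.0])
        assert out.attrs["n_positive"] == 1

    def test_shared_latent_concordance_matches_theory(self):
        # two antibodies = shared latent + independent noise(sd 0.5):
        # expected Pearson share 1/(1+0.25); Spearman close to it
        rng = np.random.default_rng(5)
        rhos = []
        for _ in range(100):
            latent = rng.standard_normal(68)
            a = latent + 0.5 * rng.standard_normal(68)
            b = latent + 0.5 * rng.standard_normal(68)
            pm = self._pm({"a": a, "b": b})
            rhos.append(
                aq.antibody_pair_concordance(pm, [("a", "b")])["rho"].iloc[0]
            )
        assert np.mean(rhos) == pytest.approx(1 / 1.25, abs=0.05)

    def test_insufficient_overlap_reported_missing(self):
        pm = self._pm({"a": np.arange(2.0), "b": np.arange(2.0)})
        out = aq.antibody_pair_concordance(pm, [("a", "b")])
        assert np.isnan(out["rho"].iloc[0])


class TestQuantifyEndToEnd:
    def test_low_noise_recovery_of_latent_ranks(self):
        # with technical noise off, the pipeline recovers the latent trait
        # rank order nearly perfectly (the small residual comes from the
        # load estimator consuming signal across finitely many antibodies)
        cfg = SimulationConfig(
            n_individuals=68, n_variants=20, n_traits=40, seed=23,
            load_effect_sd=0.3, batch_effect_sd=0.3, noise_sd=0.0, bio_rep_sd=0.0,
            arrays_per_print=40, dual_platform_fraction=0.0,
        )
        gm, _ = simulate_genotypes(cfg)
        prot, _ = simulate_true_traits(gm, [], cfg)
        features, _ = simulate_array_features(prot, cfg)
        pm = aq.quantify(features, apply_qc=False)
        rhos = [
            stats.spearmanr(pm.values[t], prot.loc[pm.values.index, t]).statistic
            for t in pm.traits
        ]
        assert min(rhos) > 0.9
        assert np.median(rhos) > 0.95

    def test_rank_order_preserved_by_location_normalizations(self, small_cohort):
        # load and batch corrections are per-sample/per-batch shifts: the
        # within-array ranking of technical replicate means is unchanged
        pm = aq.quantify(small_cohort.features, apply_qc=False)
        assert len(pm.traits) == small_cohort.config.n_traits
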