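"""Design arithmetic, validation statistics and scenario behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crossblup as cb
from crossblup.scenarios import (
    BROILER_FAMILY_COUNTS,
    SCENARIOS,
    evaluate_units,
    expected_overlap,
    families_from_counts,
    families_from_records,
    make_cv_groups,
    measure_overlap,
    reliability_weight,
    sample_matched_cb_subset,
    scale_validation_correlation,
    summarize_replicates,
    weighted_correlation,
    weighted_regression_bias,
    win_fraction,
)


def _published_families():
    pb = dict(zip(BROILER_FAMILY_COUNTS["family_size"], BROILER_FAMILY_COUNTS["n_pb_families"]))
    cb_avail = dict(zip(BROILER_FAMILY_COUNTS["family_size"], BROILER_FAMILY_COUNTS["n_cb_available"]))
    return pb, families_from_counts(cb_avail)


class TestMatchedSampling:
    def test_published_counts_select_4655_animals(self):
        pb, fams = _published_families()
        selected, table = sample_matched_cb_subset(pb, fams, seed=0)
        assert len(selected) == 4655
        assert table.n_selected_animals == 4655

    def test_scarce_sizes_select_all_available(self):
        pb, fams = _published_families()
        _, table = sample_matched_cb_subset(pb, fams, seed=1)
        t = table.table.set_index("family_size")
        assert t.loc[7, "n_selected"] == 3  # only 3 of 6 matched families exist
        assert t.loc[11, "n_selected"] == 0  # none available
        assert (t["n_selected"] == np.minimum(t["n_pb_families"], t["n_cb_available"])).all()

    def test_equal_counts_select_everything(self):
        fams = families_from_counts({2: 5, 3: 4})
        pb = {2: 5, 3: 4}
        sel_a, _ = sample_matched_cb_subset(pb, fams, seed=2)
        sel_b, _ = sample_matched_cb_subset(pb, fams, seed=3)
        assert sorted(sel_a) == sorted(sel_b)
        assert measure_overlap(sel_a, sel_b) == 1.0

    def test_monte_carlo_overlap_matches_hypergeometric_expectation(self):
        """Replicate-pair overlap per family size converges to
        n_selected / n_available."""
        fams = families_from_counts({3: 40})
        pb = {3: 25}
        rng_seeds = range(200)
        fracs = [
            measure_overlap(
                sample_matched_cb_subset(pb, fams, seed=2 * s)[0],
                sample_matched_cb_subset(pb, fams, seed=2 * s + 1)[0],
            )
            for s in rng_seeds
        ]
        expect = expected_overlap(25, 40)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - expect) < 3 * se + 1e-3

    def test_expected_overlap_values(self):
        assert expected_overlap(117, 177) == pytest.approx(0.661, abs=5e-4)
        assert expected_overlap(0, 10) == 0.0
        assert measure_overlap([], []) == 0.0


class TestCVGroups:
    def test_ten_sires_five_groups_all_pairs(self):
        part = make_cv_groups([f"S{i}" for i in range(10)], 5, seed=1)
        assert part.sizes == [2, 2, 2, 2, 2]

    def test_too_few_sires_raises(self):
        with pytest.raises(ValueError):
            make_cv_groups(["S1", "S2"], 5)

    def test_partition_is_disjoint_and_complete(self):
        sires = [f"S{i}" for i in range(37)]
        part = make_cv_groups(sires, 5, seed=2)
        assert sorted(part.sizes) == [7, 7, 7, 8, 8]
        assert part.all_sires() == set(sires)
        assert sum(part.sizes) == 37


class TestWeightedStatistics:
    def test_hand_example(self):
        assert weighted_correlation([1, 2, 3], [2, 4, 6], [1, 1, 2]) == pytest.approx(1.0)
        assert weighted_regression_bias([1, 2, 3], [2, 4, 6], [1, 1, 2], 1.0) == pytest.approx(2.0)

    def test_equal_weights_reduce_to_pearson_and_ols(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=50), rng.normal(size=50)
        w = np.full(50, 3.0)
        assert weighted_correlation(x, y, w) == pytest.approx(np.corrcoef(x, y)[0, 1])
        slope = np.polyfit(x, y, 1)[0]
        assert weighted_regression_bias(x, y, w, 1.0) == pytest.approx(slope)

    def test_offspring_average_exactly_half_gebv_gives_unit_bias(self):
        gebv = np.array([1.0, -0.4, 2.2, 0.3])
        assert weighted_regression_bias(gebv, gebv / 2, None, 2.0) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=500), st.floats(min_value=0.01, max_value=0.99))
    def test_reliability_weight_bounds_and_monotonicity(self, n, h2):
        w = reliability_weight(n, h2)
        assert 0 < w < 1
        assert reliability_weight(n + 1, h2) > w

    def test_reliability_weight_values_and_limits(self):
        assert reliability_weight(1, 0.2) == pytest.approx(0.05)
        assert reliability_weight(10, 0.23) == pytest.approx(0.575 / 1.5175)
        assert reliability_weight(10**9, 0.2) == pytest.approx(1.0, abs=1e-6)

    def test_scaled_correlation(self):
        assert scale_validation_correlation(0.0, "individual", 0.5) == 0.0
        assert scale_validation_correlation(0.16, "individual", 0.2304) == pytest.approx(0.16 / 0.48)
        assert scale_validation_correlation(0.3, "offspring_average", 1.0) == pytest.approx(0.3)
        with pytest.raises(ValueError):
            scale_validation_correlation(0.1, "nonsense", 0.5)


class TestSummaries:
    def _toy_results(self, corrs_x, corrs_y):
        rows = []
        for r, (cx, cy) in enumerate(zip(corrs_x, corrs_y)):
            rows.append((r, "X", "T", cx, 1.0, 10))
            rows.append((r, "Y", "T", cy, 1.0, 10))
        return pd.DataFrame(
            rows,
            columns=["replicate", "scenario", "trait", "validation_correlation",
                     "regression_coefficient", "n_units"],
        )

    def test_identical_replicates_have_zero_sd(self):
        res = self._toy_results([0.2] * 5, [0.1] * 5)
        summary = summarize_replicates(res).set_index("scenario")
        assert summary.loc["X", "sd_correlation"] == 0.0
        assert summary.loc["X", "mean_correlation"] == pytest.approx(0.2)

    def test_win_fraction_extremes_and_ties(self):
        res = self._toy_results([0.3, 0.3, 0.3], [0.1, 0.1, 0.1])
        assert win_fraction(res, "X", "Y") == 1.0
        res = self._toy_results([0.2, 0.2], [0.2, 0.2])
        assert win_fraction(res, "X", "Y") == 0.5

    def test_win_fraction_tracks_bernoulli_rate(self):
        rng = np.random.default_rng(6)
        wins = rng.random(100) < 0.7
        cx = np.where(wins, 0.3, 0.1)
        res = self._toy_results(cx, [0.2] * 100)
        assert win_fraction(res, "X", "Y") == pytest.approx(0.7, abs=0.12)


class TestScenarioRuns:
    def test_scenario_grid_is_the_published_design(self):
        assert set(SCENARIOS) == {
            "PB-A", "CB-A", "CB-A-BOA", "PB-I", "CB-I", "CB-I-BOA", "CB-A-DAM"
        }
        assert SCENARIOS["CB-I-BOA"].grm_kind == "boa_sire"
        assert SCENARIOS["PB-A"].grm_kind == "single"
        assert SCENARIOS["CB-A"].grm_kind == "multibreed"

    def test_no_leakage_in_any_fold(self, study_results):
        """Validation units never have offspring or paternal half-sibs in
        the reference set: all offspring follow their sire's CV group."""
        _, dataset = study_results
        data = cb.prepare_study_data(dataset, "BW7", h2_policy=0.18)
        part = make_cv_groups(data.sires_with_cb, 5, seed=9)
        subset = data.cb_offspring
        for val_sires in part.groups:
            val = set(val_sires)
            ref_cb = [a for a in subset if data.sire_of[a] not in val]
            assert not {data.sire_of[a] for a in ref_cb} & val
        units = cb.run_scenario(
            SCENARIOS["CB-I"], data, subset, part,
            cb.VarianceComponents(sigma2_a=0.15, sigma2_m=0.05, sigma2_e=0.8),
        )
        assert set(units["unit_id"]).issubset(set(subset))
        assert units["fold"].nunique() == 5

    def test_individual_boa_uses_crossbreds_only(self, study_results):
        _, dataset = study_results
        data = cb.prepare_study_data(dataset, "BW7", h2_policy=0.18)
        from crossblup.scenarios import _build_scenario_grm

        cb_ids = data.cb_offspring[:50]
        g = _build_scenario_grm(SCENARIOS["CB-I-BOA"], data, [], cb_ids)
        assert g.kind == "boa_sire"
        assert list(g.ids) == list(cb_ids)
        # reduced form: T T' / sum 2p(1-p), expected CB diagonal near 0.5
        assert np.diag(g.values).mean() == pytest.approx(0.5, abs=0.08)

    def test_fitted_correlation_exceeds_held_out(self, study_results):
        """Degenerate single-fold sanity check: correlating GEBV with the
        records they were fitted on beats held-out validation."""
        results, dataset = study_results
        data = cb.prepare_study_data(dataset, "BW7", h2_policy=0.18)
        from crossblup.scenarios import CVPartition

        subset = data.cb_offspring
        vc = cb.VarianceComponents(sigma2_a=0.15, sigma2_m=0.05, sigma2_e=0.8)
        half = data.sires_with_cb[: len(data.sires_with_cb) // 2]
        other = [s for s in data.sires_with_cb if s not in half]
        heldout_units = cb.run_scenario(
            SCENARIOS["CB-I"], data, subset, CVPartition([half]), vc
        )
        heldout, _ = evaluate_units(heldout_units, "individual")
        # refit on everyone, correlate with fitted animals' own records
        train_units = cb.run_scenario(
            SCENARIOS["CB-I"], data, subset, CVPartition([other]), vc,
            check_leakage=False,
        )
        # in-sample: candidates equal reference here
        ref_ids = [a for a in subset if data.sire_of[a] not in set(other)]
        grm_ids = ref_ids
        from crossblup.scenarios import _build_scenario_grm
        from crossblup.blup import build_design, solve_mme

        g = _build_scenario_grm(SCENARIOS["CB-I"], data, [], ref_ids)
        design = build_design(
            data.phenotypes[data.phenotypes["animal_id"].isin(ref_ids)],
            grm_ids=g.ids, model="animal",
        )
        sol = solve_mme(design, g, vc)
        insample = np.corrcoef(
            sol.gebv.loc[ref_ids].to_numpy(), data.y_corrected(ref_ids)
        )[0, 1]
        assert insample > heldout > 0

    def test_replicate_results_within_bounds(self, study_results):
        results, _ = study_results
        assert results["validation_correlation"].between(-1, 1).all()
        assert np.isfinite(results["regression_coefficient"]).all()
        assert set(results["scenario"]) == {"CB-I", "CB-I-BOA"}
        assert results["replicate"].nunique() == 30

    def test_purebred_reference_beats_half_genome_boa_reference(self):
        """With r_pc = 1, identical lines and family-matched reference
        sizes, validating sire GEBV on offspring averages favours the
        purebred reference over the crossbred breed-of-origin reference:
        sire-line alleles in crossbreds carry only half the genetic
        variance, the rest of each record acting as noise."""
        import warnings

        cfg = cb.SimConfig(
            n_markers=800, n_qtl=250,
            n_sires=30, n_sires_both=28, n_sires_pb_only=1, n_sires_cb_only=1,
            n_pb_dams=110, n_cb_dams=220, n_dam_line_founders=70,
            n_pb_offspring=650, n_cb_offspring=1200,
            traits=(cb.TraitSpec("T", h2_pb=0.25, h2_cb=0.25, r_pc=1.0),),
            divergence=0.0, seed=404,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res, _ = cb.run_study(
                cfg, ["PB-A", "CB-A-BOA"], n_replicates=16, base_seed=17,
                h2_policy="animal",
            )
        means = res.groupby("scenario")["validation_correlation"].mean()
        assert means["PB-A"] > means["CB-A-BOA"]
        assert means["CB-A-BOA"] > 0  # the half-genome reference still predicts

    def test_families_from_records_groups_by_sire_and_dam(self, small_dataset):
        phen = small_dataset.phenotypes
        cb_rec = phen[(phen["genetic_group"] == "CB") & (phen["trait"] == "BW7")]
        fams = families_from_records(cb_rec, small_dataset.pedigree)
        assert sum(len(f) for f in fams) == cb_rec["animal_id"].nunique()
        sire_of = dict(zip(small_dataset.pedigree["animal_id"], small_dataset.pedigree["sire_id"]))
        dam_of = dict(zip(cb_rec["animal_id"], cb_rec["dam_id"]))
        for fam in fams:
            assert len({(sire_of[a], dam_of[a]) for a in fam}) == 1
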