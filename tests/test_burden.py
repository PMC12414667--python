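"""Burden estimation: exact count arithmetic, carrier-value penetrance on
the published carrier labs, excess-burden accounting, allelic series, and
cross-cohort concordance."""

import numpy as np
import pandas as pd
import pytest

from adh1score import burden, phenotypes, scoring

# Serum labs of the ten heterozygous carriers of previously reported
# gain-of-function variants observed in a ~434k-person biobank (mM).
KNOWN_CARRIER_CALCIUM = [2.13, 2.07, 2.07, 2.19, 2.19, 2.20, 1.96, 2.39, 2.22, 2.36]
KNOWN_CARRIER_PHOSPHATE = [1.46, 1.44, 1.70, 1.51, 1.27, 1.23, 1.57, 1.04, 1.37, 1.29]


class TestCarrierFrequency:
    def test_zero_carriers(self):
        assert burden.carrier_frequency(0, 1000) == 0.0

    @pytest.mark.parametrize("n,cohort,expected", [
        (10, 433_793, 2.31),
        (16, 229_987, 6.96),
    ])
    def test_exact_ratio_per_100k(self, n, cohort, expected):
        assert burden.carrier_frequency(n, cohort) == pytest.approx(expected, abs=0.005)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            burden.carrier_frequency(-1, 100)


class TestLabPenetrance:
    def test_hypocalcemia_six_of_ten(self):
        assert burden.lab_penetrance(KNOWN_CARRIER_CALCIUM, 2.2, "below") == 0.6

    def test_hyperphosphatemia_four_of_ten(self):
        assert burden.lab_penetrance(KNOWN_CARRIER_PHOSPHATE, 1.45, "above") == 0.4

    def test_no_values_beyond_limit(self):
        assert burden.lab_penetrance([2.3, 2.4], 2.2, "below") == 0.0

    def test_empty_is_missing(self):
        assert burden.lab_penetrance([], 2.2, "below") is None

    def test_boundary_is_strict(self):
        assert burden.lab_penetrance([2.2], 2.2, "below") == 0.0


class TestDxPenetrance:
    def _phen(self, flags, records=None):
        n = len(flags)
        return pd.DataFrame({
            "individual_id": [f"i{k}" for k in range(n)],
            "cat_hypoparathyroidism": flags,
            "cat_calcium_phosphorus_disorder": [False] * n,
            "has_full_records": records if records is not None else [True] * n,
        })

    def test_one_of_six(self):
        df = self._phen([True] + [False] * 5)
        assert burden.dx_penetrance(df) == pytest.approx(1 / 6)

    def test_four_of_nine(self):
        df = self._phen([True] * 4 + [False] * 5)
        assert burden.dx_penetrance(df) == pytest.approx(4 / 9)

    def test_none_flagged(self):
        assert burden.dx_penetrance(self._phen([False] * 4)) == 0.0

    def test_only_full_record_carriers_are_evaluable(self):
        df = self._phen([True, False, False], records=[False, True, True])
        assert burden.dx_penetrance(df) == 0.0    # the flagged carrier lacks records

    def test_zero_evaluable_is_missing(self):
        df = self._phen([True], records=[False])
        assert burden.dx_penetrance(df) is None


class TestExcessBurden:
    def test_zero_baseline(self):
        est = burden.excess_burden(14, 20, 0.0, 100_000)
        assert est.excess == 14.0 and est.excess_per_100k == 14.0

    def test_arithmetic(self):
        est = burden.excess_burden(20, 60, 0.10, 500_000)
        assert est.expected_affected == 6.0
        assert est.excess == 14.0
        assert est.excess_per_100k == pytest.approx(2.8)

    def test_observed_equal_expected(self):
        est = burden.excess_burden(6, 60, 0.10, 1000)
        assert est.excess == 0.0

    def test_negative_excess_floors_at_zero_with_diagnostics(self):
        est = burden.excess_burden(2, 60, 0.10, 1000)
        assert est.excess == 0.0 and est.raw_excess == -4.0

    def test_observed_exceeding_carriers_rejected(self):
        with pytest.raises(ValueError):
            burden.excess_burden(10, 5, 0.1, 1000)

    def test_frequency_is_exact(self):
        est = burden.excess_burden(0, 7, 0.0, 433_793)
        assert est.frequency_per_100k == pytest.approx(7 / 433_793 * 100_000, rel=1e-12)


class TestAllelicSeries:
    def test_three_singleton_classes_ordered(self):
        df = pd.DataFrame({
            "variant_id": ["a", "b", "c"],
            "series_class": ["common", "intermediate", "known"],
            "calcium_beta": [-0.01, -0.1, -0.4],
            "maf": [0.1, 1e-4, 2e-6],
        })
        out = burden.allelic_series_summary(df).set_index("series_class")
        assert (out.loc["common", "median_calcium_beta"]
                > out.loc["intermediate", "median_calcium_beta"]
                > out.loc["known", "median_calcium_beta"])

    def test_single_class_single_row(self):
        df = pd.DataFrame({"variant_id": ["a"], "series_class": ["known"],
                           "calcium_beta": [-0.3], "maf": [1e-5]})
        assert len(burden.allelic_series_summary(df)) == 1

    def test_empty_class_omitted_with_warning(self, caplog):
        df = pd.DataFrame({"variant_id": ["a", "b"],
                           "series_class": ["known", "empty"],
                           "calcium_beta": [-0.3, np.nan], "maf": [1e-5, 1e-5]})
        with caplog.at_level("WARNING"):
            out = burden.allelic_series_summary(df)
        assert list(out["series_class"]) == ["known"]
        assert any("empty" in r.message for r in caplog.records)

    def test_generator_truth_ordering_recovered(self, medium_cohort,
                                                medium_phenotypes):
        """Estimated carrier betas reproduce the ground-truth ordering of the
        allelic series: established GoF < intermediate GoF < synonymous ~ 0."""
        scores, assoc = scoring.score_cohort(
            medium_cohort.variants, medium_cohort.individuals,
            medium_phenotypes, collect_associations=True)
        cal = (assoc[assoc["phenotype"] == "calcium"]
               .sort_values(["variant_id", "p_value"])
               .drop_duplicates("variant_id"))
        cls = medium_cohort.truth.set_index("variant_id")["class_label"]
        maf = medium_cohort.variants.set_index("variant_id")["maf_EUR"]
        df = pd.DataFrame({
            "variant_id": cal["variant_id"],
            "series_class": cal["variant_id"].map(cls),
            "calcium_beta": cal["beta"].to_numpy(),
            "maf": cal["variant_id"].map(maf),
        })
        out = burden.allelic_series_summary(df).set_index("series_class")
        assert (out.loc["gof_known", "median_calcium_beta"]
                < out.loc["gof_intermediate", "median_calcium_beta"]
                < out.loc["synonymous", "median_calcium_beta"] + 0.05)
        assert abs(out.loc["synonymous", "median_calcium_beta"]) < 0.05


class TestCrossCohortConcordance:
    def test_identical_tables_all_in_both(self):
        df = pd.DataFrame({"variant_id": ["a", "b", "c"],
                           "variant_score": [2.0, 0.5, 3.0]})
        rep = burden.cross_cohort_concordance(df, df.copy(), 1.5)
        assert rep["n_shared_variants"] == 3
        assert rep["above_in_both"] == 2
        assert rep["above_in_a_only"] == rep["above_in_b_only"] == 0

    def test_disjoint_sets_share_nothing(self):
        a = pd.DataFrame({"variant_id": ["a"], "variant_score": [2.0]})
        b = pd.DataFrame({"variant_id": ["b"], "variant_score": [2.0]})
        rep = burden.cross_cohort_concordance(a, b, 1.5)
        assert rep["n_shared_variants"] == 0

    def test_direction_concordance_fraction(self):
        betas = pd.DataFrame({"variant_id": ["a", "b", "c", "d"],
                              "calcium_beta_a": [-0.2, -0.1, 0.3, -0.4],
                              "calcium_beta_c": [-0.1, 0.2, 0.1, -0.2]})
        a = pd.DataFrame({"variant_id": list("abcd"), "variant_score": [2.0] * 4})
        rep = burden.cross_cohort_concordance(a, a.copy(), 1.5, betas_c=betas)
        assert rep["fraction_same_direction_in_c"] == pytest.approx(0.75)

    def test_true_gof_replicate_across_cohorts_more_than_null_variants(self):
        """Two cohorts simulated from the same ground truth call the
        established GoF variants above threshold in both far more often than
        effect-free variants."""
        from adh1score import simulate
        reps = {}
        for seed in (21, 22):
            cfg = simulate.SimulationConfig(
                n_individuals=20_000, strata=("EUR",), seed=seed,
                variant_classes=(
                    simulate.known_gof_class(),
                    simulate.VariantClassSpec(class_label="neutral", n_variants=40,
                                              carrier_count_range=(1, 20)),
                ),
            )
            coh = simulate.generate_cohort(cfg)
            phen = phenotypes.build_phenotypes(coh.individuals)
            scores, _ = scoring.score_cohort(coh.variants, coh.individuals, phen)
            # harmonize ids: same class/profile index across seeds
            scores = scores.assign(
                variant_id=scores["variant_id"].map(
                    {v: f"h{i}" for i, v in enumerate(coh.variants["variant_id"])}))
            reps[seed] = scores[["variant_id", "variant_score"]]
        rep = burden.cross_cohort_concordance(reps[21], reps[22], 1.5)
        n_gof = 13
        gof_ids = {f"h{i}" for i in range(n_gof)}
        a = reps[21].set_index("variant_id")["variant_score"]
        b = reps[22].set_index("variant_id")["variant_score"]
        both = (a > 1.5) & (b > 1.5)
        gof_rate = both[both.index.isin(gof_ids)].mean()
        null_rate = both[~both.index.isin(gof_ids)].mean()
        assert gof_rate > null_rate + 0.3
        assert rep["above_in_both"] >= int(both[both.index.isin(gof_ids)].sum())
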