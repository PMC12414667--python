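"""ADH1 score: hotspot geometry, direction-constrained sub-scores, exact
additivity, monotonicity, and class separation on synthetic data."""

import numpy as np
import pytest

from adh1score import scoring
from adh1score.scoring import ScoreWeights, SubScoreVector

W = ScoreWeights()


class TestHotspot:
    @pytest.mark.parametrize("pos,expected", [
        (124, True),    # inside 116-136
        (104, False),   # just before the first hotspot
        (116, True), (136, True),       # inclusive bounds
        (137, False), (115, False),
        (819, True), (837, True), (838, False),
    ])
    def test_flag(self, pos, expected):
        assert scoring.hotspot_flag(pos) is expected

    def test_invalid_position(self):
        with pytest.raises(ValueError):
            scoring.hotspot_flag(0)


class TestSubScores:
    @pytest.mark.parametrize("beta,p,expected", [
        (-0.24, 9.1e-3, 3.0),    # significant calcium-lowering association
        (-0.01, 0.90, 0.0),      # null association
        (+0.30, 0.001, 0.0),     # wrong direction blocks the component
    ])
    def test_calcium(self, beta, p, expected):
        assert scoring.calcium_subscore(beta, p, W) == expected

    @pytest.mark.parametrize("beta,p,expected", [
        (0.35, 2.2e-2, 1.0),
        (0.05, 0.64, 0.0),
        (-0.21, 0.001, 0.0),
    ])
    def test_phosphate(self, beta, p, expected):
        assert scoring.phosphate_subscore(beta, p, W) == expected

    @pytest.mark.parametrize("frac,expected", [
        (0.9, 0.2), (0.5, 0.0), (0.0, 0.0),
    ])
    def test_insilico_majority_rule(self, frac, expected):
        assert scoring.insilico_subscore(frac, W) == pytest.approx(expected)

    def test_insilico_graded_is_fraction_scaled(self):
        assert scoring.insilico_subscore(0.35, W, mode="graded") == pytest.approx(0.07)

    def test_dx_medication_subscores_from_carrier_phenotypes(self):
        from adh1score.phenotypes import PhenotypeVector
        carriers = [
            PhenotypeVector("a", adh1_phecode_flags={"hypoparathyroidism": True},
                            adh1_medication_count=1),
            PhenotypeVector("b", adh1_phecode_flags={}, adh1_medication_count=0),
        ]
        dx, med = scoring.dx_medication_subscores(
            carriers, {"hypoparathyroidism": 2.4e-3, "medication": 0.03}, W)
        assert dx["hypoparathyroidism"] == 1.0
        assert all(dx[c] == 0.0 for c in scoring.DX_CATEGORIES
                   if c != "hypoparathyroidism")
        assert med == 1.0
        # no carrier with any relevant phecode -> all zero regardless of p
        dx0, med0 = scoring.dx_medication_subscores(
            [PhenotypeVector("c")], {c: 1e-9 for c in scoring.DX_CATEGORIES}, W)
        assert set(dx0.values()) == {0.0} and med0 == 0.0
        with pytest.raises(ValueError):
            scoring.dx_medication_subscores([], {}, W)

    def test_dx_component_fires_with_carrier_and_enrichment(self):
        assert scoring._binary_component(True, 2.4e-3, W.w_dx_category, 0.05, "binary") == 1.0
        assert scoring._binary_component(False, 1e-9, W.w_dx_category, 0.05, "binary") == 0.0
        assert scoring._binary_component(True, 0.5, W.w_dx_category, 0.05, "binary") == 0.0


class TestGradedFactor:
    def test_full_credit_at_alpha_and_zero_beyond_window(self):
        assert scoring._grade(0.05, 0.05) == 1.0
        assert scoring._grade(0.01, 0.05) == 1.0
        assert scoring._grade(0.25, 0.05) == 0.0
        assert scoring._grade(0.9, 0.05) == 0.0

    def test_monotone_decreasing_in_p(self):
        ps = np.linspace(0.01, 0.4, 50)
        grades = [scoring._grade(p, 0.05) for p in ps]
        assert all(a >= b for a, b in zip(grades, grades[1:]))


class TestAdditivity:
    def test_all_components_firing_totals_ten_point_seven(self):
        ssv = SubScoreVector("v", "s", calcium=3.0, phosphate=1.0,
                             dx={c: 1.0 for c in scoring.DX_CATEGORIES},
                             medication=1.0, hotspot=0.5, insilico=0.2)
        assert ssv.total == pytest.approx(10.7, abs=1e-12)

    def test_zero_components_total_zero(self):
        assert SubScoreVector("v", "s").total == 0.0

    def test_adding_a_component_never_decreases_total(self):
        base = SubScoreVector("v", "s", calcium=3.0)
        more = SubScoreVector("v", "s", calcium=3.0, medication=1.0)
        assert more.total >= base.total

    def test_variant_score_requires_carriers(self):
        import pandas as pd
        with pytest.raises(ValueError):
            scoring.adh1_score(pd.Series({"variant_id": "v"}), [])


@pytest.fixture(scope="module")
def scored(small_cohort, small_phenotypes):
    scores, _ = scoring.score_cohort(small_cohort.variants,
                                     small_cohort.individuals,
                                     small_phenotypes, mode="binary")
    return scores


class TestScoreCohort:
    def test_totals_are_exact_component_sums(self, scored):
        recomputed = scored[list(scoring.COMPONENT_COLUMNS)].sum(axis=1)
        assert (recomputed == scored["total"]).all()

    def test_variant_score_is_max_over_strata(self, scored):
        for vid, grp in scored.groupby("variant_id"):
            assert (grp["variant_score"] == grp["total"].max()).all()

    def test_components_take_only_weight_or_zero_in_binary_mode(self, scored):
        for col, w in [("sub_calcium", 3.0), ("sub_phosphate", 1.0),
                       ("sub_medication", 1.0), ("sub_hotspot", 0.5),
                       ("sub_insilico", 0.2)]:
            assert set(np.round(scored[col].unique(), 12)) <= {0.0, w}

    def test_invariant_to_individual_relabeling(self, small_cohort, small_phenotypes):
        """Renaming every individual id consistently leaves all totals
        unchanged."""
        ren = {i: f"X{k:05d}" for k, i in
               enumerate(small_cohort.individuals["individual_id"])}
        ind = small_cohort.individuals.assign(
            individual_id=lambda d: d["individual_id"].map(ren))
        phe = small_phenotypes.assign(
            individual_id=lambda d: d["individual_id"].map(ren))
        var = small_cohort.variants.assign(
            carriers=lambda d: d["carriers"].map(
                lambda s: ",".join(ren[c] for c in s.split(","))))
        a, _ = scoring.score_cohort(small_cohort.variants, small_cohort.individuals,
                                    small_phenotypes)
        b, _ = scoring.score_cohort(var, ind, phe)
        assert np.allclose(a.sort_values(["variant_id", "stratum"])["total"],
                           b.sort_values(["variant_id", "stratum"])["total"])

    def test_known_gof_separate_from_synonymous(self, medium_cohort,
                                                medium_phenotypes):
        """Mean score of established GoF variants far exceeds the synonymous
        mean — the separation that makes thresholding meaningful."""
        scores, _ = scoring.score_cohort(medium_cohort.variants,
                                         medium_cohort.individuals,
                                         medium_phenotypes, mode="binary")
        cls = medium_cohort.truth.set_index("variant_id")["class_label"]
        scores = scores.assign(cls=scores["variant_id"].map(cls))
        gof = scores.loc[scores["cls"] == "gof_known", "variant_score"]
        syn = scores.loc[scores["cls"] == "synonymous", "variant_score"]
        assert gof.mean() > syn.mean() + 2.0

    def test_hard_filter_excludes_synonymous_and_common(self, small_cohort):
        mask = scoring.hard_filter(small_cohort.variants, "EUR")
        kept = small_cohort.variants[mask]
        assert (kept["consequence"] != "synonymous").all()
        assert (kept["maf_EUR"] < 0.01).all()
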