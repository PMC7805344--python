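"""Synthetic-cohort generator: determinism, count conservation, IO."""

import io

import numpy as np
import pandas as pd
import pytest

from neocea.cohort import (
    CohortSpec,
    CohortParseError,
    CohortSpecError,
    PercentileTable,
    Stratum,
    build_fixture_cohort,
    default_cohort_spec,
    read_cohort,
    sample_cohort,
    write_cohort,
)
from neocea.effectiveness import cohort_effects


def _one_stratum(**kw):
    base = dict(
        bw_low_g=2500, bw_high_g=2600, n_tested=1, n_suitable=1,
        n_preterm_true=1, n_preterm_correct_metabolic=1,
        n_preterm_correct_basic=0, n_sga_true=0,
        n_sga_correct_metabolic=0, n_sga_correct_basic=0,
    )
    base.update(kw)
    return Stratum(**base)


class TestSpecValidation:
    def test_correct_count_exceeding_true_names_stratum(self):
        s = _one_stratum(n_preterm_correct_metabolic=2, n_suitable=2, n_tested=2)
        with pytest.raises(CohortSpecError, match=r"\[2500, 2600\).*exceeds"):
            CohortSpec(strata=(s,)).validate()

    def test_overlapping_bins_rejected(self):
        a = _one_stratum()
        b = _one_stratum(bw_low_g=2550, bw_high_g=2650)
        with pytest.raises(CohortSpecError, match="overlap"):
            CohortSpec(strata=(a, b)).validate()

    def test_unknown_overlap_rule_rejected(self):
        with pytest.raises(CohortSpecError, match="overlap_rule"):
            CohortSpec(strata=(), overlap_rule="sideways").validate()


class TestFixtureBuild:
    def test_marginal_totals(self, cohort):
        assert len(cohort) == 3969
        suitable = cohort[cohort.sample_suitable]
        assert len(suitable) == 3045
        assert (suitable.sample_type == "heel").sum() == 975
        assert (suitable.sample_type == "cord").sum() == 2070
        assert (suitable.ga_ultrasound_wk < 37).sum() == 276

    def test_builds_are_byte_identical(self, spec):
        a, b = io.StringIO(), io.StringIO()
        write_cohort(build_fixture_cohort(spec), a)
        write_cohort(build_fixture_cohort(spec), b)
        assert a.getvalue() == b.getvalue()

    def test_empty_spec_gives_empty_cohort(self):
        cohort = build_fixture_cohort(CohortSpec(strata=()))
        assert cohort.empty and list(cohort.columns)[0] == "infant_id"

    def test_single_forced_record(self):
        cohort = build_fixture_cohort(CohortSpec(strata=(_one_stratum(),)))
        row = cohort.iloc[0]
        assert len(cohort) == 1
        assert row.ga_ultrasound_wk < 37 and row.ga_metabolic_wk < 38

    @pytest.mark.parametrize("rule", ["maximal", "minimal", "independent"])
    def test_count_conservation_every_stratum(self, rule):
        """Classifying the fixture recovers every spec count exactly."""
        spec = default_cohort_spec(overlap_rule=rule)
        cohort = build_fixture_cohort(spec)
        for s in spec.strata:
            expected = {
                ("metabolic", "preterm"): (s.n_preterm_true, s.n_preterm_correct_metabolic),
                ("basic", "preterm"): (s.n_preterm_true, s.n_preterm_correct_basic),
                ("metabolic", "sga"): (s.n_sga_true, s.n_sga_correct_metabolic),
                ("basic", "sga"): (s.n_sga_true, s.n_sga_correct_basic),
            }
            for (alg, outcome), (n_true, n_correct) in expected.items():
                got = cohort_effects(
                    cohort, alg, outcome, annualization_factor=1.0,
                    bw_range=(s.bw_low_g, s.bw_high_g),
                )
                assert got.n_true == n_true, (s.bw_low_g, alg, outcome)
                assert got.n_correct == n_correct, (s.bw_low_g, alg, outcome)

    def test_annual_counts_are_exact_thirds(self, spec):
        assert spec.annualization_factor == pytest.approx(1 / 3)
        assert spec.total("n_preterm_correct_basic") == 166  # 55.3/y
        assert spec.total("n_preterm_correct_metabolic") == 192  # 64.0/y
        assert spec.total("n_sga_true") == 748  # 249.3/y
        assert spec.total("n_sga_correct_metabolic") == 538  # 179.3/y
        assert spec.total("n_sga_correct_basic") == 102  # 34.0/y


class TestPercentileTable:
    def test_requires_strict_monotonicity(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            PercentileTable(ga_wk=(32, 33, 34), p10_weight_g=(800, 800, 900))

    def test_domain_error_outside_range(self, table):
        with pytest.raises(ValueError, match="domain"):
            table.p10(30.0)

    def test_incompatible_table_rejected_at_build(self, spec):
        # p10 above every birthweight: all records would be misplaced as SGA
        high = PercentileTable(ga_wk=(32, 44), p10_weight_g=(6000, 7000))
        with pytest.raises(CohortSpecError, match="percentile"):
            build_fixture_cohort(spec, table=high)


class TestSampling:
    def test_same_seed_identical(self, spec):
        a = sample_cohort(spec, 500, seed=7)
        b = sample_cohort(spec, 500, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_n_rejected(self, spec):
        with pytest.raises(ValueError):
            sample_cohort(spec, 0, seed=1)

    def test_preterm_fraction_matches_suitable_rate(self, spec):
        cohort = sample_cohort(spec, 3969, seed=11)
        suitable = cohort[cohort.sample_suitable]
        frac = (suitable.ga_ultrasound_wk < 37).mean()
        p = 92 / 1015
        se = np.sqrt(p * (1 - p) / len(suitable))
        assert abs(frac - p) < 3 * se

    def test_stratum_frequencies_converge(self, spec):
        cohort = sample_cohort(spec, 50_000, seed=3)
        total = sum(s.n_tested for s in spec.strata)
        for s in spec.strata:
            got = (
                (cohort.birthweight_g >= s.bw_low_g)
                & (cohort.birthweight_g < s.bw_high_g)
            ).mean()
            assert abs(got - s.n_tested / total) < 0.01


class TestRoundTrip:
    def test_write_read_lossless(self, cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(back, cohort)

    def test_missing_metabolic_on_unsuitable_accepted(self, cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        unsuitable = back[~back.sample_suitable]
        assert unsuitable.ga_metabolic_wk.isna().all()

    def test_negative_birthweight_rejected_with_line(self, cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        bad = cohort.head(3).copy()
        bad.loc[1, "birthweight_g"] = -10
        write_cohort(bad, path)
        with pytest.raises(CohortParseError, match="line 3"):
            read_cohort(path)

    def test_metabolic_ga_on_unsuitable_rejected(self, cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        bad = cohort[~cohort.sample_suitable].head(2).copy().reset_index(drop=True)
        bad.loc[0, "ga_metabolic_wk"] = 38.0
        write_cohort(bad, path)
        with pytest.raises(CohortParseError, match="unsuitable"):
            read_cohort(path)
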