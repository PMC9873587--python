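"""Data model, CSV round-trips, covariate preprocessing, capture tallies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import bombus_occupancy as bo
from bombus_occupancy.survey_data import SurveyDataError


class TestReadWrite:
    def test_toy_csv_transcription(self, toy_survey, tmp_path):
        """A single detection row becomes exactly one 1 in the tensor."""
        paths = bo.write_survey_csv(toy_survey, tmp_path)
        survey = bo.read_survey_csv(paths["sites"], paths["visits"], paths["detections"])
        assert survey.detections.values.sum() == 1
        assert survey.detections.values[survey.species_names.index("x"), 0, 0] == 1

    def test_round_trip_identity(self, small_sim, tmp_path):
        survey, _, _ = small_sim
        paths = bo.write_survey_csv(survey, tmp_path)
        back = bo.read_survey_csv(paths["sites"], paths["visits"], paths["detections"],
                                  species=survey.species_names)
        assert back.site_ids == survey.site_ids
        assert back.species_names == survey.species_names
        np.testing.assert_array_equal(back.detections.values, survey.detections.values)
        np.testing.assert_array_equal(back.detections.mask, survey.detections.mask)
        pd.testing.assert_frame_equal(back.sites, survey.sites)
        pd.testing.assert_frame_equal(back.visits, survey.visits)

    def test_unknown_site_reference_is_an_error(self, toy_survey, tmp_path):
        paths = bo.write_survey_csv(toy_survey, tmp_path)
        det = pd.read_csv(paths["detections"])
        det.loc[len(det)] = ["Z99", 1, "x", 1]
        det.to_csv(paths["detections"], index=False)
        with pytest.raises(SurveyDataError, match="Z99"):
            bo.read_survey_csv(paths["sites"], paths["visits"], paths["detections"])

    def test_conflicting_duplicate_detection_rows(self, toy_survey, tmp_path):
        paths = bo.write_survey_csv(toy_survey, tmp_path)
        det = pd.read_csv(paths["detections"])
        det.loc[len(det)] = ["A", 1, "x", 0]  # contradicts the recorded 1
        det.to_csv(paths["detections"], index=False)
        with pytest.raises(SurveyDataError, match="conflict"):
            bo.read_survey_csv(paths["sites"], paths["visits"], paths["detections"])

    def test_percent_canopy_converted_to_fraction(self, toy_tables):
        sites, visits = toy_tables
        sites = sites.assign(canopy_openness=[60.0, 20.0])
        survey = bo.SurveyData(sites, visits, _empty(2, 2, 2))
        assert np.allclose(sorted(survey.sites["canopy_openness"]), [0.2, 0.6])


def _empty(s, j, k):
    return bo.DetectionTensor(np.zeros((s, j, k), np.int8), np.ones((j, k), bool), [f"s{i}" for i in range(s)])


class TestPooling:
    @pytest.mark.parametrize(
        "counts, abundance, richness",
        [
            ({"A": [3, 2], "B": [0, 5]}, 10, 2),
            ({"A": [0, 0], "B": [0, 0]}, 0, 0),
            ({"T1": [1], "T2": [1], "T3": [1]}, 3, 1),  # pooled across, not per transect
            ({}, 0, 0),
        ],
    )
    def test_examples(self, counts, abundance, richness):
        assert bo.pool_floral_counts(counts) == (abundance, richness)

    def test_negative_count_rejected(self):
        with pytest.raises(SurveyDataError, match="negative"):
            bo.pool_floral_counts({"A": [3, -1]})

    @given(
        st.dictionaries(
            st.text(min_size=1, max_size=3),
            st.lists(st.integers(min_value=0, max_value=50), max_size=6),
            max_size=4,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_abundance_is_grand_total(self, counts):
        abundance, richness = bo.pool_floral_counts(counts)
        assert abundance == sum(sum(v) for v in counts.values())
        assert 0 <= richness <= max((len(v) for v in counts.values()), default=0)


class TestBuildDesign:
    def test_standardized_columns_have_mean_zero_sd_one(self, small_sim):
        survey, _, _ = small_sim
        design = bo.build_design(survey)
        for p, name in enumerate(design.occ_names):
            if name in ("burn_status", "burn_status:canopy_openness"):
                continue
            col = design.X_occ[:, p]
            assert abs(col.mean()) < 1e-9
            assert abs(col.std(ddof=1) - 1) < 1e-9
        det_rows = design.X_det[design.mask]
        for p, name in enumerate(design.det_names):
            if name in ("burn_status", "canopy_openness"):
                continue  # site-level column standardized over sites, broadcast to visits
            col = det_rows[:, p]
            assert abs(col.mean()) < 1e-9
            assert abs(col.std(ddof=1) - 1) < 1e-9

    def test_interaction_is_product_of_parents(self, small_sim):
        survey, _, _ = small_sim
        design = bo.build_design(survey)
        names = list(design.occ_names)
        prod = design.X_occ[:, names.index("burn_status")] * design.X_occ[:, names.index("canopy_openness")]
        np.testing.assert_allclose(design.X_occ[:, names.index("burn_status:canopy_openness")], prod)
        # burned site with standardized canopy c has interaction c; unburned 0
        burned = design.site_burn == 1
        assert (design.X_occ[~burned, names.index("burn_status:canopy_openness")] == 0).all()

    def test_site_floral_is_mean_of_log_visit_values(self, toy_survey):
        design = bo.build_design(toy_survey)
        rec = design.standardization["occ"]["log_floral_abundance"]
        # site A visit abundances {10, 30}: site value mean(log 11, log 31)
        expected_raw = np.array(
            [np.mean([np.log(11.0), np.log(31.0)]), np.mean([np.log(1.0), np.log(6.0)])]
        )
        names = list(design.occ_names)
        col = design.X_occ[:, names.index("log_floral_abundance")]
        np.testing.assert_allclose(col * rec.sd + rec.mean, expected_raw, atol=1e-12)

    def test_zero_variance_covariate_is_an_error(self, toy_tables):
        sites, visits = toy_tables
        sites = sites.assign(canopy_openness=[0.4, 0.4])
        survey = bo.SurveyData(sites, visits, _empty(2, 2, 2))
        with pytest.raises(SurveyDataError, match="zero variance"):
            bo.build_design(survey)

    def test_interaction_without_parents_is_an_error(self, toy_survey):
        spec = bo.ModelSpec(occ_covariates=("burn_status:canopy_openness",))
        with pytest.raises(SurveyDataError, match="interaction"):
            bo.build_design(toy_survey, spec)

    def test_row_order_invariance(self, small_sim):
        survey, _, _ = small_sim
        design = bo.build_design(survey)
        perm = np.random.default_rng(0).permutation(len(survey.sites))
        shuffled = bo.SurveyData(
            survey.sites.iloc[perm].reset_index(drop=True),
            survey.visits.sample(frac=1, random_state=1).reset_index(drop=True),
            bo.DetectionTensor(
                survey.detections.values[:, perm, :],
                survey.detections.mask[perm, :],
                survey.species_names,
            ),
        )
        design2 = bo.build_design(shuffled)
        np.testing.assert_allclose(design2.X_occ, design.X_occ)
        np.testing.assert_allclose(design2.X_det, design.X_det)

    def test_standardization_record_round_trips(self, small_sim):
        survey, _, _ = small_sim
        design = bo.build_design(survey)
        rec = design.standardization["det"]["log_floral_abundance"]
        raw = survey.visits["floral_abundance"].to_numpy(float)
        np.testing.assert_allclose(rec.original(rec.standardize(raw)), raw, atol=1e-9)


class TestTallies:
    def test_study_capture_table(self):
        """Packaged capture table: totals, per-method species counts, top-3 share."""
        summary = bo.tally_captures(bo.load_table1_captures())
        assert summary.trap_total == 290
        assert summary.net_total == 102
        assert summary.trap_species == 10
        assert summary.net_species == 8
        assert summary.combined_species == 11
        assert summary.top_k_trap_share == 242

    def test_conservation_over_species(self):
        table = bo.load_table1_captures()
        summary = bo.tally_captures(table)
        per_species = table["trap_unburned"] + table["trap_burned"]
        assert summary.trap_total == per_species.sum()
        assert summary.net_total == table["net_burned"].sum()

    def test_empty_table_gives_zeros(self):
        empty = pd.DataFrame(columns=["species", "trap_unburned", "trap_burned", "net_burned"])
        summary = bo.tally_captures(empty)
        assert (
            summary.trap_total,
            summary.net_total,
            summary.trap_species,
            summary.net_species,
            summary.combined_species,
            summary.top_k_trap_share,
        ) == (0, 0, 0, 0, 0, 0)
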