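"""Synthetic measurement generator: counts, determinism, curve behavior."""

from collections import Counter

import numpy as np
import pytest

from magmeta import synthetic as sd


class TestPropertyResponse:
    def test_zero_field_returns_base_value_exactly(self):
        curve = sd.MagnetizationCurve("sigma", 0.072, -0.004, 150.0, roughness_sd=0.0)
        assert sd.property_response(curve, 0.0, seed=3) == 0.072

    def test_smooth_response_is_monotone_in_field(self):
        curve = sd.MagnetizationCurve("EC", 1200.0, 60.0, 150.0, roughness_sd=0.0)
        values = [sd.property_response(curve, b, seed=0) for b in sd.FIELD_GRID_MT]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_saturating_exponential_reference_value(self):
        # frozen value from direct formula evaluation:
        # 0.072 - 0.004 * (1 - exp(-450/150))
        curve = sd.MagnetizationCurve("sigma", 0.072, -0.004, 150.0, roughness_sd=0.0)
        assert sd.property_response(curve, 450.0, seed=0) == pytest.approx(
            0.06819914827347145, rel=1e-12
        )

    def test_roughness_is_frozen_per_level(self):
        curve = sd.MagnetizationCurve("pH", 6.8, 0.25, 200.0, roughness_sd=0.05)
        a = sd.property_response(curve, 100.0, seed=7)
        b = sd.property_response(curve, 100.0, seed=7)
        c = sd.property_response(curve, 100.0, seed=8)
        assert a == b
        assert a != c

    def test_negative_field_rejected(self):
        curve = sd.MagnetizationCurve("eta", 1.0, -0.08, 200.0)
        with pytest.raises(ValueError):
            sd.property_response(curve, -1.0, seed=0)


class TestReplicateDistribution:
    @pytest.mark.parametrize(
        "total, expected",
        [
            (106, [11] * 6 + [10] * 4),  # static records per property
            (16, [2] * 6 + [1] * 4),     # dynamic records per property
            (10, [1] * 10),
        ],
    )
    def test_even_distribution_extras_to_lowest_levels(self, total, expected):
        assert sd.distribute_replicates(total, 10) == expected

    def test_zero_levels_is_a_config_error(self):
        with pytest.raises(ValueError):
            sd.distribute_replicates(5, 0)


class TestStudyDataset:
    def test_study_scale_counts(self, study_records):
        by_domain = Counter(m.domain for m in study_records)
        assert by_domain["dynamic"] == 64
        assert by_domain["static"] == 424
        per = Counter((m.property, m.domain) for m in study_records)
        for prop in sd.PROPERTIES:
            assert per[(prop, "static")] == 106
            assert per[(prop, "dynamic")] == 16

    def test_same_seed_gives_identical_records(self):
        a = sd.generate_study_dataset(sd.study_preset(seed=5))
        b = sd.generate_study_dataset(sd.study_preset(seed=5))
        assert a == b

    def test_different_seeds_differ(self):
        a = sd.generate_study_dataset(sd.study_preset(seed=5))
        b = sd.generate_study_dataset(sd.study_preset(seed=6))
        assert a != b

    def test_values_respect_physical_ranges(self, study_records):
        for m in study_records:
            if m.property == "pH":
                assert 0.0 < m.value < 14.0
            else:
                assert m.value > 0.0
            assert m.field_mT in sd.FIELD_GRID_MT

    def test_replicate_noise_sd_matches_configuration(self):
        # 10,000 replicates at one level: empirical sd within 20% of noise_sd
        curve = sd.MagnetizationCurve("sigma", 0.072, -0.004, 150.0, 0.0, 0.001)
        config = sd.GeneratorConfig(
            curves={("sigma", "static"): curve},
            reps={("sigma", "static"): 10_000},
            field_levels=[100.0],
            seed=11,
        )
        values = np.array([m.value for m in sd.generate_study_dataset(config)])
        assert len(values) == 10_000
        assert abs(values.std() - 0.001) / 0.001 < 0.2

    def test_static_dynamic_level_means_differ(self, study_records):
        # the cross-domain shift is nonzero and measurable
        sigma = sd.filter_records(study_records, property="sigma")
        shifts = []
        for level in sd.FIELD_GRID_MT:
            stat = [m.value for m in sigma if m.domain == "static" and m.field_mT == level]
            dyn = [m.value for m in sigma if m.domain == "dynamic" and m.field_mT == level]
            shifts.append(abs(np.mean(stat) - np.mean(dyn)))
        assert np.mean(shifts) > 0.0005


class TestCsvRoundTrip:
    def test_round_trip_preserves_records(self, tmp_path, study_records):
        path = tmp_path / "data.csv"
        sd.write_csv(study_records, path)
        back = sd.read_csv(path)
        key = lambda m: (m.property, m.domain, m.field_mT, m.replicate)
        assert sorted(back, key=key) == sorted(study_records, key=key)
        header = path.read_text(encoding="utf-8").splitlines()[0]
        assert header == "property,field_mT,domain,replicate,value"

    def test_deterministic_row_order(self, study_records):
        frame = sd.records_to_frame(study_records)
        assert list(frame.columns) == sd.CSV_COLUMNS
        # property blocks in canonical order, domains ordered within property
        firsts = frame.drop_duplicates("property")["property"].tolist()
        assert firsts == list(sd.PROPERTIES)

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="missing columns"):
            sd.frame_to_records(pd.DataFrame({"property": ["sigma"]}))
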