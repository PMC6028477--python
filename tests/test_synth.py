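"""Replicate expansion, normalization, splitting, benchmark surfaces."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootmedia.media import ION_ORDER, IonProfile
from rootmedia.synth import (
    NormalizationSpec,
    SplitSpec,
    TreatmentRecord,
    benchmark_surface,
    expand_replicates,
    split,
    treatments_from_reference,
)


@pytest.fixture(scope="module")
def treatments(reference_table):
    return treatments_from_reference(reference_table)


class TestExpandReplicates:
    def test_fixture_expands_to_216_rows(self, treatments):
        rows = expand_replicates(treatments, "R%", seed=0)
        assert len(rows) == 216
        assert rows.groupby("code").size().eq(6).all()

    def test_deterministic_given_seed(self, treatments):
        a = expand_replicates(treatments, "RN", seed=42)
        b = expand_replicates(treatments, "RN", seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = expand_replicates(treatments, "RN", seed=43)
        assert not np.allclose(a["value"], c["value"])

    def test_zero_se_gives_exact_means(self):
        t = TreatmentRecord(
            1, IonProfile(40, 20, 15, 2, 1), means={"RN": 8.17}, ses={"RN": 0.0}
        )
        rows = expand_replicates([t], "RN", seed=0)
        assert np.all(rows["value"] == 8.17)

    def test_values_clamped_to_physical_domain(self, treatments):
        for seed in range(3):
            rpct = expand_replicates(treatments, "R%", seed=seed)["value"]
            assert rpct.between(0.0, 1.0).all()
            dw = expand_replicates(treatments, "DW", seed=seed)["value"]
            assert (dw >= 0.0).all()

    def test_noise_model_grand_mean_matches_reported_mean(self, treatments):
        """Medium 1 RN: the mean of many replicate draws recovers 8.17."""
        medium1 = [t for t in treatments if t.code == 1]
        values = np.concatenate(
            [expand_replicates(medium1, "RN", seed=s)["value"] for s in range(1700)]
        )
        assert len(values) >= 10_000
        assert values.mean() == pytest.approx(8.17, abs=0.05)
        # per-replicate spread is SE * sqrt(6)
        assert values.std() == pytest.approx(0.31 * np.sqrt(6), rel=0.05)

    def test_unknown_response_rejected(self, treatments):
        with pytest.raises(ValueError, match="unknown response"):
            expand_replicates(treatments, "XX", seed=0)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError, match="SE"):
            TreatmentRecord(1, IonProfile(1, 1, 1, 1, 1), means={"RN": 1.0}, ses={"RN": -0.1})


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        df = pd.DataFrame({"value": [2.0, 4.0, 6.0]})
        spec = NormalizationSpec.fit(df, ["value"])
        out = spec.transform(df)["value"].to_numpy()
        assert out == pytest.approx([-1.0, 0.0, 1.0])

    def test_out_of_range_values_map_outside_unit_interval(self):
        spec = NormalizationSpec(minima={"value": 0.0}, maxima={"value": 1.0})
        out = spec.transform(pd.DataFrame({"value": [2.0, -1.0]}))["value"]
        assert out.iloc[0] > 1.0 and out.iloc[1] < -1.0

    @given(
        st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=50).filter(
            lambda v: max(v) > min(v)
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_round_trip_is_identity(self, values):
        df = pd.DataFrame({"value": values})
        spec = NormalizationSpec.fit(df, ["value"])
        back = spec.inverse(spec.transform(df))["value"].to_numpy()
        assert back == pytest.approx(np.asarray(values), rel=1e-9, abs=1e-6)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="max"):
            NormalizationSpec.fit(pd.DataFrame({"value": [1.0, 1.0]}), ["value"])

    def test_serialization_roundtrip(self):
        spec = NormalizationSpec(minima={"k": 9.4}, maxima={"k": 18.79})
        again = NormalizationSpec.from_dict(spec.to_dict())
        assert again.minima == spec.minima and again.maxima == spec.maxima


class TestSplit:
    def test_partition_sizes_and_determinism(self, treatments):
        rows = expand_replicates(treatments, "FW", seed=0)
        spec = SplitSpec(130, 86, seed=5)
        train, test = split(rows, spec)
        assert (len(train), len(test)) == (130, 86)
        train2, test2 = split(rows, spec)
        pd.testing.assert_frame_equal(train, train2)
        pd.testing.assert_frame_equal(test, test2)

    def test_partitions_are_disjoint_and_exhaustive(self, treatments):
        rows = expand_replicates(treatments, "FW", seed=0)
        train, test = split(rows, SplitSpec(130, 86, seed=1))
        union = pd.concat([train, test]).sort_index()
        pd.testing.assert_frame_equal(union, rows)
        assert set(train.index).isdisjoint(test.index)

    def test_both_partitions_cover_most_media(self, treatments):
        rows = expand_replicates(treatments, "FW", seed=0)
        for seed in range(5):
            train, test = split(rows, SplitSpec(130, 86, seed=seed))
            assert train["code"].nunique() >= 30
            assert test["code"].nunique() >= 30

    def test_size_mismatch_rejected(self, treatments):
        rows = expand_replicates(treatments, "FW", seed=0)
        with pytest.raises(ValueError, match="split sizes"):
            split(rows, SplitSpec(100, 100, seed=0))


class TestBenchmarkSurface:
    def test_quadratic_argmax_at_requested_center(self):
        surf = benchmark_surface("quadratic_bowl", seed=0)
        center = surf.bounds.mean(axis=1)
        assert surf.argmax == pytest.approx(center)
        assert surf.func(center[None, :])[0] == pytest.approx(surf.maximum)
        # strictly lower away from the maximum
        off = center * 1.05
        assert surf.func(off[None, :])[0] < surf.maximum

    def test_zero_noise_sampled_means_lie_on_surface(self):
        surf = benchmark_surface("quadratic_bowl", params={"se": 0.0}, seed=3)
        rows = expand_replicates(surf.treatments, "R%", seed=0)
        ions = rows[list(ION_ORDER)].to_numpy()
        expected = np.clip(surf.func(ions), 0.0, 1.0)
        assert rows["value"].to_numpy() == pytest.approx(expected)

    def test_table6_like_maximum_within_observed_response_range(self):
        surf = benchmark_surface("table6_like", seed=0)
        grid = np.random.default_rng(0).uniform(
            surf.bounds[:, 0], surf.bounds[:, 1], size=(4000, 5)
        )
        values = surf.func(grid)
        assert values.max() <= surf.maximum + 1e-9
        assert 0.0 < surf.maximum <= 1.0

    def test_argmax_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            benchmark_surface("quadratic_bowl", params={"center": np.full(5, 1e4)})

    def test_inactive_ion_does_not_affect_surface(self):
        active = np.array([True, True, True, True, False])
        surf = benchmark_surface("quadratic_bowl", params={"active": active}, seed=0)
        X = np.tile(surf.bounds.mean(axis=1), (2, 1))
        X[1, 4] = surf.bounds[4, 0]  # move only Cl-
        v = surf.func(X)
        assert v[0] == pytest.approx(v[1])
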