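"""Ellipsoid volumetrics, species averaging, log scaling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seasonbrain import (
    ellipsoid_volume,
    log_scale,
    rest_of_brain,
    species_means,
    structure_volume,
)
from seasonbrain.morphometrics import REGIONS, STRUCTURES, individual_volumes

dims = st.floats(min_value=0.05, max_value=50.0, allow_nan=False)


class TestEllipsoidVolume:
    def test_unit_dimensions(self):
        assert ellipsoid_volume(1, 1, 1) == pytest.approx(math.pi / 8.58, rel=1e-12)
        assert ellipsoid_volume(1, 1, 1) == pytest.approx(0.366153, abs=1e-5)

    def test_direct_reevaluation(self):
        # independent evaluation of L*W*H*pi/(6*1.43) at (4.58, 3.20, 2.10)
        expected = 4.58 * 3.20 * 2.10 * math.pi / 8.58
        assert ellipsoid_volume(4.58, 3.20, 2.10) == pytest.approx(expected, rel=1e-14)
        assert ellipsoid_volume(4.58, 3.20, 2.10) == pytest.approx(11.269, abs=1e-3)

    @settings(deadline=None, derandomize=True)
    @given(L=dims, W=dims, H=dims)
    def test_cubic_scaling(self, L, W, H):
        assert ellipsoid_volume(2 * L, 2 * W, 2 * H) == pytest.approx(
            8 * ellipsoid_volume(L, W, H), rel=1e-12
        )

    @settings(deadline=None, derandomize=True)
    @given(L=dims, W=dims, H=dims, f=st.floats(min_value=1.01, max_value=3.0))
    def test_strictly_increasing_in_each_dimension(self, L, W, H, f):
        v = ellipsoid_volume(L, W, H)
        assert ellipsoid_volume(f * L, W, H) > v
        assert ellipsoid_volume(L, f * W, H) > v
        assert ellipsoid_volume(L, W, f * H) > v

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, -2, 1), (1, 1, 0)])
    def test_nonpositive_dimension_rejected(self, bad):
        with pytest.raises(ValueError):
            ellipsoid_volume(*bad)


class TestStructureVolume:
    def test_unpaired_brain_not_doubled(self):
        assert structure_volume(1, 1, 1, structure="brain") == pytest.approx(
            math.pi / 8.58
        )

    def test_paired_optic_tectum_doubled(self):
        assert structure_volume(1, 1, 1, structure="optic_tectum") == pytest.approx(
            2 * math.pi / 8.58
        )

    @pytest.mark.parametrize("s", STRUCTURES)
    def test_paired_vs_unpaired_exact_factor(self, s):
        from seasonbrain.morphometrics import PAIRED

        v = structure_volume(2.3, 1.1, 0.9, structure=s)
        base = ellipsoid_volume(2.3, 1.1, 0.9)
        assert v == pytest.approx(2 * base if s in PAIRED else base, rel=1e-12)

    def test_brain_cannot_be_flagged_paired(self):
        with pytest.raises(ValueError, match="paired"):
            structure_volume(1, 1, 1, structure="brain", paired=True)


class TestLogScale:
    def test_reference_points(self):
        assert log_scale(1.0) == pytest.approx(3.0, abs=1e-12)
        assert log_scale(0.001) == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(x=st.floats(min_value=1e-6, max_value=1e6))
    def test_round_trip_inverse(self, x):
        assert 10 ** log_scale(x) / 1000.0 == pytest.approx(x, rel=1e-12)

    def test_monotone_preserves_ordering(self):
        v = np.array([0.002, 0.4, 3.0, 117.0])
        assert np.all(np.diff(log_scale(v)) > 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_scale(0.0)


class TestRestOfBrain:
    def test_simple_difference(self):
        assert rest_of_brain(10.0, 4.0) == pytest.approx(6.0)

    def test_small_region_limit(self):
        assert rest_of_brain(10.0, 1e-9) == pytest.approx(10.0, rel=1e-8)

    def test_region_at_least_brain_rejected(self):
        with pytest.raises(ValueError):
            rest_of_brain(10.0, 10.0)

    def test_bookkeeping_identity(self, analysis_inputs):
        """brain - rest_of_brain sums back to the region volumes."""
        traits, *_ = analysis_inputs
        sp = species_means(traits)
        brain = sp["brain_volume"].to_numpy()
        total = sum(
            brain - rest_of_brain(brain, sp[f"{r}_volume"].to_numpy())
            for r in REGIONS
        )
        np.testing.assert_allclose(
            total, sum(sp[f"{r}_volume"].to_numpy() for r in REGIONS), rtol=1e-12
        )


def _individuals(rows):
    base = {
        "individual_id": [f"i{k}" for k in range(len(rows))],
        "svl_mm": 50.0,
        "mass_mg": 9000.0,
    }
    df = pd.DataFrame(rows)
    for k, v in base.items():
        if k not in df:
            df[k] = v
    for s in STRUCTURES:
        if f"{s}_volume" not in df:
            df[f"{s}_volume"] = 30.0 if s == "brain" else 2.0
    return df


class TestSpeciesMeans:
    def test_single_individual_passthrough(self):
        df = _individuals([{"species": "a", "brain_volume": 12.5}])
        out = species_means(individual_volumes(df))
        assert out.loc["a", "brain_volume"] == pytest.approx(12.5)
        assert out.loc["a", "n_individuals"] == 1

    def test_arithmetic_mean_on_raw_scale(self):
        df = _individuals(
            [{"species": "a", "brain_volume": 10.0}, {"species": "a", "brain_volume": 20.0}]
        )
        out = species_means(individual_volumes(df))
        assert out.loc["a", "brain_volume"] == pytest.approx(15.0)

    def test_weighted_sum_conservation(self, analysis_inputs):
        """Sum over species of mean x n equals the sum over individuals."""
        traits, *_ = analysis_inputs
        sp = species_means(traits)
        assert len(sp) == 30 and sp["n_individuals"].sum() == 171
        for col in ["svl_mm", "brain_volume", "optic_tectum_volume"]:
            np.testing.assert_allclose(
                (sp[col] * sp["n_individuals"]).sum(), traits[col].sum(), rtol=1e-10
            )

    def test_conflicting_locality_rejected(self):
        df = _individuals(
            [
                {"species": "a", "altitude_m": 100.0},
                {"species": "a", "altitude_m": 200.0},
            ]
        )
        with pytest.raises(ValueError, match="altitude"):
            species_means(individual_volumes(df))


class TestIndividualVolumes:
    def test_lwh_converted_with_doubling(self):
        df = _individuals([{"species": "a"}]).drop(columns=["optic_tectum_volume"])
        for d, v in zip(("L", "W", "H"), (2.0, 1.5, 1.0)):
            df[f"optic_tectum_{d}"] = v
        out = individual_volumes(df)
        assert out["optic_tectum_volume"].iloc[0] == pytest.approx(
            2 * ellipsoid_volume(2.0, 1.5, 1.0)
        )

    def test_precomputed_volume_wins_with_warning(self, caplog):
        df = _individuals([{"species": "a", "brain_volume": 30.0}])
        for d in ("L", "W", "H"):
            df[f"brain_{d}"] = 1.0
        with caplog.at_level("WARNING", logger="seasonbrain.morphometrics"):
            out = individual_volumes(df)
        assert out["brain_volume"].iloc[0] == pytest.approx(30.0)
        assert any("precomputed" in r.message for r in caplog.records)

    def test_missing_structure_rejected(self):
        df = _individuals([{"species": "a"}]).drop(columns=["cerebellum_volume"])
        with pytest.raises(ValueError, match="cerebellum"):
            individual_volumes(df)
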