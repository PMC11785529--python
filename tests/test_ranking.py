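"""Fence, Wasserstein distance, Z-scores and ensemble ranking."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from nppeval.errors import ValidationError
from nppeval.grid import BiomeMask
from nppeval.ranking import (
    biome_weighted_emd,
    delta_npp_by_rank,
    emd_1d,
    iqr_fence,
    rank_models,
    zscore,
)
from nppeval.synthetic import DRIVERS
from tests.oracles import emd_bruteforce


class TestIqrFence:
    def test_extreme_outlier_removed(self):
        vals = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 1000.0])
        out = iqr_fence(vals, k=3.0)
        np.testing.assert_array_equal(np.sort(out), np.arange(1.0, 9.0))

    def test_all_equal_sample_unchanged(self):
        vals = np.full(10, 3.3)
        np.testing.assert_array_equal(iqr_fence(vals), vals)

    def test_sample_inside_fence_unchanged(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=50)  # normal sample: k=3 fence removes nothing here
        out = iqr_fence(vals)
        assert out.size == vals.size

    def test_small_sample_returned_unfiltered(self):
        vals = np.array([1.0, 2.0, 5000.0])
        np.testing.assert_array_equal(iqr_fence(vals), vals)


class TestEmd1d:
    def test_identical_samples_zero(self):
        u = np.array([1.0, 2.0, 5.0])
        assert emd_1d(u, u) == 0.0

    def test_point_masses(self):
        assert emd_1d(np.array([0.0]), np.array([1.0])) == pytest.approx(1.0)

    def test_shifted_quartet(self):
        u = np.array([1.0, 2, 3, 4])
        v = np.array([2.0, 3, 4, 5])
        assert emd_1d(u, v) == pytest.approx(1.0, abs=1e-12)
        assert emd_bruteforce(u, v) == pytest.approx(1.0, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            emd_1d(np.array([]), np.array([1.0]))

    @given(
        u=st.lists(st.floats(-50, 50), min_size=1, max_size=20),
        v=st.lists(st.floats(-50, 50), min_size=1, max_size=20),
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_bruteforce_cdf_integration(self, u, v):
        u, v = np.asarray(u), np.asarray(v)
        assert emd_1d(u, v) == pytest.approx(emd_bruteforce(u, v), abs=1e-10)
        assert emd_1d(u, v) == pytest.approx(emd_1d(v, u), abs=1e-12)  # symmetry


def _maps_from_samples(samples: dict[str, np.ndarray]) -> xr.Dataset:
    """Wrap per-driver 1-D coefficient samples as a (1, n) coefficient map."""
    n = len(next(iter(samples.values())))
    data = {}
    for d in DRIVERS:
        data[f"beta_{d}"] = (("lat", "lon"), samples[d].reshape(1, n))
        data[f"sig_{d}"] = (("lat", "lon"), np.ones((1, n), dtype=bool))
    return xr.Dataset(data, coords={"lat": [0.0], "lon": np.arange(n, dtype=float)})


class TestBiomeWeightedEmd:
    def _biomes(self, n, proportions):
        labels = np.zeros((1, n), dtype=int)
        edges = np.cumsum([0] + [int(round(p * n)) for p in proportions])
        for b in range(len(proportions)):
            labels[0, edges[b] : edges[b + 1]] = b
        return BiomeMask(labels=labels, proportions=dict(enumerate(proportions)))

    def test_weighted_mean_of_biome_distances(self):
        rng = np.random.default_rng(1)
        n = 40
        biomes = self._biomes(n, [0.75, 0.25])
        base = rng.normal(size=n)
        shifted = base.copy()
        shifted[biomes.labels[0] == 0] += 1.0  # biome EMDs {1, 3}
        shifted[biomes.labels[0] == 1] += 3.0
        obs = _maps_from_samples({d: base for d in DRIVERS})
        mod = _maps_from_samples({d: shifted for d in DRIVERS})
        out = biome_weighted_emd(mod, obs, biomes)
        for d in DRIVERS:
            assert out[d] == pytest.approx(1.5, abs=1e-9)

    def test_identical_maps_zero_distance(self):
        rng = np.random.default_rng(2)
        samples = {d: rng.normal(size=30) for d in DRIVERS}
        maps = _maps_from_samples(samples)
        out = biome_weighted_emd(maps, maps, self._biomes(30, [0.5, 0.5]))
        assert all(v == 0.0 for v in out.values())

    def test_uniform_shift_recovers_magnitude(self):
        rng = np.random.default_rng(3)
        base = {d: rng.normal(size=60) for d in DRIVERS}
        shift = {"sst": 0.3, "chl": -0.2, "mld": 0.05}
        shifted = {d: base[d] + shift[d] for d in DRIVERS}
        out = biome_weighted_emd(
            _maps_from_samples(shifted),
            _maps_from_samples(base),
            self._biomes(60, [0.4, 0.6]),
        )
        for d in DRIVERS:
            assert out[d] == pytest.approx(abs(shift[d]), abs=1e-8)

    def test_empty_biome_dropped_and_renormalised(self):
        rng = np.random.default_rng(4)
        base = {d: rng.normal(size=20) for d in DRIVERS}
        obs = _maps_from_samples(base)
        mod = _maps_from_samples({d: base[d] + 1.0 for d in DRIVERS})
        # mask out all model significance in biome 1
        biomes = self._biomes(20, [0.5, 0.5])
        for d in DRIVERS:
            mod[f"sig_{d}"][0, biomes.labels[0] == 1] = False
        out = biome_weighted_emd(mod, obs, biomes)
        for d in DRIVERS:
            assert out[d] == pytest.approx(1.0, abs=1e-8)

    def test_no_overlapping_biome_rejected(self):
        rng = np.random.default_rng(5)
        base = {d: rng.normal(size=10) for d in DRIVERS}
        obs = _maps_from_samples(base)
        mod = _maps_from_samples(base)
        for d in DRIVERS:
            mod[f"sig_{d}"][:] = False
        with pytest.raises(ValidationError):
            biome_weighted_emd(mod, obs, self._biomes(10, [1.0]))

    @pytest.mark.parametrize("alpha", [0.5, 2.0, 10.0])
    def test_scale_equivariance(self, alpha):
        rng = np.random.default_rng(6)
        base = {d: rng.normal(size=30) for d in DRIVERS}
        other = {d: rng.normal(size=30) for d in DRIVERS}
        biomes = self._biomes(30, [0.5, 0.5])
        d1 = biome_weighted_emd(_maps_from_samples(other), _maps_from_samples(base), biomes)
        d2 = biome_weighted_emd(
            _maps_from_samples({d: alpha * other[d] for d in DRIVERS}),
            _maps_from_samples({d: alpha * base[d] for d in DRIVERS}),
            biomes,
        )
        for d in DRIVERS:
            assert d2[d] == pytest.approx(alpha * d1[d], rel=1e-9)


class TestZscore:
    def test_value_at_mean_is_zero(self):
        assert zscore(4.0, np.array([2.0, 4.0, 6.0])) == 0.0

    def test_sample_sigma_example(self):
        assert zscore(6.0, np.array([2.0, 4.0, 6.0])) == pytest.approx(1.0)

    def test_degenerate_ensemble_zero(self):
        assert zscore(5.0, np.full(4, 5.0)) == 0.0

    def test_small_ensemble_rejected(self):
        with pytest.raises(ValidationError):
            zscore(1.0, np.array([1.0]))


def _emd_table(emds_by_model, algorithm="alg", assessment=1):
    rows = []
    for model, per_driver in emds_by_model.items():
        for d, v in zip(DRIVERS, per_driver):
            rows.append(
                dict(model=model, algorithm=algorithm, assessment=assessment, driver=d, emd=v)
            )
    return pd.DataFrame(rows)


class TestRankModels:
    def test_three_model_example(self):
        """EMD means {1,2,3} with zero spread: combined Z {-0.5, 0, 0.5}."""
        table = _emd_table({"a": [1, 1, 1], "b": [2, 2, 2], "c": [3, 3, 3]})
        out = rank_models(table)
        z = out.set_index("model")["combined_z"]
        assert z["a"] == pytest.approx(-0.5)
        assert z["b"] == pytest.approx(0.0)
        assert z["c"] == pytest.approx(0.5)
        assert list(out.sort_values("rank")["model"]) == ["a", "b", "c"]

    def test_identical_models_tie_break_by_model_id(self):
        table = _emd_table({"m2": [1, 2, 3], "m1": [1, 2, 3], "m3": [1, 2, 3]})
        out = rank_models(table)
        assert np.allclose(out["combined_z"], 0.0)
        assert list(out.sort_values("rank")["model"]) == ["m1", "m2", "m3"]

    def test_rank_is_permutation_and_order_invariant(self):
        rng = np.random.default_rng(7)
        emds = {f"m{k}": rng.random(3).tolist() for k in range(6)}
        out1 = rank_models(_emd_table(emds))
        shuffled = dict(reversed(list(emds.items())))
        out2 = rank_models(_emd_table(shuffled))
        r1 = out1.set_index("model")["rank"]
        r2 = out2.set_index("model")["rank"]
        assert sorted(r1) == list(range(1, 7))
        assert (r1.sort_index() == r2.sort_index()).all()

    def test_combined_z_has_zero_ensemble_mean(self):
        rng = np.random.default_rng(8)
        emds = {f"m{k}": rng.random(3).tolist() for k in range(9)}
        out = rank_models(_emd_table(emds))
        assert abs(out["combined_z"].mean()) < 1e-12

    def test_model_missing_driver_excluded(self):
        table = _emd_table({"a": [1, 1, 1], "b": [2, 2, 2], "c": [3, 3, 3]})
        table = table[~((table["model"] == "c") & (table["driver"] == "mld"))]
        out = rank_models(table)
        assert set(out["model"]) == {"a", "b"}

    def test_delta_npp_by_rank_errorbar_rule(self):
        frames = []
        for assessment in (1, 2, 3):
            # model order flips between b and c at rank 2/3; a always rank 1
            order = {"a": [0.1] * 3, "b": [1 + 0.1 * assessment] * 3,
                     "c": [2 - 0.4 * assessment] * 3}
            frames.append(_emd_table(order, assessment=assessment))
        table = pd.concat(frames)
        rankings = rank_models(table, delta_npps={"a": -1.0, "b": 0.5, "c": 2.0})
        byrank = delta_npp_by_rank(rankings).set_index("rank")
        assert np.isnan(byrank.loc[1, "delta_npp_std"])  # same model every time
        assert byrank.loc[2, "n_models"] > 1
        assert np.isfinite(byrank.loc[2, "delta_npp_std"])
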