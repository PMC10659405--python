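"""Hierarchical bootstrap: resampling contract, P_boot, joint distributions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitoboot.hierboot import (
    METRIC_COUNT,
    METRIC_MEDIAN_AREA,
    BootstrapConfig,
    HierarchicalDataset,
    joint_distribution,
    p_boot,
    resample_once,
    run_bootstrap,
    sampling_size_test,
)
from mitoboot.synthetic import GeneratorParams, generate_hierarchy


def make_dataset(
    n_animals=2, n_sections=2, n_tiles=4, objs_per_tile=3, area=1.0, seed=0
):
    """Small single-genotype/single-layer dataset with constant or noisy areas."""
    rng = np.random.default_rng(seed)
    tile_rows, obj_rows = [], []
    for a in range(n_animals):
        for s in range(n_sections):
            for t in range(n_tiles):
                tid = f"a{a}s{s}t{t}"
                tile_rows.append(
                    {
                        "tile_id": tid,
                        "section_id": f"a{a}s{s}",
                        "animal_id": f"a{a}",
                        "genotype": "CTL",
                        "layer": "SR",
                        "mito_count": objs_per_tile,
                    }
                )
                for j in range(objs_per_tile):
                    obj_rows.append(
                        {
                            "object_id": f"{tid}o{j}",
                            "tile_id": tid,
                            "area_um2": area if area is not None else rng.uniform(0.1, 2),
                        }
                    )
    return HierarchicalDataset(pd.DataFrame(tile_rows), pd.DataFrame(obj_rows))


class TestDatasetValidation:
    def test_duplicate_tiles_rejected(self):
        tiles = pd.DataFrame(
            {
                "tile_id": ["t0", "t0"],
                "section_id": ["s", "s"],
                "animal_id": ["a", "a"],
                "genotype": ["CTL", "CTL"],
                "layer": ["SR", "SR"],
                "mito_count": [1, 1],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            HierarchicalDataset(tiles)

    def test_orphan_objects_rejected(self):
        ds = make_dataset()
        with pytest.raises(ValueError, match="unknown tiles"):
            HierarchicalDataset(
                ds.tiles, pd.DataFrame({"tile_id": ["nope"], "area_um2": [1.0]})
            )

    def test_missing_group_named_in_error(self):
        ds = make_dataset()
        with pytest.raises(ValueError, match="cKO"):
            ds.group_arrays("cKO", "SR")

    def test_area_metric_requires_objects(self):
        ds = HierarchicalDataset(make_dataset().tiles)  # tiles only
        cfg = BootstrapConfig(metric=METRIC_MEDIAN_AREA, n_reps=2)
        with pytest.raises(ValueError, match="objects"):
            run_bootstrap(ds, cfg)


class TestResampling:
    def test_constant_dataset_median_is_constant(self):
        ds = make_dataset(area=1.0)
        for metric in (METRIC_MEDIAN_AREA, METRIC_COUNT):
            cfg = BootstrapConfig(metric=metric, n_reps=50, seed=1)
            res = run_bootstrap(ds, cfg)[("CTL", "SR")]
            expected = 1.0 if metric == METRIC_MEDIAN_AREA else 3.0
            assert np.all(res.medians == expected)

    def test_default_draw_counts(self):
        """One repetition pools 3*3*50 = 450 tiles and 450*100 = 45,000 objects."""
        ds = make_dataset()
        rng = np.random.default_rng(0)
        _, tiles = resample_once(
            ds, ("CTL", "SR"), BootstrapConfig(metric=METRIC_COUNT),
            rng, return_values=True,
        )
        assert len(tiles) == 450
        _, objs = resample_once(
            ds, ("CTL", "SR"), BootstrapConfig(metric=METRIC_MEDIAN_AREA),
            rng, return_values=True,
        )
        assert len(objs) == 45_000

    def test_determinism(self):
        ds = make_dataset(area=None, seed=4)
        cfg = BootstrapConfig(metric=METRIC_MEDIAN_AREA, n_reps=25, seed=42)
        a = run_bootstrap(ds, cfg)[("CTL", "SR")].medians
        b = run_bootstrap(ds, cfg)[("CTL", "SR")].medians
        np.testing.assert_array_equal(a, b)

    def test_null_pboot_with_zero_random_effects(self):
        """Two groups from one distribution, no cluster effects: p_boot is
        calibrated, i.e. its mean over seeds is near 0.5 (per seed it behaves
        like a p-value and is broadly distributed)."""
        pbs = []
        for seed in range(20):
            params = GeneratorParams.null(seed=seed, animal_cv=0.0, section_cv=0.0)
            ds = generate_hierarchy(params, with_objects=False)
            cfg = BootstrapConfig(metric=METRIC_COUNT, n_reps=500, seed=seed + 10)
            res = run_bootstrap(ds, cfg, groups=[("CTL", "SLM"), ("cKO", "SLM")])
            pbs.append(
                p_boot(res[("CTL", "SLM")].medians, res[("cKO", "SLM")].medians)
            )
        assert 0.4 <= np.mean(pbs) <= 0.6


class TestPBoot:
    def test_examples(self):
        assert p_boot([2, 3], [1, 1]) == 1.0
        assert p_boot([1, 1], [1, 1]) == 0.5
        assert p_boot([1, 2, 3], [2, 2, 2]) == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            p_boot([1, 2], [1])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    def test_antisymmetry(self, values, seed):
        rng = np.random.default_rng(seed)
        a = np.array(values, dtype=float)
        b = rng.permutation(a)
        assert p_boot(a, b) + p_boot(b, a) == pytest.approx(1.0, abs=0)


class TestJointDistribution:
    def test_bin_counts_per_metric(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(200), rng.random(200)
        assert joint_distribution(a, b, METRIC_COUNT).hist.shape == (10, 10)
        assert joint_distribution(a, b, METRIC_MEDIAN_AREA).hist.shape == (100, 100)

    def test_mass_conservation(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=500), rng.normal(size=500)
        jd = joint_distribution(a, b, METRIC_MEDIAN_AREA)
        assert jd.hist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_identical_arrays_on_diagonal(self):
        a = np.linspace(0, 1, 100)
        jd = joint_distribution(a, a, METRIC_COUNT)
        assert jd.p_boot == 0.5
        off_diag = jd.hist - np.diag(np.diag(jd.hist))
        assert off_diag.sum() == pytest.approx(0.0, abs=1e-12)

    def test_zero_range_degenerates_to_single_bin(self):
        a = np.full(10, 2.0)
        jd = joint_distribution(a, a, METRIC_MEDIAN_AREA)
        assert jd.hist.shape == (1, 1) and jd.hist[0, 0] == 1.0


class TestSamplingSizeTest:
    def test_default_candidates_and_shape(self):
        ds = make_dataset(n_tiles=6)
        table = sampling_size_test(
            ds, "tiles", n_reps=20, n_runs=2, seed=0, groups=[("CTL", "SR")]
        )
        assert sorted(table["size"]) == [20, 32, 50]
        assert {"grand_median_sd", "rep_median_sd"} <= set(table.columns)
        table2 = sampling_size_test(
            ds, "mitochondria", n_reps=10, n_runs=2, seed=0, groups=[("CTL", "SR")]
        )
        assert sorted(table2["size"]) == [5, 10, 20, 50, 100]

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            sampling_size_test(make_dataset(), "animals")
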