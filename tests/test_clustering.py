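import numpy as np
import pytest

from morphatlas.clustering import (
    SamplingParams,
    cut_zones,
    hierarchical_cluster,
    reconstruct_zone_volume,
    sample_for_clustering,
    zone_profiles,
)
from morphatlas.core_io import LabelVolume
from morphatlas.signal_mapping import SignalVolume
from morphatlas.synthetic import PhantomSpec, make_phantom, make_zoned_signal


def full_cube_label(n=36, spacing=1.0):
    return LabelVolume(np.ones((n, n, n), dtype=np.uint8), (spacing,) * 3)


def uniform_channel(label, value=1.0, name="c"):
    return SignalVolume(
        np.full(label.shape, value) * label.data, label.spacing,
        valid_mask=label.data.astype(bool), channel_name=name,
    )


@pytest.fixture(scope="module")
def planted_zones():
    # 36³ voxels at 1.5 µm = 54³ µm: the three x-slabs land exactly on the
    # 18 µm supervoxel grid, so every sampled row has a single truth zone
    label = full_cube_label(36, 1.5)
    means = np.array([[1.0, 5.0], [5.0, 1.0], [9.0, 9.0]])
    noise_sd = 0.1  # 10x separation: planted gaps are >= 4, noise sd 0.1 per voxel
    channels, truth = make_zoned_signal(label, 3, means, noise_sd=noise_sd, seed=4)
    return label, channels, truth, means, noise_sd


class TestSampling:
    def test_default_edge_is_18(self):
        assert SamplingParams().edge == 18.0

    def test_cube_36um_edge18_gives_8_rows(self):
        label = full_cube_label(36, 1.0)
        table = sample_for_clustering([uniform_channel(label)], label)
        assert table.n_rows == 8  # 2 x 2 x 2 grid
        np.testing.assert_array_equal(np.sort(table.grid_indices, axis=0)[[0, -1]], [[0, 0, 0], [1, 1, 1]])

    def test_uniform_channel_rows_all_one(self):
        label = full_cube_label()
        table = sample_for_clustering([uniform_channel(label, 1.0)], label)
        np.testing.assert_allclose(table.values, 1.0)

    def test_coverage_filter(self):
        # slab fills 12 of each 18-voxel cell: coverage 2/3 passes 0.5, fails 0.95
        data = np.zeros((36, 36, 36), dtype=np.uint8)
        data[:, :, :12] = 1
        label = LabelVolume(data, (1.0, 1.0, 1.0))
        table_loose = sample_for_clustering(
            [uniform_channel(label)], label, SamplingParams(min_coverage=0.5)
        )
        assert table_loose.n_rows == 4
        with pytest.raises(ValueError):
            sample_for_clustering(
                [uniform_channel(label)], label, SamplingParams(min_coverage=0.95)
            )

    def test_empty_consensus(self):
        label = LabelVolume(np.zeros((8, 8, 8), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(ValueError):
            sample_for_clustering([uniform_channel(full_cube_label(8))], label)

    def test_tsv_export(self, tmp_path):
        label = full_cube_label()
        table = sample_for_clustering([uniform_channel(label)], label)
        table.write_tsv(tmp_path / "t.cdt.txt")
        lines = (tmp_path / "t.cdt.txt").read_text().splitlines()
        assert lines[0].startswith("UID\tNAME\tGWEIGHT")
        assert len(lines) == table.n_rows + 2


class TestHierarchicalCluster:
    def _table(self, values):
        from morphatlas.clustering import ClusterTable

        values = np.asarray(values, dtype=float)
        n = len(values)
        return ClusterTable(
            grid_indices=np.array([[i, 0, 0] for i in range(n)]),
            centroids_um=np.zeros((n, 3)),
            values=values,
            channels=[f"c{j}" for j in range(values.shape[1])],
            grid_origin=(0, 0, 0),
            cell_vox=(1, 1, 1),
            volume_shape=(n, 1, 1),
        )

    def test_two_rows_single_merge_at_distance(self):
        table = self._table([[0.0, 0.0], [3.0, 4.0]])
        dend = hierarchical_cluster(table)
        assert len(dend.merges) == 1
        assert dend.merges[0, 2] == pytest.approx(5.0)

    def test_n_minus_one_merges(self, rng):
        table = self._table(rng.random((17, 3)))
        dend = hierarchical_cluster(table)
        assert len(dend.merges) == 16
        assert dend.leaf_count == 17

    def test_complete_linkage_heights_nondecreasing(self, rng):
        table = self._table(rng.random((20, 4)))
        dend = hierarchical_cluster(table)
        assert np.all(np.diff(dend.merges[:, 2]) >= 0)

    def test_final_merge_separates_two_tight_groups(self, rng):
        a = rng.normal(0.0, 0.01, (10, 3))
        b = rng.normal(0.0, 0.01, (10, 3)) + 2.0  # 100x the internal spread
        table = self._table(np.vstack([a, b]))
        dend = hierarchical_cluster(table)
        zones = cut_zones(dend, 2)
        groups = {tuple(sorted(np.flatnonzero(zones.row_zones == z))) for z in (1, 2)}
        assert groups == {tuple(range(10)), tuple(range(10, 20))}

    def test_missing_rows_dropped_with_warning(self, caplog):
        vals = np.array([[0.0, 0.0], [1.0, np.nan], [3.0, 4.0], [3.1, 4.1]])
        with caplog.at_level("WARNING"):
            dend = hierarchical_cluster(self._table(vals))
        assert dend.leaf_count == 3
        assert 1 not in dend.row_indices

    def test_single_row_errors(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(self._table([[1.0, 2.0]]))

    def test_permutation_invariance_up_to_relabelling(self, rng):
        vals = np.vstack([rng.normal(m, 0.05, (8, 2)) for m in (0.0, 3.0, 6.0)])
        table = self._table(vals)
        z1 = cut_zones(hierarchical_cluster(table), 3)
        perm = rng.permutation(len(vals))
        z2 = cut_zones(hierarchical_cluster(self._table(vals[perm])), 3)
        back = np.empty_like(z2.row_zones)
        back[perm] = z2.row_zones
        # same partition: zone labels agree after best matching
        for z in (1, 2, 3):
            members = np.flatnonzero(z1.row_zones == z)
            assert len(set(back[members])) == 1


class TestCutZones:
    def _dend(self, rng, n=12):
        from morphatlas.clustering import ClusterTable

        vals = rng.random((n, 2))
        table = ClusterTable(
            grid_indices=np.array([[i, 0, 0] for i in range(n)]),
            centroids_um=np.zeros((n, 3)),
            values=vals,
            channels=["a", "b"],
            grid_origin=(0, 0, 0),
            cell_vox=(1, 1, 1),
            volume_shape=(n, 1, 1),
        )
        return hierarchical_cluster(table)

    def test_k1_all_one_zone(self, rng):
        zones = cut_zones(self._dend(rng), 1)
        assert set(zones.row_zones) == {1}

    def test_k_equals_leaf_count(self, rng):
        dend = self._dend(rng)
        zones = cut_zones(dend, dend.leaf_count)
        assert sorted(zones.row_zones) == list(range(1, dend.leaf_count + 1))

    def test_invalid_k(self, rng):
        dend = self._dend(rng)
        with pytest.raises(ValueError):
            cut_zones(dend, 0)
        with pytest.raises(ValueError):
            cut_zones(dend, dend.leaf_count + 1)

    def test_zone_ids_by_decreasing_size(self, rng):
        vals = np.vstack([rng.normal(0, 0.01, (9, 2)), rng.normal(5, 0.01, (3, 2))])
        from morphatlas.clustering import ClusterTable

        table = ClusterTable(
            grid_indices=np.array([[i, 0, 0] for i in range(12)]),
            centroids_um=np.zeros((12, 3)),
            values=vals,
            channels=["a", "b"],
            grid_origin=(0, 0, 0),
            cell_vox=(1, 1, 1),
            volume_shape=(12, 1, 1),
        )
        zones = cut_zones(hierarchical_cluster(table), 2)
        assert (zones.row_zones == 1).sum() == 9  # bigger cluster gets zone 1


class TestPlantedRecovery:
    def test_zone_recovery_95pct(self, planted_zones):
        label, channels, truth, means, noise_sd = planted_zones
        table = sample_for_clustering(channels, label, SamplingParams(edge=18.0))
        dend = hierarchical_cluster(table)
        zones = cut_zones(dend, 3)
        # majority truth zone per supervoxel row
        lo, cv = table.grid_origin, table.cell_vox
        correct = total = 0
        mapping = {}
        rows_truth = []
        for r in range(table.n_rows):
            g = table.grid_indices[r]
            sl = tuple(slice(lo[a] + g[a] * cv[a], lo[a] + (g[a] + 1) * cv[a]) for a in range(3))
            tz = truth[sl]
            tz = tz[tz > 0]
            rows_truth.append(np.bincount(tz).argmax())
        rows_truth = np.asarray(rows_truth)
        for z in (1, 2, 3):
            members = rows_truth[zones.row_zones[: table.n_rows] == z]
            mapping[z] = np.bincount(members).argmax()
        for r in range(table.n_rows):
            total += 1
            correct += mapping[zones.row_zones[r]] == rows_truth[r]
        assert correct / total >= 0.95

    def test_profiles_near_planted_means(self, planted_zones):
        label, channels, truth, means, noise_sd = planted_zones
        table = sample_for_clustering(channels, label, SamplingParams(edge=18.0))
        zones = cut_zones(hierarchical_cluster(table), 3)
        profiles = zone_profiles(table, zones)
        for z in (1, 2, 3):
            prof = profiles.loc[z].to_numpy()
            planted = means[np.argmin(np.linalg.norm(means - prof, axis=1))]
            n_vox = (zones.row_zones[: table.n_rows] == z).sum() * np.prod(table.cell_vox)
            tol = max(5 * noise_sd / np.sqrt(n_vox), 0.02)
            np.testing.assert_allclose(prof, planted, atol=tol)


class TestZoneProfiles:
    def test_single_zone_equals_column_means(self, rng):
        label = full_cube_label()
        chans = [uniform_channel(label, 2.0, "a"), uniform_channel(label, 3.0, "b")]
        table = sample_for_clustering(chans, label)
        zones = cut_zones(hierarchical_cluster(table), 1)
        prof = zone_profiles(table, zones)
        np.testing.assert_allclose(prof.loc[1].to_numpy(), np.nanmean(table.values, axis=0))

    def test_held_out_channel_identical_profile(self, planted_zones):
        label, channels, truth, _, _ = planted_zones
        table = sample_for_clustering(channels, label, SamplingParams(edge=18.0))
        extra = sample_for_clustering([channels[0]], label, SamplingParams(edge=18.0))
        zones = cut_zones(hierarchical_cluster(table), 3)
        prof = zone_profiles(table, zones, extra=extra)
        np.testing.assert_allclose(
            prof[table.channels[0]].to_numpy(), prof[extra.channels[0]].to_numpy()
        )

    def test_grand_mean_conservation(self, planted_zones):
        label, channels, _, _, _ = planted_zones
        table = sample_for_clustering(channels, label, SamplingParams(edge=18.0))
        zones = cut_zones(hierarchical_cluster(table), 3)
        prof = zone_profiles(table, zones)
        sizes = np.array([(zones.row_zones[: table.n_rows] == z).sum() for z in (1, 2, 3)])
        weighted = (prof.to_numpy() * sizes[:, None]).sum(axis=0) / sizes.sum()
        np.testing.assert_allclose(weighted, table.values.mean(axis=0), rtol=1e-10)


class TestReconstruction:
    def test_single_zone_matches_consensus(self):
        label = full_cube_label()
        table = sample_for_clustering([uniform_channel(label)], label)
        zones = cut_zones(hierarchical_cluster(table), 1)
        zmap = reconstruct_zone_volume(zones, table, label)
        np.testing.assert_array_equal((zmap.data > 0).astype(np.uint8), label.data)
        assert set(np.unique(zmap.data)) == {1}

    def test_round_trip_zone_ids(self, planted_zones):
        label, channels, _, _, _ = planted_zones
        table = sample_for_clustering(channels, label, SamplingParams(edge=18.0))
        zones = cut_zones(hierarchical_cluster(table), 3)
        zmap = reconstruct_zone_volume(zones, table, label)
        lo, cv = table.grid_origin, table.cell_vox
        for r in range(table.n_rows):
            g = table.grid_indices[r]
            sl = tuple(slice(lo[a] + g[a] * cv[a], lo[a] + (g[a] + 1) * cv[a]) for a in range(3))
            cell = zmap.data[sl][label.data[sl].astype(bool)]
            vals = set(np.unique(cell))
            assert vals == {zones.row_zones[r]}

    def test_dropped_rows_zero(self):
        data = np.zeros((36, 36, 36), dtype=np.uint8)
        data[:, :, :20] = 1
        label = LabelVolume(data, (1.0, 1.0, 1.0))
        table = sample_for_clustering(
            [uniform_channel(label)], label, SamplingParams(min_coverage=0.9)
        )
        zones = cut_zones(hierarchical_cluster(table), 1)
        zmap = reconstruct_zone_volume(zones, table, label)
        # cells only partially covered were dropped -> zone 0 there
        assert (zmap.data[:, :, 18:20] == 0).all()
        assert (zmap.data[:, :, :18] == 1).all()
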