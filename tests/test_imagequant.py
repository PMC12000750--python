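"""3-D single-cell quantification: segmentation, masks, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import match_to_truth
from osteochip import (
    AnalysisConfig,
    ImageStack,
    LabelVolume,
    PhenotypeParams,
    assign_cell_territories,
    classify_cell,
    collagen_positive_fraction,
    extracellular_mask,
    generate_cell_stack,
    generate_viability_stack,
    quantify_stack,
    quantify_viability,
    segment_nuclei,
)
from osteochip.errors import (
    InvariantViolationError,
    ShapeMismatchError,
    UndefinedFractionError,
)

VOX = (2.0, 0.42, 0.42)


def _ball_stack(centers_um, radius_um=3.0, shape=(16, 96, 96), value=200.0,
                n_channels=1, roles=None):
    """Render spheres into channel 0 of a fresh stack."""
    vol = np.zeros((n_channels,) + shape, dtype=np.float32)
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * VOX[0],
        np.arange(shape[1]) * VOX[1],
        np.arange(shape[2]) * VOX[2],
        indexing="ij",
    )
    for c in centers_um:
        mask = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= radius_um**2
        vol[0][mask] = value
    return ImageStack(vol, VOX, roles or {"nuclei": 0})


class TestSegmentNuclei:
    def test_empty_channel_gives_zero_objects(self):
        stack = ImageStack(np.zeros((1, 8, 32, 32), dtype=np.float32), VOX,
                           {"nuclei": 0})
        labels = segment_nuclei(stack)
        assert labels.n_objects == 0

    def test_recovers_well_separated_nuclei(self, noiseless_stack):
        """Object count equals the ground-truth cell count and every
        centroid lies within one voxel of its true position (oracle:
        connected components of the noiseless mask)."""
        stack, truth, _ = noiseless_stack
        labels = segment_nuclei(stack)
        assert labels.n_objects == len(truth)
        cents = labels.centroids_um()
        true_c = truth[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy()
        from scipy.spatial import cKDTree

        dist, idx = cKDTree(true_c).query(cents)
        assert len(np.unique(idx)) == len(truth)
        assert np.max(dist) <= max(VOX)  # within one (largest) voxel edge

    def test_watershed_splits_merged_pair(self):
        """Two spheres fused into one blob are split back into two objects
        by the distance-transform watershed (oracle: two seeds placed)."""
        centers = [(16.0, 20.0, 16.0), (16.0, 20.0, 23.0)]  # 7 μm apart, r=4
        stack = _ball_stack(centers, radius_um=4.0)
        binary = np.asarray(stack.channel("nuclei")) > 0
        import scipy.ndimage as ndi

        _, n_blobs = ndi.label(binary, structure=np.ones((3, 3, 3)))
        assert n_blobs == 1  # genuinely merged
        labels = segment_nuclei(stack, min_separation_um=5.0)
        assert labels.n_objects == 2

    def test_min_volume_filter(self):
        stack = _ball_stack([(16.0, 20.0, 20.0)], radius_um=1.0)
        assert segment_nuclei(stack, min_volume_um3=500.0).n_objects == 0
        assert segment_nuclei(stack, min_volume_um3=1.0).n_objects == 1


class TestTerritories:
    def test_single_seed_takes_all_foreground(self):
        """One-cell stack: the whole foreground belongs to the only seed."""
        p = PhenotypeParams(n_cells=1, fractions=(0.0, 0.0, 1.0),
                            noise_gaussian_sd=0.0, shape=(20, 96, 96))
        stack, _ = generate_cell_stack(p, seed=3)
        seeds = segment_nuclei(stack)
        assert seeds.n_objects == 1
        territories = assign_cell_territories(seeds, stack)
        foreground = (np.asarray(stack.channel("actin")) > 0) | (
            np.asarray(stack.channel("nascent")) > 0
        )
        assert np.array_equal(territories.labels > 0, foreground | (seeds.labels > 0))
        assert territories.n_objects == 1

    def test_territories_partition_foreground(self, noiseless_stack):
        """Each cell's rendered voxels map to exactly its own seed."""
        stack, truth, _ = noiseless_stack
        seeds = segment_nuclei(stack)
        territories = assign_cell_territories(seeds, stack)
        foreground = (np.asarray(stack.channel("actin")) > 0) | (
            np.asarray(stack.channel("nascent")) > 0
        )
        assert np.all(territories.labels[foreground] > 0)
        # voxel-exact: each territory's voxel count equals that cell's
        # rendered actin+shell footprint (cells are disjoint by design)
        assert territories.n_objects == seeds.n_objects

    def test_relabeling_permutes_territories(self, noiseless_stack):
        """Territory volumes are invariant under a seed relabeling."""
        stack, _, _ = noiseless_stack
        seeds = segment_nuclei(stack)
        k = seeds.n_objects
        perm = np.concatenate([[0], np.roll(np.arange(1, k + 1), 1)])
        permuted = LabelVolume(perm[seeds.labels].astype(np.int32), seeds.voxel_size)
        t1 = assign_cell_territories(seeds, stack)
        t2 = assign_cell_territories(permuted, stack)
        v1 = np.bincount(t1.labels.ravel(), minlength=k + 1)[1:]
        v2 = np.bincount(t2.labels.ravel(), minlength=k + 1)[1:]
        np.testing.assert_array_equal(np.sort(v1), np.sort(v2))
        np.testing.assert_array_equal(v1, v2[perm[1:] - 1])


class TestExtracellularMask:
    def test_subtraction_counts(self):
        nascent = np.zeros((4, 10, 10), dtype=bool)
        nascent.ravel()[:100] = True
        actin = np.zeros_like(nascent)
        actin.ravel()[:60] = True
        ecm = extracellular_mask(nascent, actin)
        assert int(ecm.sum()) == 40
        assert not np.any(ecm & actin)
        assert np.all(nascent[ecm])

    def test_nascent_inside_actin_gives_empty(self):
        nascent = np.zeros((2, 5, 5), dtype=bool)
        nascent[1, 2, 2] = True
        actin = np.ones_like(nascent)
        assert extracellular_mask(nascent, actin).sum() == 0

    def test_empty_nascent_gives_empty(self):
        empty = np.zeros((2, 5, 5), dtype=bool)
        assert extracellular_mask(empty, np.ones_like(empty)).sum() == 0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeMismatchError):
            extracellular_mask(np.zeros((2, 5, 5), bool), np.zeros((2, 5, 6), bool))


class TestClassifyCell:
    @pytest.mark.parametrize(
        "total, ecm, expected",
        [(0, 0, "negative"), (500, 0, "restricted"), (500, 120, "secreting"),
         (4, 0, "negative"), (5, 0, "restricted"), (5, 1, "secreting")],
    )
    def test_taxonomy(self, total, ecm, expected):
        assert classify_cell(total, ecm, detection_min=5) == expected

    def test_ecm_exceeding_total_raises(self):
        with pytest.raises(InvariantViolationError):
            classify_cell(10, 11, 5)

    @settings(derandomize=True, max_examples=100)
    @given(
        total=st.integers(0, 1000),
        ecm_frac=st.floats(0, 1),
        floor_lo=st.integers(0, 50),
        floor_hi=st.integers(0, 50),
    )
    def test_raising_detection_floor_moves_toward_negative(
        self, total, ecm_frac, floor_lo, floor_hi
    ):
        """Monotonicity: a higher detection floor can only demote a cell
        toward 'negative', never promote it toward 'secreting'."""
        lo, hi = sorted((floor_lo, floor_hi))
        ecm = int(total * ecm_frac)
        rank = {"negative": 0, "restricted": 1, "secreting": 2}
        assert rank[classify_cell(total, ecm, hi)] <= rank[classify_cell(total, ecm, lo)]


class TestQuantifyStack:
    def test_noiseless_volumes_exact(self, noiseless_stack):
        """On noiseless input, per-cell volumes equal ground-truth voxel
        counts × voxel volume exactly, and every class label matches."""
        stack, truth, _ = noiseless_stack
        records, summary = quantify_stack(stack)
        assert summary["n_cells"] == len(truth)
        matched = match_to_truth(records, truth)
        np.testing.assert_array_equal(
            records["total_nascent_voxels"].to_numpy(),
            matched["total_nascent_voxels"].to_numpy(),
        )
        np.testing.assert_array_equal(
            records["extracellular_nascent_voxels"].to_numpy(),
            matched["extracellular_nascent_voxels"].to_numpy(),
        )
        np.testing.assert_allclose(
            records["total_nascent_volume_um3"],
            matched["total_nascent_voxels"] * stack.voxel_volume,
            rtol=1e-12,
        )
        assert (records["class_label"].to_numpy()
                == matched["class_label"].to_numpy()).all()

    def test_class_fractions_recovered_with_noise(self, lownoise_stack):
        stack, truth, _ = lownoise_stack
        _, summary = quantify_stack(stack)
        true_frac = truth["class_label"].value_counts(normalize=True)
        for cls in ("negative", "restricted", "secreting"):
            assert summary["class_fractions"][cls] == pytest.approx(
                float(true_frac.get(cls, 0.0)), abs=0.05
            )

    def test_fractions_sum_to_one_and_volumes_ordered(self, lownoise_stack):
        stack, _, _ = lownoise_stack
        records, summary = quantify_stack(stack)
        assert sum(summary["class_fractions"].values()) == pytest.approx(1.0)
        assert (
            records["extracellular_nascent_volume_um3"]
            <= records["total_nascent_volume_um3"] + 1e-9
        ).all()

    def test_translation_invariance(self, noiseless_stack):
        """Whole-voxel stack translation leaves the volume multiset intact."""
        stack, _, _ = noiseless_stack
        shifted = ImageStack(
            np.roll(stack.voxels, shift=(0, 1, 2, 3), axis=(0, 1, 2, 3)),
            stack.voxel_size,
            stack.channel_roles,
        )
        r1, _ = quantify_stack(stack)
        r2, _ = quantify_stack(shifted)
        assert sorted(r1["total_nascent_voxels"]) == sorted(r2["total_nascent_voxels"])
        assert sorted(r1["class_label"]) == sorted(r2["class_label"])


class TestCollagenFraction:
    def test_printed_definition_30_of_120(self):
        """30 collagen-positive cells of 120 nuclei give exactly 25%."""
        shape = (4, 120, 120)
        labels = np.zeros(shape, dtype=np.int32)
        collagen = np.zeros(shape, dtype=np.float32)
        k = 0
        for gy in range(12):
            for gx in range(10):
                k += 1
                y, x = 4 + 10 * gy, 6 + 12 * gx
                labels[1:3, y:y + 3, x:x + 3] = k
                if k <= 30:
                    collagen[1:3, y:y + 3, x:x + 3] = 150.0
        stack = ImageStack(
            np.stack([np.zeros(shape, np.float32), collagen]),
            VOX,
            {"nuclei": 0, "collagen1": 1},
        )
        nuclei = LabelVolume(labels, VOX)
        frac = collagen_positive_fraction(stack, nuclei, "collagen1",
                                          threshold=75.0, min_overlap_voxels=5)
        assert frac == pytest.approx(25.0)

    def test_zero_signal_gives_zero_percent(self):
        shape = (4, 40, 40)
        labels = np.zeros(shape, dtype=np.int32)
        labels[1:3, 5:8, 5:8] = 1
        stack = ImageStack(np.zeros((2,) + shape, np.float32), VOX,
                           {"nuclei": 0, "collagen1": 1})
        frac = collagen_positive_fraction(stack, LabelVolume(labels, VOX),
                                          "collagen1", threshold=75.0)
        assert frac == 0.0

    def test_zero_nuclei_raises(self):
        shape = (4, 20, 20)
        stack = ImageStack(np.zeros((2,) + shape, np.float32), VOX,
                           {"nuclei": 0, "collagen1": 1})
        with pytest.raises(UndefinedFractionError):
            collagen_positive_fraction(
                stack, LabelVolume(np.zeros(shape, np.int32), VOX), "collagen1"
            )

    def test_known_phenotype_fraction_recovered(self):
        """A stack generated with ~40% collagen-positive cells yields the
        realized ground-truth percentage within 5 points."""
        p = PhenotypeParams(n_cells=40, collagen1_positive_fraction=0.4,
                            shape=(32, 384, 384))
        stack, truth = generate_cell_stack(p, seed=6)
        seeds = segment_nuclei(stack)
        frac = collagen_positive_fraction(stack, seeds, "collagen1")
        assert frac == pytest.approx(100 * truth["collagen1_positive"].mean(), abs=5.0)


class TestViability:
    @staticmethod
    def _grid_stack(n_live, n_dead):
        shape = (3, 110, 130)
        vol = np.zeros((2,) + shape, dtype=np.float32)
        k = 0
        for gy in range(10):
            for gx in range(10):
                if k >= n_live + n_dead:
                    break
                ch = 0 if k < n_live else 1
                y, x = 4 + 10 * gy, 6 + 12 * gx
                vol[ch, 1:3, y:y + 6, x:x + 8] = 200.0
                k += 1
        return ImageStack(vol, VOX, {"live": 0, "dead": 1})

    def test_printed_definition_80_of_100(self):
        pct, counts = quantify_viability(self._grid_stack(80, 20))
        assert counts["live"] == 80 and counts["dead"] == 20
        assert pct == pytest.approx(80.0)

    def test_all_dead_gives_zero(self):
        pct, _ = quantify_viability(self._grid_stack(0, 30))
        assert pct == 0.0

    def test_no_cells_raises(self):
        stack = ImageStack(np.zeros((2, 3, 20, 20), np.float32), VOX,
                           {"live": 0, "dead": 1})
        with pytest.raises(UndefinedFractionError):
            quantify_viability(stack)

    def test_double_positive_counts_as_dead(self):
        stack = self._grid_stack(2, 1)
        # make the first live object also dead-positive
        live_mask = np.asarray(stack.channel("live")) > 0
        import scipy.ndimage as ndi

        labels, _ = ndi.label(live_mask, structure=np.ones((3, 3, 3)))
        stack.voxels[1][labels == 1] = 200.0
        pct, counts = quantify_viability(stack)
        assert counts["double_positive"] == 1
        assert counts["live"] == 1 and counts["dead"] == 2
        assert pct == pytest.approx(100.0 / 3.0)

    def test_ground_truth_viability_recovered(self):
        """≥250-cell synthetic image: recovered viability within ±3 points
        of the realized ground truth."""
        stack, truth = generate_viability_stack(
            n_cells=300, live_fraction=0.9, seed=5
        )
        pct, counts = quantify_viability(stack)
        assert counts["total"] >= 250
        assert pct == pytest.approx(100 * truth["live"].mean(), abs=3.0)
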