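import dataclasses

import numpy as np
import pytest
from shapely.geometry import Point

from canopyseg import (
    Affine,
    Crown,
    CrownSet,
    FieldTree,
    FieldTreeSet,
    RasterGrid,
    fit_power_law,
    impute_field_radius,
    impute_itc_height,
    itc_height_from_chm,
    make_allometric_sample,
    match,
)

from oracles import greedy_one_to_one


class TestFitPowerLaw:
    def test_exact_recovery(self):
        x = np.array([1.0, 4.0, 9.0, 16.0])
        model = fit_power_law(x, 2.0 * x**0.5)
        assert model.a == pytest.approx(2.0, abs=1e-6)
        assert model.b == pytest.approx(0.5, abs=1e-6)
        assert model.converged

    def test_constant_data(self):
        model = fit_power_law([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])
        assert model.a == pytest.approx(4.0, abs=1e-6)
        assert model.b == pytest.approx(0.0, abs=1e-6)

    def test_noisy_recovery_within_tolerance(self):
        x, y = make_allometric_sample(1.5, 0.8, noise_sd=0.05, n=200, seed=99, x_range=(0.5, 10.0))
        model = fit_power_law(x, y)
        assert abs(model.a - 1.5) < 0.1
        assert abs(model.b - 0.8) < 0.05
        assert model.n_fit == 200

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3 points"):
            fit_power_law([1.0, 2.0], [1.0, 2.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_power_law([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])


def _tree(i, x=0.0, y=0.0, h=20.0, d=30.0, r=3.0):
    return FieldTree(i, x, y, height_m=h, dbh_cm=d, crown_radius_m=r)


class TestImputeFieldRadius:
    def test_noop_when_complete(self):
        trees = FieldTreeSet([_tree(1), _tree(2), _tree(3)])
        out, model = impute_field_radius(trees)
        assert model is None
        assert [t.crown_radius_m for t in out] == [3.0, 3.0, 3.0]

    def test_exact_allometric_recovery(self):
        rng = np.random.default_rng(5)
        trees = []
        for i in range(10):
            h = rng.uniform(10, 30)
            d = rng.uniform(10, 60)
            trees.append(_tree(i, h=h, d=d, r=0.5 * (h * d) ** 0.4))
        blanked_truth = trees[4].crown_radius_m
        trees[4] = dataclasses.replace(trees[4], crown_radius_m=None)
        out, model = impute_field_radius(FieldTreeSet(trees))
        assert out.trees[4].crown_radius_m == pytest.approx(blanked_truth, abs=1e-6)
        assert model.n_fit == 9

    def test_measured_radii_never_overwritten(self):
        trees = [_tree(i, h=10 + i, d=20 + i, r=2.0 + i) for i in range(5)]
        trees[0] = dataclasses.replace(trees[0], crown_radius_m=None)
        out, _ = impute_field_radius(FieldTreeSet(trees))
        assert [t.crown_radius_m for t in out.trees[1:]] == [3.0, 4.0, 5.0, 6.0]

    def test_noisy_imputation_rmse_bounded(self):
        rng = np.random.default_rng(17)
        noise_sd = 0.2
        trees, truth = [], {}
        for i in range(100):
            h = rng.uniform(10, 30)
            d = rng.uniform(10, 60)
            r = 0.5 * (h * d) ** 0.4 + rng.normal(0, noise_sd)
            trees.append(_tree(i, h=h, d=d, r=r))
        blank = rng.choice(100, size=30, replace=False)
        for i in blank:
            truth[i] = trees[i].crown_radius_m
            trees[i] = dataclasses.replace(trees[i], crown_radius_m=None)
        out, _ = impute_field_radius(FieldTreeSet(trees))
        err = [out.trees[i].crown_radius_m - truth[i] for i in blank]
        assert np.sqrt(np.mean(np.square(err))) < 1.5 * noise_sd

    def test_insufficient_training(self):
        trees = [_tree(1), _tree(2), _tree(3, r=None)]
        with pytest.raises(ValueError, match=">= 3"):
            impute_field_radius(FieldTreeSet(trees))


def _chm(values, nodata=None):
    values = np.asarray(values, dtype=float)
    return RasterGrid(values, Affine.north_up(0, values.shape[0], 1.0), nodata=nodata)


class TestItcHeightFromChm:
    def test_constant_chm(self):
        crown = Crown(1, Point(2.5, 2.5).buffer(1.4))
        assert itc_height_from_chm(crown, _chm(np.full((5, 5), 20.0))) == 20.0

    def test_cone_peak_inside(self):
        values = np.zeros((5, 5))
        values[2, 2] = 23.0
        crown = Crown(1, Point(2.5, 2.5).buffer(1.8))
        assert itc_height_from_chm(crown, _chm(values)) == 23.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(21)
        values = rng.uniform(0, 30, (15, 15))
        chm = _chm(values)
        crown = Crown(1, Point(7.3, 8.1).buffer(3.7))
        expected = max(
            values[r, c]
            for r in range(15)
            for c in range(15)
            if crown.geometry.contains(Point(*chm.transform.pixel_center(r, c)))
        )
        assert itc_height_from_chm(crown, chm) == pytest.approx(expected)

    def test_no_pixel_center_inside(self):
        crown = Crown(1, Point(0.5, 4.49).buffer(0.005))
        assert itc_height_from_chm(crown, _chm(np.ones((5, 5)))) is None

    def test_all_nodata_overlap(self):
        crown = Crown(1, Point(2.5, 2.5).buffer(1.0))
        assert itc_height_from_chm(crown, _chm(np.full((5, 5), -1.0), nodata=-1.0)) is None


class TestImputeItcHeight:
    def _crowns(self, n=6, with_height=True):
        crowns = []
        for i in range(n):
            r = 1.5 + 0.5 * i
            poly = Point(i * 20.0, 0.0).buffer(r, quad_segs=64)
            h = 8.0 * r**0.9 if with_height else None
            crowns.append(Crown(i, poly, height_m=h))
        return CrownSet(crowns)

    def test_noop_when_heights_present(self):
        crowns = self._crowns()
        out, model = impute_itc_height(crowns)
        assert model is None
        assert [c.height_m for c in out] == [c.height_m for c in crowns]

    def test_exact_recovery_of_blanked_height(self):
        crowns = list(self._crowns(8))
        truth = crowns[3].height_m
        crowns[3] = dataclasses.replace(crowns[3], height_m=None)
        out, model = impute_itc_height(CrownSet(crowns))
        # buffered circles are near-exact, so the allometry is near noise-free
        assert out.crowns[3].height_m == pytest.approx(truth, rel=1e-3)
        assert model.a == pytest.approx(8.0, rel=1e-2)

    def test_radius_always_filled_from_area(self):
        out, _ = impute_itc_height(self._crowns())
        for c in out:
            assert c.radius_m == pytest.approx(c.equal_area_radius(), rel=1e-6)

    def test_chm_fills_heights_before_allometry(self):
        crowns = CrownSet([Crown(1, Point(2.5, 2.5).buffer(1.5))])
        out, model = impute_itc_height(crowns, _chm(np.full((5, 5), 19.0)))
        assert model is None
        assert out.crowns[0].height_m == 19.0


class TestMatch:
    def _crown(self, i, x, y, h=20.0, r=3.0):
        return Crown(i, Point(x, y).buffer(1.0), height_m=h, radius_m=r)

    def test_identical_pair_zero_distance(self):
        itcs = CrownSet([self._crown(1, 0, 0, h=20, r=3)])
        trees = FieldTreeSet([_tree(1, 0, 0, h=20, d=30, r=3)])
        result = match(itcs, trees)
        p = result.pairs[0]
        assert (p.d_pos, p.d_attr, p.d_total) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_345_triangle(self):
        itcs = CrownSet([self._crown(1, 0, 0)])
        trees = FieldTreeSet([_tree("near", 3, 4), _tree("far", 6, 8)])
        result = match(itcs, trees)
        assert result.pairs[0].stem_id == "near"
        assert result.pairs[0].d_pos == pytest.approx(5.0)
        assert result.unmatched_trees == ["far"]

    def test_total_is_sum_of_components(self):
        itcs = CrownSet([self._crown(1, 0, 0, h=22, r=2.5)])
        trees = FieldTreeSet([_tree(1, 1, 1, h=20, d=30, r=3)])
        p = match(itcs, trees).pairs[0]
        assert p.d_total == pytest.approx(p.d_pos + p.d_attr)
        assert p.d_total >= max(p.d_pos, p.d_attr)

    def test_nearest_mode_allows_duplicate_claims(self):
        itcs = CrownSet([self._crown(1, 0, 0), self._crown(2, 1, 0)])
        trees = FieldTreeSet([_tree(1, 0.4, 0)])
        result = match(itcs, trees, mode="nearest")
        assert [p.stem_id for p in result.pairs] == [1, 1]

    def test_nearest_mode_locality(self):
        """Perturbing an unrelated far tree never changes a crown's match."""
        itcs = CrownSet([self._crown(1, 0, 0)])
        trees = FieldTreeSet([_tree("a", 1, 0), _tree("b", 500, 500)])
        before = match(itcs, trees).pairs[0].stem_id
        moved = FieldTreeSet([_tree("a", 1, 0), _tree("b", 800, 800)])
        assert match(itcs, moved).pairs[0].stem_id == before == "a"

    def test_one_to_one_matches_greedy_oracle(self):
        rng = np.random.default_rng(13)
        itcs = CrownSet(
            [
                self._crown(i, *rng.uniform(0, 50, 2), h=rng.uniform(10, 30), r=rng.uniform(1, 5))
                for i in range(10)
            ]
        )
        trees = FieldTreeSet(
            [
                _tree(j, *rng.uniform(0, 50, 2), h=rng.uniform(10, 30), d=30, r=rng.uniform(1, 5))
                for j in range(10)
            ]
        )
        result = match(itcs, trees, mode="one-to-one")
        # independent exhaustive greedy over the full 10x10 distance table
        from canopyseg.alignment import _distance_components

        d = np.empty((10, 10))
        for i, c in enumerate(itcs):
            for j, t in enumerate(trees):
                dp, da = _distance_components(c, t)
                d[i, j] = dp + da
        oracle_pairs = {(i, j) for i, j in greedy_one_to_one(d)}
        got = {
            (p.itc_id, p.stem_id) for p in result.pairs
        }
        assert got == oracle_pairs
        assert len({p.stem_id for p in result.pairs}) == len(result.pairs)

    def test_one_to_one_stable_under_row_reordering(self):
        rng = np.random.default_rng(29)
        crowns = [
            self._crown(i, *rng.uniform(0, 50, 2), h=rng.uniform(10, 30), r=2.0)
            for i in range(6)
        ]
        trees = [
            _tree(j, *rng.uniform(0, 50, 2), h=rng.uniform(10, 30), d=30, r=2.0)
            for j in range(6)
        ]
        a = match(CrownSet(crowns), FieldTreeSet(trees), mode="one-to-one")
        b = match(
            CrownSet(list(reversed(crowns))),
            FieldTreeSet(list(reversed(trees))),
            mode="one-to-one",
        )
        assert {(p.itc_id, p.stem_id) for p in a.pairs} == {
            (p.itc_id, p.stem_id) for p in b.pairs
        }

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            match(CrownSet([]), FieldTreeSet([_tree(1)]))

    def test_max_distance_cutoff(self):
        itcs = CrownSet([self._crown(1, 0, 0)])
        trees = FieldTreeSet([_tree(1, 100, 100)])
        result = match(itcs, trees, max_distance=10.0)
        assert result.pairs == [] and result.unmatched_itcs == [1]


class TestEndToEndAlignment:
    def test_synthetic_recovery(self, scene):
        """On the default scene, nearly all stems match their generating crown."""
        from canopyseg import delineate

        pred = delineate(scene.cube)
        trees, _ = impute_field_radius(scene.trees)
        itcs, _ = impute_itc_height(pred, scene.chm)
        result = match(itcs, trees, mode="one-to-one")
        apex_to_stem = {}
        for t, (r, c) in zip(scene.trees, scene.apices):
            x, y = scene.cube.transform.pixel_center(r, c)
            for cr in pred:
                if cr.geometry.covers(Point(x, y)):
                    apex_to_stem[cr.crown_id] = t.stem_id
        correct = sum(1 for p in result.pairs if apex_to_stem.get(p.itc_id) == p.stem_id)
        assert correct / len(scene.trees) >= 0.95
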