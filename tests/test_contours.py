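"""STDEV*COEFF contour maps, site summaries and derivative enumeration."""

import numpy as np
import pytest
from rdkit import Chem

from fqdesign import contours, fields, pls, synth
from fqdesign.contours import (
    ContourMap,
    DERIVATIVE_REGISTRY,
    SubstitutionScheme,
    cross_product_derivatives,
    enumerate_derivatives,
    stdev_coeff_map,
    summarize_sites,
    threshold_contours,
)


@pytest.fixture(scope="module")
def toy_fit():
    ts = synth.make_toy_set(n_mol=10, n_atoms=5, noise_sd=0.0, seed=5)
    n = min(4, np.linalg.matrix_rank(ts.X - ts.X.mean(0)))
    model = pls.fit_pls(ts.X, ts.y, n)
    return ts, model


class TestStdevCoeff:
    def test_matches_hand_computed_product(self, toy_fit):
        ts, model = toy_fit
        cmap = stdev_coeff_map(model, ts.descriptors)
        sds = ts.descriptors.column_sds(scaled=True)
        labels = ts.descriptors.column_fields()
        offset = 0
        for k in fields.FIELD_KINDS:
            kept = ts.descriptors.kept[k]
            nk = int(kept.sum())
            expected = sds[offset:offset + nk] * model.coef[offset:offset + nk]
            np.testing.assert_allclose(cmap.values[k][kept], expected, atol=1e-12)
            assert np.all(cmap.values[k][~kept] == 0.0)  # masked columns
            offset += nk
        assert offset == len(labels)

    def test_doubling_y_doubles_values(self, toy_fit):
        ts, model = toy_fit
        m2 = pls.fit_pls(ts.X, 2.0 * ts.y, model.n_components)
        a = stdev_coeff_map(model, ts.descriptors)
        b = stdev_coeff_map(m2, ts.descriptors)
        for k in fields.FIELD_KINDS:
            np.testing.assert_allclose(b.values[k], 2.0 * a.values[k], atol=1e-9)

    def test_molecule_permutation_invariance(self, toy_fit):
        ts, model = toy_fit
        desc = ts.descriptors
        perm = np.random.default_rng(1).permutation(desc.n_molecules)
        shuffled = fields.DescriptorMatrix(
            blocks={k: v[perm] for k, v in desc.blocks.items()},
            kept=desc.kept, block_scale=desc.block_scale, grid=desc.grid,
            probe=desc.probe, molecule_ids=[desc.molecule_ids[i] for i in perm],
            filter_sd=desc.filter_sd,
        )
        a = threshold_contours(stdev_coeff_map(model, desc))
        b = threshold_contours(stdev_coeff_map(model, shuffled))
        for k in fields.FIELD_KINDS:
            np.testing.assert_allclose(a.values[k], b.values[k], atol=1e-12)
            np.testing.assert_array_equal(a.favored[k], b.favored[k])

    def test_model_matrix_mismatch_rejected(self, toy_fit):
        ts, model = toy_fit
        bad = pls.PLSModel(n_components=1, coef=np.ones(3), intercept=0.0)
        with pytest.raises(ValueError, match="kept columns"):
            stdev_coeff_map(bad, ts.descriptors)


def _bare_map(values, points=None):
    n = len(values)
    pts = points if points is not None else np.c_[np.arange(n), np.zeros(n), np.zeros(n)]
    return ContourMap(
        values={"S": np.asarray(values, float)},
        kept={"S": np.ones(n, bool)},
        grid_points=np.asarray(pts, float),
    )


class TestThresholds:
    def test_ten_distinct_values_gives_two_and_two(self):
        cmap = threshold_contours(_bare_map(np.arange(10.0)), 80, 20)
        # sorted-list index arithmetic: linear-interpolation percentiles at
        # 80/20 fall between order statistics 7-8 and 1-2
        assert cmap.favored["S"].sum() == 2
        assert cmap.disfavored["S"].sum() == 2

    def test_all_equal_values_mask_nothing(self):
        cmap = threshold_contours(_bare_map(np.ones(6)), 80, 20)
        assert not cmap.favored["S"].any() and not cmap.disfavored["S"].any()

    def test_masks_never_overlap(self, rng):
        vals = rng.normal(size=25)
        cmap = threshold_contours(_bare_map(vals), 70, 30)
        assert not (cmap.favored["S"] & cmap.disfavored["S"]).any()

    def test_inverted_percentiles_rejected(self):
        with pytest.raises(ValueError):
            threshold_contours(_bare_map(np.arange(5.0)), 20, 80)

    def test_planted_top_coefficient_is_favored(self, toy_fit):
        # a point whose stdev*coeff tops the kept columns must be in the
        # favored mask for any percentile at or below its rank
        ts, model = toy_fit
        cmap = threshold_contours(stdev_coeff_map(model, ts.descriptors), 80, 20)
        for k in fields.FIELD_KINDS:
            kept = cmap.kept[k]
            if kept.sum() < 5:
                continue
            top = np.argmax(np.where(kept, cmap.values[k], -np.inf))
            assert cmap.favored[k][top]


class TestSiteSummaries:
    def test_single_favored_sphere_flags_one_site(self):
        vals = np.zeros(27)
        grid = fields.GridSpec(origin=(-2, -2, -2), spacing=2.0, dims=(3, 3, 3))
        pts = grid.points()
        near_a = np.linalg.norm(pts - np.array([-2.0, -2.0, -2.0]), axis=1) < 1.5
        vals[near_a] = 5.0
        cmap = threshold_contours(_bare_map(vals, pts), 90, 10)
        out = summarize_sites(
            cmap, {"A": np.array([-2.0, -2.0, -2.0]), "B": np.array([2.0, 2.0, 2.0])},
            radius=1.0,
        )
        flags = out.set_index("site")["flag"]
        assert flags["A"] == "favored" and flags["B"] != "favored"

    def test_zero_radius_is_neutral_with_warning(self):
        cmap = threshold_contours(_bare_map(np.arange(8.0)), 80, 20)
        with pytest.warns(UserWarning, match="no kept grid points"):
            out = summarize_sites(cmap, {"A": np.array([0.5, 0.5, 0.5])}, radius=0.0)
        assert (out["flag"] == "neutral").all()

    def test_matches_brute_force_point_in_sphere_tally(self, rng):
        grid = fields.GridSpec(origin=(-3, -3, -3), spacing=1.5, dims=(4, 4, 4))
        pts = grid.points()
        vals = rng.normal(size=len(pts))
        cmap = ContourMap(
            values={"S": vals, "E": -vals},
            kept={"S": np.ones(len(pts), bool), "E": np.ones(len(pts), bool)},
            grid_points=pts,
        )
        threshold_contours(cmap, 75, 25)
        site = np.array([0.3, -0.7, 1.1])
        out = summarize_sites(cmap, {"X": site}, radius=2.0).set_index("field")["flag"]
        for k in ("S", "E"):  # explicit distance loop as the oracle
            nf = nd = 0
            for j, p in enumerate(pts):
                if np.sqrt(((p - site) ** 2).sum()) <= 2.0:
                    nf += bool(cmap.favored[k][j])
                    nd += bool(cmap.disfavored[k][j])
            expect = "favored" if nf > nd else "disfavored" if nd > nf else "neutral"
            assert out[k] == expect


class TestEnumeration:
    def test_registry_yields_sixteen_valid_derivatives(self):
        specs, errors = enumerate_derivatives(SubstitutionScheme())
        assert errors == []
        assert len(specs) == 16
        names = [s.name for s in specs]
        assert names == [n for n, _ in DERIVATIVE_REGISTRY]
        # mono-substitutions at site 1, two at site 5, six bis-substituted
        only1 = [s for s in specs if set(s.substitutions) == {1}]
        only5 = [s for s in specs if set(s.substitutions) == {5}]
        both = [s for s in specs if set(s.substitutions) == {1, 5}]
        assert (len(only1), len(only5), len(both)) == (8, 2, 6)
        for s in specs:  # valence-correct structures
            assert Chem.SanitizeMol(s.molecule.mol, catchErrors=True) == 0

    def test_derivative_10_carries_ethyl_and_phosphino(self):
        specs, _ = enumerate_derivatives(SubstitutionScheme())
        d10 = {s.name: s for s in specs}["Derivative-10"]
        assert d10.substitutions == {1: "C2H5", 5: "PH2"}
        smi = Chem.MolToSmiles(d10.molecule.mol)
        assert "P" in smi and "CC" in smi

    def test_matches_shipped_fixture_smiles(self):
        fixture = {m.id: Chem.MolToSmiles(m.mol)
                   for m in synth.load_fixture("tro_derivatives.smi")}
        specs, _ = enumerate_derivatives(SubstitutionScheme())
        for s in specs:
            assert Chem.MolToSmiles(s.molecule.mol) == fixture[s.name]

    def test_empty_registry(self):
        specs, errors = enumerate_derivatives(SubstitutionScheme(), registry=[])
        assert specs == [] and errors == []

    def test_cross_product_mode(self):
        specs = cross_product_derivatives(
            SubstitutionScheme(), {1: ["CH3", "C2H5"]}
        )
        assert len(specs) == 2

    def test_unknown_group_reported_not_fatal(self):
        specs, errors = enumerate_derivatives(
            SubstitutionScheme(),
            registry=[("bad", {1: "XYZ"}), ("good", {1: "CH3"})],
        )
        assert len(specs) == 1 and specs[0].name == "good"
        assert errors and errors[0][0] == "bad"
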