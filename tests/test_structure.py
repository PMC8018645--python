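"""PCA, triangle-area metric (Heron oracle), Ward clustering (brute-force
merge oracle) and the marker screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaplast.structure import (
    marker_screen,
    pca,
    variety_area,
    variety_areas,
    ward_clustering,
)


def frame(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])])


class TestPca:
    def test_collinear_points_put_all_inertia_on_pc1(self):
        t = np.linspace(0, 1, 6)
        m = frame(np.column_stack([t, 2 * t]))
        model = pca(m)
        assert model.inertia[0] == pytest.approx(1.0)

    def test_score_covariance_is_diagonal_eigenvalues(self, rng):
        m = frame(rng.normal(size=(15, 4)))
        model = pca(m)
        cov = np.cov(model.scores.to_numpy(), rowvar=False)
        eig = np.diag(cov).copy()
        np.testing.assert_allclose(cov, np.diag(eig), atol=1e-10)
        assert np.all(np.diff(eig) <= 1e-10)  # non-increasing

    def test_full_reconstruction(self, rng):
        m = frame(rng.normal(size=(10, 6)))
        model = pca(m)
        recon = model.scores.to_numpy() @ model.loadings.to_numpy().T + m.mean().to_numpy()
        np.testing.assert_allclose(recon, m.to_numpy(), atol=1e-9)

    def test_scores_have_zero_column_means(self, rng):
        model = pca(frame(rng.normal(size=(12, 5))))
        assert np.abs(model.scores.mean()).max() < 1e-10

    def test_matches_sklearn_up_to_convention(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        x = rng.normal(size=(20, 6))
        model = pca(frame(x))
        sk = SkPCA().fit(x)
        np.testing.assert_allclose(model.inertia, sk.explained_variance_ratio_, atol=1e-10)
        np.testing.assert_allclose(
            np.abs(model.scores.to_numpy()), np.abs(sk.transform(x)), atol=1e-8
        )

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            pca(frame(np.ones((2, 3))))


class TestVarietyArea:
    def test_unit_right_triangle(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        area, _ = variety_area(pts)
        assert area == pytest.approx(0.5)

    def test_collinear_points_give_zero(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], dtype=float)
        area, _ = variety_area(pts)
        assert area == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_heron_formula(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-5, 5, size=(3, 3))
        area, _ = variety_area(pts)
        a = np.linalg.norm(pts[0] - pts[1])
        b = np.linalg.norm(pts[1] - pts[2])
        c = np.linalg.norm(pts[2] - pts[0])
        s = (a + b + c) / 2
        heron = np.sqrt(max(s * (s - a) * (s - b) * (s - c), 0.0))
        assert area == pytest.approx(heron, rel=1e-7, abs=1e-9)

    def test_rigid_rotation_invariance(self, rng):
        from scipy.stats import special_ortho_group

        pts = rng.normal(size=(3, 3))
        q = special_ortho_group.rvs(3, random_state=1)
        a1, _ = variety_area(pts)
        a2, _ = variety_area(pts @ q.T)
        assert a1 == pytest.approx(a2, rel=1e-10)

    def test_quadratic_scaling(self, rng):
        pts = rng.normal(size=(3, 3))
        a1, _ = variety_area(pts)
        a2, _ = variety_area(3.0 * pts)
        assert a2 == pytest.approx(9.0 * a1, rel=1e-10)

    def test_pc_sign_flip_leaves_area_unchanged(self, rng):
        pts = rng.normal(size=(3, 3))
        inertia = np.array([0.15, 0.12, 0.08])
        flipped = pts.copy()
        flipped[:, 1] *= -1.0
        assert variety_area(pts, inertia) == pytest.approx(variety_area(flipped, inertia))

    def test_wrong_point_count_rejected(self):
        with pytest.raises(ValueError):
            variety_area(np.zeros((4, 3)))

    def test_higher_response_variety_has_larger_area(self):
        # one variety with k-times the environment response on all PCs
        from metaplast.core import block_means, scale_compounds, stack_means
        from metaplast.simulate import CompoundSpec, SimSpec, simulate_panel

        comps = [CompoundSpec(f"c{i}", sigma_g=0.5, sigma_e=1.0, sigma_resid=0.05)
                 for i in range(10)]
        spec = SimSpec(n_varieties=6, n_locations=3, n_years=1, n_blocks=2,
                       compounds=comps,
                       fw_slopes={f"c{i}": [3.0, 1.0, 1.0, 1.0, 0.6, 0.4]
                                  for i in range(10)},
                       seed=17)
        table, _ = simulate_panel(spec)
        scaled = scale_compounds(stack_means(block_means(table)))
        areas = variety_areas(pca(scaled))
        assert areas["area"].idxmax() == "V01"


class TestWardClustering:
    def test_recovers_two_separated_groups(self, rng):
        x = np.vstack([rng.normal(0, 0.1, (4, 3)), rng.normal(10, 0.1, (4, 3))])
        clust = ward_clustering(frame(x))
        cut = clust.cut(2)
        assert len(set(cut.iloc[:4])) == 1
        assert len(set(cut.iloc[4:])) == 1
        assert cut.iloc[0] != cut.iloc[-1]

    def test_three_point_merge_order_matches_ward_criterion(self):
        # brute force: first Ward merge minimizes d^2/2 between singletons
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]])
        clust = ward_clustering(frame(pts))
        pairs = {
            (i, j): np.sum((pts[i] - pts[j]) ** 2) / 2
            for i, j in itertools.combinations(range(3), 2)
        }
        best = min(pairs, key=pairs.get)
        first_merge = set(clust.linkage[0, :2].astype(int))
        assert first_merge == set(best)
        assert clust.linkage[0, 2] == pytest.approx(np.sqrt(2 * pairs[best]))

    def test_row_order_invariance(self, rng):
        x = frame(rng.normal(size=(7, 4)))
        perm = rng.permutation(7)
        c1 = ward_clustering(x).cut(3)
        c2 = ward_clustering(x.iloc[perm]).cut(3)
        # same partition regardless of label numbering
        for a, b in itertools.combinations(x.index, 2):
            assert (c1[a] == c1[b]) == (c2[a] == c2[b])

    def test_newick_parses_with_all_leaves(self, rng):
        import io

        from Bio import Phylo

        x = frame(rng.normal(size=(5, 3)))
        nwk = ward_clustering(x).to_newick()
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(x.index)

    def test_cut_larger_than_n_rejected(self, rng):
        clust = ward_clustering(frame(rng.normal(size=(3, 2))))
        with pytest.raises(ValueError):
            clust.cut(4)


class TestMarkerScreen:
    def test_planted_marker_ranks_first_and_is_selected(self, rng):
        n_per, p = 10, 6
        y = np.repeat(["a", "b"], n_per)
        x = rng.normal(size=(2 * n_per, p))
        x[n_per:, 0] += 4.0  # strong variety effect on compound 0
        cols = [f"c{i}" for i in range(p)]
        res = marker_screen(pd.DataFrame(x, columns=cols), y, n_trees=100,
                            n_permutations=49, importance_floor=0.0, seed=0)
        assert res.table.index[0] == "c0"
        assert "c0" in res.selected
        assert res.oob_error < 0.2

    def test_pure_noise_selection_rate_near_alpha(self, rng):
        # with no signal, each compound should be selected ~alpha of the time
        hits, trials = 0, 0
        for rep in range(15):
            y = np.repeat(["a", "b"], 8)
            x = rng.normal(size=(16, 4))
            res = marker_screen(pd.DataFrame(x, columns=list("wxyz")), y,
                                n_trees=50, n_permutations=39,
                                importance_floor=0.0, seed=rep)
            hits += int(res.table["p_value"].lt(0.05).sum())
            trials += 4
        assert hits / trials < 0.2

    def test_single_class_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(6, 3)))
        with pytest.raises(ValueError):
            marker_screen(x, np.repeat("a", 6), n_trees=10, n_permutations=5)
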