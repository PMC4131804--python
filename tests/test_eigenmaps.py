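"""Truncated connectivity, PCNM eigenvector extraction, Moran's I."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from skbio.stats.ordination import pcoa

import pcnmkit as pk


def sites_df(pts):
    return pd.DataFrame(
        [(f"s{i}", x, y) for i, (x, y) in enumerate(pts)],
        columns=["site_id", "x", "y"],
    )


class TestTruncation:
    def test_rule_is_inclusive_at_t(self):
        d = pk.pairwise_distance_matrix(
            sites_df([(0, 0), (1000, 0), (3000, 0)])
        )
        w = pk.truncate_distance_matrix(d, t=2000.0)
        assert w.values[0, 1] == 1000.0          # below t: kept
        assert w.values[1, 2] == 2000.0          # exactly t: kept (inclusive)
        assert w.values[0, 2] == 4 * 2000.0      # beyond t: 4t
        assert np.all(np.diag(w.values) == 0)

    def test_input_unmodified(self):
        d = pk.pairwise_distance_matrix(sites_df([(0, 0), (1, 0), (9, 0)]),
                                        planar_ok=True)
        before = d.values.copy()
        pk.truncate_distance_matrix(d, t=2.0)
        assert np.array_equal(d.values, before)

    @pytest.mark.parametrize("t,mult", [(0.0, 4.0), (-1.0, 4.0), (5.0, 1.0),
                                        (5.0, 0.5)])
    def test_invalid_parameters(self, t, mult, grid_dmat):
        with pytest.raises(ValueError):
            pk.truncate_distance_matrix(grid_dmat, t=t, multiplier=mult)


def brute_force_pcnm_eigenvalues(w):
    """Independent Gower double-centering + eigendecomposition, looped."""
    n = w.shape[0]
    a = -0.5 * w**2
    g = np.empty_like(a)
    grand = a.mean()
    for i in range(n):
        for j in range(n):
            g[i, j] = a[i, j] - a[i, :].mean() - a[:, j].mean() + grand
    return np.sort(np.linalg.eigvalsh(g))[::-1]


class TestEigenmap:
    def test_columns_zero_mean_orthogonal(self, grid_eigenmap):
        s = grid_eigenmap.scores
        assert np.abs(s.mean(axis=0)).max() < 1e-9
        gram = s.T @ s
        assert np.allclose(gram, np.eye(s.shape[1]), atol=1e-9)

    def test_eigenvalues_positive_descending(self, grid_eigenmap):
        lam = grid_eigenmap.eigenvalues
        assert np.all(lam > 0)
        assert np.all(np.diff(lam) <= 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1e4, size=(rng.integers(6, 13), 2))
        d = pk.pairwise_distance_matrix(sites_df(pts))
        t = pk.mst_threshold(d)
        w = pk.truncate_distance_matrix(d, t)
        emap = pk.compute_eigenmap(w)
        oracle = brute_force_pcnm_eigenvalues(w.values)
        oracle = oracle[oracle > 1e-9 * oracle[0]]
        assert np.allclose(emap.eigenvalues, oracle, rtol=1e-8)

    def test_untruncated_equals_classical_pcoa(self, small_random_sites):
        """With t >= max distance the map is plain PCoA of D: skbio agrees
        on eigenvalues and sqrt(lambda)-scaled scores reconstruct D."""
        d = pk.pairwise_distance_matrix(small_random_sites)
        t = d.values.max()
        emap = pk.compute_eigenmap(pk.truncate_distance_matrix(d, t))
        ref = pcoa(d.values, method="eigh")
        ref_lam = ref.eigvals.to_numpy()
        ref_lam = ref_lam[ref_lam > 1e-9 * ref_lam.max()]
        assert np.allclose(emap.eigenvalues, ref_lam, rtol=1e-8)
        coords = emap.scaled_scores()
        recon = np.sqrt(
            ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        )
        assert np.allclose(recon, d.values, atol=1e-6 * d.values.max())

    def test_matches_vegan_pcnm(self, tmp_path):
        """R vegan::pcnm (the reference PCNM implementation) produces the
        same threshold and positive eigenvalues on a random layout."""
        sites = pk.make_random_sites(15, extent=5e4, seed=9, aspect=1.0)
        f = tmp_path / "sites.csv"
        sites.to_csv(f, index=False)
        d = pk.pairwise_distance_matrix(sites)
        t = pk.mst_threshold(d)
        emap = pk.compute_eigenmap(pk.truncate_distance_matrix(d, t))
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            s <- read.csv("{f}")
            p <- pcnm(dist(s[, c("x", "y")]))
            v <- p$values[p$values > 1e-9 * max(p$values)]
            cat(format(c(p$threshold, v), digits = 15), sep = "\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        nums = [float(x) for x in out.stdout.split()]
        assert t == pytest.approx(nums[0], rel=1e-9)
        assert np.allclose(emap.eigenvalues, nums[1:], rtol=1e-8)

    def test_transect_sign_changes_and_moran(self, transect_eigenmap):
        """On a 1-D equidistant transect the eigenvectors are the known
        sinusoids: column k crosses zero k times, and column 1 (broadest
        wave) has the largest Moran's I."""
        sites, emap = transect_eigenmap
        for k in range(10):
            changes = int(np.sum(np.diff(np.sign(emap.scores[:, k])) != 0))
            assert changes == k + 1
        d = pk.pairwise_distance_matrix(sites)
        t = pk.mst_threshold(d)
        stats = [pk.morans_i(emap.scores[:, k], d, t)[0]
                 for k in range(emap.n_vectors)]
        assert int(np.argmax(stats)) == 0

    def test_permutation_equivariance(self):
        """Reordering sites permutes score rows and keeps eigenvalues.

        Uses an irregular layout: eigenvectors are only unique up to
        rotation inside degenerate eigenspaces, so symmetric lattices
        (repeated eigenvalues) are excluded by construction, and any
        residual near-degenerate pairs are skipped explicitly.
        """
        sites = pk.make_random_sites(20, extent=1e5, seed=5, aspect=1.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(sites))
        emap1 = pk.eigenmap_for_sites(sites)
        emap2 = pk.eigenmap_for_sites(sites.iloc[perm].reset_index(drop=True))
        assert np.allclose(emap1.eigenvalues, emap2.eigenvalues, rtol=1e-9)
        lam = emap1.eigenvalues
        gaps = np.min(np.abs(lam[:, None] - lam[None, :])
                      + np.diag(np.full(len(lam), np.inf)), axis=1)
        s1, s2 = emap1.scores[perm], emap2.scores
        for k in range(s1.shape[1]):
            if gaps[k] < 1e-6 * lam[0]:
                continue
            assert (np.allclose(s1[:, k], s2[:, k], atol=1e-8)
                    or np.allclose(s1[:, k], -s2[:, k], atol=1e-8))

    def test_sign_fixing_deterministic(self, grid_sites):
        emap1 = pk.eigenmap_for_sites(grid_sites)
        emap2 = pk.eigenmap_for_sites(grid_sites)
        assert np.array_equal(emap1.scores, emap2.scores)
        for k in range(emap1.n_vectors):
            col = emap1.scores[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_total_dimension_grows_with_sites(self):
        """Eigendecomposition dimension equals n; adding a site raises it."""
        for n in (5, 8, 12):
            sites = pk.make_random_sites(n, extent=1e4, seed=3, aspect=1.0)
            emap = pk.eigenmap_for_sites(sites)
            assert emap.n_sites == n
            assert 0 < emap.n_vectors < n

    def test_too_few_sites_rejected(self):
        d = pk.pairwise_distance_matrix(sites_df([(0, 0), (10, 0)]),
                                        planar_ok=True)
        w = pk.truncate_distance_matrix(d, 10.0)
        with pytest.raises(ValueError):
            pk.compute_eigenmap(w)


class TestMoransI:
    def test_gradient_positive(self):
        sites = pk.make_grid_sites(10, 2, 1000.0)
        d = pk.pairwise_distance_matrix(sites)
        t = pk.mst_threshold(d)
        i_stat, expect = pk.morans_i(sites["x"].to_numpy(), d, t)
        assert i_stat > 0 > expect

    def test_checkerboard_negative_matches_loop_oracle(self, grid_sites,
                                                       grid_dmat):
        x = ((grid_sites["x"] / 1000 + grid_sites["y"] / 1000) % 2).to_numpy()
        x = np.where(x == 0, -1.0, 1.0)
        t = pk.mst_threshold(grid_dmat)
        i_stat, _ = pk.morans_i(x, grid_dmat, t)
        assert i_stat < 0
        # brute-force double sum
        n = len(x)
        z = x - x.mean()
        num = s0 = 0.0
        for i in range(n):
            for j in range(n):
                d_ij = grid_dmat.values[i, j]
                if 0 < d_ij <= t:
                    num += z[i] * z[j]
                    s0 += 1
        oracle = (n / s0) * num / (z @ z)
        assert i_stat == pytest.approx(oracle, abs=1e-12)

    def test_first_eigenvector_positively_autocorrelated(self, grid_eigenmap,
                                                         grid_dmat):
        t = pk.mst_threshold(grid_dmat)
        i_stat, expect = pk.morans_i(grid_eigenmap.scores[:, 0], grid_dmat, t)
        assert i_stat > expect == pytest.approx(-1 / (grid_eigenmap.n_sites - 1))

    def test_errors(self, grid_dmat):
        t = pk.mst_threshold(grid_dmat)
        with pytest.raises(ValueError, match="constant"):
            pk.morans_i(np.ones(grid_dmat.n), grid_dmat, t)
        with pytest.raises(ValueError, match="neighbour"):
            pk.morans_i(np.arange(grid_dmat.n, dtype=float), grid_dmat, t=1.0)
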