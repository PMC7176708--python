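"""GPA, shape PCA, phylogenetic signal and phylogenetic PLS."""

import subprocess

import numpy as np
import pytest

from mandifem.errors import InvalidArgumentError
from mandifem.morphometrics import (
    gpa,
    kmult,
    pca,
    phylo_pls,
    procrustes_distance,
)
from mandifem.synth import Phylogeny, simulate_phylogeny


def rot(deg):
    th = np.deg2rad(deg)
    return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])


class TestGpa:
    def test_similarity_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 2))
        y = 2.0 * (x @ rot(30.0)) + np.array([5.0, -3.0])
        assert procrustes_distance(x, y) < 1e-10

    def test_unit_centroid_size_and_consensus_fixed_point(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(3, 12, 2))
        shape = gpa(x)
        for cfg in shape.procrustes_coords:
            assert np.linalg.norm(cfg) == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(cfg.mean(axis=0), 0.0, atol=1e-12)
        # consensus is the (normalised) mean and a fixed point of one more pass
        mean = shape.procrustes_coords.mean(axis=0)
        mean -= mean.mean(axis=0)
        mean /= np.linalg.norm(mean)
        np.testing.assert_allclose(shape.consensus, mean, atol=1e-8)

    def test_invariant_to_random_similarity_of_inputs(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 12, 2))
        xt = np.stack(
            [
                rng.uniform(0.5, 3.0) * (cfg @ rot(rng.uniform(0, 360)))
                + rng.normal(size=2) * 10
                for cfg in x
            ]
        )
        s0 = gpa(x)
        s1 = gpa(xt)
        # compare aligned shapes after removing the global rotation ambiguity
        d = [
            procrustes_distance(a, b)
            for a, b in zip(s0.procrustes_coords, s1.procrustes_coords)
        ]
        assert max(d) < 1e-8

    def test_degenerate_configuration_named(self):
        x = np.zeros((2, 12, 2))
        x[1] = np.random.default_rng(3).normal(size=(12, 2))
        with pytest.raises(InvalidArgumentError, match="spec0"):
            gpa(x, ids=["spec0", "spec1"])


class TestPca:
    def test_single_direction_explains_everything(self):
        t = np.linspace(-1, 1, 10)
        x = np.outer(t, np.array([1.0, 2.0, -0.5]))
        res = pca(x)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 6))
        res = pca(x)
        recon = res.scores @ res.loadings + x.mean(axis=0)
        np.testing.assert_allclose(recon, x, atol=1e-9)

    def test_fractions_monotone_and_sum_to_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(15, 8)) * np.arange(1, 9)
        res = pca(x)
        f = res.explained_variance_fraction
        assert np.all(np.diff(f) <= 1e-12)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_truncation_warns(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(4, 10))  # rank 3 after centring
        with pytest.warns(UserWarning, match="rank"):
            res = pca(x, n_components=8)
        assert res.scores.shape[1] == 3


class TestKmult:
    def test_bm_calibration(self, tree30, bm_factory):
        draw, labels = bm_factory
        rng = np.random.default_rng(7)
        ks = [
            kmult(draw(rng), tree30, labels=labels, n_perm=0)["K"] for _ in range(100)
        ]
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_iid_data_has_low_k_and_high_p(self, tree30, bm_factory):
        _, labels = bm_factory
        rng = np.random.default_rng(8)
        ks, ps = [], []
        for r in range(30):
            res = kmult(
                rng.standard_normal((30, 8)), tree30, labels=labels, n_perm=99, seed=r
            )
            ks.append(res["K"])
            ps.append(res["p"])
        assert np.mean(ks) < 0.5
        assert np.median(ps) > 0.05

    def test_strong_signal_detected(self, tree30, bm_factory):
        draw, labels = bm_factory
        rng = np.random.default_rng(9)
        hits = sum(
            kmult(draw(rng), tree30, labels=labels, n_perm=99, seed=r)["p"] <= 0.05
            for r in range(20)
        )
        assert hits >= 18  # >= 90% power under pure BM

    def test_star_phylogeny_reduces_to_nonphylogenetic_ratio(self):
        """With C proportional to the identity, K compares plain centred
        sums of squares and equals 1 for any data."""
        star = Phylogeny.from_newick("(a:1,b:1,c:1,d:1,e:1);")
        rng = np.random.default_rng(10)
        x = rng.normal(size=(5, 3))
        res = kmult(x, star, labels=list("abcde"), n_perm=0)
        assert res["K"] == pytest.approx(1.0, rel=1e-10)

    def test_univariate_matches_r_phytools(self, tmp_path):
        """Independent oracle: Blomberg's K from phytools on one trait."""
        tree = simulate_phylogeny(8, seed=11)
        c, labels = tree.vcv()
        rng = np.random.default_rng(12)
        y = np.linalg.cholesky(c + 1e-12 * np.eye(8)) @ rng.standard_normal(8)
        res = kmult(y[:, None], tree, labels=labels, n_perm=0)

        nwk = tmp_path / "tree.nwk"
        nwk.write_text(tree.newick() + "\n")
        dat = tmp_path / "trait.csv"
        dat.write_text("\n".join(f"{l},{float(v)!r}" for l, v in zip(labels, y)) + "\n")
        script = (
            "suppressMessages(library(phytools));"
            f"tr <- read.tree('{nwk}');"
            f"d <- read.csv('{dat}', header=FALSE);"
            "x <- setNames(d$V2, d$V1);"
            "cat(sprintf('%.12f', phylosig(tr, x, method='K')))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        k_r = float(out.stdout.strip().split()[-1])
        assert res["K"] == pytest.approx(k_r, rel=1e-6)

    def test_too_few_shared_tips_rejected(self, tree30):
        with pytest.raises(InvalidArgumentError):
            kmult(np.zeros((3, 2)), tree30, labels=["z1", "z2", "z3"])


def ordinary_pls_r(x1, x2):
    """Plain two-block PLS r for the star-phylogeny reduction check."""
    z1 = x1 - x1.mean(axis=0)
    z2 = x2 - x2.mean(axis=0)
    u, s, vt = np.linalg.svd(z1.T @ z2 / (len(z1) - 1), full_matrices=False)
    a, b = z1 @ u[:, 0], z2 @ vt[0]
    return abs(np.corrcoef(a, b)[0, 1])


class TestPhyloPls:
    def test_identical_blocks_give_r_one(self, tree30, bm_factory):
        draw, labels = bm_factory
        rng = np.random.default_rng(13)
        x = draw(rng, p=5)
        res = phylo_pls(x, x, tree30, labels=labels, n_perm=19, seed=0)
        assert res["r_pls"] == pytest.approx(1.0, abs=1e-9)

    def test_star_phylogeny_reduces_to_ordinary_pls(self):
        star = Phylogeny.from_newick("(a:1,b:1,c:1,d:1,e:1,f:1,g:1,h:1);")
        rng = np.random.default_rng(14)
        x1 = rng.normal(size=(8, 4))
        x2 = rng.normal(size=(8, 3))
        res = phylo_pls(x1, x2, star, labels=list("abcdefgh"), n_perm=9, seed=0)
        assert res["r_pls"] == pytest.approx(ordinary_pls_r(x1, x2), rel=1e-8)

    def test_shared_latent_factor_detected(self, tree30, bm_factory):
        draw, labels = bm_factory
        rng = np.random.default_rng(15)
        latent = draw(rng, p=1)
        x1 = latent + 0.1 * draw(rng, p=4)
        x2 = latent + 0.1 * draw(rng, p=3)
        res = phylo_pls(x1, x2, tree30, labels=labels, n_perm=999, seed=1)
        assert res["r_pls"] >= 0.9
        assert res["p"] <= 0.01
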