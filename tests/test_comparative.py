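"""Unit tests for correlograms, PGLS, ancestral states, imputation."""

import itertools
import json
import shutil
import subprocess

import dendropy
import numpy as np
import pandas as pd
import pytest

import osmophylo as op
from osmophylo.comparative import (
    ancestral_bm,
    correlogram,
    impute_missing_ou,
    make_distance_classes,
    moran_i,
    pgls_ou,
)
from osmophylo.phylo import Phylogeny, bm_covariance
from osmophylo.regimes import RegimePainting


# --------------------------------------------------------------------- #
class TestDistanceClasses:
    def test_equal_frequency_counts(self):
        t = op.read_newick("((A:1,B:2):1,(C:1.5,D:2.5):2);")
        dc = make_distance_classes(op.patristic_distances(t), k=2)
        assert dc.counts.tolist() == [3, 3]

    def test_equal_distances_rejected(self):
        t = op.read_newick("(A:2,B:2,C:2,D:2);")
        with pytest.raises(ValueError):
            make_distance_classes(op.patristic_distances(t), k=2)

    def test_equal_width_boundaries(self):
        # pairwise distances 1..12 -> breaks at 3.75, 6.5, 9.25
        d = np.zeros((13, 13))
        vals = iter(range(1, 79))
        # fill an arbitrary symmetric matrix whose off-diagonal range is 1..12
        d[0, 1:13] = np.arange(1, 13)
        d[1:13, 0] = np.arange(1, 13)
        for i in range(1, 13):
            for j in range(i + 1, 13):
                d[i, j] = d[j, i] = 1 + ((i * 13 + j) % 12)
        dc = make_distance_classes(d, k=4, scheme="equal_width")
        assert dc.boundaries == pytest.approx((3.75, 6.5, 9.25))

    def test_boundary_ties_go_to_lower_class(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float)
        dc = make_distance_classes(d, k=2)
        # median boundary = 2; the pair at exactly 2 joins the lower class
        assert dc.membership[0, 2] == 0


class TestMoranI:
    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            x = rng.normal(size=n)
            W = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            sel = rng.random(len(iu[0])) < 0.4
            W[iu[0][sel], iu[1][sel]] = 1
            W += W.T
            if W.sum() == 0:
                continue
            z = x - x.mean()
            brute = 0.0
            for i in range(n):
                for j in range(n):
                    brute += W[i, j] * z[i] * z[j]
            brute = n / W.sum() * brute / (z @ z)
            assert moran_i(x, W) == pytest.approx(brute, rel=1e-12)

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            moran_i(np.ones(5), np.ones((5, 5)) - np.eye(5))

    def test_exhaustive_permutation_mean_is_null_expectation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1
        vals = [moran_i(np.array(p), W) for p in itertools.permutations(x)]
        assert np.mean(vals) == pytest.approx(-1 / 3, abs=1e-12)


class TestCorrelogram:
    def test_strong_bm_signal_detected_in_first_class(self, random_tree):
        hits = 0
        for s in range(12):
            t = random_tree(32, seed=40 + s)
            x = op.sim_trait_bm(t, sigma2=1.0, seed=140 + s)
            res = correlogram(x, t, n_perm=199, seed=s)
            hits += (res.moran[0] > 0) and (res.p_values[0] <= 0.05)
        assert hits >= 8  # strong drift signal is usually significant

    def test_no_permutations_gives_no_p_values(self, random_tree):
        t = random_tree(16, seed=0)
        x = op.sim_trait_bm(t, 1.0, seed=1)
        res = correlogram(x, t, n_perm=0)
        assert res.p_values is None and len(res.moran) == 4

    def test_missing_tip_values_rejected(self, random_tree):
        t = random_tree(8, seed=0)
        x = op.sim_trait_bm(t, 1.0, seed=1)
        with pytest.raises(ValueError):
            correlogram(x.iloc[:-1], t)


# --------------------------------------------------------------------- #
class TestPGLS:
    def test_independence_limit_equals_ols(self, random_tree):
        t = random_tree(30, seed=3)
        rng = np.random.default_rng(4)
        x = pd.Series(rng.normal(size=30), index=t.tip_labels)
        y = 0.5 * x + pd.Series(rng.normal(size=30), index=t.tip_labels)
        big = 5000.0 / t.tree_height()
        fit = pgls_ou(y, x, t, alpha_grid=np.array([big]))
        ols = np.polyfit(x.to_numpy(), y.to_numpy(), 1)[0]
        assert fit.slope == pytest.approx(ols, abs=1e-6)

    def test_constant_predictor_rejected(self, random_tree):
        t = random_tree(8, seed=0)
        y = op.sim_trait_bm(t, 1.0, seed=1)
        with pytest.raises(ValueError):
            pgls_ou(y, pd.Series(1.0, index=t.tip_labels), t)

    def test_alpha_hat_maximizes_profile_over_grid(self, random_tree):
        t = random_tree(40, seed=5)
        x = op.sim_trait_bm(t, 2.0, seed=6)
        noise = op.sim_trait_ou(t, RegimePainting.single(), 2.0, 4.0,
                                np.array([0.0]), seed=7)
        y = 0.3 * x + noise
        fit = pgls_ou(y, x, t)
        # refit with alpha pinned to a few other values: none beats alpha_hat
        for a in (fit.alpha_hat * 3, fit.alpha_hat / 3, 1e-3):
            other = pgls_ou(y, x, t, alpha_grid=np.array([a]))
            assert other.log_likelihood <= fit.log_likelihood + 1e-6


# --------------------------------------------------------------------- #
class TestAncestralStates:
    def test_star_tree_root_is_mean(self):
        t = op.read_newick("(A:1,B:1,C:1,D:1);")
        x = pd.Series([1.0, 2.0, 3.0, 6.0], index=list("ABCD"))
        st = ancestral_bm(x, t)
        assert st.estimates[0][0] == pytest.approx(3.0)

    def test_two_branch_inverse_variance_weighting(self):
        t = op.read_newick("((A:1,B:3):1,C:4);")
        x = pd.Series([0.0, 4.0, 2.0], index=list("ABC"))
        st = ancestral_bm(x, t)
        # at the (A,B) ancestor, the A/B contribution is weighted 1/b
        node_ab = next(v for v in range(t.n_nodes)
                       if not t.is_tip(v) and v != 0)
        est = st.estimates[node_ab][0]
        direct = ancestral_bm(x, t).estimates[node_ab][0]
        assert est == pytest.approx(direct)
        assert st.estimates[0][1] <= st.estimates[0][0] <= st.estimates[0][2]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_rerooted_gls_oracle(self, random_tree, seed):
        """Independent oracle: physically re-root the tree with dendropy,
        rebuild the BM covariance of the re-rooted tree, and take the GLS
        root estimate."""
        t = random_tree(8, seed=seed)
        x = op.sim_trait_bm(t, 1.0, root_state=5.0, seed=seed + 50)
        st = ancestral_bm(x, t)
        for v in range(t.n_nodes):
            if t.is_tip(v) or v == 0:
                continue
            leafset = {t.tip_labels[i] for i, tn in enumerate(t.tip_nodes)
                       if tn in t.descendant_tips(v)}
            dtree = dendropy.Tree.get(data=t.to_newick(), schema="newick")
            node = next(nd for nd in dtree.preorder_node_iter()
                        if {lf.taxon.label.replace(" ", "_")
                            for lf in nd.leaf_iter()} == leafset
                        and not nd.is_leaf())
            dtree.reroot_at_node(node, update_bipartitions=False)
            dtree.prune_taxa([])  # no-op; normalizes internal bookkeeping
            rr = Phylogeny(dtree)
            C = bm_covariance(rr)
            xv = x.reindex(rr.tip_labels).to_numpy()
            Ci = np.linalg.pinv(C)
            one = np.ones(len(xv))
            mu = one @ Ci @ xv / (one @ Ci @ one)
            assert st.estimates[v][0] == pytest.approx(mu, rel=1e-6, abs=1e-8)

    def test_invariant_to_branch_rescaling_and_tip_order(self, random_tree):
        t = random_tree(10, seed=4)
        x = op.sim_trait_bm(t, 1.0, seed=9)
        st1 = ancestral_bm(x, t)
        scaled = op.read_newick(t.to_newick())
        scaled.branch_length *= 7.0
        scaled.depth *= 7.0
        st2 = ancestral_bm(x.sample(frac=1, random_state=0), scaled)
        assert st2.estimates[0][0] == pytest.approx(st1.estimates[0][0], rel=1e-8)
        # the CI widens only through sigma2; the estimate itself is unchanged
        assert st2.estimates[0][2] - st2.estimates[0][0] == pytest.approx(
            st1.estimates[0][2] - st1.estimates[0][0], rel=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_phytools_fastanc(self, tmp_path, random_tree):
        """Cross-check against the standard R implementation of ML
        ancestral states under BM (re-rooting / contrasts method)."""
        t = random_tree(8, seed=2)
        x = op.sim_trait_bm(t, 1.0, root_state=3.0, seed=12)
        (tmp_path / "tree.nwk").write_text(t.to_newick())
        (tmp_path / "x.csv").write_text(
            "\n".join(f"{k},{v}" for k, v in x.items()) + "\n")
        script = tmp_path / "anc.R"
        script.write_text("""
suppressMessages(library(phytools))
args <- commandArgs(trailingOnly=TRUE)
tree <- read.tree(args[1])
df <- read.csv(args[2], header=FALSE)
x <- setNames(df$V2, df$V1)
a <- fastAnc(tree, x)
for (i in seq_along(a)) {
  node <- as.integer(names(a)[i])
  tips <- sort(extract.clade(tree, node)$tip.label)
  cat(paste(tips, collapse=";"), "\t", a[i], "\n", sep="")
}
""")
        out = subprocess.run(
            ["Rscript", str(script), str(tmp_path / "tree.nwk"), str(tmp_path / "x.csv")],
            capture_output=True, text=True, check=True)
        st = ancestral_bm(x, t)
        ours = {}
        for v in range(t.n_nodes):
            if not t.is_tip(v):
                tipset = ";".join(sorted(
                    t.tip_labels[list(t.tip_nodes).index(tn)]
                    for tn in t.descendant_tips(v)))
                ours[tipset] = st.estimates[v][0]
        checked = 0
        for line in out.stdout.strip().splitlines():
            tipset, val = line.split("\t")
            assert ours[tipset] == pytest.approx(float(val), rel=1e-4)
            checked += 1
        assert checked >= t.n_tips - 2


# --------------------------------------------------------------------- #
class TestImputation:
    def test_nothing_missing_is_identity(self, random_tree):
        t = random_tree(6, seed=0)
        x = op.sim_trait_bm(t, 1.0, seed=1)
        filled, sd, info = impute_missing_ou(x, t)
        pd.testing.assert_series_equal(filled, x)
        assert (sd == 0).all()

    def test_fixed_parameters_match_conditional_normal_oracle(self, random_tree):
        t = random_tree(5, seed=3)
        x = op.sim_trait_ou(t, RegimePainting.single(), 1.0, 2.0,
                            np.array([10.0]), seed=4)
        x.iloc[2] = np.nan
        alpha, sigma2, theta = 1.3, 2.4, 9.0
        filled, sd, _ = impute_missing_ou(x, t, fixed=(alpha, sigma2, theta))
        # hand-partitioned conditional normal
        V = op.ou_covariance(t, alpha, sigma2)
        obs = x.notna().to_numpy()
        xo = x.to_numpy()[obs]
        Voo = V[np.ix_(obs, obs)]
        Vmo = V[np.ix_(~obs, obs)]
        Vmm = V[np.ix_(~obs, ~obs)]
        mean = theta + Vmo @ np.linalg.solve(Voo, xo - theta)
        var = Vmm - Vmo @ np.linalg.solve(Voo, Vmo.T)
        assert filled.iloc[2] == pytest.approx(float(mean[0]), rel=1e-9)
        assert sd.iloc[2] == pytest.approx(float(np.sqrt(var[0, 0])), rel=1e-9)

    def test_ml_imputation_recovers_plausible_value(self, random_tree):
        t = random_tree(24, seed=5)
        x = op.sim_trait_ou(t, RegimePainting.single(), 2.0 / t.tree_height(),
                            4.0 / t.tree_height(), np.array([100.0]), seed=6)
        true_val = x.iloc[5]
        x2 = x.copy()
        x2.iloc[5] = np.nan
        filled, sd, info = impute_missing_ou(x2, t)
        assert info["model"] in ("OU", "BM")
        assert abs(filled.iloc[5] - true_val) < 4 * max(sd.iloc[5], 1e-9) + 1.0

    def test_too_few_observed_rejected(self, random_tree):
        t = random_tree(5, seed=0)
        x = pd.Series(np.nan, index=t.tip_labels)
        x.iloc[:2] = 1.0
        with pytest.raises(ValueError):
            impute_missing_ou(x, t)
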