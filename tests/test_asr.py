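"""Brownian-motion ancestral reconstruction against independent oracles.

The dense oracle builds the tip covariance C explicitly and evaluates the
multivariate normal directly; the joint-ML oracle solves the graph-Laplacian
normal equations (minimize the sum of squared, length-weighted edge changes)
— an independent route to the same internal states.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, pearsonr

import floralevo as fe
from floralevo.asr import interpolate_on_branch

from conftest import laplacian_states_oracle, random_tree


class TestBmLoglik:
    def test_two_independent_standard_normals(self):
        t = fe.parse_newick("(A:1,B:1);")
        ll = fe.bm_loglik(t, {"A": 0.0, "B": 0.0}, sigma2=1.0, root_state=0.0)
        assert ll == pytest.approx(-np.log(2 * np.pi))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_dense_mvn_oracle(self, seed):
        t = random_tree(seed, n_tips=6)
        rng = np.random.default_rng(seed)
        x = dict(zip(t.tips, rng.normal(1.0, 2.0, size=6)))
        sigma2, root = 0.7, 1.3
        C, taxa = t.vcv()
        oracle = multivariate_normal(
            mean=np.full(6, root), cov=sigma2 * C
        ).logpdf(np.array([x[a] for a in taxa]))
        assert fe.bm_loglik(t, x, sigma2, root) == pytest.approx(oracle, rel=1e-10)

    def test_change_of_variables(self):
        # doubling sigma2 while scaling data by sqrt(2) changes the loglik
        # only by the Jacobian term -n/2 * log(2)
        t = random_tree(11, n_tips=6)
        rng = np.random.default_rng(11)
        x = dict(zip(t.tips, rng.normal(size=6)))
        x2 = {k: v * np.sqrt(2.0) for k, v in x.items()}
        ll1 = fe.bm_loglik(t, x, 1.0, 0.0)
        ll2 = fe.bm_loglik(t, x2, 2.0, 0.0)
        assert ll2 == pytest.approx(ll1 - 0.5 * 6 * np.log(2.0))

    def test_missing_tip_error(self):
        t = fe.parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="C"):
            fe.bm_loglik(t, {"A": 0.0, "B": 1.0}, 1.0, 0.0)


class TestFitBmAsr:
    def test_two_tips_equal_branches_midpoint(self):
        t = fe.parse_newick("(A:1,B:1);")
        r = fe.fit_bm_asr(t, {"A": 2.0, "B": 6.0})
        assert r.fit.root_state == pytest.approx(4.0)

    def test_two_tips_weighted_gls(self):
        # closed form: root = (a/t1 + b/t2) / (1/t1 + 1/t2)
        t = fe.parse_newick("(A:2,B:1);")
        r = fe.fit_bm_asr(t, {"A": 2.0, "B": 6.0})
        assert r.fit.root_state == pytest.approx((2 / 2 + 6 / 1) / (1 / 2 + 1 / 1))

    def test_star_tree_arithmetic_mean(self):
        t = fe.parse_newick("(A:1,B:1,C:1,D:1);")
        r = fe.fit_bm_asr(t, {"A": 1.0, "B": 2.0, "C": 3.0, "D": 6.0})
        assert r.fit.root_state == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_states_match_laplacian_oracle(self, seed):
        n = 4 + seed % 5
        t = random_tree(seed + 50, n_tips=n)
        rng = np.random.default_rng(seed)
        x = dict(zip(t.tips, rng.normal(size=n)))
        r = fe.fit_bm_asr(t, x)
        oracle = laplacian_states_oracle(t, x)
        for node, val in oracle.items():
            assert r.node_states[node] == pytest.approx(val, abs=1e-6)

    def test_affine_equivariance(self):
        t = random_tree(3, n_tips=7)
        rng = np.random.default_rng(3)
        x = dict(zip(t.tips, rng.normal(size=7)))
        a, b = -2.5, 7.0
        r1 = fe.fit_bm_asr(t, x)
        r2 = fe.fit_bm_asr(t, {k: a * v + b for k, v in x.items()})
        for node in r1.node_states:
            assert r2.node_states[node] == pytest.approx(
                a * r1.node_states[node] + b, abs=1e-8
            )

    def test_zero_variance_degenerate(self):
        t = fe.parse_newick("((A:1,B:1):1,C:2);")
        with pytest.warns(UserWarning):
            r = fe.fit_bm_asr(t, {"A": 5.0, "B": 5.0, "C": 5.0})
        assert r.fit.degenerate
        assert all(v == 5.0 for v in r.node_states.values())

    def test_root_estimate_unbiased_under_bm(self):
        tree = fe.sim_tree(16, seed=9)
        height = max(tree.depths().values())
        errs = []
        for i in range(500):
            df, truth = fe.sim_bm_traits(
                tree, {"x": 1.0}, {"x": 0.0}, seed=1000 + i
            )
            r = fe.fit_bm_asr(tree, df.set_index("species")["x"])
            errs.append(r.fit.root_state)
        assert abs(np.mean(errs)) < 0.1 * np.sqrt(height)


class TestInterpolate:
    @pytest.mark.parametrize(
        "ps,cs,dp,dc,expect",
        [
            (0.0, 10.0, 1.0, 1.0, 5.0),
            (3.0, 9.0, 0.0, 2.0, 3.0),
            (2.0, 8.0, 1.0, 3.0, 3.5),
        ],
        ids=["midpoint", "at-parent", "hand-computed"],
    )
    def test_bridge_mean(self, ps, cs, dp, dc, expect):
        assert interpolate_on_branch(ps, cs, dp, dc) == pytest.approx(expect)

    def test_zero_span_error(self):
        with pytest.raises(ValueError):
            interpolate_on_branch(0.0, 1.0, 0.0, 0.0)


class TestReconstructedProgenitors:
    def _toy(self):
        # polyploid copies attach partway up the M and P terminal edges
        t = fe.parse_newick(
            "((((M:1,q_1:1):1,(P:1,q_2:1):1):1,(X:1,Y:1):2):1,Z:4);"
        )
        reg = fe.PolyploidRegistry(
            (
                fe.PolyploidEntry(
                    accession="q", species="q", maternal="M", paternal="P", age=0.5
                ),
            )
        )
        traits = pd.DataFrame(
            {
                "species": ["M", "P", "X", "Y", "Z"],
                "tube_length": [2.0, 4.0, 1.0, 1.5, 3.0],
                "tube_width": [0.4, 0.8, 0.2, 0.3, 0.6],
            }
        )
        return t, reg, traits

    def test_midpoint_invariant(self):
        t, reg, traits = self._toy()
        rec = fe.reconstructed_progenitors(
            t, reg, traits, traits=("tube_length", "tube_width")
        )["q"]
        np.testing.assert_allclose(
            rec.reconstructed_midpoint,
            0.5 * (rec.maternal_state + rec.paternal_state),
        )

    def test_anchor_interpolates_on_terminal_edge(self):
        t, reg, traits = self._toy()
        # anchors sit halfway up the 2-unit M/P terminal edges of the
        # diploid view; check against manual bridge interpolation
        dip = fe.diploid_view(t, reg)
        res = fe.fit_bm_asr(dip, traits.set_index("species")["tube_length"])
        rec = fe.reconstructed_progenitors(
            t, reg, traits, traits=("tube_length",)
        )["q"]
        parent_state = res.node_states[dip.parent["M"]]
        manual = interpolate_on_branch(parent_state, 2.0, 1.0, 1.0)
        assert rec.maternal_state[0] == pytest.approx(manual)

    def test_zero_offset_anchor_equals_node_state(self):
        # copy attaches at a polytomy node that survives pruning, so the
        # anchor coincides with a diploid internal node
        t = fe.parse_newick(
            "(((M:1,X:1):1,(P:1,q_2:1):1,q_1:1):1,(Y:1,Z:1):2);"
        )
        reg = fe.PolyploidRegistry(
            (
                fe.PolyploidEntry(
                    accession="q", species="q", maternal="M", paternal="P", age=0.5
                ),
            )
        )
        traits = pd.DataFrame(
            {
                "species": ["M", "P", "X", "Y", "Z"],
                "tube_length": [2.0, 4.0, 1.0, 1.5, 3.0],
            }
        )
        attach = t.parent["q_1"]
        dip = fe.diploid_view(t, reg)
        assert attach in set(dip.nodes)
        res = fe.fit_bm_asr(dip, traits.set_index("species")["tube_length"])
        rec = fe.reconstructed_progenitors(t, reg, traits, traits=("tube_length",))[
            "q"
        ]
        assert rec.maternal_state[0] == pytest.approx(res.node_states[attach])

    def test_simulation_recovery_correlation(self):
        # single-event scenarios with known true anchor states
        true_vals, est_vals = [], []
        for i in range(200):
            sc = fe.simulate_scenario(
                3000 + i, n_diploid_tips=12, event_plan=((1.4, 1),)
            )
            rec = fe.reconstructed_progenitors(
                sc.full_tree,
                sc.registry,
                sc.diploid_means,
                traits=("tube_length",),
            )
            e = sc.registry.entries[0]
            sp = e.species
            for role, est in (
                ("m", rec[e.accession].maternal_state[0]),
                ("p", rec[e.accession].paternal_state[0]),
            ):
                true_vals.append(sc.node_truth["tube_length"][f"{sp}_anchor_{role}"])
                est_vals.append(est)
        r, _ = pearsonr(true_vals, est_vals)
        assert r > 0.8
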