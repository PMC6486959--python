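"""Divergence vectors, hierarchical averaging, quadrant labels, drift."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import floralevo as fe
from floralevo.vectors import (
    DivergenceVector,
    VectorSet,
    diploid_edge_vectors,
    hierarchical_mean,
    polyploid_vectors,
    progenitor_drift,
    progenitor_midpoint,
    quadrant_classify,
)


def photo_table():
    rows = []
    for plant, base in (("p1", 2.0), ("p2", 4.0)):
        # unequal flower counts across plants
        flowers = ("f1", "f2", "f3") if plant == "p1" else ("f1",)
        for fl in flowers:
            for ph, off in zip(("x1", "x2"), (-0.5, 0.5)):
                rows.append(
                    {
                        "species": "sp",
                        "accession": "acc",
                        "plant": plant,
                        "flower": fl,
                        "photo": ph,
                        "tube_length": base + off,
                    }
                )
    return pd.DataFrame(rows)


class TestHierarchicalMean:
    def test_photo_to_flower(self):
        df = pd.DataFrame(
            {
                "species": "s",
                "accession": "a",
                "plant": "p",
                "flower": "f",
                "photo": [f"x{i}" for i in range(5)],
                "tube_length": [1.0, 2.0, 3.0, 4.0, 5.0],
            }
        )
        out = hierarchical_mean(df, "flower")
        assert out["tube_length"].iloc[0] == pytest.approx(3.0)

    def test_means_of_means_ignores_unequal_counts(self):
        out = hierarchical_mean(photo_table(), "accession")
        # plant means are 2 and 4 regardless of flower counts
        assert out["tube_length"].iloc[0] == pytest.approx(3.0)

    def test_replicate_order_invariance(self):
        df = photo_table()
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = hierarchical_mean(df, "species")["tube_length"].iloc[0]
        b = hierarchical_mean(shuffled, "species")["tube_length"].iloc[0]
        assert a == pytest.approx(b)


class TestMidpoint:
    def test_elementwise_mean(self):
        np.testing.assert_allclose(
            progenitor_midpoint((2.0, 4.0), (4.0, 8.0)), (3.0, 6.0)
        )

    def test_identical_progenitors(self):
        np.testing.assert_allclose(
            progenitor_midpoint((1.0, 2.0), (1.0, 2.0)), (1.0, 2.0)
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            progenitor_midpoint((1.0,), (1.0, 2.0))


class TestPolyploidVectors:
    def _registry(self):
        return fe.PolyploidRegistry(
            (
                fe.PolyploidEntry(
                    accession="q1", species="q", maternal="M", paternal="P", age=0.5
                ),
            )
        )

    def _frames(self, acc_lw=(2.0, 7.0)):
        prog = pd.DataFrame(
            {
                "species": ["M", "P"],
                "tube_length": [2.0, 4.0],
                "tube_width": [4.0, 8.0],
            }
        )
        acc = pd.DataFrame(
            {
                "accession": ["q1"],
                "tube_length": [acc_lw[0]],
                "tube_width": [acc_lw[1]],
            }
        )
        return prog, acc

    def test_vector_is_mean_minus_midpoint(self):
        prog, acc = self._frames()
        vs = polyploid_vectors(self._registry(), acc, prog)
        v = vs.vectors[0]
        assert (v.dx, v.dy) == pytest.approx((-1.0, 1.0))
        assert v.group == "young"

    def test_zero_vector_excluded_and_flagged(self):
        prog, acc = self._frames(acc_lw=(3.0, 6.0))  # exactly the midpoint
        vs = polyploid_vectors(self._registry(), acc, prog)
        assert vs.n == 0 and len(vs.excluded) == 1

    def test_default_scenario_has_twenty_accessions(self):
        sc = fe.simulate_scenario(42)
        vs = polyploid_vectors(
            sc.registry, sc.accession_means, sc.diploid_means, basis="extant"
        )
        assert vs.n == 20
        assert sum(v.group == "young" for v in vs.vectors) == 13
        assert sum(v.group == "old" for v in vs.vectors) == 7

    def test_missing_accession_error(self):
        prog, acc = self._frames()
        with pytest.raises(ValueError, match="q1"):
            polyploid_vectors(self._registry(), acc.iloc[:0], prog)


class TestDiploidEdgeVectors:
    def test_edge_count_three_tips(self):
        tree = fe.parse_newick("((A:1,B:1):1,C:2);")
        df, _ = fe.sim_bm_traits(
            tree, {"tube_length": 1.0, "tube_width": 0.1},
            {"tube_length": 4.0, "tube_width": 1.0}, seed=0,
        )
        rx = fe.fit_bm_asr(tree, df.set_index("species")["tube_length"])
        ry = fe.fit_bm_asr(tree, df.set_index("species")["tube_width"])
        vs = diploid_edge_vectors(tree, rx, ry, tip_values=df)
        assert vs.n + len(vs.excluded) == 4

    def test_thirty_tip_tree_yields_fifty_eight(self):
        # a rooted bifurcating tree with 30 tips has 2n - 2 = 58 edges
        tree = fe.sim_tree(30, seed=4)
        df, _ = fe.sim_bm_traits(
            tree, {"tube_length": 1.0, "tube_width": 0.1},
            {"tube_length": 4.0, "tube_width": 1.0}, seed=5,
        )
        rx = fe.fit_bm_asr(tree, df.set_index("species")["tube_length"])
        ry = fe.fit_bm_asr(tree, df.set_index("species")["tube_width"])
        vs = diploid_edge_vectors(tree, rx, ry, tip_values=df)
        assert vs.n + len(vs.excluded) == 58

    def test_rotation_covariance(self):
        # rotating the trait plane rotates every vector, magnitudes unchanged
        tree = fe.sim_tree(12, seed=6)
        df, _ = fe.sim_bm_traits(
            tree, {"tube_length": 1.0, "tube_width": 1.0},
            {"tube_length": 0.0, "tube_width": 0.0}, seed=7,
        )
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        cols = ["tube_length", "tube_width"]
        rot = df.copy()
        rot[cols] = df[cols].to_numpy() @ R.T

        def vecs(table):
            rx = fe.fit_bm_asr(tree, table.set_index("species")[cols[0]])
            ry = fe.fit_bm_asr(tree, table.set_index("species")[cols[1]])
            return diploid_edge_vectors(tree, rx, ry, tip_values=table)

        v1, v2 = vecs(df), vecs(rot)
        for a, b in zip(v1.vectors, v2.vectors):
            expect = R @ np.array([a.dx, a.dy])
            assert (b.dx, b.dy) == pytest.approx(tuple(expect), abs=1e-8)
            assert b.magnitude == pytest.approx(a.magnitude, abs=1e-8)


class TestQuadrants:
    @pytest.mark.parametrize(
        "dx,dy,label",
        [
            (-1.0, 1.0, "shorter, wider"),
            (2.0, 0.1, "longer, wider"),
            (-0.1, -0.1, "shorter, narrower"),
            (0.5, -2.0, "longer, narrower"),
            (0.0, 1.0, "wider (length unchanged)"),
            (-1.0, 0.0, "shorter (width unchanged)"),
        ],
    )
    def test_length_width_labels(self, dx, dy, label):
        assert quadrant_classify(DivergenceVector(dx, dy)) == label

    def test_zero_vector_error(self):
        with pytest.raises(ValueError):
            quadrant_classify(DivergenceVector(0.0, 0.0))


class TestProgenitorDrift:
    def test_three_four_five(self):
        reg = fe.PolyploidRegistry(
            (
                fe.PolyploidEntry(
                    accession="q1", species="q", maternal="M", paternal="P", age=1.4
                ),
            )
        )
        extant = pd.DataFrame(
            {
                "species": ["M", "P"],
                "tube_length": [1.0, 1.0],
                "tube_width": [1.0, 1.0],
            }
        )
        rec = {
            "q1": fe.ProgenitorReconstruction(
                accession="q1",
                traits=("tube_length", "tube_width"),
                maternal_state=np.array([4.0, 5.0]),
                paternal_state=np.array([1.0, 1.0]),
            )
        }
        t = progenitor_drift(extant, rec, reg)
        m = t.set_index("role")
        assert m.loc["maternal", "distance"] == pytest.approx(5.0)
        assert m.loc["paternal", "distance"] == pytest.approx(0.0)

    def test_drift_increases_with_age(self):
        # older origins anchor deeper in the tree, so reconstructed progenitor
        # states drift farther from extant means on average
        rows = []
        for i in range(60):
            sc = fe.simulate_scenario(
                8000 + i,
                n_diploid_tips=16,
                event_plan=((0.4, 1), (1.4, 1), (4.3, 1)),
            )
            rec = fe.reconstructed_progenitors(
                sc.full_tree, sc.registry, sc.diploid_means
            )
            rows.append(progenitor_drift(sc.diploid_means, rec, sc.registry))
        t = pd.concat(rows)
        rho, _ = spearmanr(t["distance"], t["age"])
        assert rho > 0
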