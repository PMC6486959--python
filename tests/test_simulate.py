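"""Generators: reproducibility, construction invariants, ensemble checks."""

import numpy as np
import pandas as pd
import pytest

import floralevo as fe
from floralevo.morphometrics import procrustes_distance
from floralevo.simulate import (
    DisplacementSpec,
    SimConfig,
    expand_replicates,
    sim_landmarks,
    sim_spectra,
)
from floralevo.spectra import normalize_area
from floralevo.vectors import polyploid_vectors


class TestSimTree:
    def test_deterministic_under_seed(self):
        a = fe.write_newick(fe.sim_tree(32, seed=5))
        b = fe.write_newick(fe.sim_tree(32, seed=5))
        assert a == b

    def test_bifurcating_internal_count(self):
        t = fe.sim_tree(17, seed=1)
        assert len(t.internal_nodes) == 16

    def test_depth_scales_inversely_with_birth_rate(self):
        heights = {}
        for rate in (0.5, 2.0):
            hs = [
                max(fe.sim_tree(10, birth_rate=rate, seed=s).depths().values())
                for s in range(40)
            ]
            heights[rate] = np.mean(hs)
        assert heights[0.5] > 2.5 * heights[2.0]


class TestSimBmTraits:
    def test_zero_rate_collapses_to_root_state(self):
        t = fe.sim_tree(6, seed=0)
        df, _ = fe.sim_bm_traits(t, {"x": 1e-20}, {"x": 3.0}, seed=1)
        np.testing.assert_allclose(df["x"], 3.0, atol=1e-6)

    def test_ensemble_tip_covariance_matches_sigma2_C(self):
        t = fe.parse_newick("((A:1,B:1):1,C:2);")
        C, taxa = t.vcv()
        reps = 2000
        X = np.empty((reps, 3))
        for i in range(reps):
            df, _ = fe.sim_bm_traits(t, {"x": 1.0}, {"x": 0.0}, seed=i)
            X[i] = df.set_index("species")["x"].reindex(taxa).to_numpy()
        emp = np.cov(X.T)
        assert np.abs(emp - C).max() / C.max() < 0.1


class TestScenario:
    def test_reproducible(self):
        a = fe.simulate_scenario(11)
        b = fe.simulate_scenario(11)
        assert fe.write_newick(a.full_tree) == fe.write_newick(b.full_tree)
        pd.testing.assert_frame_equal(a.accession_means, b.accession_means)
        pd.testing.assert_frame_equal(a.displacement_truth, b.displacement_truth)

    def test_study_scale_composition(self):
        sc = fe.simulate_scenario(12)
        assert sc.diploid_tree.n_tips == 32
        assert len(sc.registry) == 20
        young = [e for e in sc.registry if e.age_class == "young"]
        old = [e for e in sc.registry if e.age_class == "old"]
        assert (len(young), len(old)) == (13, 7)
        # both homeolog copies present in the full tree
        tips = set(sc.full_tree.tips)
        for e in sc.registry:
            assert e.maternal_tip in tips and e.paternal_tip in tips

    def test_zero_displacement_gives_zero_vectors(self):
        null_disp = {
            "length_width": DisplacementSpec(kappa=0.0, magnitude_frac=0.0),
            "shape": DisplacementSpec(kappa=0.0, magnitude_frac=0.0),
        }
        sc = fe.simulate_scenario(13, displacement=null_disp)
        vs = polyploid_vectors(
            sc.registry, sc.accession_means, sc.diploid_means, basis="extant"
        )
        assert vs.n == 0 and len(vs.excluded) == 20

    def test_biased_displacement_lands_in_quadrant(self):
        sc = fe.simulate_scenario(14)  # default: kappa=4 toward 135 degrees
        vs = polyploid_vectors(
            sc.registry, sc.accession_means, sc.diploid_means,
            plane="length_width", basis="extant",
        )
        labels = [fe.quadrant_classify(v) for v in vs.vectors]
        assert sum(l == "shorter, wider" for l in labels) > len(labels) / 2

    def test_truth_records_match_vectors(self):
        sc = fe.simulate_scenario(15)
        vs = polyploid_vectors(
            sc.registry, sc.accession_means, sc.diploid_means,
            plane="length_width", basis="extant",
        )
        truth = sc.displacement_truth.query("plane == 'length_width'").set_index(
            "accession"
        )
        for v in vs.vectors:
            assert v.magnitude == pytest.approx(truth.loc[v.source, "magnitude"])
            assert v.angle == pytest.approx(truth.loc[v.source, "angle"], abs=1e-9)


class TestReplicates:
    def test_scenario_photo_table_recovers_means(self):
        from floralevo.simulate import photo_level_table

        sc = fe.simulate_scenario(2, n_diploid_tips=8, event_plan=((0.6, 1),))
        df = photo_level_table(sc, seed=3)
        assert len(df) == (8 + 1) * 125
        back = fe.hierarchical_mean(df, "species").set_index("species")
        truth = sc.diploid_means.set_index("species")
        # replicate noise is small relative to the trait range
        rng = truth["tube_length"].max() - truth["tube_length"].min()
        err = (back["tube_length"] - truth["tube_length"]).abs().dropna()
        assert err.max() < 0.15 * rng

    def test_design_shape(self):
        means = pd.DataFrame({"species": ["a", "b"], "tube_length": [2.0, 3.0]})
        df = expand_replicates(means, design=(5, 5, 5), seed=0)
        assert len(df) == 2 * 125
        assert fe.validate_trait_table(df) == "photo"

    def test_zero_noise_preserves_means(self):
        means = pd.DataFrame({"species": ["a", "b"], "tube_length": [2.0, 3.0]})
        df = expand_replicates(
            means, design=(3, 3, 3), noise_sd={"tube_length": 0.0}, seed=0
        )
        out = fe.hierarchical_mean(df, "species")
        np.testing.assert_allclose(
            out.sort_values("species")["tube_length"], [2.0, 3.0]
        )


class TestSimSpectra:
    def test_shared_archetype_collapses_after_normalization(self):
        specs, groups = sim_spectra(
            archetypes=[[(500.0, 40.0, 0.4)]], n_per_group=2, noise_sd=0.0, seed=0
        )
        a, b = (normalize_area(s) for s in specs)
        np.testing.assert_allclose(a.reflectance, b.reflectance, atol=1e-10)

    def test_two_archetypes_yield_retained_component(self):
        specs, _ = sim_spectra(n_per_group=8, seed=1)
        normed = [normalize_area(s) for s in specs]
        out = fe.spectra_pca(normed)
        assert out.retained >= 1

    def test_dip_outside_band_rejected(self):
        with pytest.raises(ValueError):
            sim_spectra(archetypes=[[(900.0, 20.0, 0.3)]], seed=0)


class TestSimLandmarks:
    def test_zero_noise_zero_deformation_identical_shapes(self):
        configs, _ = sim_landmarks(n_specimens=5, s_sd=0.0, noise_sd=0.0, seed=0)
        for c in configs[1:]:
            assert procrustes_distance(configs[0], c) < 1e-8

    def test_reproducible(self):
        a, sa = sim_landmarks(n_specimens=6, seed=3)
        b, sb = sim_landmarks(n_specimens=6, seed=3)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(sa, sb)
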