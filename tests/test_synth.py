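import numpy as np
import pandas as pd
import pytest

import exprevo as ev
from exprevo.io import ValidationError
from exprevo.synth import (CONUS_SPECIES, GLAND_TYPE, LEG_SPECIES,
                           STUDY_SPECIES, Shift, three_class_map,
                           two_class_map)

from conftest import dense_cov


class TestSimulateTree:
    def test_random_is_ultrametric(self):
        for seed in range(5):
            t = ev.simulate_tree(4 + seed, topology="random", seed=seed)
            d = t.depths()[t.is_tip]
            assert d.max() - d.min() < 1e-9 * max(d.max(), 1.0)

    def test_study_topology_venom_clade_monophyletic(self):
        t = ev.simulate_tree(12, topology="study")
        assert sorted(t.tip_labels) == sorted(STUDY_SPECIES)
        node = t.mrca(CONUS_SPECIES)
        assert sorted(t.clade_tips(node)) == sorted(CONUS_SPECIES)
        # the glandless lineage is sister to the venomous clade
        node18 = t.mrca(CONUS_SPECIES + ["MMI"])
        assert sorted(t.clade_tips(node18)) == sorted(CONUS_SPECIES + ["MMI"])

    def test_study_topology_deterministic(self):
        a = ev.simulate_tree(12, topology="study").to_newick()
        b = ev.simulate_tree(12, topology="study").to_newick()
        assert a == b

    def test_random_seed_determinism(self):
        a = ev.simulate_tree(8, topology="random", seed=3).to_newick()
        b = ev.simulate_tree(8, topology="random", seed=3).to_newick()
        assert a == b

    def test_study_topology_requires_12(self):
        with pytest.raises(ValidationError):
            ev.simulate_tree(10, topology="study")

    def test_class_maps_cover_groups(self):
        t = ev.simulate_tree(12, topology="study")
        t.apply_class_map(three_class_map())
        for sp in CONUS_SPECIES:
            assert t.rate_class[t.tip_index(sp)] == 2
        for sp in LEG_SPECIES:
            assert t.rate_class[t.tip_index(sp)] == 1
        for sp, gt in GLAND_TYPE.items():
            if gt in ("OEG", "glandless"):
                assert t.rate_class[t.tip_index(sp)] == 0


class TestSimulateBMTraits:
    def test_increment_variance(self):
        """Two tips at distance 2: var(tip1 - tip2) = 2 sigma^2 t."""
        t = ev.SpeciesTree.from_newick("(A:1,B:1);")
        tips, _ = ev.simulate_bm_traits(t, 10000, {0: 1.0}, seed=0)
        diff = tips["A"] - tips["B"]
        assert np.var(diff) == pytest.approx(2.0, rel=0.05)

    def test_tip_covariance_matches_bm(self, study_tree):
        """With a fixed root, empirical tip covariance matches the rate-weighted
        shared-path matrix entrywise within Monte-Carlo error."""
        sig = {0: 0.6, 1: 1.8}
        n = 8000
        tips, _ = ev.simulate_bm_traits(study_tree, n, sig, root_sd=0.0, seed=1)
        C = dense_cov(study_tree, list(tips.columns), sig)
        emp = np.cov(tips.to_numpy().T)
        # SE of a sample covariance ~ sqrt((c_ii c_jj + c_ij^2)/n)
        for i in range(12):
            for j in range(12):
                se = np.sqrt((C[i, i] * C[j, j] + C[i, j] ** 2) / n)
                assert abs(emp[i, j] - C[i, j]) < 3.5 * se

    def test_degenerate_sigma(self, study_tree):
        tips, _ = ev.simulate_bm_traits(study_tree, 50, {0: 1e-12, 1: 1e-12},
                                        seed=2)
        assert tips.std(axis=1).max() < 1e-4


class TestSimulateExpression:
    def _config(self, **kw):
        defaults = dict(n_ogs=120, seed=0, frac_tissue_specific=0.1,
                        replicate_noise_sd=0.0, frac_multi_member=0.3,
                        rate_classes={0: 0.6, 1: 1.8})
        defaults.update(kw)
        return ev.SimConfig(**defaults)

    def test_noise_free_replicates_identical(self, study_tree):
        sim = ev.simulate_expression(study_tree, self._config())
        expr = sim.expressions["CIM"]
        gland = [s for s in expr.values.columns if "_gland_" in s]
        assert np.allclose(expr.values[gland].std(axis=1), 0.0)

    def test_shared_baseline_without_planting(self, study_tree):
        """Non-specific OGs have identical tissue profiles noise-free."""
        sim = ev.simulate_expression(study_tree, self._config())
        prof = ev.tissue_means(sim.expressions["MPI"], "MPI")
        planted = set().union(*sim.true_specific.values())
        bg = [f"MPI_{og}" for og in sim.og_map.og_ids if og not in planted][:20]
        sub = prof.loc[bg]
        assert np.allclose(sub.std(axis=1), 0.0, atol=1e-9)

    def test_planted_specificity_recovered(self, study_tree):
        sim = ev.simulate_expression(study_tree, self._config())
        calls = ev.classify_specific(ev.tissue_means(sim.expressions["PMA"], "PMA"))
        for tissue, ogs in sim.true_specific.items():
            for og in ogs:
                assert calls.loc[f"PMA_{og}", "assigned_tissue"] == tissue

    def test_shift_changes_truth_ancestral(self, study_tree):
        shift = Shift(tips=CONUS_SPECIES + ["MMI"], tissue="gland",
                      delta=-3.0, ogs="specific:esophagus")
        sim0 = ev.simulate_expression(study_tree, self._config())
        sim1 = ev.simulate_expression(study_tree, self._config(shifts=[shift]))
        node = study_tree.mrca(CONUS_SPECIES + ["MMI"])
        ogs = sorted(sim1.true_specific["esophagus"])
        d = (sim1.true_ancestral["gland"].loc[node, ogs]
             - sim0.true_ancestral["gland"].loc[node, ogs])
        assert np.allclose(d, -3.0)
        parent = int(study_tree.parent[node])
        dp = (sim1.true_ancestral["gland"].loc[parent, ogs]
              - sim0.true_ancestral["gland"].loc[parent, ogs])
        assert np.allclose(dp, 0.0)

    def test_og_map_and_multi_members(self, study_tree):
        sim = ev.simulate_expression(study_tree, self._config())
        counts = sim.og_map.table.groupby(["og_id", "species"]).size()
        assert counts.max() == 2 and counts.min() == 1
        frac = (counts == 2).mean()
        assert 0.15 < frac < 0.45  # around the configured 0.3
        # every OG complete across all 12 species
        assert len(sim.og_map.complete_ogs()) == 120

    def test_missing_tissue_combination(self, study_tree):
        cfg = self._config(missing=[("MMI", "gland")])
        sim = ev.simulate_expression(study_tree, cfg)
        tissues = set(sim.expressions["MMI"].samples["tissue"])
        assert "gland" not in tissues
        prof = ev.tissue_means(sim.expressions["MMI"], "MMI")
        assert "gland" not in prof.columns

    def test_seed_determinism(self, study_tree):
        a = ev.simulate_expression(study_tree, self._config())
        b = ev.simulate_expression(study_tree, self._config())
        pd.testing.assert_frame_equal(a.expressions["CQU"].values,
                                      b.expressions["CQU"].values)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            ev.SimConfig(frac_secreted=1.5)
        with pytest.raises(ValidationError):
            ev.SimConfig(rate_classes={0: -1.0})
        with pytest.raises(ValidationError):
            ev.SimConfig(n_replicates=0)


class TestWriteStudy:
    def test_round_trip_through_disk(self, tmp_path, study_tree):
        cfg = ev.SimConfig(n_ogs=30, seed=1, frac_tissue_specific=0.1,
                           rate_classes={0: 0.6, 1: 1.8})
        sim = ev.simulate_expression(study_tree, cfg)
        paths = ev.write_study(sim, tmp_path / "study")
        tree = ev.read_tree(paths["tree"])
        assert sorted(tree.tip_labels) == sorted(study_tree.tip_labels)
        expr = ev.read_expression(paths["expr:MPI"],
                                  str(paths["expr:MPI"]).replace("_tpm", "_samples"))
        pd.testing.assert_index_equal(expr.values.index,
                                      sim.expressions["MPI"].values.index,
                                      check_names=False)
        assert np.allclose(expr.values.to_numpy(),
                           sim.expressions["MPI"].values.to_numpy(), atol=1e-6)
        og_map = ev.read_og_map(paths["og_map"])
        assert og_map.og_ids == sim.og_map.og_ids
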