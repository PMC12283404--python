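"""Generator contracts: determinism, distributional properties, planted truth."""

import hashlib
import math

import numpy as np
import pandas as pd
import pytest

from epirange.cleaning import CleaningConfig, clean_all
from epirange.io_formats import (
    RegionAtlas,
    read_checklist,
    read_occurrences,
    read_ref_points,
    read_trees,
)
from epirange.range_metrics import compute_eoo
from epirange.synthetic_data import (
    VIOLATION_CLASSES,
    _two_clade_tree,
    expected_hull_fraction,
    make_scenario,
    make_toy_atlas,
    polytomy_resolutions,
    simulate_lifeform,
    simulate_log_range,
    simulate_occurrences,
    simulate_tree,
    tree_depth,
)


class TestSimulateTree:
    def test_topology_counts(self):
        tree = simulate_tree(3, 1.0, seed=1)
        assert len(tree.leaf_nodes()) == 3
        assert sum(1 for _ in tree.preorder_internal_node_iter()) == 2

    def test_same_seed_identical_newick(self):
        a = simulate_tree(12, 1.0, seed=4).as_string(schema="newick")
        b = simulate_tree(12, 1.0, seed=4).as_string(schema="newick")
        assert a == b
        c = simulate_tree(12, 1.0, seed=5).as_string(schema="newick")
        assert a != c

    def test_mean_depth_matches_yule_expectation(self):
        n, lam = 50, 1.0
        depths = [tree_depth(simulate_tree(n, lam, s)) for s in range(300)]
        expected = sum(1.0 / (k * lam) for k in range(2, n + 1))
        assert abs(np.mean(depths) - expected) / expected < 0.10


class TestSimulateLifeform:
    def test_absorbing_case_all_terrestrial(self):
        tree = simulate_tree(20, 1.0, seed=2)
        labels = simulate_lifeform(tree, (0.0, 0.5), seed=3)
        assert set(labels.values()) == {"terrestrial"}

    def test_stationary_fraction_for_symmetric_rates(self):
        total = epi = 0
        for s in range(30):
            tree = simulate_tree(100, 1.0, seed=100 + s)
            labels = simulate_lifeform(tree, (0.6, 0.6), seed=200 + s)
            vals = list(labels.values())
            total += len(vals)
            epi += sum(v == "epiphyte" for v in vals)
        frac = epi / total
        # tips within a tree are correlated: allow a generous Monte-Carlo band
        assert abs(frac - 0.5) < 0.1

    def test_low_rates_cluster_lifeform_with_clades(self):
        def cramers_v(labels, clades):
            ct = pd.crosstab(pd.Series(labels), pd.Series(clades)).to_numpy()
            n = ct.sum()
            if min(ct.shape) < 2:
                return 0.0
            exp = np.outer(ct.sum(1), ct.sum(0)) / n
            return float(np.sqrt((((ct - exp) ** 2) / exp).sum() / n))

        # With symmetric rates the two clade stems diverge in state at most
        # half the time, so strong association (V > 0.5) appears in roughly
        # half of the replicates under low rates and essentially never under
        # fast (phylogeny-erasing) rates.
        strong = {}
        for rates in ((0.08, 0.08), (5.0, 5.0)):
            vs = []
            for s in range(40):
                tree = _two_clade_tree(80, 1.0, 20.0, seed=s)
                labels = simulate_lifeform(tree, rates, seed=300 + s)
                keys = sorted(labels)
                vs.append(cramers_v([labels[t] for t in keys],
                                    [t[0] for t in keys]))
            strong[rates] = (sum(v > 0.5 for v in vs), float(np.median(vs)))
        assert strong[(0.08, 0.08)][0] >= 12
        assert strong[(5.0, 5.0)][0] <= 3
        assert strong[(0.08, 0.08)][1] > strong[(5.0, 5.0)][1]


class TestSimulateLogRange:
    def test_noise_free_limit_is_exact_linear_predictor(self):
        tree = simulate_tree(15, 1.0, seed=6)
        labels = simulate_lifeform(tree, (0.5, 0.5), seed=7)
        taxa, y = simulate_log_range(tree, labels, 2.0, 0.5, 0.8, 1e-12, seed=8)
        ind = np.array([labels[t] == "epiphyte" for t in taxa], float)
        assert np.allclose(y, 2.0 + 0.5 * ind, atol=1e-4)

    def test_lambda_zero_noise_is_uncorrelated_across_species(self):
        tree = simulate_tree(10, 1.0, seed=16)
        labels = {l.taxon.label: "terrestrial" for l in tree.leaf_node_iter()}
        draws = np.array(
            [
                simulate_log_range(tree, labels, 0.0, 0.0, 0.0, 1.0, seed=s)[1]
                for s in range(400)
            ]
        )
        corr = np.corrcoef(draws.T)
        off = np.abs(corr[~np.eye(10, dtype=bool)])
        assert off.mean() < 0.1


@pytest.fixture(scope="module")
def species_df():
    return pd.DataFrame(
        [
            {"species": "Aster alpinus", "native_region": "R01",
             "foreign_region": "R03", "eoo_target_km2": 8000.0,
             "n_geo": 12, "n_nongeo": 6},
            {"species": "Vanda caerulea", "native_region": "R02",
             "foreign_region": "R05", "eoo_target_km2": 3000.0,
             "n_geo": 8, "n_nongeo": 4},
        ]
    )


class TestSimulateOccurrences:
    def test_zero_rates_cleaning_removes_nothing(self, species_df, toy_atlas):
        atlas, refs = toy_atlas
        geo, nongeo, truth = simulate_occurrences(species_df, {}, atlas, 1,
                                                  ref_points=refs)
        assert set(truth["label"]) == {"clean"}
        cl = [
            e for e in (
                _entry("Aster alpinus", {"R01"}),
                _entry("Vanda caerulea", {"R02"}),
            )
        ]
        cg, cn, rep = clean_all(geo, nongeo, cl, atlas, refs, CleaningConfig())
        assert len(cg) == len(geo) and len(cn) == len(nongeo)
        assert all(s.records_removed == 0 for s in rep.stages)

    def test_exact_planted_counts_removed_by_matching_filter(
        self, species_df, toy_atlas
    ):
        atlas, refs = toy_atlas
        counts = {cls: 2 for cls in VIOLATION_CLASSES}
        geo, nongeo, truth = simulate_occurrences(
            species_df, None, atlas, 2, ref_points=refs, violation_counts=counts
        )
        cl = [_entry("Aster alpinus", {"R01"}), _entry("Vanda caerulea", {"R02"})]
        cg, cn, rep = clean_all(geo, nongeo, cl, atlas, refs, CleaningConfig())
        by_filter = {name: set(rep.removed_ids(name)) for name in
                     {s.name for s in rep.stages}}
        for cls, filt in VIOLATION_CLASSES.items():
            planted = set(truth.loc[truth.label == cls, "record_id"])
            assert len(planted) == 4  # 2 per species
            assert planted <= by_filter[filt]
        removed_all = set().union(*by_filter.values())
        violations = set(truth.loc[truth.label != "clean", "record_id"])
        assert removed_all == violations  # precision == recall == 1

    def test_truth_labels_partition_records(self, species_df, toy_atlas):
        atlas, refs = toy_atlas
        geo, nongeo, truth = simulate_occurrences(
            species_df, {"duplicate_exact": 0.3, "nongeo_nonnative": 0.3},
            atlas, 3, ref_points=refs,
        )
        ids = [r.record_id for r in geo] + [r.record_id for r in nongeo]
        assert len(ids) == len(set(ids))
        assert sorted(truth["record_id"]) == sorted(ids)
        assert truth["record_id"].is_unique
        assert set(truth["label"]) <= {"clean"} | set(VIOLATION_CLASSES)

    def test_hull_area_tracks_target_for_dense_species(self, toy_atlas):
        atlas, refs = toy_atlas
        df = pd.DataFrame(
            [
                {"species": f"Sp num{i}", "native_region": "R01",
                 "foreign_region": "R02", "eoo_target_km2": 12_000.0,
                 "n_geo": 40, "n_nongeo": 0}
                for i in range(10)
            ]
        )
        geo, _, _ = simulate_occurrences(df, {}, atlas, 4, ref_points=refs)
        errs = []
        for sp in df["species"]:
            pts = [(r.latitude, r.longitude) for r in geo if r.species == sp]
            errs.append(abs(compute_eoo(pts) - 12_000.0) / 12_000.0)
        assert np.mean(errs) < 0.15
        assert max(errs) < 0.4

    def test_hull_fraction_calibration_is_sane(self):
        # more points fill the disc better; values are fractions of the disc
        f3, f30, f200 = (expected_hull_fraction(n) for n in (3, 30, 200))
        assert 0.0 < f3 < f30 < f200 < 1.0
        assert f200 > 0.85


class TestScenarios:
    def test_unknown_scenario_errors(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            make_scenario("nope", seed=0)

    def test_fixed_seed_gives_identical_files(self, tmp_path):
        a = make_scenario("baseline", {"n_species": 20}, seed=9)
        b = make_scenario("baseline", {"n_species": 20}, seed=9)
        pa = a.write(tmp_path / "a")
        pb = b.write(tmp_path / "b")
        for key in pa:
            ha = hashlib.sha256(pa[key].read_bytes()).hexdigest()
            hb = hashlib.sha256(pb[key].read_bytes()).hexdigest()
            assert ha == hb, key

    def test_emitted_files_readable_without_issues_when_clean(self, tmp_path):
        sc = make_scenario(
            "baseline",
            {"n_species": 15, "violation_rates": {}, "n_trees": 2},
            seed=3,
        )
        paths = sc.write(tmp_path)
        occ = read_occurrences(paths["occurrences_geo"])
        assert not occ.issues and occ.n_rejected == 0
        occ2 = read_occurrences(paths["occurrences_nongeo"])
        assert not occ2.issues
        cl = read_checklist(paths["checklist"])
        assert not cl.issues and len(cl) == 15
        trees = read_trees(paths["trees"])
        assert len(trees) == 2
        atlas = RegionAtlas.from_geojson(paths["regions"])
        atlas.validate_checklist(list(cl))
        assert len(read_ref_points(paths["ref_points"])) == 8

    def test_confounded_concentrates_epiphytes_in_low_clade(self):
        sc = make_scenario("confounded_clades", {"n_species": 120}, seed=1)
        in_a = np.array([t.startswith("a") for t in sc.taxa])
        ind = np.array([sc.lifeform[t] == "epiphyte" for t in sc.taxa])
        resid = sc.log_range - sc.config.beta_lifeform * ind
        low_is_a = resid[in_a].mean() < resid[~in_a].mean()
        frac_a = ind[in_a].mean()
        frac_b = ind[~in_a].mean()
        if low_is_a:
            assert frac_a > 0.7 > 0.3 > frac_b
        else:
            assert frac_b > 0.7 > 0.3 > frac_a

    def test_null_effect_has_zero_lifeform_coefficient(self):
        sc = make_scenario("null_effect", {"n_species": 12}, seed=2)
        assert sc.config.beta_lifeform == 0.0


class TestPolytomyResolutions:
    def test_resolutions_preserve_tips_and_have_lengths(self):
        tree = simulate_tree(40, 1.0, seed=12)
        res = polytomy_resolutions(tree, 5, seed=13)
        assert len(res) == 5
        tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
        for t in res:
            assert sorted(l.taxon.label for l in t.leaf_node_iter()) == tips
            for nd in t.preorder_node_iter():
                if nd.parent_node is not None:
                    assert nd.edge.length is not None and nd.edge.length >= 0


def _entry(species, regions):
    from epirange.io_formats import ChecklistEntry

    return ChecklistEntry(species, "terrestrial", "F01", frozenset(regions))
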