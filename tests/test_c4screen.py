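"""Induction calls, profile divergence, the TF filter, lineage classes."""

import numpy as np
import pandas as pd
import pytest

from grasskit import c4screen as c4
from grasskit import gradient as gr
from grasskit import synthetic as syn

SPECIES = syn.default_species()
PATTERNS = [{"Zm"}] * 4 + [{"Zm", "Sb"}] * 3 + [{"Zm", "Sb", "Sv"}]


def planted_design(seed, fold=4.0, noise_cv=0.2, n_genes=1000, n_tf=200):
    planted = tuple(
        syn.PlantedTF(i, frozenset(p), fold) for i, p in enumerate(PATTERNS)
    )
    return syn.GradientDesign(
        n_genes=n_genes, n_tf=n_tf, planted=planted, noise_cv=noise_cv,
        seed=seed,
    )


def screen(design):
    res = syn.generate_gradient(design)
    profiles = {sp: gr.mean_profiles(ds) for sp, ds in res.datasets.items()}
    cfg = c4.ScreenConfig(cluster_tf_ids=tuple(res.tf_ids))
    cands, att = c4.tf_filter(
        profiles, res.ortholog_map, list(design.species), cfg
    )
    return res, profiles, cands, att


class TestAssessInduction:
    @pytest.mark.parametrize(
        "profile,expected",
        [
            ((10, 100, 400, 800), True),   # strong tipward induction
            ((500, 500, 500, 500), False),  # high but flat: fold 1 < 4
            ((10, 8, 6, 5), False),         # declining
            ((10, 400, 200, 800), False),   # dips >10% after stage 2
            ((0, 100, 400, 800), True),     # zero base: infinite fold
        ],
    )
    def test_induction_calls(self, profile, expected):
        call, diag = c4.assess_induction(profile)
        assert call is expected


class TestNormalizeProfile:
    def test_divides_by_maximum(self):
        vec, expressed = c4.normalize_profile((2, 4, 8, 8))
        assert np.allclose(vec, (0.25, 0.5, 1, 1))
        assert expressed

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.random(4) + 0.1
        a, _ = c4.normalize_profile(p)
        b, _ = c4.normalize_profile(17.3 * p)
        assert np.allclose(a, b)

    def test_all_zero_flagged_non_expressed(self):
        vec, expressed = c4.normalize_profile((0, 0, 0, 0))
        assert not expressed


class TestProfileDivergence:
    def test_identical_profiles_zero(self):
        p = np.array([0.1, 0.5, 0.8, 1.0])
        assert c4.profile_divergence(p, p) == pytest.approx(0.0)

    def test_perfect_anticorrelation_is_two(self):
        p = np.array([0.0, 0.33, 0.67, 1.0])
        q = np.array([1.0, 0.67, 0.33, 0.0])
        assert c4.profile_divergence(p, q) == pytest.approx(2.0)

    def test_matches_hand_computed_pearson(self):
        rng = np.random.default_rng(1)
        # strongly shaped vectors stay on the correlation branch
        p = np.sort(rng.random(4))
        p /= p.max()
        q = np.sort(rng.random(4))[::-1]
        q /= q.max()
        r = np.corrcoef(p, q)[0, 1]
        assert c4.profile_divergence(p, q, flat_tol=0.0) == pytest.approx(1 - r)

    def test_constant_profile_falls_back_with_warning(self):
        p = np.array([1.0, 1.0, 1.0, 1.0])
        q = np.array([0.2, 0.4, 0.8, 1.0])
        with pytest.warns(UserWarning, match="constant"):
            d = c4.profile_divergence(p, q)
        assert d == pytest.approx(np.linalg.norm(p - q) / 2)

    def test_euclidean_metric_bounds(self):
        p = np.array([1.0, 0.0, 0.0, 1.0])
        q = np.array([0.0, 1.0, 1.0, 0.0])
        d = c4.profile_divergence(p, q, metric="euclidean-on-normalized")
        assert d == pytest.approx(1.0)


class TestClassifyLineage:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ({"Zm": True, "Sb": False, "Sv": False}, "reference-specific"),
            ({"Zm": True, "Sb": True, "Sv": False}, "Andropogoneae-shared"),
            ({"Zm": True, "Sb": True, "Sv": True}, "pan-C4"),
            ({"Zm": False, "Sb": False, "Sv": False}, "none"),
            ({"Zm": False, "Sb": True, "Sv": False}, "none"),
            ({"Zm": False, "Sb": False, "Sv": True}, "none"),
            ({"Zm": False, "Sb": True, "Sv": True}, "none"),
            ({"Zm": True, "Sb": False, "Sv": True}, "none"),
        ],
    )
    def test_all_flag_combinations(self, flags, expected):
        cand = c4.TFCandidate("tf", {}, flags, {}, frozenset())
        assert c4.classify_lineage(cand, SPECIES, "Zm") == expected

    def test_all_non_comparable_is_reference_specific(self):
        cand = c4.TFCandidate(
            "tf", {}, {}, {}, frozenset({"Sb", "Sv", "Do", "Os"})
        )
        assert c4.classify_lineage(cand, SPECIES, "Zm") == "reference-specific"


class TestTfFilter:
    def test_planted_recovery_single_seed(self):
        res, _, cands, att = screen(planted_design(seed=0))
        assert {c.gene for c in cands} == set(res.planted["gene"])
        cats = {c.gene: c.category for c in cands}
        expected = (
            ["reference-specific"] * 4 + ["Andropogoneae-shared"] * 3
            + ["pan-C4"]
        )
        assert [cats[f"TF{i:04d}"] for i in range(8)] == expected

    def test_no_signal_design_yields_no_candidates(self):
        design = syn.GradientDesign(n_genes=400, n_tf=100, noise_cv=0.2, seed=1)
        res = syn.generate_gradient(design)
        profiles = {sp: gr.mean_profiles(ds) for sp, ds in res.datasets.items()}
        cfg = c4.ScreenConfig(cluster_tf_ids=tuple(res.tf_ids))
        cands, _ = c4.tf_filter(profiles, res.ortholog_map,
                                list(design.species), cfg)
        assert cands == []

    def test_infinite_tau_returns_nothing(self):
        design = planted_design(seed=2, n_genes=300, n_tf=50)
        res = syn.generate_gradient(design)
        profiles = {sp: gr.mean_profiles(ds) for sp, ds in res.datasets.items()}
        cfg = c4.ScreenConfig(cluster_tf_ids=tuple(res.tf_ids),
                              divergence_tau=np.inf)
        cands, _ = c4.tf_filter(profiles, res.ortholog_map,
                                list(design.species), cfg)
        assert cands == []

    def test_zero_tau_returns_all_stage2_survivors(self):
        design = planted_design(seed=3, n_genes=300, n_tf=50)
        res = syn.generate_gradient(design)
        profiles = {sp: gr.mean_profiles(ds) for sp, ds in res.datasets.items()}
        cfg = c4.ScreenConfig(cluster_tf_ids=tuple(res.tf_ids),
                              divergence_tau=1e-12, min_effect=0.0)
        cands, att = c4.tf_filter(profiles, res.ortholog_map,
                                  list(design.species), cfg)
        assert len(cands) == att["mean_fpkm"] - att["c3_inconsistent"]

    def test_low_mean_fpkm_excluded(self):
        profiles = {
            sp.label: pd.DataFrame(
                {1: [3.0], 2: [3.0], 3: [3.0], 4: [3.0]}, index=["tf1"]
            )
            for sp in SPECIES
        }
        omap = pd.DataFrame(
            {sp.label: ["tf1"] for sp in SPECIES}, index=["tf1"]
        )
        cfg = c4.ScreenConfig(cluster_tf_ids=("tf1",))
        cands, att = c4.tf_filter(profiles, omap, SPECIES, cfg)
        assert att["mean_fpkm"] == 0 and cands == []

    def test_missing_orthologs_everywhere_reference_specific(self):
        profiles = {"Zm": pd.DataFrame(
            {1: [40.0], 2: [30.0], 3: [20.0], 4: [10.0]}, index=["tf1"]
        )}
        omap = pd.DataFrame(
            {sp.label: [np.nan] if sp.label != "Zm" else ["tf1"]
             for sp in SPECIES},
            index=["tf1"],
        )
        cfg = c4.ScreenConfig(cluster_tf_ids=("tf1",))
        cands, _ = c4.tf_filter(profiles, omap, SPECIES, cfg)
        assert len(cands) == 1
        assert cands[0].category == "reference-specific"
        assert cands[0].non_comparable == {"Sb", "Sv", "Do", "Os"}

    def test_recall_non_decreasing_in_fold(self):
        recalls = []
        for fold in (2.0, 4.0, 8.0):
            hits = total = 0
            for seed in range(5):
                res, _, cands, _ = screen(
                    planted_design(seed, fold=fold, n_genes=400, n_tf=100)
                )
                truth = set(res.planted["gene"])
                hits += len({c.gene for c in cands} & truth)
                total += len(truth)
            recalls.append(hits / total)
        assert recalls == sorted(recalls)
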