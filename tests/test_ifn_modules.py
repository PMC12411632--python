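import math

import numpy as np
import pandas as pd
import pytest

from clonodyn.ifn_modules import (
    FoldChangeProfile,
    cluster_panel,
    compare_scores_by_group,
    log2fc_profile,
    module_scores,
)
from clonodyn.synthetic_data import CD8_TYPES
from conftest import make_counts, make_meta


def planted_fc_profile(k_true, seed, n_genes=80, n_types=10, sep_ratio=5.0, sigma=1.0):
    """Gene fold-change rows in k_true blobs; returns (profile, truth labels).

    Separation ratio = min inter-center distance / RMS within-cluster radius.
    """
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 1, (k_true, n_types))
    dists = [np.linalg.norm(centers[i] - centers[j])
             for i in range(k_true) for j in range(i + 1, k_true)]
    radius = sigma * math.sqrt(n_types)
    centers *= sep_ratio * radius / min(dists)
    labels = np.repeat(np.arange(k_true), n_genes // k_true)
    labels = np.concatenate([labels, np.arange(n_genes - len(labels))])
    rows = centers[labels] + rng.normal(0, sigma, (n_genes, n_types))
    fc = pd.DataFrame(rows, index=[f"g{i}" for i in range(n_genes)],
                      columns=[f"T{j}" for j in range(n_types)])
    return FoldChangeProfile(fc, fc.astype(bool)), labels


def _partition_matches(assignment, truth_labels, genes):
    got = pd.Series({g: assignment[g] for g in genes})
    mapping = {}
    for lab, cluster in zip(truth_labels, got):
        mapping.setdefault(lab, cluster)
    if len(set(mapping.values())) != len(mapping):
        return False
    return all(mapping[lab] == c for lab, c in zip(truth_labels, got))


class TestLog2FCProfile:
    def _counts(self, ctl_target, sle_target, lib=100, n=50):
        dense = np.zeros((2, 2 * n), dtype=int)
        dense[0, :n] = ctl_target
        dense[0, n:] = sle_target
        dense[1, :n] = lib - ctl_target
        dense[1, n:] = lib - sle_target
        cm = make_counts(dense, gene_ids=("TARGET", "FILLER"))
        meta = make_meta(
            [(f"BC{i}", "S1", "P1", "NA", "CTL", "cM") for i in range(n)]
            + [(f"BC{i + n}", "S2", "P2", "NA", "SLE", "cM") for i in range(n)]
        )
        return cm, meta

    def test_identical_groups_give_zero(self):
        cm, meta = self._counts(10, 10)
        prof = log2fc_profile(cm, meta, ["TARGET"], pseudocount=0.0)
        assert prof.log2fc.loc["TARGET", "cM"] == pytest.approx(0.0)

    def test_exact_doubling_gives_one(self):
        cm, meta = self._counts(10, 20)
        prof = log2fc_profile(cm, meta, ["TARGET"], pseudocount=0.0)
        assert prof.log2fc.loc["TARGET", "cM"] == pytest.approx(1.0)

    def test_absent_panel_gene_dropped_with_warning(self, caplog):
        cm, meta = self._counts(10, 20)
        with caplog.at_level("WARNING"):
            prof = log2fc_profile(cm, meta, ["TARGET", "NOSUCH"])
        assert list(prof.log2fc.index) == ["TARGET"]
        assert "absent" in caplog.text

    def test_planted_elevation_recovered_per_cell_type(self, calibration_cohort):
        cfg, cohort = calibration_cohort
        prof = log2fc_profile(cohort.counts, cohort.meta, cfg.panel_genes)
        c2 = [g for g, m in cohort.truth.module_assignment.items() if m == "C2"]
        # per-cell-type mean over the 25 module genes: ~1 where planted, ~0 elsewhere
        in_cd8 = prof.log2fc.loc[c2, list(CD8_TYPES)].mean(axis=0)
        outside = prof.log2fc.loc[c2, ["B naive", "NK"]].mean(axis=0)
        assert np.abs(in_cd8 - 1.0).max() < 0.15
        assert np.abs(outside).max() < 0.15


class TestClusterPanel:
    def test_planted_four_blobs_recovered(self):
        prof, truth = planted_fc_profile(4, seed=0)
        part = cluster_panel(prof, k_range=range(2, 9), seed=0)
        assert part.K == 4
        assert max(part.silhouette_by_K, key=part.silhouette_by_K.get) == 4
        assert _partition_matches(part.assignment, truth, prof.log2fc.index)

    def test_two_identical_row_groups(self):
        fc = pd.DataFrame([[0.0, 0.0]] * 5 + [[4.0, 4.0]] * 5,
                          index=[f"g{i}" for i in range(10)], columns=["A", "B"])
        part = cluster_panel(FoldChangeProfile(fc, fc.astype(bool)), k_range=[2], seed=0)
        assert part.K == 2
        assert part.silhouette_by_K[2] == pytest.approx(1.0)

    def test_deterministic_and_row_order_invariant(self):
        prof, _ = planted_fc_profile(3, seed=5)
        a = cluster_panel(prof, k_range=range(2, 7), seed=3)
        b = cluster_panel(prof, k_range=range(2, 7), seed=3)
        assert a.assignment == b.assignment and a.K == b.K
        shuffled = FoldChangeProfile(
            prof.log2fc.sample(frac=1, random_state=9), prof.significant)
        c = cluster_panel(shuffled, k_range=range(2, 7), seed=3)
        assert c.K == a.K
        assert {g: c.assignment[g] for g in prof.log2fc.index} == a.assignment

    def test_degenerate_profile_is_error(self):
        fc = pd.DataFrame(np.ones((5, 3)), index=list("abcde"))
        with pytest.raises(ValueError, match="cluster structure"):
            cluster_panel(FoldChangeProfile(fc, fc.astype(bool)), k_range=[2])


class TestModuleScores:
    def test_constant_matrix_scores_zero(self):
        cm = make_counts(np.full((6, 20), 3))
        scores = module_scores(cm, {"M": ["G0", "G1"]}, control=False)
        assert np.allclose(scores["M"], 0.0)

    def test_single_gene_module_is_z_scored_expression(self):
        rng = np.random.default_rng(0)
        cm = make_counts(rng.poisson(3, (5, 100)))
        scores = module_scores(cm, {"M": ["G2"]}, control=False)
        from clonodyn.de_and_composition import normalize_cp10k

        x = normalize_cp10k(cm, log1p=True)[2]
        assert np.allclose(scores["M"], (x - x.mean()) / x.std())

    def test_z_normalization_within_tolerance(self, calibration_cohort):
        cfg, cohort = calibration_cohort
        sets = {"C2": [g for g, m in cohort.truth.module_assignment.items() if m == "C2"]}
        scores = module_scores(cohort.counts, sets, seed=0)
        assert abs(scores["C2"].mean()) < 1e-6
        assert abs(scores["C2"].std(ddof=0) - 1) < 1e-6

    def test_planted_elevation_shifts_scores(self, calibration_cohort):
        cfg, cohort = calibration_cohort
        sets = {"C2": [g for g, m in cohort.truth.module_assignment.items() if m == "C2"]}
        scores = module_scores(cohort.counts, sets, seed=0)
        meta = cohort.meta
        sle = meta["group"] == "SLE"
        cd8 = meta["cell_type"].isin(CD8_TYPES)
        elevated = scores.loc[meta.index[sle & cd8], "C2"].mean()
        rest = scores.loc[meta.index[sle & ~cd8 & (meta["cell_type"] != "Platelet")], "C2"].mean()
        assert elevated - rest > 0.5

    def test_missing_module_dropped(self, caplog):
        cm = make_counts(np.full((4, 10), 2))
        with caplog.at_level("WARNING"):
            scores = module_scores(cm, {"M": ["G0"], "GONE": ["NOSUCH"]}, control=False)
        assert list(scores.columns) == ["M"]


class TestCompareScoresByGroup:
    def _scores_meta(self, shift, n=150, seed=0):
        rng = np.random.default_rng(seed)
        scores = pd.DataFrame(
            {"C2": np.concatenate([rng.normal(0, 1, n), rng.normal(shift, 1, n)])},
            index=[f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)])
        meta = make_meta(
            [(f"A{i}", "P1_BF", "P1", "BF", "SLE", "CD8 Tem") for i in range(n)]
            + [(f"B{i}", "P1_FL", "P1", "FL", "SLE", "CD8 Tem") for i in range(n)])
        return scores, meta

    def test_identical_groups_p_one(self):
        scores, meta = self._scores_meta(0.0)
        scores["C2"] = 0.5
        out = compare_scores_by_group(scores, meta, "timepoint")
        assert out["p_adj"].iloc[0] == pytest.approx(1.0)

    def test_planted_flare_shift_direction(self):
        hits = 0
        for seed in range(20):
            scores, meta = self._scores_meta(0.5, seed=seed)
            out = compare_scores_by_group(scores, meta, "timepoint").set_index("group")
            hits += out.loc["FL", "mean"] > out.loc["BF", "mean"]
        assert hits >= 19

    def test_permuted_labels_are_calibrated(self):
        rng = np.random.default_rng(42)
        pvals = []
        for seed in range(60):
            scores, meta = self._scores_meta(0.0, n=40, seed=seed)
            meta = meta.copy()
            meta["timepoint"] = rng.permutation(meta["timepoint"].to_numpy())
            out = compare_scores_by_group(scores, meta, "timepoint")
            pvals.append(out["p_raw"].iloc[0])
        assert 0.35 < np.mean(pvals) < 0.65

    def test_single_group_is_error(self):
        scores, meta = self._scores_meta(0.0)
        meta["timepoint"] = "BF"
        with pytest.raises(ValueError):
            compare_scores_by_group(scores, meta, "timepoint")
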