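import itertools
import random

import numpy as np
import pandas as pd
import pytest

from clonodyn.clonotypes import call_clonotypes
from clonodyn.expansion import (
    ExpansionParams,
    classify_expansion,
    compare_expanded_scores,
    expanded_set,
    fate_table,
)
from clonodyn.repertoire import RepertoireProfile
from conftest import make_contig, make_meta
from oracles import oracle_expansion_status


def prof(counts, tp, patient="P1"):
    return RepertoireProfile((f"{patient}_{tp}",), counts, patient)


class TestClassifyExpansion:
    @pytest.mark.parametrize("bf,fl,clone,expected", [
        ({"x": 1}, {"c": 3, "x": 1}, "c", "expanded_de_novo"),      # absent -> 3 cells
        ({"c": 2, "x": 8}, {"c": 4, "x": 6}, "c", "expanded_fold"),  # 2->4, equal totals
        ({"c": 1, "x": 9}, {"c": 2, "x": 8}, "c", "excluded_min_cells"),  # fold ok, <3 cells
        ({"c": 1}, {"c": 1}, "c", "not_expanded"),
    ])
    def test_rule_examples(self, bf, fl, clone, expected):
        calls = classify_expansion(prof(bf, "BF"), prof(fl, "FL"))
        status = {c.clonotype_id: c.status for c in calls}
        assert status[clone] == expected

    def test_proportional_conjunct_blocks_count_fold(self):
        # 2 of 100 -> 4 of 400: count fold 2 but frequency halves
        bf = {"c": 2, "x": 98}
        fl = {"c": 4, "x": 396}
        calls = classify_expansion(prof(bf, "BF"), prof(fl, "FL"))
        status = {c.clonotype_id: c.status for c in calls}
        assert status["c"] == "not_expanded"
        loose = classify_expansion(prof(bf, "BF"), prof(fl, "FL"),
                                   ExpansionParams(require_proportional=False))
        assert {c.clonotype_id: c.status for c in loose}["c"] == "expanded_fold"

    def test_patient_mismatch_and_empty_fl(self):
        with pytest.raises(ValueError, match="patient"):
            classify_expansion(prof({"c": 1}, "BF", "P1"), prof({"c": 1}, "FL", "P2"))
        with pytest.raises(ValueError, match="empty"):
            classify_expansion(prof({"c": 1}, "BF"), prof({}, "FL"))

    def test_exhaustive_pairwise_grid_matches_oracle(self):
        # every (n_bf, n_fl) in 0..10 embedded alongside a filler clone
        for n_bf, n_fl, filler in itertools.product(range(11), range(11), (5, 50)):
            if n_bf == 0 and n_fl == 0:
                continue
            bf = {"f": filler}
            fl = {"f": filler}
            if n_bf:
                bf["c"] = n_bf
            if n_fl:
                fl["c"] = n_fl
            calls = classify_expansion(prof(bf, "BF"), prof(fl, "FL"))
            got = {c.clonotype_id: c.status for c in calls}["c"]
            want = oracle_expansion_status(n_bf, n_fl, filler + n_bf, filler + n_fl)
            assert got == want, (n_bf, n_fl, filler)

    def test_random_small_repertoires_match_oracle(self):
        rng = random.Random(0)
        for _ in range(400):
            clones = [f"c{i}" for i in range(rng.randrange(1, 7))]
            bf = {c: rng.randrange(0, 11) for c in clones}
            fl = {c: rng.randrange(0, 11) for c in clones}
            bf = {c: n for c, n in bf.items() if n}
            fl = {c: n for c, n in fl.items() if n}
            if not fl:
                continue
            N_bf, N_fl = max(sum(bf.values()), 1), sum(fl.values())
            calls = classify_expansion(prof(bf, "BF"), prof(fl, "FL"))
            for c in calls:
                want = oracle_expansion_status(
                    bf.get(c.clonotype_id, 0), fl.get(c.clonotype_id, 0), N_bf, N_fl)
                assert c.status == want

    def test_raising_thresholds_never_grows_expanded_set(self):
        rng = random.Random(1)
        for _ in range(50):
            bf = {f"c{i}": rng.randrange(1, 9) for i in range(rng.randrange(1, 7))}
            fl = {f"c{i}": rng.randrange(1, 20) for i in range(rng.randrange(1, 7))}
            prev_tau = None
            for tau in (1.5, 2.0, 3.0, 4.0):
                cur = expanded_set(classify_expansion(
                    prof(bf, "BF"), prof(fl, "FL"), ExpansionParams(fold_threshold=tau)))
                if prev_tau is not None:
                    assert cur <= prev_tau
                prev_tau = cur
            prev_m = None
            for m in (1, 2, 3, 5):
                cur = expanded_set(classify_expansion(
                    prof(bf, "BF"), prof(fl, "FL"), ExpansionParams(min_flare_cells=m)))
                if prev_m is not None:
                    assert cur <= prev_m
                prev_m = cur


def _paired_cells(spec):
    """spec: clone -> list of (barcode, timepoint, cell_type). Returns calls+meta."""
    contigs, meta_rows = [], []
    for clone, cells in spec.items():
        for bc, tp, ct in cells:
            contigs.append(make_contig(barcode=bc, chain="TRA", cdr3=clone))
            contigs.append(make_contig(barcode=bc, chain="TRB", v="TRBV1", cdr3=clone))
            meta_rows.append((bc, f"P1_{tp}", "P1", tp, "SLE", ct))
    calls, _ = call_clonotypes(contigs)
    return calls, make_meta(meta_rows)


class TestFateTable:
    def test_de_novo_clone_maps_from_absent(self):
        calls, meta = _paired_cells({
            "CAAF": [("B1", "FL", "CD8 Tem"), ("B2", "FL", "CD8 Tem"), ("B3", "FL", "CD8 Tem")],
        })
        expansion = classify_expansion(
            prof({"x": 5}, "BF"),
            prof({_cid(calls, "B1"): 3, "x": 5}, "FL"))
        tbl = fate_table(calls, meta, expansion)
        assert tbl.loc["absent", "CD8 Tem"] == pytest.approx(1.0)

    def test_naive_to_tem_mass(self):
        calls, meta = _paired_cells({
            "CAAF": [("B1", "BF", "CD8 naive"), ("B2", "BF", "CD8 naive"),
                     ("B3", "FL", "CD8 Tem"), ("B4", "FL", "CD8 Tem"),
                     ("B5", "FL", "CD8 Tem"), ("B6", "FL", "CD8 Tem")],
        })
        cid = _cid(calls, "B1")
        expansion = classify_expansion(
            prof({cid: 2, "x": 10}, "BF"), prof({cid: 4, "x": 10}, "FL"))
        tbl = fate_table(calls, meta, expansion)
        assert tbl.loc["CD8 naive", "CD8 Tem"] == pytest.approx(1.0)

    def test_weight_conservation_per_clonotype(self):
        calls, meta = _paired_cells({
            "CAAF": [("B1", "BF", "CD8 naive"), ("B2", "BF", "CD8 GZMK"),
                     ("B3", "FL", "CD8 Tem"), ("B4", "FL", "CD8 GZMK"),
                     ("B5", "FL", "CD8 Tem")],
            "CBBF": [("C1", "FL", "CD8 Tem"), ("C2", "FL", "CD8 Tem"), ("C3", "FL", "CD8 Tem")],
        })
        ca, cb = _cid(calls, "B1"), _cid(calls, "C1")
        expansion = classify_expansion(
            prof({ca: 2, "x": 10}, "BF"), prof({ca: 4, cb: 3, "x": 7}, "FL"))
        assert expanded_set(expansion) == {ca, cb}
        tbl = fate_table(calls, meta, expansion)
        assert tbl.to_numpy().sum() == pytest.approx(2.0)  # one unit per clonotype
        cells = fate_table(calls, meta, expansion, weighting="cells")
        assert cells.to_numpy().sum() == pytest.approx(3 + 3)


def _cid(calls, barcode):
    return "P1::" + next(c.clonotype_id for c in calls if c.barcode == barcode)


class TestCompareExpandedScores:
    def _setup(self, shift=0.0, n=200, seed=0):
        rng = np.random.default_rng(seed)
        spec = {}
        spec["CAAF"] = [(f"E{i}", "FL", "CD8 Tem") for i in range(n)]
        spec["CBBF"] = [(f"N{i}", "FL", "CD8 Tem") for i in range(n)]
        calls, meta = _paired_cells(spec)
        ce = _cid(calls, "E0")
        expansion = classify_expansion(
            prof({"x": 5}, "BF"), prof({ce: n, "x": 5}, "FL"))
        scores = pd.DataFrame(
            {"cytotox": np.concatenate([rng.normal(shift, 1, n), rng.normal(0, 1, n)])},
            index=[f"E{i}" for i in range(n)] + [f"N{i}" for i in range(n)],
        )
        return scores, expansion, calls, meta

    def test_identical_scores_give_null_result(self):
        scores, expansion, calls, meta = self._setup(shift=0.0)
        scores["cytotox"] = 1.7  # identical in both groups
        out = compare_expanded_scores(scores, expansion, calls, meta)
        fl = out[(out.timepoint == "FL")]
        assert fl["p_adj"].dropna().iloc[0] == pytest.approx(1.0)
        means = fl.set_index("expanded")["mean"]
        assert means[True] == pytest.approx(means[False])

    def test_planted_shift_recovered(self):
        scores, expansion, calls, meta = self._setup(shift=1.0, seed=1)
        out = compare_expanded_scores(scores, expansion, calls, meta)
        fl = out[(out.timepoint == "FL")].set_index("expanded")
        assert fl.loc[True, "mean"] - fl.loc[False, "mean"] == pytest.approx(1.0, abs=0.3)
        assert fl["p_adj"].dropna().iloc[0] < 1e-4

    def test_empty_expanded_group_logged(self, caplog):
        scores, expansion, calls, meta = self._setup()
        none_expanded = [c for c in expansion if not c.expanded]
        with caplog.at_level("WARNING"):
            out = compare_expanded_scores(scores, none_expanded, calls, meta)
        assert (out[out.expanded].n == 0).all()
        assert "n<2" in caplog.text
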