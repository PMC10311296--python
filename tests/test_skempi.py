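"""Mutation-table parsing, ΔΔG derivation, splits and metrics."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ppicube.skempi import (GAS_CONSTANT_KCAL, SplitPlan, ddg_from_affinities,
                            evaluate, filter_by_identity, make_split,
                            parse_mutation_string, parse_skempi)

HEADER = "#Pdb;Mutation(s)_cleaned;Affinity_mut_parsed;Affinity_wt_parsed;Temperature;Method;Hold_out_type"


def _write(tmp_path, rows):
    path = tmp_path / "skempi.csv"
    path.write_text(HEADER + "\n" + "\n".join(rows) + "\n")
    return path


class TestParseSkempi:
    def test_filter_composition(self, tmp_path):
        rows = [
            "1CSE_E_I;KI38A;1e-8;1e-9;298;ITC;Pr/PI",
            "1CSE_E_I;KI38A,EI40A;1e-8;1e-9;298;ITC;Pr/PI",   # multi-point
            "1CSE_E_I;KI39A;1e-8;1e-9;298;ELISA;Pr/PI",       # unreliable method
        ]
        records = parse_skempi(_write(tmp_path, rows))
        assert len(records) == 1
        rec = records[0]
        assert (rec.wt_aa, rec.chain, rec.residue_number, rec.mut_aa) == \
            ("K", "I", 38, "A")
        assert rec.function_class == "Pr/PI"

    def test_mutation_string_convention(self):
        assert parse_mutation_string("KI38A") == ("K", "I", 38, "", "A")
        with pytest.raises(ValueError, match="malformed"):
            parse_mutation_string("K38")

    def test_replicates_aggregate_to_median(self, tmp_path):
        rows = [
            "1ABC_A_B;KA10G;1e-8;1e-9;298;ITC;",
            "1ABC_A_B;KA10G;1e-7;1e-9;298;SPR;",
            "1ABC_A_B;KA10G;2e-8;1e-9;298;ITC;",
        ]
        records = parse_skempi(_write(tmp_path, rows))
        assert len(records) == 1
        expected = float(np.median(
            [ddg_from_affinities(1e-9, kd) for kd in (1e-8, 1e-7, 2e-8)]))
        assert records[0].ddg == pytest.approx(expected)

    def test_nonpositive_affinity_dropped(self, tmp_path):
        rows = ["1ABC_A_B;KA10G;0;1e-9;298;ITC;",
                "1ABC_A_B;KA11G;1e-8;1e-9;298;ITC;"]
        records = parse_skempi(_write(tmp_path, rows))
        assert [r.residue_number for r in records] == [11]

    def test_missing_temperature_defaults_to_298(self, tmp_path):
        rows = ["1ABC_A_B;KA10G;1e-8;1e-9;;ITC;",
                "1ABC_A_B;KA11G;1e-8;1e-9;310(assumed);ITC;"]
        records = parse_skempi(_write(tmp_path, rows))
        assert records[0].temperature == 298.0
        assert records[1].temperature == 310.0


class TestDdgFromAffinities:
    def test_equal_affinities_give_zero(self):
        assert ddg_from_affinities(1e-9, 1e-9) == 0.0

    def test_tenfold_weaker_binding_at_298K(self):
        expected = GAS_CONSTANT_KCAL * 298.0 * math.log(10.0)
        assert ddg_from_affinities(1e-9, 1e-8, 298.0) == \
            pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.364, abs=1e-3)

    @given(st.floats(1e-12, 1e-3), st.floats(1e-12, 1e-3),
           st.floats(200.0, 400.0))
    def test_antisymmetric_in_wt_mut(self, kd1, kd2, temp):
        fwd = ddg_from_affinities(kd1, kd2, temp)
        rev = ddg_from_affinities(kd2, kd1, temp)
        assert fwd == pytest.approx(-rev, abs=1e-9)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            ddg_from_affinities(0.0, 1e-9)


def _toy_records(tmp_path, n_complexes=5, per_complex=4):
    rows = []
    for c in range(n_complexes):
        for m in range(per_complex):
            rows.append(f"1XX{c}_A_B;KA{10+m}G;{(m+1)*1e-8:.1e};1e-9;298;ITC;")
    return parse_skempi(_write(tmp_path, rows))


class TestSplits:
    def test_mutation_level_kfold_partitions_records(self, tmp_path):
        records = _toy_records(tmp_path)
        plan = make_split(records, level="mutation", k=5, seed=1)
        seen = sorted(i for fold in plan.folds for i in fold["test"])
        assert seen == list(range(len(records)))
        for fold in plan.folds:
            assert set(fold["train"]).isdisjoint(fold["test"])

    def test_complex_level_split_never_leaks_a_complex(self, tmp_path):
        records = _toy_records(tmp_path)
        plan = make_split(records, level="complex", held_out_fraction=0.4,
                          seed=2)
        (fold,) = plan.folds
        train_c = {records[i].complex_id for i in fold["train"]}
        test_c = {records[i].complex_id for i in fold["test"]}
        assert train_c and test_c
        assert train_c.isdisjoint(test_c)

    def test_single_complex_rejected(self, tmp_path):
        records = _toy_records(tmp_path, n_complexes=1)
        with pytest.raises(ValueError, match="2 complexes"):
            make_split(records, level="complex", held_out_fraction=0.5)

    def test_same_seed_gives_identical_plan_file(self, tmp_path):
        records = _toy_records(tmp_path)
        paths = []
        for i in range(2):
            plan = make_split(records, level="complex", k=3, seed=7)
            p = tmp_path / f"plan{i}.json"
            plan.to_json(p)
            paths.append(p.read_text())
        assert paths[0] == paths[1]
        restored = SplitPlan.from_json(tmp_path / "plan0.json")
        assert restored.folds == json.loads(paths[0])["folds"]


class TestIdentityFilter:
    def test_drops_test_and_similar_complexes(self, tmp_path):
        records = _toy_records(tmp_path)  # complexes 1XX0..1XX4
        identity = {("1XX1_A_B", "1XX0_A_B"): 0.85,
                    ("1XX2_A_B", "1XX0_A_B"): 0.10}
        kept = filter_by_identity(records, identity,
                                  test_complexes={"1XX0_A_B"})
        kept_c = {r.complex_id for r in kept}
        assert kept_c == {"1XX2_A_B", "1XX3_A_B", "1XX4_A_B"}


def two_pass_pcc_rmse(pred, truth):
    """Independent textbook formulas for the evaluation metrics."""
    n = len(pred)
    mp, mt = sum(pred) / n, sum(truth) / n
    cov = sum((p - mp) * (t - mt) for p, t in zip(pred, truth))
    vp = sum((p - mp) ** 2 for p in pred)
    vt = sum((t - mt) ** 2 for t in truth)
    pcc = cov / math.sqrt(vp * vt)
    rmse = math.sqrt(sum((p - t) ** 2 for p, t in zip(pred, truth)) / n)
    return pcc, rmse


class TestEvaluate:
    def test_perfect_predictions(self):
        res = evaluate([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert res["overall"]["pcc"] == pytest.approx(1.0)
        assert res["overall"]["rmse"] == pytest.approx(0.0)

    def test_anticorrelated_predictions(self):
        res = evaluate([0.0, -1.0, -2.0], [0.0, 1.0, 2.0])
        assert res["overall"]["pcc"] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        res = evaluate([0.0, 1.0, 4.0], [0.0, 1.0, 2.0])
        pcc, rmse = two_pass_pcc_rmse([0.0, 1.0, 4.0], [0.0, 1.0, 2.0])
        assert res["overall"]["rmse"] == pytest.approx(math.sqrt(4.0 / 3.0))
        assert rmse == pytest.approx(math.sqrt(4.0 / 3.0))
        assert res["overall"]["pcc"] == pytest.approx(pcc)
        # hand check: cov=4, var_p=78/9, var_t=2 -> 4/sqrt(156/9) = 0.96077
        assert pcc == pytest.approx(4.0 / math.sqrt(156.0 / 9.0), abs=1e-12)
        assert pcc == pytest.approx(0.96077, abs=1e-5)

    def test_agrees_with_two_pass_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pred = rng.normal(size=30)
            truth = rng.normal(size=30)
            res = evaluate(pred, truth)
            pcc, rmse = two_pass_pcc_rmse(pred.tolist(), truth.tolist())
            assert res["overall"]["pcc"] == pytest.approx(pcc, abs=1e-10)
            assert res["overall"]["rmse"] == pytest.approx(rmse, abs=1e-10)

    def test_small_strata_reported_as_undefined(self):
        res = evaluate([0.0, 1.0, 2.0], [0.0, 1.5, 2.5],
                       strata=["COR", "COR", "RIM"])
        assert res["strata"]["RIM"] == {"pcc": None, "rmse": None, "n": 1}
        assert res["strata"]["COR"]["n"] == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate([1.0, 2.0], [1.0])
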