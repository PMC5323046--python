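from itertools import product

import numpy as np
import pandas as pd
import pytest

from hcscreen import hitcalling, platestats, synthgen
from hcscreen.errors import ContractError
from hcscreen.hitcalling import (HitThresholds, ToxicityParams,
                                 call_primary_hits, classify_treatment_response,
                                 deconvolute, flag_toxicity, rank_candidates,
                                 significance_vs_control,
                                 validate_deconvolution)


def _norm_row(gene, marker, parameter, value, sd, sirna=None,
              treatment="none"):
    return {"gene": gene, "sirna": sirna or f"{gene}_pool", "marker": marker,
            "treatment": treatment, "plate": f"{marker}-P1",
            "parameter": parameter, "value": value, "control_mean": 20.0,
            "control_sd": sd, "n_wells": 4, "flagged": False}


def _norm_table(entries):
    """entries: (gene, marker, value_spots, value_iss, sd)."""
    rows = []
    for gene, marker, vs, vi, sd in entries:
        rows.append(_norm_row(gene, marker, "spots_per_cell", vs, sd))
        rows.append(_norm_row(gene, marker, "iss_per_cell", vi, sd))
    return pd.DataFrame(rows)


class TestCallPrimaryHits:
    def test_two_sd_marker_hit(self):
        table = _norm_table([("G1", "LC3B", 1.25, 1.25, 0.10)])
        out = call_primary_hits(table)
        assert out["is_hit"].iloc[0]  # threshold 1 + 2*0.10 = 1.20
        assert out["direction"].iloc[0] == "increase"

    def test_three_sd_marker_not_hit(self):
        table = _norm_table([("G1", "WIPI2", 1.25, 1.25, 0.10)])
        out = call_primary_hits(table)
        assert not out["is_hit"].iloc[0]  # threshold 1 + 3*0.10 = 1.30

    def test_disagreeing_directions_not_hit(self):
        table = _norm_table([("G1", "LC3B", 1.5, 0.7, 0.10)])
        out = call_primary_hits(table)
        assert not out["is_hit"].iloc[0]

    def test_both_parameters_required(self):
        # only spots deviates: no hit under the both-parameter rule
        table = _norm_table([("G1", "LC3B", 1.5, 1.05, 0.10)])
        assert not call_primary_hits(table)["is_hit"].iloc[0]
        loose = HitThresholds(require_both_parameters=False)
        assert call_primary_hits(table, loose)["is_hit"].iloc[0]

    def test_decrease_direction(self):
        table = _norm_table([("G1", "LC3B", 0.7, 0.7, 0.10)])
        out = call_primary_hits(table)
        assert out["is_hit"].iloc[0]
        assert out["direction"].iloc[0] == "decrease"

    def test_direction_filter(self):
        table = _norm_table([("G1", "LC3B", 0.7, 0.7, 0.10)])
        thr = HitThresholds(direction="increase")
        assert not call_primary_hits(table, thr)["is_hit"].iloc[0]

    def test_missing_parameter_skipped(self):
        rows = [_norm_row("G1", "LC3B", "spots_per_cell", 1.5, 0.1)]
        out = call_primary_hits(pd.DataFrame(rows))
        assert len(out) == 0

    def test_controls_ignored(self):
        table = _norm_table([("sicon", "LC3B", 1.0, 1.0, 0.1),
                             ("positive", "LC3B", 3.0, 3.0, 0.1)])
        assert len(call_primary_hits(table)) == 0

    def test_cascade_monotone_in_k(self):
        rng = np.random.default_rng(5)
        entries = [(f"G{i}", "LC3B", v, w, 0.05)
                   for i, (v, w) in enumerate(
                       zip(rng.uniform(0.7, 1.6, 60),
                           rng.uniform(0.7, 1.6, 60)))]
        table = _norm_table(entries)
        strict = call_primary_hits(table, HitThresholds(k={"LC3B": 3.0}))
        loose = call_primary_hits(table, HitThresholds(k={"LC3B": 2.0}))
        strict_hits = set(strict.loc[strict["is_hit"], "gene"])
        loose_hits = set(loose.loc[loose["is_hit"], "gene"])
        assert strict_hits <= loose_hits

    def test_rule_trail_present(self):
        table = _norm_table([("G1", "LC3B", 1.25, 1.25, 0.10)])
        trail = call_primary_hits(table)["rule_trail"].iloc[0]
        assert "k=2" in trail and "hit" in trail


class TestRankCandidates:
    def _verdicts(self, marker_hits):
        """marker_hits: {marker: [(gene, score), ...]}."""
        rows = []
        for marker, hits in marker_hits.items():
            for gene, score in hits:
                v = float(np.exp(score))
                rows.append((gene, f"{gene}_pool", marker, "none", v, v,
                             0.05, 0.05, "increase", True, score,
                             "primary_hit", ""))
        return pd.DataFrame(rows, columns=hitcalling.VERDICT_COLUMNS)

    def test_top_ten_rule(self):
        hits = {"STX17": [(f"G{i}", 1.0 - 0.05 * i) for i in range(12)]}
        out = rank_candidates(self._verdicts(hits))
        assert len(out) == 10
        assert set(out["gene"]) == {f"G{i}" for i in range(10)}

    def test_multi_marker_rescue(self):
        stx = [(f"G{i}", 1.0 - 0.05 * i) for i in range(11)]
        lc3 = [("G10", 0.9), ("OTHER", 1.0)]  # G10 is rank 11 for STX17
        out = rank_candidates(self._verdicts({"STX17": stx, "LC3B": lc3}))
        stx_sel = out[out["marker"] == "STX17"]
        assert "G10" in set(stx_sel["gene"])
        assert (stx_sel.loc[stx_sel["gene"] == "G10",
                            "selected_by"] == "multi_marker").all()

    def test_rank_ten_tie_keeps_both(self):
        hits = [(f"G{i}", 1.0 - 0.05 * i) for i in range(9)]
        hits += [("T1", 0.5), ("T2", 0.5), ("LOW", 0.1)]
        out = rank_candidates(self._verdicts({"STX17": hits}))
        assert {"T1", "T2"} <= set(out["gene"])
        assert "LOW" not in set(out["gene"])

    def test_fewer_than_ten_keeps_all(self):
        hits = {"STX17": [("G1", 1.0), ("G2", 0.5)]}
        out = rank_candidates(self._verdicts(hits))
        assert len(out) == 2


class TestFlagToxicity:
    def test_generator_toxic_sirna_flagged(self, small_wells):
        flags = flag_toxicity(small_wells)
        tox = flags[flags["sirna"] == "GENE003_pool"]
        assert tox["toxic"].all()
        assert "n_cells" in tox["observables"].iloc[0]

    def test_clean_sirnas_not_flagged(self, small_wells):
        flags = flag_toxicity(small_wells)
        clean = flags[flags["sirna"] != "GENE003_pool"]
        assert not clean["toxic"].any()

    def test_morphology_only_shift_flagged(self):
        layout = synthgen.make_screen_layout(1, markers=("LC3B",), seed=31)
        model = synthgen.EffectModel(
            toxic_sirnas={"GENE001_pool": synthgen.ToxicEffect(
                cell_count_fold=1.0, morphology_fold=0.6)},
            seed=31)
        wells = synthgen.simulate_well_table(layout, model)
        flags = flag_toxicity(wells)
        rec = flags[flags["sirna"] == "GENE001_pool"]
        assert rec["toxic"].all()
        assert "nucleus" in rec["observables"].iloc[0]


def oracle_deconvolution(passes, toxic):
    """Independent enumeration of the published validation rule: remove the
    toxic siRNAs, then require 3 passes when 4 remain or 2 when 3 remain;
    fewer than 3 remaining siRNAs excludes the gene."""
    remaining = [p for p, t in zip(passes, toxic) if not t]
    if len(remaining) < 3:
        return "excluded_toxicity"
    if len(remaining) == 4:
        return "validated" if sum(remaining) >= 3 else "not_validated"
    return "validated" if sum(remaining) >= 2 else "not_validated"


class TestValidateDeconvolution:
    def test_three_of_four(self):
        assert validate_deconvolution([1, 1, 1, 0], [0, 0, 0, 0]) == "validated"

    def test_two_of_three_with_one_toxic(self):
        assert validate_deconvolution([1, 1, 0, 0], [0, 0, 0, 1]) == "validated"

    def test_two_toxic_excluded(self):
        assert validate_deconvolution([1, 1, 1, 1], [1, 1, 0, 0]) \
            == "excluded_toxicity"

    def test_exhaustive_truth_table(self):
        for passes in product([0, 1], repeat=4):
            for toxic in product([0, 1], repeat=4):
                got = validate_deconvolution(list(passes), list(toxic))
                assert got == oracle_deconvolution(passes, toxic), \
                    (passes, toxic)

    def test_wrong_sirna_count(self):
        with pytest.raises(ContractError):
            validate_deconvolution([1, 1, 1], [0, 0, 0])


class TestDeconvoluteTable:
    def _verdicts(self, gene, hits, directions=None):
        directions = directions or ["increase"] * 4
        rows = []
        for i, (h, d) in enumerate(zip(hits, directions), start=1):
            rows.append((gene, f"{gene}_si{i}", "LC3B", "none", 1.5, 1.5,
                         0.05, 0.05, d if h else "none", bool(h), 0.4,
                         "primary_hit" if h else "not_hit", ""))
        return pd.DataFrame(rows, columns=hitcalling.VERDICT_COLUMNS)

    def test_three_of_four_validates(self):
        out = deconvolute(self._verdicts("G1", [1, 1, 1, 0]))
        assert out["stage"].iloc[0] == "validated"

    def test_direction_consistency_enforced(self):
        v = self._verdicts("G1", [1, 1, 1, 0],
                           ["increase", "increase", "decrease", "none"])
        out = deconvolute(v)
        # only the two same-direction passes count: not validated
        assert out["stage"].iloc[0] == "not_validated"

    def test_toxicity_applied(self):
        tox = pd.DataFrame([("G1", "G1_si4", "LC3B", "P", True, "n_cells")],
                           columns=["gene", "sirna", "marker", "plate",
                                    "toxic", "observables"])
        out = deconvolute(self._verdicts("G1", [1, 1, 0, 0]), tox)
        assert out["stage"].iloc[0] == "validated"  # 2 of remaining 3

    def test_wrong_count_rejected(self):
        v = self._verdicts("G1", [1, 1, 1, 0]).iloc[:3]
        with pytest.raises(ContractError):
            deconvolute(v)


class TestTreatmentResponse:
    def test_dmso_and_torin(self):
        r = classify_treatment_response(
            {"DMSO": True, "Torin1": True, "BafA1": False})
        assert r.category == "DMSO+Torin1"

    def test_bafa1_only(self):
        r = classify_treatment_response(
            {"DMSO": False, "Torin1": False, "BafA1": True})
        assert r.category == "BafA1"

    def test_significant_only(self):
        r = classify_treatment_response(
            {"DMSO": False, "Torin1": False, "BafA1": False},
            significant={"Torin1": True})
        assert r.category == "significant-only"

    def test_nothing(self):
        r = classify_treatment_response(
            {"DMSO": False, "Torin1": False, "BafA1": False})
        assert r.category == "none"

    def test_missing_arm_flagged(self):
        r = classify_treatment_response({"DMSO": True})
        assert r.category == "DMSO"
        assert set(r.missing_arms) == {"Torin1", "BafA1"}


class TestSignificance:
    def test_identical_groups(self):
        p, stars = significance_vs_control([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == pytest.approx(1.0)
        assert stars == ""

    def test_separated_groups(self):
        rng = np.random.default_rng(2)
        ctl = rng.normal(0.0, 1.0, 4)
        grp = rng.normal(10.0, 1.0, 4)  # 10 sigma separation
        p, stars = significance_vs_control(grp, ctl)
        assert p < 0.001
        assert stars == "***"

    def test_bonferroni_multiplication(self):
        # build groups whose raw ANOVA p is ~0.02, then correct for 5 tests
        rng = np.random.default_rng(3)
        for _ in range(20):
            ctl = rng.normal(0.0, 1.0, 6)
            grp = rng.normal(1.5, 1.0, 6)
            raw, _ = significance_vs_control(grp, ctl, n_groups=1)
            adj, _ = significance_vs_control(grp, ctl, n_groups=5)
            assert adj == pytest.approx(min(1.0, raw * 5))

    def test_too_small_groups(self):
        with pytest.raises(ValueError):
            significance_vs_control([1.0], [1.0, 2.0])


class TestNullCalibration:
    def test_false_positive_rate_below_nominal(self):
        # all folds 1.0 over 1000 genes: the 2-SD both-parameter rule must
        # flag no more than the nominal two-sided 2-sigma fraction (~4.6%)
        layout = synthgen.make_screen_layout(1000, markers=("LC3B",), seed=77)
        wells = synthgen.simulate_well_table(
            layout, synthgen.EffectModel(seed=77))
        normalized = platestats.normalize_to_control(wells)
        verdicts = call_primary_hits(normalized)
        assert len(verdicts) == 1000
        fp = verdicts["is_hit"].mean()
        assert fp <= 0.046
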