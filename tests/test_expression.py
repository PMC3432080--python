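"""Comparative-Ct ratios, replicate t-tests and tissue patterns."""

import numpy as np
import pandas as pd
import pytest

from serprot.expression import (
    CtRecord,
    ExpressionConfig,
    analyze_ct_table,
    delta_ct,
    differential_test,
    relative_ratio,
    tissue_pattern_summary,
)


def records(dcts, condition, gene="g", time_h=24.0, ref_ct=20.0, target_offsets=None):
    out = []
    for k, dct in enumerate(dcts, start=1):
        out.append(
            CtRecord(
                gene=gene,
                condition=condition,
                time_h=time_h,
                replicate=k,
                ct_target=ref_ct + dct,
                ct_reference=ref_ct,
            )
        )
    return out


class TestDeltaCt:
    def test_scalar(self):
        r = CtRecord("g", "treated", 24.0, 1, 25.0, 20.0)
        assert delta_ct(r) == 5.0

    def test_vectorized_preserves_order(self):
        rs = records([1.0, 2.0, 3.0], "control")
        assert delta_ct(rs).tolist() == [1.0, 2.0, 3.0]

    def test_ct_bounds_enforced(self):
        with pytest.raises(ValueError):
            CtRecord("g", "treated", 24.0, 1, 50.0, 20.0)


class TestRelativeRatio:
    def test_no_change(self):
        assert relative_ratio(records([5.0] * 3, "treated"), records([5.0] * 3, "control")) == pytest.approx(1.0)

    def test_one_cycle_is_twofold(self):
        assert relative_ratio(records([4.0] * 3, "treated"), records([5.0] * 3, "control")) == pytest.approx(2.0)

    def test_unequal_efficiencies_closed_form(self):
        # target Ct drops 2 cycles, reference drops 1: ratio = 1.9^2 / 2.0
        treated = [CtRecord("g", "treated", 24.0, 1, 23.0, 19.0)]
        control = [CtRecord("g", "control", 24.0, 1, 25.0, 20.0)]
        cfg = ExpressionConfig(efficiency_target=1.9, efficiency_reference=2.0)
        assert relative_ratio(treated, control, cfg) == pytest.approx(1.9**2 / 2.0, abs=1e-12)

    def test_reciprocity(self, rng):
        for _ in range(20):
            a = records(rng.normal(5, 1, 3), "treated")
            b = records(rng.normal(5, 1, 3), "control")
            assert relative_ratio(a, b) * relative_ratio(b, a) == pytest.approx(1.0, abs=1e-9)

    def test_equals_two_to_minus_ddct(self, rng):
        for _ in range(20):
            a = records(rng.normal(4, 1, 3), "treated")
            b = records(rng.normal(5, 1, 3), "control")
            ddct = np.mean(delta_ct(a)) - np.mean(delta_ct(b))
            assert relative_ratio(a, b) == pytest.approx(2.0 ** (-ddct), abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            relative_ratio([], records([5.0], "control"))


class TestDifferentialTest:
    def test_identical_groups_p_one(self):
        res = differential_test(records([1, 2, 3], "treated"), records([1, 2, 3], "control"))
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant and res.direction == "none"

    def test_pooled_variance_closed_form(self):
        # means 2 vs 5, pooled sd 1, se = sqrt(2/3): t = -3.674, df = 4
        res = differential_test(records([1, 2, 3], "treated"), records([4, 5, 6], "control"))
        assert res.p_value == pytest.approx(0.02131164, abs=1e-6)
        assert res.significant and res.direction == "up"  # lower dCt = higher expression

    def test_too_few_replicates(self):
        with pytest.raises(ValueError, match="2 replicates"):
            differential_test(records([1.0], "treated"), records([2.0, 3.0], "control"))

    def test_fold_flag(self):
        res = differential_test(records([2.0, 2.1, 1.9], "treated"), records([5.0, 5.1, 4.9], "control"))
        assert res.fold_flagged  # ~8-fold up
        cfg = ExpressionConfig(fold_flag=16.0)
        res2 = differential_test(records([2.0, 2.1, 1.9], "treated"), records([5.0, 5.1, 4.9], "control"), cfg)
        assert not res2.fold_flagged


class TestAnalyzeCtTable:
    def test_technical_replicates_averaged(self):
        rows = []
        for cond, dct in [("treated", 4.0), ("control", 5.0)]:
            for rep in (1, 2, 3):
                for tech_jitter in (-0.1, 0.1):  # two technical measurements per replicate
                    rows.append(
                        dict(gene="g", condition=cond, time_h=24.0, replicate=rep,
                             ct_target=20 + dct + tech_jitter, ct_reference=20.0)
                    )
        res = analyze_ct_table(pd.DataFrame(rows))
        assert len(res) == 1
        assert res.ratio.iloc[0] == pytest.approx(2.0)
        # after averaging, within-group variance is exactly zero
        assert res.significant.iloc[0]

    def test_missing_column_reported(self):
        with pytest.raises(ValueError, match="ct_reference"):
            analyze_ct_table(pd.DataFrame({"gene": [], "condition": [], "time_h": [],
                                           "replicate": [], "ct_target": []}))


class TestTissuePatterns:
    def matrix(self):
        return pd.DataFrame(
            {
                "FG": [1, 1, 0, 0],
                "HG": [0, 0, 1, 0],
                "MG": [1, 1, 1, 0],
                "HL": [0, 0, 0, 0],
                "MT": [0, 0, 0, 0],
                "CA": [0, 0, 0, 0],
                "FB": [0, 0, 0, 0],
                "SG": [0, 0, 0, 0],
            },
            index=["g1", "g2", "g3", "g4"],
        )

    def test_group_consensus_foregut_midgut(self):
        per_gene, per_group = tissue_pattern_summary(self.matrix(), {"G2": ["g1", "g2"]})
        assert per_gene["g1"] == "FG+MG"
        assert per_group.loc[0, "consensus"] == "FG+MG"
        assert per_group.loc[0, "dissenting"] == ""

    def test_not_detected(self):
        per_gene, _ = tissue_pattern_summary(self.matrix())
        assert per_gene["g4"] == "not detected"

    def test_empty_group(self):
        _, per_group = tissue_pattern_summary(self.matrix(), {"empty": []})
        assert per_group.loc[0, "consensus"] == ""

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError, match="nope"):
            tissue_pattern_summary(self.matrix(), {"G": ["nope"]})

    def test_dissenting_gene_listed(self):
        _, per_group = tissue_pattern_summary(self.matrix(), {"G": ["g1", "g2", "g3"]})
        assert per_group.loc[0, "consensus"] == "FG+MG"
        assert per_group.loc[0, "dissenting"] == "g3"
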