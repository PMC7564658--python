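import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from sfsc import inka
from sfsc.synthetic_data import make_phospho_counts, make_phospho_truth


def table_from(rows, samples=("S1",)):
    """rows: (peptide_id, protein, site, *counts)."""
    cols = ["peptide_id", "protein", "site", *samples]
    return pd.DataFrame(rows, columns=cols).set_index("peptide_id")


ANN = pd.DataFrame(
    [("KIN1", 100, 130), ("KIN2", 200, 230)],
    columns=["kinase", "loop_start", "loop_end"],
)
REL = pd.DataFrame(
    [
        ("KIN1", "SUB1", 55, "PSP"),
        ("KIN1", "SUB2", 77, "NWK"),
        ("KIN2", "SUB3", 10, "PSP"),
        ("KIN2", "SUB3", 10, "NWK"),
    ],
    columns=["kinase", "substrate", "site", "evidence"],
)


class TestNormalizeCounts:
    def test_scales_to_grand_mean(self):
        table = table_from(
            [("p1", "A", 1, 60, 180), ("p2", "B", 2, 40, 120)], samples=("S1", "S2")
        )
        out = inka.normalize_counts(table)
        totals = out[["S1", "S2"]].sum()
        assert totals["S1"] == pytest.approx(200)
        assert totals["S2"] == pytest.approx(200)
        # scale factors 2.0 and 2/3
        assert out.loc["p1", "S1"] == pytest.approx(120)
        assert out.loc["p1", "S2"] == pytest.approx(120)

    def test_equal_totals_identity(self):
        table = table_from(
            [("p1", "A", 1, 50, 50), ("p2", "B", 2, 50, 50)], samples=("S1", "S2")
        )
        out = inka.normalize_counts(table)
        pd.testing.assert_frame_equal(out[["S1", "S2"]], table[["S1", "S2"]].astype(float))

    def test_zero_sample_named_in_error(self):
        table = table_from(
            [("p1", "A", 1, 10, 0)], samples=("S1", "S2")
        )
        with pytest.raises(ValueError, match="S2"):
            inka.normalize_counts(table)

    def test_grand_total_conserved(self):
        table = table_from(
            [("p1", "A", 1, 7, 13), ("p2", "B", 2, 11, 3)], samples=("S1", "S2")
        )
        out = inka.normalize_counts(table)
        assert out[["S1", "S2"]].to_numpy().sum() == pytest.approx(34)


class TestArmScores:
    def test_kinome_and_loop_sums(self):
        table = table_from(
            [("p1", "KIN1", 50, 5), ("p2", "KIN1", 110, 3)]  # p2 in loop [100,130]
        )
        kinome, loop, psp, nwk = inka.arm_scores("KIN1", table, ANN, REL)
        assert (kinome, loop) == (8.0, 3.0)
        assert (psp, nwk) == (0.0, 0.0)

    def test_substrate_arms_by_evidence(self):
        table = table_from(
            [("s1", "SUB1", 55, 6), ("s2", "SUB2", 77, 2), ("s3", "SUB2", 99, 9)]
        )
        _, _, psp, nwk = inka.arm_scores("KIN1", table, ANN, REL)
        assert psp == 6.0  # SUB1:55 only
        assert nwk == 2.0  # SUB2:77 only; unmapped site 99 ignored

    def test_dual_evidence_site_counts_in_both_arms(self):
        table = table_from([("s1", "SUB3", 10, 4)])
        _, _, psp, nwk = inka.arm_scores("KIN2", table, ANN, REL)
        assert psp == 4.0 and nwk == 4.0

    def test_unknown_kinase_warns_with_zero_arms(self):
        table = table_from([("p1", "KIN1", 50, 5)])
        with pytest.warns(UserWarning):
            arms = inka.arm_scores("NOPE", table, ANN, REL)
        assert arms == (0.0, 0.0, 0.0, 0.0)


class TestInkaScore:
    def test_hand_computed_fixture(self):
        assert inka.inka_score((8, 4, 6, 2)) == pytest.approx(np.sqrt(24))

    def test_zero_when_either_side_missing(self):
        assert inka.inka_score((0, 0, 0, 0)) == 0.0
        assert inka.inka_score((8, 4, 0, 0)) == 0.0
        assert inka.inka_score((0, 0, 6, 2)) == 0.0

    def test_degree_one_homogeneity(self):
        base = (8, 4, 6, 2)
        assert inka.inka_score(tuple(4 * a for a in base)) == pytest.approx(
            4 * inka.inka_score(base)
        )

    def test_negative_arm_rejected(self):
        with pytest.raises(ValueError):
            inka.inka_score((-1, 0, 0, 0))


def scored(scores):
    return pd.DataFrame(
        {"kinase": list(scores), "inka_score": list(scores.values())}
    )


class TestRankingAndOverlap:
    def test_rank_descending_with_alphabetical_ties(self):
        results = scored({"B": 4.0, "A": 4.0, "C": 5.0})
        assert inka.rank_kinases(results, 3) == ["C", "A", "B"]

    def test_top_n_truncates(self):
        results = scored({f"K{i:02d}": 30.0 - i for i in range(30)})
        assert len(inka.rank_kinases(results, 20)) == 20

    def test_overlap_identical_disjoint_partial(self):
        a = scored({f"K{i:02d}": 40.0 - i for i in range(20)})
        b = scored({f"J{i:02d}": 40.0 - i for i in range(20)})
        assert inka.top_overlap(a, a, 20) == 1.0
        assert inka.top_overlap(a, b, 20) == 0.0
        mixed = {f"K{i:02d}": 40.0 - i for i in range(15)}
        mixed.update({f"J{i:02d}": 20.0 - i for i in range(5)})
        c = scored(mixed)
        assert inka.top_overlap(a, c, 20) == pytest.approx(0.75)

    def test_short_profiles_warn(self):
        a = scored({"A": 3.0, "B": 2.0})
        with pytest.warns(UserWarning):
            frac = inka.top_overlap(a, a, 20)
        assert frac == 1.0


class TestTreatmentDelta:
    def test_percent_changes(self):
        control = scored({"A": 10.0, "B": 5.0, "C": 0.0})
        treated = scored({"A": 4.0, "B": 5.0, "C": 2.0})
        delta = inka.treatment_delta(control, treated).set_index("kinase")
        assert delta.loc["A", "percent_change"] == pytest.approx(-60.0)
        assert delta.loc["B", "percent_change"] == pytest.approx(0.0)
        assert not delta.loc["C", "defined"]


class TestDifferential:
    def _tables(self, shift=1.0, seed=0, n_rep=4):
        truth = make_phospho_truth(12, seed=7)
        control = make_phospho_counts(truth, n_rep, seed=seed)
        shifted = dict(truth.activities)
        first = sorted(shifted)[0]
        shifted[first] *= shift
        truth2 = make_phospho_truth(12, seed=7, activities=shifted)
        treated = make_phospho_counts(truth2, n_rep, seed=seed + 10_000)
        return first, control, treated

    def test_identical_groups_no_discoveries(self):
        _, control, _ = self._tables()
        res = inka.differential_phosphokinase({"a": control, "b": control.copy()})
        assert not res["significant"].any()

    def test_planted_shift_detected(self):
        hits = 0
        for seed in range(100):
            kinase, control, treated = self._tables(shift=10.0, seed=seed)
            res = inka.differential_phosphokinase({"ctrl": control, "odc": treated})
            sig = set(res.loc[res["significant"], "kinase"])
            hits += kinase in sig
        assert hits >= 96

    def test_null_false_discovery_controlled(self):
        any_fp = 0
        n = 150
        for seed in range(n):
            _, control, treated = self._tables(shift=1.0, seed=seed)
            res = inka.differential_phosphokinase({"a": control, "b": treated})
            any_fp += bool(res["significant"].any())
        # BH familywise-null: P(any discovery) <= alpha, plus 3 sigma MC slack
        assert any_fp / n <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)

    def test_single_replicate_rejected(self):
        truth = make_phospho_truth(3, seed=1)
        one = make_phospho_counts(truth, 1, seed=0)
        four = make_phospho_counts(truth, 4, seed=1)
        with pytest.raises(ValueError):
            inka.differential_phosphokinase({"a": one, "b": four})


class TestScalingInvariance:
    def test_global_scaling_scales_scores_and_preserves_ranks(self):
        truth = make_phospho_truth(10, seed=3)
        counts = make_phospho_counts(truth, 4, seed=3)
        samples = [c for c in counts.columns if c not in ("protein", "site")]
        res1 = inka.inka_table(counts, truth.annotations(), truth.relations)
        scaled = counts.copy()
        scaled[samples] = counts[samples] * 3.0
        res2 = inka.inka_table(scaled, truth.annotations(), truth.relations)
        merged = res1.merge(res2, on="kinase", suffixes=("_1", "_2"))
        np.testing.assert_allclose(
            merged["inka_score_2"], 3.0 * merged["inka_score_1"]
        )
        assert list(res1["kinase"]) == list(res2["kinase"])
        assert inka.top_overlap(res1, res2, 10) == 1.0

    def test_activity_recovery_spearman(self):
        truth = make_phospho_truth(20, seed=0)
        counts = make_phospho_counts(truth, 4, seed=0)
        table = inka.normalize_counts(counts)
        res = inka.inka_table(table, truth.annotations(), truth.relations)
        scores = res.set_index("kinase")["inka_score"]
        kinases = sorted(truth.activities)
        rho = spearmanr(
            [truth.activities[k] for k in kinases], scores[kinases]
        ).statistic
        assert rho > 0.8


class TestNetwork:
    def test_structure_and_evidence_labels(self):
        table = table_from(
            [("p1", "KIN1", 110, 5), ("s1", "SUB1", 55, 6), ("s3", "SUB3", 10, 4)]
        )
        results = scored({"KIN1": 5.0, "KIN2": 0.0})
        g = inka.build_network(table, REL, results)
        assert "KIN2" not in g  # zero score excluded
        assert g.nodes["KIN1"]["inka_score"] == 5.0
        assert g.edges["KIN1", "SUB1"]["evidence"] == "PSP"
        assert ("KIN1", "SUB2") not in g.edges  # site 77 unobserved
        # SUB3 maps only to the excluded kinase
        assert "SUB3" not in g

    def test_dual_evidence_single_edge(self):
        table = table_from([("s3", "SUB3", 10, 4), ("p", "KIN2", 210, 2)])
        results = scored({"KIN2": 3.0})
        g = inka.build_network(table, REL, results)
        assert g.number_of_edges() == 1
        assert g.edges["KIN2", "SUB3"]["evidence"] == "both"
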