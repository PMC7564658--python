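import numpy as np
import pandas as pd
import pytest

from sfsc import fsc_search as fs
from sfsc.synthetic_data import RUN_ID, VIABILITY, make_landscape

from test_response_model import make_model


class TestDrugUtility:
    def test_linear_only(self):
        model = make_model(["A", "B"], {"Intercept": 1.0, "A": -0.3})
        g = fs.drug_utility(model)
        assert g["A"] == pytest.approx(-0.3)
        assert g["B"] == pytest.approx(0.0)

    def test_synergy_rewards(self):
        model = make_model(["A", "B"], {"Intercept": 1.0, "A": -0.1, "A:B": -0.2})
        assert fs.drug_utility(model)["A"] == pytest.approx(-0.2)

    def test_antagonism_penalizes_below_inactive(self):
        model = make_model(["A", "B"], {"Intercept": 1.0, "A": -0.1, "A:B": 0.4})
        g = fs.drug_utility(model)
        assert g["A"] == pytest.approx(0.1)
        assert g["A"] > 0  # worse than a drug with no effect at all


class TestSelectPanel:
    UTILS = pd.Series({"A": -0.3, "B": -0.2, "C": -0.1, "D": 0.0})

    def test_keeps_lowest_scores(self):
        assert fs.select_panel(self.UTILS, 2) == ["A", "B"]

    def test_tie_breaks_lexicographically(self):
        utils = pd.Series({"A": -0.2, "B": -0.2, "C": -0.2, "D": 0.0})
        assert fs.select_panel(utils, 2) == ["A", "B"]

    def test_exclude_policy_promotes_next_ranked(self):
        assert fs.select_panel(self.UTILS, 2, flagged=("A",), policy="exclude") == [
            "B",
            "C",
        ]

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            fs.select_panel(self.UTILS, 0)
        with pytest.raises(ValueError):
            fs.select_panel(self.UTILS, 4)


class TestSelectODC:
    def _round(self, means, model):
        """Confirmation-style round over 3 drugs with specified run means."""
        design = fs.full_factorial_design(["A", "B", "C"])
        rows = []
        for rid, mean in means.items():
            for rep, delta in enumerate((-0.001, 0.0, 0.001)):
                rows.append((rid, mean + delta))
        resp = pd.DataFrame(rows, columns=[RUN_ID, VIABILITY])
        for f in design.factors:
            level = design.coded[f].to_numpy()[resp[RUN_ID]]
            resp[f"dose_{f}"] = (level + 1.0) / 2.0
        return fs.RoundResult(
            index=0,
            panel=("A", "B", "C"),
            design=design,
            response=resp,
            model=model,
            utilities=pd.Series(dtype=float),
            eliminated={},
        )

    @staticmethod
    def _rid(design, levels):
        match = (design.coded == pd.Series(levels)).all(axis=1)
        return int(np.flatnonzero(match)[0])

    def test_half_dose_combo_wins_within_tolerance(self):
        model = make_model(["A", "B", "C"], {"Intercept": 1.0})
        design = fs.full_factorial_design(["A", "B", "C"])
        full = self._rid(design, {"A": 1, "B": 1, "C": 1})
        half = self._rid(design, {"A": 0, "B": 0, "C": 0})
        means = {rid: 0.9 for rid in range(design.n_runs)}
        means[full] = 0.20
        means[half] = 0.23
        odc = fs.select_odc(self._round(means, model), max_drugs=3, tolerance=0.05)
        assert odc.levels == {"A": 0, "B": 0, "C": 0}

    def test_zero_tolerance_selects_strict_best(self):
        model = make_model(["A", "B", "C"], {"Intercept": 1.0})
        design = fs.full_factorial_design(["A", "B", "C"])
        full = self._rid(design, {"A": 1, "B": 1, "C": 1})
        half = self._rid(design, {"A": 0, "B": 0, "C": 0})
        means = {rid: 0.9 for rid in range(design.n_runs)}
        means[full] = 0.20
        means[half] = 0.23
        odc = fs.select_odc(self._round(means, model), max_drugs=3, tolerance=0.0)
        assert odc.levels == {"A": 1, "B": 1, "C": 1}

    def test_dose_tie_broken_by_synergy_sum(self):
        model = make_model(
            ["A", "B", "C"],
            {"Intercept": 1.0, "A": -0.1, "B": -0.1, "C": -0.1,
             "A:B": -0.3, "A:C": -0.1},
        )
        design = fs.full_factorial_design(["A", "B", "C"])
        ab = self._rid(design, {"A": 1, "B": 1, "C": -1})
        ac = self._rid(design, {"A": 1, "B": -1, "C": 1})
        means = {rid: 0.9 for rid in range(design.n_runs)}
        means[ab] = 0.30
        means[ac] = 0.30
        odc = fs.select_odc(self._round(means, model), max_drugs=2, tolerance=0.0)
        assert odc.drugs == ("A", "B")
        assert odc.interactions == {"A:B": -0.3}

    def test_no_candidates_rejected(self):
        model = make_model(["A", "B", "C"], {"Intercept": 1.0})
        means = {rid: 0.9 for rid in range(27)}
        rr = self._round(means, model)
        with pytest.raises(ValueError):
            fs.select_odc(rr, max_drugs=0)


class TestRunSearch:
    def test_schedule_must_decrease(self):
        land = fs.recovery_landscape(0)
        with pytest.raises(fs.ScheduleError):
            fs.run_search(fs.SimulatedAssay(land), schedule=(4, 7), seed=0)

    def test_schedule_must_match_panel(self):
        land = make_landscape(4, seed=0)
        with pytest.raises(fs.ScheduleError):
            fs.run_search(fs.SimulatedAssay(land), schedule=(10, 7, 4), seed=0)

    def test_noise_free_search_is_seed_invariant(self):
        land = fs.recovery_landscape(5, noise_sd=0.0)
        a = fs.run_search(fs.SimulatedAssay(land), seed=1)
        b = fs.run_search(fs.SimulatedAssay(land), seed=2)
        assert a.odc.to_dict() == b.odc.to_dict()

    def test_same_seed_reproduces_everything(self):
        land = fs.recovery_landscape(3, noise_sd=0.05)
        a = fs.run_search(fs.SimulatedAssay(land), seed=7)
        b = fs.run_search(fs.SimulatedAssay(land), seed=7)
        assert a.odc.to_dict() == b.odc.to_dict()
        for ra, rb in zip(a.rounds, b.rounds):
            pd.testing.assert_frame_equal(ra.response, rb.response)

    def test_single_active_drug_becomes_singleton_odc(self):
        """With one effective drug and no interactions the combination
        collapses to that drug alone (small combinations are admissible)."""
        emax = np.zeros(10)
        emax[4] = 0.9  # D05
        land = make_landscape(10, seed=2, emax=emax, noise_sd=0.0)
        result = fs.run_search(fs.SimulatedAssay(land), seed=0)
        assert result.odc.drugs == ("D05",)

    def test_planted_synergy_recovered(self):
        land = fs.recovery_landscape(0, noise_sd=0.05)
        result = fs.run_search(fs.SimulatedAssay(land), seed=0)
        assert len(set(result.odc.drugs) & set(fs.RECOVERY_ACTIVES)) >= 2
        final_panels = [r.panel for r in result.rounds if r.stage == "confirmation"]
        assert set(fs.RECOVERY_ACTIVES) <= set(final_panels[0])

    def test_hormetic_drug_flagged_and_excludable(self):
        horm = np.zeros(10)
        horm[0] = 0.3
        emax = np.full(10, 0.3)
        emax[1:4] = 0.9
        land = make_landscape(10, seed=4, emax=emax, hormesis=horm, noise_sd=0.0)
        cfg = fs.SearchConfig(hormesis_policy="exclude")
        result = fs.run_search(fs.SimulatedAssay(land), config=cfg, seed=0)
        assert "D01" in result.hormesis_flags
        for rr in result.rounds[1:]:
            assert "D01" not in rr.panel


class TestFileReplay:
    def test_replay_matches_simulated_search(self):
        land = fs.recovery_landscape(2, noise_sd=0.05)
        sim = fs.run_search(fs.SimulatedAssay(land), seed=3)
        tables = [r.response for r in sim.rounds]
        replay = fs.run_search_from_tables(tables, sim.anchors)
        assert replay.odc.to_dict() == sim.odc.to_dict()
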