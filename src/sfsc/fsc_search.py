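"""The streamlined feedback-system-control (s-FSC) search loop.

Iteratively: build a composite design over the current drug panel, dose it
at fractions of each drug's IC20 anchor, assay, fit and reduce the quadratic
response-surface model, score every drug, and shrink the panel along the
schedule (default 10 -> 7 -> 4 drugs).  A confirmation stage then enumerates
all sub-combinations of the final panel at absent/half/full dose levels and
the optimized drug combination (ODC) is the lowest-dose tested combination
whose viability sits within a tolerance of the best observed.

The per-drug utility g_i = beta_i + 1/2 * sum_j beta_ij (over retained
terms) operationalizes the selection rules: strong single-drug activity and
synergy (negative coefficients) are selected for, antagonism (positive
interaction coefficients) against.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calibration
from .oacd import (
    BLOCK_THREE,
    DesignMatrix,
    decode_doses,
    preset_design,
)
from .response_model import (
    SurfaceModel,
    fit_quadratic,
    rank_observed,
    stepwise_reduce,
    term_parents,
)
from .synthetic_data import RUN_ID, TrueLandscape, assay, dose_col, make_landscape

#: monotherapy dose grid (uM) used for calibration assays: a zero-dose
#: control plus seven log-spaced doses spanning the panel's potency range.
CALIBRATION_DOSES = (0.0, *np.geomspace(0.05, 50.0, 7).round(4))


@dataclass(frozen=True)
class SearchConfig:
    """Tunable knobs of the search loop (all deterministic given a seed)."""

    schedule: tuple[int, ...] = (10, 7, 4)
    alpha: float = 0.05  # stepwise significance level
    ic_fraction: float = 0.2  # dose anchor: IC20
    tolerance: float = 0.05  # viability window for the lowest-dose rule
    max_drugs: int = 3  # ODC size cap
    replicates: int = 3
    cal_replicates: int = 3
    center_runs: int = 1
    hormesis_policy: str = "warn"  # or "exclude"
    hormesis_threshold: float = 0.05
    confirmation: bool = True  # enumerate final-panel combinations


class ScheduleError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Assay sources
# ---------------------------------------------------------------------------


class SimulatedAssay:
    """Assay oracle backed by a :class:`TrueLandscape` simulator."""

    def __init__(self, landscape: TrueLandscape, dose_grid=CALIBRATION_DOSES):
        self.landscape = landscape
        self.drugs = list(landscape.drugs)
        self.dose_grid = tuple(dose_grid)

    def monotherapy_plan(self, drug: str) -> pd.DataFrame:
        plan = pd.DataFrame({RUN_ID: np.arange(len(self.dose_grid))})
        for d in self.drugs:
            plan[dose_col(d)] = 0.0
        plan[dose_col(drug)] = np.asarray(self.dose_grid, dtype=float)
        return plan

    def run(self, plan: pd.DataFrame, replicates: int, seed: int) -> pd.DataFrame:
        full = plan.copy()
        for d in self.drugs:  # absent drugs dose 0
            if dose_col(d) not in full.columns:
                full[dose_col(d)] = 0.0
        return assay(self.landscape, full, replicates=replicates, seed=seed)


# ---------------------------------------------------------------------------
# Utilities and panel selection
# ---------------------------------------------------------------------------


def drug_utility(model: SurfaceModel) -> pd.Series:
    """Per-drug score g_i = beta_i + 1/2 * sum over retained beta_ij.

    Lower is better: negative linear effects (activity) and negative
    interactions (synergy) reward a drug, positive interactions
    (antagonism) penalize it.  Dropped terms contribute zero.
    """
    g = {}
    for f in model.factors:
        total = model.beta(f)
        for term in model.retained:
            if ":" in term and f in term_parents(term):
                total += 0.5 * model.beta(term)
        g[f] = total
    return pd.Series(g).sort_index()


def select_panel(
    utilities: pd.Series,
    m: int,
    flagged: tuple[str, ...] = (),
    policy: str = "warn",
) -> list[str]:
    """Keep the ``m`` lowest-utility drugs, deterministically.

    Ties break lexicographically on the drug name.  Under
    ``policy="exclude"`` hormesis-flagged drugs are skipped and the next
    ranked drug promoted; the default policy only warns (the flag is
    surfaced by the caller).
    """
    if m <= 0:
        raise ValueError("target panel size must be positive")
    if m >= len(utilities):
        raise ValueError("target size must be smaller than the current panel")
    order = sorted(utilities.index, key=lambda d: (utilities[d], d))
    if policy == "exclude":
        order = [d for d in order if d not in flagged]
        if len(order) < m:
            raise ValueError("cannot exclude flagged drugs and still fill the panel")
    return sorted(order[:m])


# ---------------------------------------------------------------------------
# Rounds, ODC, search driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoundResult:
    index: int
    panel: tuple[str, ...]
    design: DesignMatrix
    response: pd.DataFrame
    model: SurfaceModel  # stepwise-reduced
    utilities: pd.Series
    eliminated: dict[str, str]  # drug -> reason
    stage: str = "search"  # or "confirmation"


@dataclass(frozen=True)
class ODC:
    """An optimized drug combination: subset, levels, observed effect."""

    drugs: tuple[str, ...]
    levels: dict[str, int]  # coded level per panel drug (-1 absent)
    mean_viability: float
    sem: float
    run_id: int
    interactions: dict[str, float]  # retained pairwise terms within subset
    rationale: str

    def to_dict(self) -> dict:
        return {
            "drugs": list(self.drugs),
            "levels": {k: int(v) for k, v in sorted(self.levels.items())},
            "mean_viability": round(self.mean_viability, 10),
            "sem": round(self.sem, 10) if np.isfinite(self.sem) else None,
            "run_id": int(self.run_id),
            "interactions": {k: round(v, 10) for k, v in sorted(self.interactions.items())},
            "rationale": self.rationale,
        }


@dataclass(frozen=True)
class SearchResult:
    rounds: tuple[RoundResult, ...]
    odc: ODC
    anchors: dict[str, float]
    hill_fits: dict[str, calibration.HillFit]
    hormesis_flags: tuple[str, ...]
    config: SearchConfig
    seed: int


def full_factorial_design(factors: list[str]) -> DesignMatrix:
    """All 3^k combinations of absent/half/full levels (confirmation stage)."""
    rows = np.array(
        list(itertools.product((-1, 0, 1), repeat=len(factors))), dtype=int
    )
    coded = pd.DataFrame(rows, columns=list(factors))
    return DesignMatrix(
        coded=coded, block=pd.Series([BLOCK_THREE] * len(rows), name="block")
    )


def select_odc(
    final: RoundResult,
    max_drugs: int = 3,
    tolerance: float = 0.05,
    model: SurfaceModel | None = None,
) -> ODC:
    """Pick the lowest-dose tested combination showing maximal effect.

    Candidates are tested runs with 1..max_drugs active (level > -1) drugs
    whose mean viability lies within ``tolerance`` of the best candidate.
    Among them the minimal total fractional dose wins (levels mapped
    -1 -> 0, 0 -> 0.5, +1 -> 1 and summed); ties break by the most negative
    sum of retained pairwise coefficients within the subset, then
    lexicographically on the drug set.
    """
    model = model or final.model
    ranked = rank_observed(final.response)
    coded = final.design.coded
    cands = []
    for row in ranked.itertuples():
        levels = coded.iloc[int(getattr(row, RUN_ID))]
        active = [f for f in final.design.factors if levels[f] > -1]
        if not 1 <= len(active) <= max_drugs:
            continue
        dose_total = float(((levels[active] + 1.0) / 2.0).sum())
        syn = {}
        for a, b in itertools.combinations(sorted(active), 2):
            term = model.interaction_term(a, b)
            if term in model.retained:
                syn[term] = model.beta(term)
        cands.append(
            {
                "run_id": int(getattr(row, RUN_ID)),
                "mean": float(row.mean_viability),
                "sem": float(row.sem),
                "active": tuple(sorted(active)),
                "levels": {f: int(levels[f]) for f in final.design.factors},
                "dose_total": dose_total,
                "syn_sum": sum(syn.values()),
                "interactions": syn,
            }
        )
    if not cands:
        raise ValueError("no tested combination meets the ODC size constraint")
    best = min(c["mean"] for c in cands)
    eligible = [c for c in cands if c["mean"] <= best + tolerance]
    winner = min(
        eligible, key=lambda c: (c["dose_total"], c["syn_sum"], c["active"])
    )
    rationale = (
        f"lowest total dose ({winner['dose_total']:g}) among {len(eligible)} "
        f"combination(s) within {tolerance:g} of the best observed viability "
        f"{best:.4f}"
    )
    return ODC(
        drugs=winner["active"],
        levels=winner["levels"],
        mean_viability=winner["mean"],
        sem=winner["sem"],
        run_id=winner["run_id"],
        interactions=winner["interactions"],
        rationale=rationale,
    )


def run_search(
    source,
    schedule: tuple[int, ...] | None = None,
    config: SearchConfig | None = None,
    seed: int = 0,
) -> SearchResult:
    """Execute the full s-FSC loop against an assay source.

    Per round: preset composite design over the surviving panel, doses
    decoded from the calibration anchors (all at or below the IC20), assay,
    quadratic fit, stepwise reduction, drug utilities, panel selection.
    A confirmation stage (full absent/half/full factorial over the final
    panel) then supplies the tested combinations from which the ODC is
    selected.  Fully reproducible given ``seed``.
    """
    config = config or SearchConfig()
    schedule = tuple(schedule if schedule is not None else config.schedule)
    if any(b >= a for a, b in zip(schedule, schedule[1:])):
        raise ScheduleError(f"schedule must be strictly decreasing: {schedule}")
    if schedule[0] != len(source.drugs):
        raise ScheduleError(
            f"schedule starts at {schedule[0]} but the source has "
            f"{len(source.drugs)} drugs"
        )
    rng = np.random.default_rng(seed)
    cal_seeds = rng.integers(0, 2**31 - 1, size=len(source.drugs))
    round_seeds = rng.integers(0, 2**31 - 1, size=len(schedule) + 1)

    # calibration: monotherapy curves -> IC_p anchors + hormesis flags
    anchors: dict[str, float] = {}
    fits: dict[str, calibration.HillFit] = {}
    flagged: list[str] = []
    for i, drug in enumerate(source.drugs):
        plan = source.monotherapy_plan(drug)
        table = source.run(plan, config.cal_replicates, int(cal_seeds[i]))
        doses = table[dose_col(drug)].to_numpy(float)
        viab = table["viability"].to_numpy(float)
        fit = calibration.fit_hill(doses, viab)
        fits[drug] = fit
        horm, _ = calibration.detect_hormesis(doses, viab, config.hormesis_threshold)
        if horm:
            flagged.append(drug)
        if fit.converged and fit.informative:
            anchors[drug] = calibration.effective_dose(fit, config.ic_fraction)
        else:  # flat curve: fall back to the median tested dose
            pos = [d for d in np.unique(doses) if d > 0]
            anchors[drug] = float(np.median(pos))

    panel = sorted(source.drugs)
    rounds: list[RoundResult] = []
    for idx, k in enumerate(schedule):
        design = preset_design(k, config.center_runs).rename_factors(panel)
        plan = decode_doses(design, anchors)
        response = source.run(plan, config.replicates, int(round_seeds[idx]))
        model = stepwise_reduce(fit_quadratic(design, response), config.alpha)
        utilities = drug_utility(model)
        eliminated: dict[str, str] = {}
        if idx + 1 < len(schedule):
            keep = select_panel(
                utilities, schedule[idx + 1], tuple(flagged), config.hormesis_policy
            )
            for d in panel:
                if d not in keep:
                    reason = (
                        "hormesis-flagged (policy=exclude)"
                        if config.hormesis_policy == "exclude" and d in flagged
                        else f"utility g={utilities[d]:+.4f} outside the top "
                        f"{schedule[idx + 1]}"
                    )
                    eliminated[d] = reason
        else:
            keep = panel
        rounds.append(
            RoundResult(
                index=idx,
                panel=tuple(panel),
                design=design,
                response=response,
                model=model,
                utilities=utilities,
                eliminated=eliminated,
            )
        )
        panel = keep

    final = rounds[-1]
    if config.confirmation:
        design = full_factorial_design(list(final.panel))
        plan = decode_doses(design, anchors)
        response = source.run(plan, config.replicates, int(round_seeds[-1]))
        model = stepwise_reduce(fit_quadratic(design, response), config.alpha)
        final = RoundResult(
            index=len(schedule),
            panel=final.panel,
            design=design,
            response=response,
            model=model,
            utilities=drug_utility(model),
            eliminated={},
            stage="confirmation",
        )
        rounds.append(final)
    odc = select_odc(final, config.max_drugs, config.tolerance)
    return SearchResult(
        rounds=tuple(rounds),
        odc=odc,
        anchors=anchors,
        hill_fits=fits,
        hormesis_flags=tuple(flagged),
        config=config,
        seed=seed,
    )


def run_search_from_tables(
    tables: list[pd.DataFrame],
    anchors: dict[str, float],
    schedule: tuple[int, ...] | None = None,
    config: SearchConfig | None = None,
) -> SearchResult:
    """Replay the search loop against pre-recorded response tables.

    ``tables`` holds one response table per scheduled round, with run ids
    matching the preset design for that round's panel size, plus an
    optional final table for the confirmation stage (the full
    absent/half/full enumeration of the surviving panel).  Panels shrink
    between rounds exactly as in the simulated loop.
    """
    config = config or SearchConfig()
    schedule = tuple(schedule if schedule is not None else config.schedule)
    if any(b >= a for a, b in zip(schedule, schedule[1:])):
        raise ScheduleError(f"schedule must be strictly decreasing: {schedule}")
    if len(tables) not in (len(schedule), len(schedule) + 1):
        raise ValueError(
            f"need {len(schedule)} response tables (plus an optional "
            f"confirmation table), got {len(tables)}"
        )
    panel = sorted(anchors)
    if len(panel) != schedule[0]:
        raise ScheduleError(
            f"schedule starts at {schedule[0]} but {len(panel)} anchors given"
        )
    rounds: list[RoundResult] = []
    for idx, k in enumerate(schedule):
        design = preset_design(k, config.center_runs).rename_factors(panel)
        response = tables[idx]
        model = stepwise_reduce(fit_quadratic(design, response), config.alpha)
        utilities = drug_utility(model)
        eliminated: dict[str, str] = {}
        if idx + 1 < len(schedule):
            keep = select_panel(utilities, schedule[idx + 1])
            for d in panel:
                if d not in keep:
                    eliminated[d] = (
                        f"utility g={utilities[d]:+.4f} outside the top "
                        f"{schedule[idx + 1]}"
                    )
        else:
            keep = panel
        rounds.append(
            RoundResult(idx, tuple(panel), design, response, model, utilities,
                        eliminated)
        )
        panel = keep
    final = rounds[-1]
    if len(tables) == len(schedule) + 1:
        design = full_factorial_design(list(final.panel))
        response = tables[-1]
        model = stepwise_reduce(fit_quadratic(design, response), config.alpha)
        final = RoundResult(
            len(schedule), final.panel, design, response, model,
            drug_utility(model), {}, stage="confirmation",
        )
        rounds.append(final)
    odc = select_odc(final, config.max_drugs, config.tolerance)
    return SearchResult(
        rounds=tuple(rounds), odc=odc, anchors=dict(anchors), hill_fits={},
        hormesis_flags=(), config=config, seed=-1,
    )


# ---------------------------------------------------------------------------
# Reference simulation scenario for recovery studies
# ---------------------------------------------------------------------------

#: documented ground truth of the recovery scenario: three active drugs
#: (maximal inhibition 0.9) that are mutually synergistic (gamma = +2 on all
#: three pairs) hidden in a 10-drug panel of weak drugs (maximal inhibition
#: 0.25-0.45).
RECOVERY_ACTIVES = ("D01", "D02", "D03")
RECOVERY_EMAX_ACTIVE = 0.9
RECOVERY_GAMMA = 2.0
RECOVERY_EMAX_WEAK = (0.25, 0.45)


def recovery_landscape(seed: int = 0, noise_sd: float = 0.05) -> TrueLandscape:
    """The 10-drug planted-synergy landscape used in recovery studies."""
    rng = np.random.default_rng(seed)
    emax = rng.uniform(*RECOVERY_EMAX_WEAK, 10)
    emax[:3] = RECOVERY_EMAX_ACTIVE
    planted = [(i, j, RECOVERY_GAMMA) for i, j in itertools.combinations(range(3), 2)]
    return make_landscape(10, planted, seed=seed, emax=emax, noise_sd=noise_sd)
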