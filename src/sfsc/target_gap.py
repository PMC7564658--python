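"""Residual-kinase analysis and add-on drug proposal.

Given a drug-target matrix (fractional kinase inhibition per drug at a
stated dose), the selected combination's coverage of the active kinome is
the per-kinase maximum inhibition over the combination's drugs.  Kinases
that stay highly ranked after treatment yet uncovered are residual targets;
candidate add-on drugs are ranked by the sum of their inhibition of the
residual kinases weighted by each kinase's post-treatment activity score —
the logic by which a MET/FAK inhibitor is proposed when those kinases
remain active after treatment.  Only additions are proposed, never
substitutions: swapping a combination drug out for the add-on is known to
underperform.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inka import rank_kinases

COVERAGE_THRESHOLD = 0.5


@dataclass(frozen=True)
class DrugTargetMatrix:
    """Drug x kinase fractional-inhibition table at stated doses."""

    inhibition: pd.DataFrame  # rows drugs, columns kinases, values in [0,1]
    doses: dict[str, float] = field(default_factory=dict)  # per-drug dose

    def __post_init__(self) -> None:
        vals = self.inhibition.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("inhibition fractions must lie in [0, 1]")
        missing = [d for d in self.inhibition.index if d not in self.doses]
        if missing:
            raise ValueError(f"missing dose metadata for drugs: {missing}")

    @property
    def drugs(self) -> list[str]:
        return list(self.inhibition.index)

    @property
    def kinases(self) -> list[str]:
        return list(self.inhibition.columns)


def odc_coverage(
    odc: tuple[str, ...],
    dtm: DrugTargetMatrix,
    kinases: list[str],
    threshold: float = COVERAGE_THRESHOLD,
) -> tuple[list[str], list[str]]:
    """Partition kinases into (covered, uncovered) by the combination.

    A kinase is covered iff the maximum inhibition over the combination's
    drugs reaches ``threshold``; a kinase absent from the matrix is
    uncovered.
    """
    missing = [d for d in odc if d not in dtm.inhibition.index]
    if missing:
        raise ValueError(f"drug(s) missing from the target matrix: {missing}")
    covered, uncovered = [], []
    for k in kinases:
        if k in dtm.inhibition.columns:
            hit = float(dtm.inhibition.loc[list(odc), k].max())
        else:
            hit = 0.0
        (covered if hit >= threshold else uncovered).append(k)
    return covered, uncovered


def residual_active(
    post_treatment: pd.DataFrame,
    covered: set[str] | list[str],
    top_n: int = 20,
) -> list[str]:
    """Top post-treatment kinases not covered by the combination, by score."""
    covered = set(covered)
    return [k for k in rank_kinases(post_treatment, top_n) if k not in covered]


def propose_addon(
    residual: list[str],
    dtm: DrugTargetMatrix,
    exclude: tuple[str, ...] = (),
    post_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rank candidate add-on drugs against the residual active kinases.

    Each non-excluded drug scores the sum over residual kinases of its
    fractional inhibition weighted by the kinase's post-treatment INKA
    score (weight 1 when no scores are supplied).  Descending score, ties
    lexicographic.  The combination's own drugs are excluded even when they
    score best.
    """
    if not residual:
        raise ValueError(
            "no residual active kinases: the combination already covers the "
            "active kinome, no add-on needed"
        )
    weights = pd.Series(1.0, index=residual)
    if post_scores is not None:
        s = post_scores.set_index("kinase")["inka_score"]
        weights = s.reindex(residual).fillna(0.0)
    rows = []
    for drug in dtm.drugs:
        if drug in exclude:
            continue
        contrib = {
            k: float(dtm.inhibition.loc[drug, k]) * float(weights[k])
            if k in dtm.inhibition.columns
            else 0.0
            for k in residual
        }
        rows.append((drug, sum(contrib.values()), contrib))
    out = pd.DataFrame(rows, columns=["drug", "score", "per_kinase"])
    return out.sort_values(
        ["score", "drug"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
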