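"""Second-order response-surface modelling of combination screens.

The response is the viability fraction (1 = untreated) regressed on coded
dose levels, so a negative linear coefficient means single-drug activity, a
negative pairwise interaction synergy, and a positive interaction
antagonism; quadratic terms measure sensitivity to dose changes.  The full
model is reduced by hierarchical backward elimination and the retained
interaction signs classify each drug pair.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .oacd import DesignMatrix, check_estimability, model_matrix, quadratic_terms
from .synthetic_data import RUN_ID, VIABILITY

SYNERGY = "synergy"
ANTAGONISM = "antagonism"
ADDITIVE = "additive"


class RankDeficiencyError(ValueError):
    """Raised when the design cannot estimate the requested terms."""

    def __init__(self, inestimable):
        self.inestimable = tuple(inestimable)
        super().__init__(
            "design is rank-deficient; inestimable terms: "
            + ", ".join(self.inestimable)
        )


def term_parents(term: str) -> tuple[str, ...]:
    """Linear factors a higher-order term depends on (empty for linear)."""
    if ":" in term:
        return tuple(term.split(":"))
    if term.endswith("^2"):
        return (term[:-2],)
    return ()


@dataclass(frozen=True)
class SurfaceModel:
    """A fitted (possibly reduced) quadratic response-surface model."""

    factors: tuple[str, ...]
    coef: pd.Series
    se: pd.Series
    pvalues: pd.Series
    r2: float
    retained: tuple[str, ...]
    X: pd.DataFrame = field(repr=False)  # full-model matrix, stacked replicates
    y: np.ndarray = field(repr=False)

    def beta(self, term: str) -> float:
        """Coefficient of a retained term; 0 for a dropped term."""
        return float(self.coef.get(term, 0.0))

    def interaction_term(self, a: str, b: str) -> str:
        i, j = self.factors.index(a), self.factors.index(b)
        if i == j:
            raise ValueError("interaction needs two distinct drugs")
        first, second = (a, b) if i < j else (b, a)
        return f"{first}:{second}"

    def predict(self, coded: pd.DataFrame) -> np.ndarray:
        """Evaluate the retained polynomial at coded-level points."""
        Xp = model_matrix(coded[list(self.factors)], list(self.retained))
        return Xp.to_numpy() @ self.coef.loc[list(self.retained)].to_numpy()


def _ols(X: pd.DataFrame, y: np.ndarray, terms: list[str],
         error_scale: tuple[float, float] | None = None):
    """OLS fit; returns (params, se, pvalues, r2).

    When ``error_scale = (mse, df)`` is given, standard errors and p-values
    are referenced to that error variance instead of the submodel's own
    residual mean square.  Anchoring all partial tests to the full model's
    error estimate avoids the optimistic shrinkage of sigma-hat that
    sequential elimination otherwise induces (the Draper-Smith
    recommendation for backward elimination).
    """
    res = sm.OLS(y, X[terms]).fit()
    if error_scale is None:
        return res.params, res.bse, res.pvalues, float(res.rsquared)
    mse, df = error_scale
    diag = np.diag(res.normalized_cov_params)
    if mse > 1e-20:
        se = np.sqrt(mse * diag)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = res.params.to_numpy() / se
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
    else:  # noise-free response: coefficients are exact
        se = np.zeros(len(terms))
        pvals = np.where(np.abs(res.params.to_numpy()) > 1e-12, 0.0, 1.0)
    return (
        res.params,
        pd.Series(se, index=terms),
        pd.Series(pvals, index=terms),
        float(res.rsquared),
    )


def _make_model(factors, fit, retained, X, y) -> SurfaceModel:
    params, se, pvalues, r2 = fit
    return SurfaceModel(
        factors=tuple(factors),
        coef=pd.Series(np.asarray(params), index=retained),
        se=pd.Series(np.asarray(se), index=retained),
        pvalues=pd.Series(np.asarray(pvalues), index=retained),
        r2=r2,
        retained=tuple(retained),
        X=X,
        y=y,
    )


def fit_quadratic(design: DesignMatrix, response: pd.DataFrame) -> SurfaceModel:
    """OLS fit of the full quadratic model on coded levels.

    Replicate read-outs enter stacked (not averaged) so the residual degrees
    of freedom, and hence the per-term p-values, reflect replicate noise.
    ``response`` must carry ``run_id`` and ``viability`` columns; run ids
    index rows of the design.
    """
    for col in (RUN_ID, VIABILITY):
        if col not in response.columns:
            raise ValueError(f"response table lacks a {col!r} column")
    run_ids = response[RUN_ID].to_numpy()
    if run_ids.min() < 0 or run_ids.max() >= design.n_runs:
        raise ValueError("response run_id outside the design's run range")
    report = check_estimability(design)
    if not report.full_rank:
        raise RankDeficiencyError(report.inestimable)
    coded_rows = design.coded.iloc[run_ids].reset_index(drop=True)
    terms = quadratic_terms(design.factors)
    X = model_matrix(coded_rows, terms)
    y = response[VIABILITY].to_numpy(dtype=float)
    return _make_model(design.factors, _ols(X, y, terms), terms, X, y)


def stepwise_reduce(model: SurfaceModel, alpha: float = 0.05) -> SurfaceModel:
    """Hierarchical backward elimination at significance level ``alpha``.

    Repeatedly drops the least significant droppable term with p > alpha,
    refitting the coefficients after each drop.  A linear term is droppable
    only when none of its child interaction/quadratic terms is retained;
    the intercept is never dropped.  Ties (equal p) break by lexicographic
    term name, so the reduction is deterministic.

    Significance is judged by the full model's partial t-tests (with its
    residual mean square as the error estimate), not by re-estimated
    submodel errors: re-estimation after every drop is known to shrink the
    apparent error and inflate the null retention rate above alpha, whereas
    the full-model tests are exactly calibrated.  On the (near-)orthogonal
    composite designs used here the two conventions pick the same terms.
    """
    retained = list(model.retained)
    X, y = model.X, model.y
    n, p_full = X.shape
    df_full = n - p_full
    if df_full <= 0:
        raise ValueError("stepwise reduction needs residual degrees of freedom")
    res_full = sm.OLS(y, X).fit()
    error_scale = (float(res_full.scale), df_full)
    # decision p-values, fixed once from the full model
    _, _, decision_p, _ = _ols(X, y, list(X.columns), error_scale)
    while True:
        droppable = []
        for t in retained:
            if t == "Intercept":
                continue
            if not term_parents(t):  # linear: check for retained children
                has_child = any(
                    t in term_parents(other) for other in retained if other != t
                )
                if has_child:
                    continue
            droppable.append(t)
        worst = None
        for t in droppable:
            p = float(decision_p[t])
            if p <= alpha or np.isnan(p):
                continue
            if worst is None or p > worst[0] or (p == worst[0] and t < worst[1]):
                worst = (p, t)
        if worst is None:
            break
        retained.remove(worst[1])
    fit = _ols(X, y, retained, error_scale)
    return _make_model(model.factors, fit, retained, X, y)


def classify_terms(model: SurfaceModel) -> dict[tuple[str, str], str]:
    """Per-pair interaction label from the retained coefficient sign.

    A retained negative interaction is synergy, a retained positive one
    antagonism; a dropped interaction term means the pair acts additively.
    """
    labels: dict[tuple[str, str], str] = {}
    factors = list(model.factors)
    for i, a in enumerate(factors):
        for b in factors[i + 1 :]:
            term = f"{a}:{b}"
            if term not in model.retained:
                labels[(a, b)] = ADDITIVE
            else:
                beta = model.beta(term)
                labels[(a, b)] = SYNERGY if beta < 0 else ANTAGONISM
    return labels


def predict_surface(
    model: SurfaceModel,
    pair: tuple[str, str],
    grid=(-1, 0, 1),
    others_at: float = -1.0,
) -> pd.DataFrame:
    """Predicted-viability grid over two drugs, others fixed at a coded level.

    The default ``others_at=-1`` holds every other drug absent, matching the
    two-drug response surfaces drawn for a final combination.
    """
    a, b = pair
    for drug in pair:
        if drug not in model.factors:
            raise ValueError(f"unknown drug {drug!r}")
    levels = list(grid)
    points = []
    for la in levels:
        for lb in levels:
            row = {f: others_at for f in model.factors}
            row[a], row[b] = la, lb
            points.append(row)
    preds = model.predict(pd.DataFrame(points))
    return pd.DataFrame(
        preds.reshape(len(levels), len(levels)), index=levels, columns=levels
    )


def rank_observed(response: pd.DataFrame) -> pd.DataFrame:
    """Rank tested combinations by mean observed viability (best first).

    A combination is a distinct dosing row (run).  Ties break by fewer
    active drugs, then lexicographically on the dose signature, so ordering
    is stable.  SEM uses the sample standard deviation (ddof=1).
    """
    if RUN_ID not in response.columns or len(response) == 0:
        raise ValueError("response table must be non-empty with run_id")
    dcols = sorted(c for c in response.columns if c.startswith("dose_"))
    rows = []
    for run_id, grp in response.groupby(RUN_ID):
        v = grp[VIABILITY].to_numpy(dtype=float)
        mean = float(v.mean())
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
        doses = grp.iloc[0][dcols] if dcols else pd.Series(dtype=float)
        n_active = int((doses.to_numpy(float) > 0).sum()) if dcols else 0
        signature = ";".join(f"{c}={doses[c]:g}" for c in dcols)
        rows.append((run_id, mean, sem, len(v), n_active, signature))
    out = pd.DataFrame(
        rows,
        columns=[RUN_ID, "mean_viability", "sem", "n", "n_active", "signature"],
    )
    out = out.sort_values(
        ["mean_viability", "n_active", "signature"], kind="mergesort"
    ).reset_index(drop=True)
    out.index.name = "rank"
    return out
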