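"""Monotherapy dose-response calibration.

Fits a four-parameter logistic (4PL) to viability read-outs and converts the
fit into the dose anchors (IC20, or any ED_p) that set the coded dose levels
of the combination designs.  Viability, not inhibition, is the modelled
response: v(d) = top - emax * d^h / (d^h + ec50^h), with ``top`` the
untreated plateau and ``emax`` the maximal absolute inhibition, so the
fitted curve is monotone non-increasing in dose.  Hormetic drugs (growth
stimulation at low dose) are detected and flagged, never silently modelled.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

#: multi-start grid over the Hill slope; ec50 starts come from dose quantiles.
H_STARTS = (0.5, 1.0, 2.0, 4.0)
EC50_QUANTILES = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class HillFit:
    """A bounded 4PL fit of viability against dose."""

    top: float
    emax: float
    h: float
    ec50: float
    rss: float
    converged: bool
    informative: bool

    def predict(self, dose) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        return self.top - self.emax * _phi(d, self.h, self.ec50)

    def inhibition(self, dose) -> np.ndarray:
        """Absolute inhibition top - v(d) = emax * phi(d)."""
        return self.emax * _phi(np.asarray(dose, dtype=float), self.h, self.ec50)


def _phi(d: np.ndarray, h: float, ec50: float) -> np.ndarray:
    """Occupancy term d^h / (d^h + ec50^h), defined as 0 at d = 0."""
    out = np.zeros_like(d, dtype=float)
    pos = d > 0
    dh = d[pos] ** h
    out[pos] = dh / (dh + ec50**h)
    return out


def fit_hill(doses, viabilities) -> HillFit:
    """Bounded nonlinear least-squares 4PL fit with a documented multi-start.

    Requires at least four distinct doses including a zero/near-zero control.
    A response vector with (numerically) no variation yields a flat fit
    flagged non-informative rather than an error.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(viabilities, dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and viabilities must have equal length")
    if np.any(d < 0):
        raise ValueError("doses must be nonnegative")
    distinct = np.unique(d)
    if len(distinct) < 4:
        raise ValueError("need at least 4 distinct doses")
    if distinct.min() > 0.05 * distinct.max():
        raise ValueError("need a zero or near-zero control dose")

    top0 = float(np.mean(y[d == distinct.min()]))
    if np.std(y) < 1e-12:
        return HillFit(top=top0, emax=0.0, h=1.0, ec50=float(np.median(distinct[distinct > 0])),
                       rss=0.0, converged=True, informative=False)

    dpos = distinct[distinct > 0]
    lo = np.array([0.0, 0.0, 0.05, dpos.min() / 20.0])
    hi = np.array([2.0, 1.5, 8.0, dpos.max() * 20.0])
    emax0 = float(np.clip(top0 - np.mean(y[d == distinct.max()]), 0.01, 1.4))

    def resid(theta):
        top, emax, h, ec50 = theta
        return top - emax * _phi(d, h, ec50) - y

    best = None
    for h0 in H_STARTS:
        for q in EC50_QUANTILES:
            ec0 = float(np.quantile(dpos, q))
            x0 = np.clip([top0, emax0, h0, ec0], lo + 1e-9, hi - 1e-9)
            try:
                sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14,
                                    ftol=1e-14, gtol=1e-14)
            except Exception:  # pragma: no cover - scipy failure safety net
                continue
            rss = float(np.sum(sol.fun**2))
            key = (round(rss, 12), sol.x[2])  # ties broken by smaller slope
            if best is None or key < best[0]:
                best = (key, sol, rss)
    if best is None:  # pragma: no cover
        return HillFit(top=top0, emax=0.0, h=1.0, ec50=float(np.median(dpos)),
                       rss=float("inf"), converged=False, informative=False)
    _, sol, rss = best
    top, emax, h, ec50 = (float(v) for v in sol.x)
    informative = emax > 1e-3
    return HillFit(top=top, emax=emax, h=h, ec50=ec50, rss=rss,
                   converged=bool(sol.success), informative=informative)


def effective_dose(fit: HillFit, p: float) -> float:
    """Dose producing the fraction ``p`` of the drug's maximal inhibition.

    Closed form of the 4PL: d = ec50 * (p / (1 - p))^(1/h); p = 0.2 gives
    the IC20 anchor, p = 0.5 the ec50 itself.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly between 0 and 1")
    if not (fit.converged and fit.informative):
        raise ValueError("cannot compute an effective dose from a "
                         "non-informative or unconverged fit")
    return float(fit.ec50 * (p / (1.0 - p)) ** (1.0 / fit.h))


def detect_hormesis(doses, viabilities, threshold: float = 0.05):
    """Flag growth stimulation above control at any nonzero dose.

    Returns ``(flagged, offending_doses)`` where a dose offends when its mean
    viability exceeds the zero-dose control mean by strictly more than
    ``threshold``.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(viabilities, dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and viabilities must have equal length")
    if not np.any(d == 0):
        raise ValueError("hormesis detection requires a zero-dose control")
    control = float(np.mean(y[d == 0]))
    offending = []
    for dose in np.unique(d[d > 0]):
        if float(np.mean(y[d == dose])) > control + threshold:
            offending.append(float(dose))
    return (len(offending) > 0, offending)
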