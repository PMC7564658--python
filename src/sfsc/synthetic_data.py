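"""Ground-truth simulators for combination screens and phosphoproteomes.

Two generators live here:

* a multi-drug viability landscape — Hill-type monotherapy curves combined
  under Bliss independence, with planted pairwise synergy/antagonism acting
  multiplicatively on the Bliss baseline, optional low-dose hormesis, and
  Gaussian assay noise — standing in for a cell line's unknown response
  surface in a metabolic-activity (viability) assay;
* a spectral-count phosphoproteome driven by latent kinase activities
  through a known kinase-substrate map, used to validate activity scoring.

Every stochastic draw is seeded, so downstream search and scoring stages are
testable end-to-end without any external data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# Column conventions for response tables (shared with io/response_model).
RUN_ID = "run_id"
REPLICATE = "replicate"
VIABILITY = "viability"
DOSE_PREFIX = "dose_"

#: truncation range for noisy viability readouts; the upper bound admits
#: hormetic (above-control) wells.
ASSAY_CLIP = (0.0, 1.2)

# Documented parameter ranges for randomly drawn monotherapy curves:
# fractional maximal inhibition, Hill slope, and midpoint dose (uM,
# log-uniform).  Chosen to resemble kinase-inhibitor panels dosed in the
# sub-uM .. 10 uM range.
EMAX_RANGE = (0.55, 0.95)
HILL_RANGE = (0.8, 2.5)
EC50_RANGE = (0.5, 5.0)

# Poisson intensity per unit kinase activity for phosphopeptide counts:
# ALPHA for peptides on the kinase protein itself (scaled by peptide
# multiplicity), BETA for each mapped substrate site.
ALPHA_DEFAULT = 2.0
BETA_DEFAULT = 1.0


def dose_col(drug: str) -> str:
    return DOSE_PREFIX + drug


@dataclass(frozen=True)
class TrueLandscape:
    """Simulation ground truth for a panel of drugs.

    ``gamma`` is the symmetric pairwise interaction matrix on fractional
    effects: positive entries are synergistic (they depress viability below
    the Bliss product), negative entries antagonistic, zero independent.
    """

    drugs: tuple[str, ...]
    emax: np.ndarray
    hill: np.ndarray
    ec50: np.ndarray
    gamma: np.ndarray
    hormesis: np.ndarray
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        n = len(self.drugs)
        for name in ("emax", "hill", "ec50", "hormesis"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if self.gamma.shape != (n, n):
            raise ValueError("gamma must be square over the drug panel")
        if not np.allclose(self.gamma, self.gamma.T):
            raise ValueError("gamma must be symmetric")
        if np.any(np.diag(self.gamma) != 0):
            raise ValueError("gamma must have a zero diagonal")
        if np.any((self.emax < 0) | (self.emax > 1)):
            raise ValueError("emax must lie in [0, 1]")
        if np.any(self.hill <= 0) or np.any(self.ec50 <= 0):
            raise ValueError("hill and ec50 must be positive")
        if np.any(self.hormesis < 0):
            raise ValueError("hormesis amplitudes must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    def index(self, drug: str) -> int:
        return self.drugs.index(drug)


def make_landscape(
    n_drugs: int,
    planted: list[tuple[int, int, float]] | None = None,
    seed: int = 0,
    *,
    emax: np.ndarray | None = None,
    hormesis: np.ndarray | None = None,
    noise_sd: float = 0.05,
) -> TrueLandscape:
    """Draw a reproducible landscape with the given interactions planted.

    All gammas other than the planted ones are zero.  Hill parameters are
    drawn from the documented module-level ranges; ``emax`` may be supplied
    explicitly to plant strong/weak single-drug activities.
    """
    if n_drugs < 2:
        raise ValueError("need at least two drugs")
    rng = np.random.default_rng(seed)
    drugs = tuple(f"D{i + 1:02d}" for i in range(n_drugs))
    emax_arr = (
        rng.uniform(*EMAX_RANGE, n_drugs) if emax is None else np.asarray(emax, float)
    )
    hill = rng.uniform(*HILL_RANGE, n_drugs)
    ec50 = np.exp(rng.uniform(np.log(EC50_RANGE[0]), np.log(EC50_RANGE[1]), n_drugs))
    gamma = np.zeros((n_drugs, n_drugs))
    seen: set[tuple[int, int]] = set()
    for i, j, g in planted or []:
        if i == j:
            raise ValueError(f"cannot plant a self-interaction ({i},{i})")
        if not (0 <= i < n_drugs and 0 <= j < n_drugs):
            raise ValueError(f"planted index ({i},{j}) out of range")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"duplicate planted pair {key}")
        seen.add(key)
        gamma[i, j] = gamma[j, i] = g
    horm = np.zeros(n_drugs) if hormesis is None else np.asarray(hormesis, float)
    return TrueLandscape(
        drugs=drugs,
        emax=emax_arr,
        hill=hill,
        ec50=ec50,
        gamma=gamma,
        hormesis=horm,
        noise_sd=float(noise_sd),
        seed=seed,
    )


def fractional_effects(landscape: TrueLandscape, doses: np.ndarray) -> np.ndarray:
    """Per-drug fractional effect f_i at the given doses.

    f_i = emax_i * d^h / (d^h + ec50^h), minus the hormetic bump
    s_i * (d/ec50) * exp(1 - d/ec50) when configured, so f_i can be negative
    (growth stimulation) at low dose.
    """
    d = np.asarray(doses, dtype=float)
    if d.shape != (landscape.n_drugs,):
        raise ValueError("doses must give one value per drug")
    if np.any(d < 0):
        raise ValueError("doses must be nonnegative")
    with np.errstate(divide="ignore"):
        dh = np.where(d > 0, d, np.nan) ** landscape.hill
    f = np.where(d > 0, landscape.emax * dh / (dh + landscape.ec50**landscape.hill), 0.0)
    rel = d / landscape.ec50
    f = f - landscape.hormesis * rel * np.exp(1.0 - rel)
    return f


def viability(landscape: TrueLandscape, doses) -> float:
    """Noise-free viability fraction under a dose combination.

    Baseline is the Bliss-independence product of single-drug survivals;
    pairwise interactions multiply it by exp(-gamma_ij * f_i * f_j), so a
    positive gamma (synergy) lowers viability below the Bliss product.
    The result is clipped to [0, 1] (or [0, 1.2] when hormesis is present,
    so stimulated wells can read above control).
    """
    f = fractional_effects(landscape, np.asarray(doses, dtype=float))
    v0 = np.prod(1.0 - f)
    iu, ju = np.triu_indices(landscape.n_drugs, k=1)
    inter = np.exp(-np.sum(landscape.gamma[iu, ju] * f[iu] * f[ju]))
    upper = ASSAY_CLIP[1] if np.any(landscape.hormesis > 0) else 1.0
    return float(np.clip(v0 * inter, 0.0, upper))


def assay(
    landscape: TrueLandscape,
    plan: pd.DataFrame,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a plate read-out for a dosing plan.

    ``plan`` needs a ``run_id`` column plus a ``dose_<drug>`` column per
    drug.  Gaussian noise with sd ``landscape.noise_sd`` is added per
    replicate and truncated to the assay range [0, 1.2].
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    cols = [dose_col(d) for d in landscape.drugs]
    missing = [c for c in cols if c not in plan.columns]
    if missing:
        raise ValueError(f"plan lacks dose columns: {missing}")
    rng = np.random.default_rng(seed)
    doses = plan[cols].to_numpy(dtype=float)
    clean = np.array([viability(landscape, row) for row in doses])
    rows = []
    for rep in range(1, replicates + 1):
        noisy = clean + rng.normal(0.0, landscape.noise_sd, size=len(clean))
        noisy = np.clip(noisy, *ASSAY_CLIP)
        block = plan[[RUN_ID] + cols].copy()
        block[REPLICATE] = rep
        block[VIABILITY] = noisy
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Synthetic phosphoproteomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhosphoTruth:
    """Latent ground truth behind a synthetic phosphoproteome.

    ``activities`` are nonnegative latent kinase intensities; ``relations``
    is a kinase-substrate table (columns kinase, substrate, site, evidence
    in {PSP, NWK}); ``peptides`` lists the phosphopeptides carried by each
    kinase protein as (site, multiplicity) pairs, the first of which lies in
    the activation loop; ``loop`` maps each kinase to its activation-loop
    interval (1-based inclusive).
    """

    activities: dict[str, float]
    relations: pd.DataFrame
    peptides: dict[str, list[tuple[int, int]]]
    loop: dict[str, tuple[int, int]]
    depth: float = 1.0

    def __post_init__(self) -> None:
        if not self.activities:
            raise ValueError("kinase set must be non-empty")
        vals = np.array(list(self.activities.values()), dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("activities must be finite and nonnegative")

    def annotations(self) -> pd.DataFrame:
        """Activation-loop annotation table (kinase, loop_start, loop_end)."""
        return pd.DataFrame(
            [(k, s, e) for k, (s, e) in self.loop.items()],
            columns=["kinase", "loop_start", "loop_end"],
        )


def make_phospho_truth(
    n_kinases: int,
    seed: int = 0,
    *,
    activity_range: tuple[float, float] = (1.0, 10.0),
    peptides_per_kinase: int = 3,
    substrates_per_kinase: int = 4,
    activities: dict[str, float] | None = None,
) -> PhosphoTruth:
    """Draw a random truth: log-spread activities, loop intervals, and a
    kinase-substrate map with mixed PSP/NWK evidence."""
    if n_kinases < 1:
        raise ValueError("need at least one kinase")
    rng = np.random.default_rng(seed)
    kinases = [f"KIN{i + 1:02d}" for i in range(n_kinases)]
    lo, hi = activity_range
    drawn = np.exp(rng.uniform(np.log(lo), np.log(hi), n_kinases))
    if activities is None:
        acts = dict(zip(kinases, drawn))
    else:
        # explicit activities replace the drawn ones; the rng stream stays
        # aligned so the peptide/substrate layout is seed-stable
        acts = dict(activities)
        kinases = list(acts)
    loop, peptides, rel_rows = {}, {}, []
    for k in kinases:
        start = int(rng.integers(150, 300))
        loop[k] = (start, start + 30)
        peps = [(start + int(rng.integers(0, 31)), 1)]
        for _ in range(peptides_per_kinase - 1):
            peps.append((int(rng.integers(1, 140)), int(rng.integers(1, 4))))
        peptides[k] = peps
        for s in range(substrates_per_kinase):
            sub = f"SUB_{k}_{s + 1}"
            site = int(rng.integers(1, 500))
            evidence = ["PSP", "NWK", "both"][int(rng.integers(0, 3))]
            if evidence == "both":
                rel_rows.append((k, sub, site, "PSP"))
                rel_rows.append((k, sub, site, "NWK"))
            else:
                rel_rows.append((k, sub, site, evidence))
    relations = pd.DataFrame(rel_rows, columns=["kinase", "substrate", "site", "evidence"])
    return PhosphoTruth(activities=acts, relations=relations, peptides=peptides, loop=loop)


def make_phospho_counts(
    truth: PhosphoTruth,
    n_samples: int,
    seed: int = 0,
    *,
    alpha: float = ALPHA_DEFAULT,
    beta: float = BETA_DEFAULT,
    sample_prefix: str = "S",
) -> pd.DataFrame:
    """Sample a phosphopeptide spectral-count table from the truth.

    Counts on a kinase's own peptides are Poisson(alpha * depth * a_k *
    multiplicity); counts on each mapped substrate site are Poisson(beta *
    depth * a_k), summed over kinases sharing that site.  Rows are
    phosphopeptides (peptide_id, protein, site), columns the samples.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    samples = [f"{sample_prefix}{i + 1}" for i in range(n_samples)]
    meta, mus = [], []
    for k, peps in truth.peptides.items():
        a = truth.activities[k]
        for idx, (site, mult) in enumerate(peps):
            meta.append((f"{k}_pep{idx + 1}", k, site))
            mus.append(alpha * truth.depth * a * mult)
    sub_mu: dict[tuple[str, int], float] = {}
    for row in truth.relations.drop_duplicates(["kinase", "substrate", "site"]).itertuples():
        key = (row.substrate, int(row.site))
        sub_mu[key] = sub_mu.get(key, 0.0) + beta * truth.depth * truth.activities[row.kinase]
    for (sub, site), mu in sorted(sub_mu.items()):
        meta.append((f"{sub}_p{site}", sub, site))
        mus.append(mu)
    counts = rng.poisson(np.asarray(mus)[:, None], size=(len(mus), n_samples))
    table = pd.DataFrame(
        meta, columns=["peptide_id", "protein", "site"]
    ).join(pd.DataFrame(counts, columns=samples))
    return table.set_index("peptide_id")
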