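"""Integrative inferred kinase activity (INKA) scoring.

A kinase's activity is inferred from phosphopeptide spectral counts along
four evidence arms: counts on the kinase protein itself (kinome), the
subset lying in its activation loop, and counts on substrate phosphosites
attributed to the kinase by curated (PSP) or predicted (NWK) kinase-
substrate relations.  The score is the geometric mean of the kinase-centric
and substrate-centric sides:

    score = sqrt( mean(kinome, loop) * mean(psp, nwk) )

so a kinase needs evidence on both sides to score above zero.  The module
also normalizes count tables across samples, ranks kinases, compares
treatments, tests differential phosphokinase expression, and builds
kinase-substrate evidence networks.
"""
from __future__ import annotations

from dataclasses import dataclass
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

META_COLS = ("protein", "site")
EVIDENCE = ("PSP", "NWK")

TOP_N_DEFAULT = 20


def _sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


def normalize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample to the grand mean of the per-sample totals.

    Conserves the grand total of counts; errors on an all-zero sample,
    naming it.
    """
    samples = _sample_columns(table)
    if not samples:
        raise ValueError("table has no sample columns")
    totals = table[samples].sum(axis=0).astype(float)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    scale = totals.mean() / totals
    out = table.copy()
    out[samples] = table[samples].astype(float) * scale
    out.attrs["normalized"] = True
    return out


@dataclass(frozen=True)
class INKAResult:
    kinase: str
    kinome: float
    activation_loop: float
    psp_substrate: float
    nwk_substrate: float
    inka_score: float


def arm_scores(
    kinase: str,
    table: pd.DataFrame,
    annotations: pd.DataFrame,
    relations: pd.DataFrame,
    samples: list[str] | None = None,
) -> tuple[float, float, float, float]:
    """Evidence-arm sums for one kinase (kinome, loop, PSP, NWK).

    Counts are summed over the selected samples.  The activation-loop arm
    sums the kinase's own phosphopeptides whose site falls inside the
    annotated interval; the substrate arms sum peptides matching a
    (substrate protein, site) relation of that evidence class, each peptide
    counted once per arm.
    """
    samples = samples or _sample_columns(table)
    own = table[table["protein"] == kinase]
    if own.empty and relations[relations["kinase"] == kinase].empty:
        warnings.warn(f"kinase {kinase!r} has no peptides and no relations")
    kinome = float(own[samples].to_numpy().sum())
    loop_rows = annotations[annotations["kinase"] == kinase]
    loop = 0.0
    if not loop_rows.empty:
        start = int(loop_rows.iloc[0]["loop_start"])
        end = int(loop_rows.iloc[0]["loop_end"])
        in_loop = own[(own["site"] >= start) & (own["site"] <= end)]
        loop = float(in_loop[samples].to_numpy().sum())
    arms = {}
    for ev in EVIDENCE:
        rel = relations[(relations["kinase"] == kinase) & (relations["evidence"] == ev)]
        keys = set(zip(rel["substrate"], rel["site"].astype(int)))
        if keys:
            mask = [
                (p, int(s)) in keys
                for p, s in zip(table["protein"], table["site"].astype(int))
            ]
            arms[ev] = float(table.loc[mask, samples].to_numpy().sum())
        else:
            arms[ev] = 0.0
    return kinome, loop, arms["PSP"], arms["NWK"]


def inka_score(arms) -> float:
    """Combine the four arms into one activity score.

    Geometric mean of the kinase-centric mean (kinome, activation loop) and
    the substrate-centric mean (PSP, NWK); homogeneous of degree 1 in the
    counts, and zero when either side lacks evidence.
    """
    kinome, loop, psp, nwk = (float(a) for a in arms)
    if min(kinome, loop, psp, nwk) < 0:
        raise ValueError("arm values must be nonnegative")
    kinase_centric = (kinome + loop) / 2.0
    substrate_centric = (psp + nwk) / 2.0
    return float(np.sqrt(kinase_centric * substrate_centric))


def inka_table(
    table: pd.DataFrame,
    annotations: pd.DataFrame,
    relations: pd.DataFrame,
    kinases: list[str] | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Score every kinase; returns a table sorted by descending score.

    The kinase universe defaults to the union of annotated kinases and
    relation sources.  Ranks are 1-based; ties in score break
    lexicographically on the kinase name.
    """
    if kinases is None:
        kinases = sorted(set(annotations["kinase"]) | set(relations["kinase"]))
    rows = []
    for k in kinases:
        arms = arm_scores(k, table, annotations, relations, samples)
        rows.append((k, *arms, inka_score(arms)))
    out = pd.DataFrame(
        rows,
        columns=["kinase", "kinome", "activation_loop", "psp_substrate",
                 "nwk_substrate", "inka_score"],
    )
    out = out.sort_values(
        ["inka_score", "kinase"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def rank_kinases(results: pd.DataFrame, top_n: int = TOP_N_DEFAULT) -> list[str]:
    """Top-N kinase identifiers by descending score (ties alphabetical)."""
    ordered = results.sort_values(
        ["inka_score", "kinase"], ascending=[False, True], kind="mergesort"
    )
    return list(ordered["kinase"].head(top_n))


def top_overlap(a: pd.DataFrame, b: pd.DataFrame, n: int = TOP_N_DEFAULT) -> float:
    """Fraction of the top-N kinases shared between two scored profiles."""
    avail = min(n, len(a), len(b))
    if avail < n:
        warnings.warn(
            f"fewer than {n} kinases available; overlap computed over {avail}"
        )
        n = avail
    if n == 0:
        raise ValueError("no kinases to compare")
    return len(set(rank_kinases(a, n)) & set(rank_kinases(b, n))) / n


def treatment_delta(control: pd.DataFrame, treated: pd.DataFrame) -> pd.DataFrame:
    """Per-kinase percent change of the INKA score under treatment.

    100 * (treated - control) / control; kinases with a zero control score
    get ``defined = False`` and an NaN percent change.
    """
    c = control.set_index("kinase")["inka_score"]
    t = treated.set_index("kinase")["inka_score"]
    shared = sorted(set(c.index) & set(t.index))
    rows = []
    for k in shared:
        if c[k] == 0:
            rows.append((k, np.nan, False))
        else:
            rows.append((k, 100.0 * (t[k] - c[k]) / c[k], True))
    return pd.DataFrame(rows, columns=["kinase", "percent_change", "defined"])


def differential_phosphokinase(
    groups: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided t-test on per-kinase aggregated counts, BH-corrected.

    ``groups`` maps exactly two condition names to normalized count tables
    whose sample columns are replicates.  Counts are aggregated per kinase
    protein (summed over its peptides) within each replicate.
    """
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    (name_a, tab_a), (name_b, tab_b) = groups.items()
    agg = {}
    for name, tab in ((name_a, tab_a), (name_b, tab_b)):
        samples = _sample_columns(tab)
        if len(samples) < 2:
            raise ValueError(f"group {name!r} needs >= 2 replicates")
        agg[name] = tab.groupby("protein")[samples].sum()
    kinases = sorted(set(agg[name_a].index) & set(agg[name_b].index))
    stats_rows = []
    for k in kinases:
        xa = agg[name_a].loc[k].to_numpy(float)
        xb = agg[name_b].loc[k].to_numpy(float)
        if np.std(xa) == 0 and np.std(xb) == 0:
            # no within-group variance: no evidence either way
            t, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                # near-constant count vectors trip scipy's moment warning
                warnings.simplefilter("ignore", RuntimeWarning)
                t, p = stats.ttest_ind(xa, xb)
            if not np.isfinite(p):
                t, p = 0.0, 1.0
        stats_rows.append((k, float(t), float(p)))
    out = pd.DataFrame(stats_rows, columns=["kinase", "t_stat", "p_value"])
    reject, p_adj, _, _ = multipletests(out["p_value"], alpha=alpha, method="fdr_bh")
    out["p_adjusted"] = p_adj
    out["significant"] = reject
    return out


def build_network(
    table: pd.DataFrame,
    relations: pd.DataFrame,
    results: pd.DataFrame,
) -> nx.Graph:
    """Kinase-substrate network of positively scoring kinases.

    Nodes are kinases (with their INKA score as an attribute) and the
    substrate proteins whose relation sites are observed in the count
    table; each edge carries its evidence class (PSP, NWK or both).
    """
    scores = results.set_index("kinase")["inka_score"]
    active = set(scores[scores > 0].index)
    observed = set(zip(table["protein"], table["site"].astype(int)))
    g = nx.Graph()
    for k in sorted(active):
        g.add_node(k, kind="kinase", inka_score=float(scores[k]))
    edge_ev: dict[tuple[str, str], set[str]] = {}
    for row in relations.itertuples():
        if row.kinase not in active:
            continue
        if (row.substrate, int(row.site)) not in observed:
            continue
        edge_ev.setdefault((row.kinase, row.substrate), set()).add(row.evidence)
    for (k, sub), evs in sorted(edge_ev.items()):
        if sub not in g:
            g.add_node(sub, kind="substrate")
        g.add_edge(k, sub, evidence="both" if len(evs) > 1 else next(iter(evs)))
    return g
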