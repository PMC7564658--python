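"""File formats and run configuration.

Everything crosses the filesystem as plain text: response tables, designs,
dosing plans and fit reports as CSV; spectral counts, annotations and
kinase-substrate relations as TSV; networks as SIF or GraphML; models,
combinations and reports as JSON; run configuration as YAML.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .calibration import HillFit
from .fsc_search import ODC, SearchConfig
from .oacd import BLOCK_CENTER, BLOCK_THREE, BLOCK_TWO, DesignMatrix
from .response_model import SurfaceModel
from .synthetic_data import DOSE_PREFIX, REPLICATE, RUN_ID, VIABILITY


class FormatError(ValueError):
    """Raised for malformed input files; carries line context where known."""


# ---------------------------------------------------------------------------
# Response tables
# ---------------------------------------------------------------------------


def read_response_csv(path) -> pd.DataFrame:
    """Read and validate a response table (run_id, dose_*, replicate, viability).

    Malformed values are reported with their 1-based file line numbers
    (line 1 is the header).
    """
    path = Path(path)
    table = pd.read_csv(path)
    required = [RUN_ID, REPLICATE, VIABILITY]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    dose_cols = [c for c in table.columns if c.startswith(DOSE_PREFIX)]
    if not dose_cols:
        raise FormatError(f"{path}: no dose_<drug> columns found")
    problems = []
    for col in dose_cols + [VIABILITY]:
        numeric = pd.to_numeric(table[col], errors="coerce")
        for idx in table.index[numeric.isna()]:
            problems.append(f"line {idx + 2}: non-numeric {col}={table.at[idx, col]!r}")
        table[col] = numeric
    for col in dose_cols:
        for idx in table.index[table[col] < 0]:
            problems.append(f"line {idx + 2}: negative dose {col}={table.at[idx, col]}")
    if problems:
        raise FormatError(f"{path}: " + "; ".join(problems))
    return table


def write_response_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Designs and dosing plans
# ---------------------------------------------------------------------------


def write_design_csv(design: DesignMatrix, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design_csv(path) -> DesignMatrix:
    frame = pd.read_csv(path)
    for col in (RUN_ID, "block"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    bad = set(frame["block"]) - {BLOCK_TWO, BLOCK_THREE, BLOCK_CENTER}
    if bad:
        raise FormatError(f"{path}: unknown block label(s): {sorted(bad)}")
    factors = [c for c in frame.columns if c not in (RUN_ID, "block")]
    coded = frame[factors].astype(int)
    return DesignMatrix(coded=coded, block=frame["block"])


# ---------------------------------------------------------------------------
# Calibration reports
# ---------------------------------------------------------------------------


def write_fit_report(fits: dict[str, HillFit], path_csv, path_json=None) -> None:
    rows = [{"drug": d, **asdict(f)} for d, f in sorted(fits.items())]
    pd.DataFrame(rows).to_csv(path_csv, index=False)
    if path_json is not None:
        Path(path_json).write_text(json.dumps(rows, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Phosphoproteomics tables
# ---------------------------------------------------------------------------


def read_counts_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("peptide_id", "protein", "site"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return table.set_index("peptide_id")


def write_counts_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_annotations_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("kinase", "loop_start", "loop_end"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return table


def read_relations_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("kinase", "substrate", "site", "evidence"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    bad = set(table["evidence"]) - {"PSP", "NWK"}
    if bad:
        raise FormatError(f"{path}: unknown evidence class(es): {sorted(bad)}")
    return table


def read_dtm_csv(path):
    """Drug-target matrix CSV: columns drug, dose, then one column per kinase."""
    from .target_gap import DrugTargetMatrix

    table = pd.read_csv(path)
    for col in ("drug", "dose"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    doses = dict(zip(table["drug"], table["dose"].astype(float)))
    inhibition = table.drop(columns=["dose"]).set_index("drug")
    return DrugTargetMatrix(inhibition=inhibition.astype(float), doses=doses)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def write_network(graph: nx.Graph, fmt: str, path) -> None:
    """Write a kinase-substrate network as SIF or GraphML.

    SIF records are ``source <evidence> target``; GraphML carries the node
    INKA-score attributes and round-trips through networkx.
    """
    path = Path(path)
    if fmt == "SIF":
        lines = [
            f"{u}\t{d.get('evidence', 'pp')}\t{v}"
            for u, v, d in sorted(graph.edges(data=True))
        ]
        isolated = sorted(n for n in graph.nodes if graph.degree(n) == 0)
        lines += [str(n) for n in isolated]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "GraphML":
        nx.write_graphml(graph, path)
    else:
        raise FormatError(f"unknown network format {fmt!r}; use SIF or GraphML")


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# Models and combinations
# ---------------------------------------------------------------------------


def write_model_json(model: SurfaceModel, path) -> None:
    payload = {
        "factors": list(model.factors),
        "retained": list(model.retained),
        "coefficients": {t: round(model.beta(t), 12) for t in model.retained},
        "p_values": {t: round(float(model.pvalues[t]), 12) for t in model.retained},
        "r_squared": round(model.r2, 12),
        "response": "viability",
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_coefficient_csv(model: SurfaceModel, path) -> None:
    """Coefficient table with a panel per term class (linear, interaction,
    quadratic), mirroring how surface-model coefficients are reported."""
    rows = []
    for t in model.retained:
        if t == "Intercept":
            panel = "intercept"
        elif ":" in t:
            panel = "interaction"
        elif t.endswith("^2"):
            panel = "quadratic"
        else:
            panel = "linear"
        rows.append(
            {
                "panel": panel,
                "term": t,
                "coefficient": model.beta(t),
                "se": float(model.se[t]),
                "p_value": float(model.pvalues[t]),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_odc_json(odc: ODC, path) -> None:
    Path(path).write_text(json.dumps(odc.to_dict(), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Structured run configuration; the source of truth for every stage.

    Round-trips losslessly through YAML; every stochastic stage derives its
    seed from ``seed``.
    """

    seed: int = 0
    search: SearchConfig = field(default_factory=SearchConfig)
    coverage_threshold: float = 0.5
    top_n: int = 20
    noise_sd: float = 0.05

    def to_dict(self) -> dict:
        d = asdict(self)
        d["search"]["schedule"] = list(self.search.schedule)
        return d


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    search_raw = raw.pop("search", {})
    if "schedule" in search_raw:
        search_raw["schedule"] = tuple(search_raw["schedule"])
    return RunConfig(search=SearchConfig(**search_raw), **raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
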