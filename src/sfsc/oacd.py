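"""Orthogonal-array composite designs (OACD).

An OACD stacks a two-level regular fraction (levels -1/+1), a strength-2
three-level orthogonal array (levels -1/0/+1), and centre runs, so that the
full second-order model — intercept, linear, pairwise-interaction, and
quadratic terms — is estimable from a modest number of runs.  Coded levels
follow the screening convention: -1 = drug absent, 0 = half the anchor dose,
+1 = the anchor dose (typically the per-drug IC20 from calibration).

The two-level fractions are built from generator words with the resolution
computed from the defining relation; the three-level arrays come from a
small built-in catalogue (9-, 18- and 27-run arrays) verified to strength 2
by exhaustive pair counting in the test suite.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import RUN_ID, dose_col

FACTOR_LETTERS = "ABCDEFGHJKLMN"  # I skipped: it denotes the identity word
BLOCK_TWO = "two_level"
BLOCK_THREE = "three_level"
BLOCK_CENTER = "center"

#: catalogued strength-2 three-level arrays, by canonical name.
OA_CATALOG = ("OA(9,3^4)", "OA(18,3^7)", "OA(27,3^13)")
_OA_COLUMNS = {"OA(9,3^4)": 4, "OA(18,3^7)": 7, "OA(27,3^13)": 13}

# Composite-design presets: generator words for the two-level fraction and
# the three-level array to pair it with.  Each preset passes full-rank
# quadratic estimability (verified by test); the 7- and 10-factor fractions
# carry 32 and 64 runs because the 36- and 66-term quadratic models need at
# least that many distinct runs alongside the catalogued arrays.
PRESETS: dict[int, dict] = {
    4: {"generators": ("D=ABC",), "oa": "OA(9,3^4)"},
    7: {"generators": ("F=ABCD", "G=ABDE"), "oa": "OA(18,3^7)"},
    10: {"generators": ("G=ABC", "H=ABD", "J=ADE", "K=CEF"), "oa": "OA(27,3^13)"},
}


class DesignError(ValueError):
    """Raised for invalid or inadmissible design constructions."""


@dataclass
class DesignMatrix:
    """Coded-level run matrix with per-run block provenance."""

    coded: pd.DataFrame  # runs x factors, values in {-1, 0, +1}
    block: pd.Series  # per-run block label

    def __post_init__(self) -> None:
        vals = self.coded.to_numpy()
        if not np.isin(vals, (-1, 0, 1)).all():
            raise DesignError("coded levels must be in {-1, 0, +1}")
        if len(self.block) != len(self.coded):
            raise DesignError("block labels must match the run count")
        two = self.coded[self.block.to_numpy() == BLOCK_TWO].to_numpy()
        if two.size and (two == 0).any():
            raise DesignError("two-level block may not contain 0 levels")

    @property
    def factors(self) -> list[str]:
        return list(self.coded.columns)

    @property
    def n_runs(self) -> int:
        return len(self.coded)

    def rename_factors(self, names: list[str]) -> "DesignMatrix":
        if len(names) != len(self.coded.columns):
            raise DesignError("need one name per factor")
        coded = self.coded.copy()
        coded.columns = list(names)
        return DesignMatrix(coded=coded, block=self.block.copy())

    def to_frame(self) -> pd.DataFrame:
        out = self.coded.copy()
        out.insert(0, RUN_ID, np.arange(len(out)))
        out["block"] = self.block.to_numpy()
        return out


# ---------------------------------------------------------------------------
# Two-level regular fractions
# ---------------------------------------------------------------------------


def _word_product(*words: str) -> str:
    letters: set[str] = set()
    for w in words:
        letters ^= set(w)
    return "".join(sorted(letters))


def _defining_relation(gen_words: list[str]) -> list[str]:
    words = []
    for r in range(1, len(gen_words) + 1):
        for sub in itertools.combinations(gen_words, r):
            words.append(_word_product(*sub))
    return words


def two_level_fraction(k: int, generators: tuple[str, ...] = ()) -> pd.DataFrame:
    """Regular 2^(k-g) fraction at levels {-1, +1} from generator words.

    Generators are written ``"D=ABC"``: the generated factor is the product
    of base-factor columns.  The resolution is computed from the closure of
    the defining relation and attached as ``.attrs["resolution"]``; designs
    of resolution below III (aliased main effects) are rejected.
    """
    g = len(generators)
    n_base = k - g
    if n_base < 1 or k > len(FACTOR_LETTERS):
        raise DesignError(f"unsupported factor count k={k} with {g} generators")
    letters = FACTOR_LETTERS[:k]
    base = letters[:n_base]
    gen_words = []
    seen_left = set(base)
    for gen in generators:
        try:
            left, right = gen.split("=")
        except ValueError as exc:
            raise DesignError(f"malformed generator {gen!r}") from exc
        if left in seen_left or left not in letters:
            raise DesignError(f"generator {gen!r} redefines or misnames a factor")
        if not right or any(ch not in base for ch in right):
            raise DesignError(f"generator {gen!r} must reference base factors only")
        seen_left.add(left)
        gen_words.append(_word_product(left, right))
    rows = np.array(list(itertools.product((-1, 1), repeat=n_base)), dtype=int)
    cols = {base[i]: rows[:, i] for i in range(n_base)}
    for gen in generators:
        left, right = gen.split("=")
        col = np.ones(len(rows), dtype=int)
        for ch in right:
            col = col * cols[ch]
        cols[left] = col
    if gen_words:
        relation = _defining_relation(gen_words)
        resolution = min(len(w) for w in relation)
        if resolution < 3:
            bad = min((w for w in relation if len(w) < 3), key=len)
            raise DesignError(
                f"resolution {resolution} design: main effects aliased ({bad!r} "
                "in the defining relation)"
            )
    else:
        resolution = np.inf
    frame = pd.DataFrame({l: cols[l] for l in letters})
    frame.attrs["resolution"] = resolution
    return frame


# ---------------------------------------------------------------------------
# Three-level orthogonal arrays
# ---------------------------------------------------------------------------


def _oa_linear(n_pow: int, points: list[tuple[int, ...]]) -> np.ndarray:
    """Strength-2 OA from GF(3) linear forms: rows are GF(3)^n_pow, one
    column per projective direction."""
    rows = np.array(list(itertools.product(range(3), repeat=n_pow)), dtype=int)
    return np.column_stack([(rows @ np.array(p)) % 3 for p in points])


# one representative per point of PG(2,3): 13 pairwise non-proportional
# directions in GF(3)^3 -> the saturated 27-run strength-2 array.
_PG23 = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 2, 0), (1, 0, 1),
         (1, 0, 2), (0, 1, 1), (0, 1, 2), (1, 1, 1), (1, 1, 2), (1, 2, 1),
         (1, 2, 2)]

def _l18() -> np.ndarray:
    # the classical 18-run array (three-level part of the mixed 18-run
    # design); strength 2: every level pair appears exactly twice per
    # column pair (verified exhaustively in the tests).
    packed = [
        "1111111", "1222222", "1333333",
        "2112233", "2223311", "2331122",
        "3121323", "3232131", "3313212",
        "1133221", "1211332", "1322113",
        "2123132", "2231213", "2312321",
        "3132312", "3213123", "3321231",
    ]
    return np.array([[int(c) for c in row] for row in packed], dtype=int) - 1


def _oa_array(name: str) -> np.ndarray:
    if name == "OA(9,3^4)":
        return _oa_linear(2, [(1, 0), (0, 1), (1, 1), (1, 2)])
    if name == "OA(18,3^7)":
        return _l18()
    if name == "OA(27,3^13)":
        return _oa_linear(3, _PG23)
    raise DesignError(f"unknown orthogonal array {name!r}; catalogue: {OA_CATALOG}")


def three_level_oa(catalog: str, k: int) -> pd.DataFrame:
    """First ``k`` columns of a catalogued strength-2 array, coded -1/0/+1.

    Restricting to a column subset preserves strength 2 (the property is
    defined per column pair); the test suite verifies this by exhaustive
    pair counting rather than assuming it.
    """
    n_cols = _OA_COLUMNS.get(catalog)
    if n_cols is None:
        raise DesignError(f"unknown orthogonal array {catalog!r}; catalogue: {OA_CATALOG}")
    if k < 1:
        raise DesignError("need at least one factor")
    if k > n_cols:
        sufficient = [n for n in OA_CATALOG if _OA_COLUMNS[n] >= k]
        if not sufficient:
            raise DesignError(f"no catalogued array has {k} columns")
        raise DesignError(
            f"{catalog} has only {n_cols} columns; smallest sufficient array "
            f"is {sufficient[0]}"
        )
    arr = _oa_array(catalog)[:, :k] - 1  # {0,1,2} -> {-1,0,+1}
    return pd.DataFrame(arr, columns=list(FACTOR_LETTERS[:k]))


# ---------------------------------------------------------------------------
# Composition, estimability, decoding
# ---------------------------------------------------------------------------


def compose_oacd(two_level: pd.DataFrame, three_level: pd.DataFrame,
                 center_runs: int = 1) -> DesignMatrix:
    """Stack the blocks (plus all-zero centre runs) into one design."""
    if two_level.shape[1] != three_level.shape[1]:
        raise DesignError(
            f"factor mismatch: two-level block has {two_level.shape[1]} "
            f"factors, three-level block {three_level.shape[1]}"
        )
    if center_runs < 0:
        raise DesignError("center_runs must be >= 0")
    k = two_level.shape[1]
    names = list(two_level.columns)
    blocks = [two_level.to_numpy(), three_level.to_numpy()]
    labels = [BLOCK_TWO] * len(two_level) + [BLOCK_THREE] * len(three_level)
    if center_runs:
        blocks.append(np.zeros((center_runs, k), dtype=int))
        labels += [BLOCK_CENTER] * center_runs
    coded = pd.DataFrame(np.vstack(blocks).astype(int), columns=names)
    return DesignMatrix(coded=coded, block=pd.Series(labels, name="block"))


def quadratic_terms(factors: list[str]) -> list[str]:
    """Term names of the full second-order model, in canonical order."""
    terms = ["Intercept"] + list(factors)
    terms += [f"{a}:{b}" for a, b in itertools.combinations(factors, 2)]
    terms += [f"{f}^2" for f in factors]
    return terms


def model_matrix(coded: pd.DataFrame, terms: list[str] | None = None) -> pd.DataFrame:
    """Model matrix of the quadratic response-surface model on coded levels."""
    factors = list(coded.columns)
    if terms is None:
        terms = quadratic_terms(factors)
    cols = {}
    for t in terms:
        if t == "Intercept":
            cols[t] = np.ones(len(coded))
        elif ":" in t:
            a, b = t.split(":")
            cols[t] = coded[a].to_numpy(float) * coded[b].to_numpy(float)
        elif t.endswith("^2"):
            cols[t] = coded[t[:-2]].to_numpy(float) ** 2
        else:
            cols[t] = coded[t].to_numpy(float)
    return pd.DataFrame(cols, index=coded.index)


@dataclass(frozen=True)
class EstimabilityReport:
    n_runs: int
    n_terms: int
    rank: int
    condition_number: float
    inestimable: tuple[str, ...]

    @property
    def full_rank(self) -> bool:
        return self.rank == self.n_terms


def check_estimability(design: DesignMatrix,
                       terms: list[str] | None = None) -> EstimabilityReport:
    """Rank and conditioning of the quadratic model matrix on this design.

    When rank-deficient, the report names terms outside a maximal estimable
    set (via QR with column pivoting).
    """
    if design.n_runs < 1:
        raise DesignError("design must contain at least one run")
    X = model_matrix(design.coded, terms)
    arr = X.to_numpy()
    rank = int(np.linalg.matrix_rank(arr))
    cond = float(np.linalg.cond(arr))
    inestimable: tuple[str, ...] = ()
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(arr, pivoting=True, mode="economic")
        keep = set(piv[:rank])
        inestimable = tuple(X.columns[i] for i in range(X.shape[1]) if i not in keep)
    return EstimabilityReport(
        n_runs=len(arr), n_terms=X.shape[1], rank=rank,
        condition_number=cond, inestimable=inestimable,
    )


def preset_design(k: int, center_runs: int = 1) -> DesignMatrix:
    """Shipped OACD preset for ``k`` factors (4, 7 or 10)."""
    if k not in PRESETS:
        raise DesignError(f"no preset for k={k}; presets exist for {sorted(PRESETS)}")
    spec = PRESETS[k]
    tl = two_level_fraction(k, spec["generators"])
    th = three_level_oa(spec["oa"], k)
    return compose_oacd(tl, th, center_runs=center_runs)


def decode_doses(design: DesignMatrix, anchors: dict[str, float]) -> pd.DataFrame:
    """Translate coded levels into a dosing plan in concentration units.

    Level -1 means the drug is absent, 0 means half the anchor dose, +1 the
    anchor dose (per-drug IC20 in the screening workflow).
    """
    missing = [f for f in design.factors if f not in anchors]
    if missing:
        raise DesignError(f"missing dose anchors for factors: {missing}")
    plan = pd.DataFrame({RUN_ID: np.arange(design.n_runs)})
    for f in design.factors:
        level = design.coded[f].to_numpy(float)
        plan[dose_col(f)] = (level + 1.0) / 2.0 * anchors[f]
    return plan


def encode_doses(plan: pd.DataFrame, anchors: dict[str, float],
                 factors: list[str]) -> pd.DataFrame:
    """Inverse of :func:`decode_doses` on exact half/full anchor doses."""
    coded = {}
    for f in factors:
        dose = plan[dose_col(f)].to_numpy(float)
        level = 2.0 * dose / anchors[f] - 1.0
        rounded = np.rint(level).astype(int)
        if not np.allclose(level, rounded, atol=1e-9):
            raise DesignError(f"doses for {f} are not on the coded grid")
        coded[f] = rounded
    return pd.DataFrame(coded)
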