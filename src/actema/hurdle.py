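"""Two-part (hurdle) model grid over determinants, intensities and windows.

For every cell of the default grid — 7 momentary determinants x 3
activity intensities (LPA, MVPA, TPA) x 4 prospective windows (15, 30,
60, 120 min), i.e. 84 models — the pipeline fits:

1. a logistic random-intercept GLMM on the dichotomised outcome (any
   activity vs none), reported as an odds ratio (OR) per 1-unit
   within-person increase of the determinant; and
2. on the rows with at least one active minute, Gaussian / Poisson /
   negative-binomial random-intercept candidates, choosing the family
   with the lowest AIC, reported as expB (the exponentiated count
   coefficient).

Both parts carry the hybrid within/between decomposition; only the
within-person effect is surfaced in the main report.  The count part
fits an untruncated NB to the positive subset by default, mirroring the
classical two-step hurdle description; ``truncated=True`` swaps in the
zero-truncated NB likelihood as a sensitivity analysis.  No multiple-
testing correction is applied across cells (alpha < .05 throughout); a
Benjamini-Hochberg column is emitted as supplementary output only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glmm import (EffectSummary, MixedGLM, select_family, summarize_effect)

__all__ = [
    "DETERMINANT_COLUMNS",
    "ModelGridSpec",
    "HurdleCellResult",
    "HurdleModel",
    "HurdleResults",
    "enumerate_models",
    "fit_hurdle_cell",
    "run_grid",
    "render_results",
    "sign_map",
    "format_p",
    "format_effect",
    "item_descriptives",
]

#: determinant name -> EMA item column
DETERMINANT_COLUMNS = {
    "relaxation": "relax",
    "satisfaction": "satisf",
    "irritation": "irrit",
    "feeling_down": "down",
    "fatigue": "fatigue",
    "intention": "intention",
    "self_efficacy": "selfeff",
}

DEFAULT_INTENSITIES = ("lpa", "mvpa", "tpa")
DEFAULT_COUNT_CANDIDATES = ("gaussian", "poisson", "negbin")


@dataclass(frozen=True)
class ModelGridSpec:
    """The model grid: determinants x intensities x windows."""

    determinants: tuple = tuple(DETERMINANT_COLUMNS)
    intensities: tuple = DEFAULT_INTENSITIES
    windows: tuple = (15, 30, 60, 120)

    def __post_init__(self):
        if not (self.determinants and self.intensities and self.windows):
            raise ValueError("empty grid dimension")

    @property
    def size(self) -> int:
        return len(self.determinants) * len(self.intensities) * len(self.windows)


def enumerate_models(grid: ModelGridSpec):
    """Deterministic cell order: determinant-major, then intensity, then window."""
    return [
        (d, i, w)
        for d in grid.determinants
        for i in grid.intensities
        for w in grid.windows
    ]


@dataclass
class HurdleCellResult:
    """Paired logistic + count effect summaries for one grid cell."""

    determinant: str
    intensity: str
    window: int
    logistic: EffectSummary | None = None
    logistic_n: int = 0
    logistic_converged: bool = False
    count: EffectSummary | None = None
    count_family: str | None = None
    count_n: int = 0
    count_converged: bool = False
    warnings: list = field(default_factory=list)

    @property
    def cell_id(self) -> str:
        return f"{self.determinant}/{self.intensity}/{self.window}"

    def to_dict(self) -> dict:
        d = {
            "determinant": self.determinant,
            "intensity": self.intensity,
            "window": self.window,
            "logistic_n": self.logistic_n,
            "count_family": self.count_family,
            "count_n": self.count_n,
            "warnings": list(self.warnings),
        }
        for part, eff in (("or", self.logistic), ("expb", self.count)):
            if eff is None:
                d.update({part: None, f"{part}_lo": None, f"{part}_hi": None,
                          f"{part}_p": None})
            else:
                d.update({part: eff.point, f"{part}_lo": eff.ci_low,
                          f"{part}_hi": eff.ci_high, f"{part}_p": eff.p})
        return d


def fit_hurdle_cell(
    dataset: pd.DataFrame,
    cell,
    group: str = "participant_id",
    truncated: bool = False,
    min_positive_rows: int = 50,
    min_positive_clusters: int = 10,
    n_quad: int = 15,
) -> HurdleCellResult:
    """Fit both hurdle parts for one (determinant, intensity, window) cell."""
    determinant, intensity, window = cell
    item = DETERMINANT_COLUMNS.get(determinant, determinant)
    out = HurdleCellResult(determinant, intensity, window)
    ycol = f"{intensity}_{window}"
    anycol = f"any_{intensity}_{window}"
    if ycol not in dataset.columns:
        out.warnings.append(f"outcome column {ycol} absent")
        return out

    rows = dataset[[group, item, ycol, anycol]].dropna()
    if rows.empty:
        out.warnings.append("no complete rows")
        return out

    # part 1: any activity vs none
    if rows[anycol].nunique() < 2:
        out.warnings.append("degenerate dichotomous outcome (all 0 or all 1)")
    else:
        try:
            m = MixedGLM.from_dataframe(rows, anycol, item, group,
                                        family="binomial", n_quad=n_quad)
            res = m.fit()
            out.logistic = summarize_effect(res, "within", scale="OR")
            out.logistic_n = int(res.nobs)
            out.logistic_converged = bool(res.converged)
            if not res.converged:
                out.warnings.append("logistic part did not converge")
        except Exception as exc:  # separation and friends: isolate the cell
            out.warnings.append(f"logistic part failed: {exc}")
    if out.logistic_n == 0:
        out.logistic_n = int(len(rows))

    # part 2: amount among the active
    pos = rows[rows[ycol] >= 1]
    if (len(pos) < min_positive_rows
            or pos[group].nunique() < min_positive_clusters):
        out.warnings.append(
            f"positive subset too small for the count part "
            f"({len(pos)} rows, {pos[group].nunique()} clusters)")
        return out
    candidates = list(DEFAULT_COUNT_CANDIDATES)
    if truncated:
        candidates = [("truncnegbin" if c == "negbin" else c)
                      for c in candidates]
    fits = {}
    for fam in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits[fam] = MixedGLM.from_dataframe(
                    pos, ycol, item, group, family=fam, n_quad=n_quad).fit()
        except Exception as exc:
            out.warnings.append(f"{fam} candidate failed: {exc}")
    if not fits:
        return out
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best = select_family(fits)
    except RuntimeError as exc:
        out.warnings.append(str(exc))
        return out
    out.count = summarize_effect(best, "within", scale="expB")
    out.count_family = best.family
    out.count_n = int(best.nobs)
    out.count_converged = bool(best.converged)
    return out


def run_grid(dataset: pd.DataFrame, grid: ModelGridSpec | None = None,
             **options) -> list:
    """Fit every grid cell independently; failures never abort the run."""
    if grid is None:
        grid = ModelGridSpec()
    results = []
    for cell in enumerate_models(grid):
        try:
            results.append(fit_hurdle_cell(dataset, cell, **options))
        except Exception as exc:  # pragma: no cover - belt and braces
            r = HurdleCellResult(*cell)
            r.warnings.append(f"cell failed: {exc}")
            results.append(r)
    return results


# ---------------------------------------------------------------------------
# Model/Results wrappers
# ---------------------------------------------------------------------------


class HurdleModel:
    """The full hurdle-model grid on a linked-observation dataset.

    ``HurdleModel(dataset).fit()`` fits all cells and returns a
    :class:`HurdleResults`.
    """

    def __init__(self, dataset: pd.DataFrame, grid: ModelGridSpec | None = None,
                 group: str = "participant_id", truncated: bool = False,
                 min_positive_rows: int = 50, min_positive_clusters: int = 10,
                 n_quad: int = 15):
        self.dataset = dataset
        self.grid = grid if grid is not None else ModelGridSpec()
        self.options = dict(group=group, truncated=truncated,
                            min_positive_rows=min_positive_rows,
                            min_positive_clusters=min_positive_clusters,
                            n_quad=n_quad)

    def fit(self) -> "HurdleResults":
        cells = run_grid(self.dataset, self.grid, **self.options)
        return HurdleResults(self, cells)


class HurdleResults:
    """Results of a fitted grid; renders the report tables."""

    def __init__(self, model: HurdleModel, cells: list):
        self.model = model
        self.cells = cells

    def to_table(self) -> pd.DataFrame:
        return render_results(self.cells)

    def sign_map(self, part: str = "logistic") -> pd.DataFrame:
        return sign_map(self.cells, part=part)

    def to_records(self) -> list:
        return [c.to_dict() for c in self.cells]

    def summary(self) -> str:
        tab = self.to_table()
        n_sig_or = sum(1 for c in self.cells
                       if c.logistic is not None and c.logistic.significant)
        n_sig_cnt = sum(1 for c in self.cells
                        if c.count is not None and c.count.significant)
        head = (f"Hurdle model grid: {len(self.cells)} cells "
                f"({n_sig_or} significant logistic, "
                f"{n_sig_cnt} significant count effects at alpha=.05)")
        return head + "\n" + tab.to_string(index=False)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def format_p(p: float | None) -> str:
    """P-value house style: '<.001', '.006', '.03'."""
    if p is None or not np.isfinite(p):
        return ""
    if p < 0.001:
        return "<.001"
    if p < 0.01:
        return f"{p:.3f}".lstrip("0")
    return f"{p:.2f}".lstrip("0")


def format_effect(eff: EffectSummary | None) -> str:
    """'1.33 (1.26-1.41)' style effect + CI."""
    if eff is None:
        return ""
    return f"{eff.point:.2f} ({eff.ci_low:.2f}-{eff.ci_high:.2f})"


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (supplementary column)."""
    from statsmodels.stats.multitest import multipletests

    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def render_results(cells: list) -> pd.DataFrame:
    """Results table: one row per cell with OR (95% CI), P, expB (95% CI), P."""
    rows = []
    for c in cells:
        rows.append({
            "determinant": c.determinant,
            "intensity": c.intensity.upper(),
            "window": c.window,
            "OR (95% CI)": format_effect(c.logistic),
            "P value": format_p(c.logistic.p if c.logistic else None),
            "count family": c.count_family or "",
            "expB (95% CI)": format_effect(c.count),
            "P value (count)": format_p(c.count.p if c.count else None),
            "_or_p": c.logistic.p if c.logistic else np.nan,
            "_expb_p": c.count.p if c.count else np.nan,
        })
    df = pd.DataFrame(rows)
    df["P BH (OR)"] = _bh_adjust(df["_or_p"].to_numpy(dtype=float))
    df["P BH (expB)"] = _bh_adjust(df["_expb_p"].to_numpy(dtype=float))
    return df.drop(columns=["_or_p", "_expb_p"])


def sign_map(cells: list, part: str = "logistic", alpha: float = 0.05
             ) -> pd.DataFrame:
    """Direction map: '+'/'-' for significant cells, blank otherwise."""
    recs = {}
    for c in cells:
        eff = c.logistic if part == "logistic" else c.count
        mark = ""
        if eff is not None and eff.p < alpha:
            mark = "+" if eff.coef > 0 else "-"
        recs.setdefault(c.determinant, {})[(c.intensity.upper(), c.window)] = mark
    df = pd.DataFrame.from_dict(recs, orient="index")
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df.sort_index(axis=1)


def item_descriptives(dataset: pd.DataFrame, items=None) -> pd.DataFrame:
    """Mean (SD), median and quartiles per EMA item, over linked observations."""
    if items is None:
        items = [c for c in DETERMINANT_COLUMNS.values() if c in dataset.columns]
    rows = []
    for col in items:
        x = dataset[col].dropna()
        rows.append({
            "item": col,
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
            "median": float(x.median()),
            "q1": float(x.quantile(0.25)),
            "q3": float(x.quantile(0.75)),
        })
    return pd.DataFrame(rows)
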