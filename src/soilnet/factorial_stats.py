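"""Factorial F-tests, correlation screens and agronomic efficiency.

The ANOVA is restricted to balanced complete factorial designs (the study
layout is 3 x 3 x 2 with 3 replicates), where all sums-of-squares types
coincide; unbalanced input is rejected rather than silently approximated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import SampleDesign

__all__ = [
    "AnovaRow",
    "AnovaTable",
    "CorrelationResult",
    "CorrelationScreen",
    "factorial_anova",
    "correlation_screen",
    "agronomic_efficiency",
]

_FACTORS = ("ismb", "fertilizer", "habitat")


@dataclass(frozen=True)
class AnovaRow:
    term: str
    df: int
    f: float
    p: float


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    df_residual: int
    ss: dict[str, float]
    ss_residual: float

    def __getitem__(self, term: str) -> AnovaRow:
        for row in self.rows:
            if row.term == term:
                return row
        raise KeyError(term)

    @property
    def terms(self) -> list[str]:
        return [row.term for row in self.rows]


def _check_balanced(design: SampleDesign, samples: list[str],
                    factors=_FACTORS) -> None:
    levels = {f: sorted(set(design.factor(f, samples))) for f in factors}
    cells: dict[tuple, int] = {}
    for s in samples:
        info = design[s]
        cells[tuple(getattr(info, f) for f in factors)] = (
            cells.get(tuple(getattr(info, f) for f in factors), 0) + 1
        )
    counts = set()
    for combo in product(*(levels[f] for f in factors)):
        n = cells.get(combo, 0)
        if n == 0:
            raise ValueError(f"empty design cell {dict(zip(factors, combo))}")
        counts.add(n)
    if len(counts) != 1:
        raise ValueError(f"unbalanced design: cell sizes {sorted(counts)}")
    if counts.pop() < 2:
        raise ValueError("need at least 2 replicates per cell")


def factorial_anova(response, design: SampleDesign,
                    factors=_FACTORS) -> AnovaTable:
    """Full-factorial ANOVA (main effects plus all interactions).

    ``response`` maps sample id -> value (or is an array aligned with the
    non-native samples of the design).  Native samples are excluded: they do
    not belong to the factorial layout.
    """
    samples = design.non_native_samples()
    if isinstance(response, dict):
        missing = [s for s in samples if s not in response]
        if missing:
            raise ValueError(f"response missing for samples {missing[:5]}")
        y = np.array([float(response[s]) for s in samples])
    else:
        y = np.asarray(response, dtype=float)
        if y.shape != (len(samples),):
            raise ValueError("response length must match non-native samples")
    _check_balanced(design, samples, factors)

    frame = pd.DataFrame({f: design.factor(f, samples) for f in factors})
    frame["y"] = y

    terms: list[tuple[str, ...]] = []
    for k in range(1, len(factors) + 1):
        from itertools import combinations

        terms.extend(combinations(factors, k))

    if np.ptp(y) < 1e-12 * max(1.0, abs(y).max()):
        # constant response: no variance to attribute
        rows = []
        n_levels = {f: len(set(frame[f])) for f in factors}
        for term in terms:
            df = int(np.prod([n_levels[f] - 1 for f in term]))
            rows.append(AnovaRow(":".join(term), df, 0.0, 1.0))
        df_res = len(y) - sum(r.df for r in rows) - 1
        return AnovaTable(rows, df_res, {r.term: 0.0 for r in rows}, 0.0)

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    formula = "y ~ " + " * ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=frame).fit()
    table = sm.stats.anova_lm(fit, typ=1)

    def _label(term: tuple[str, ...]) -> str:
        return ":".join(f"C({f})" for f in term)

    rows = []
    ss = {}
    for term in terms:
        row = table.loc[_label(term)]
        name = ":".join(term)
        rows.append(AnovaRow(name, int(row["df"]), float(row["F"]), float(row["PR(>F)"])))
        ss[name] = float(row["sum_sq"])
    residual = table.loc["Residual"]
    return AnovaTable(rows, int(residual["df"]), ss, float(residual["sum_sq"]))


@dataclass(frozen=True)
class CorrelationResult:
    a: str
    b: str
    coefficient: float
    p: float
    n: int
    slope: float | None  # Pearson only
    missing: bool = False


@dataclass
class CorrelationScreen:
    method: str
    results: list[CorrelationResult]

    def get(self, a: str, b: str) -> CorrelationResult:
        for r in self.results:
            if {r.a, r.b} == {a, b}:
                return r
        raise KeyError((a, b))


def correlation_screen(x_table: dict, y_table: dict,
                       method: str = "pearson") -> CorrelationScreen:
    """All-pairs correlation between two named variable sets.

    Each table maps variable name -> 1-D array; arrays must be paired
    (same observation order).  Constant variables yield missing results.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson or spearman")
    results = []
    for name_x, x in x_table.items():
        x = np.asarray(x, dtype=float)
        for name_y, y in y_table.items():
            y = np.asarray(y, dtype=float)
            if x.shape != y.shape or x.ndim != 1:
                raise ValueError(f"unpaired variables {name_x!r}/{name_y!r}")
            if x.size < 4:
                raise ValueError("need at least 4 paired observations")
            if np.ptp(x) < 1e-300 or np.ptp(y) < 1e-300:
                results.append(CorrelationResult(name_x, name_y, np.nan, np.nan,
                                                 x.size, None, missing=True))
                continue
            if method == "pearson":
                r, p = stats.pearsonr(x, y)
                slope = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
            else:
                r, p = stats.spearmanr(x, y)
                slope = None
            results.append(CorrelationResult(name_x, name_y, float(r), float(p),
                                             x.size, slope))
    return CorrelationScreen(method, results)


def agronomic_efficiency(yield_fert: float, yield_nofert: float,
                         n_applied: float) -> float:
    """Yield gain over the unfertilized control per unit N applied (kg/kg)."""
    if n_applied <= 0:
        raise ValueError("applied N must be positive")
    return (yield_fert - yield_nofert) / n_applied
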