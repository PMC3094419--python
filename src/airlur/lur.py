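"""Supervised forward-selection land-use regression.

Candidate predictors are organised in four ordered groups — traffic
variables, traffic-related land use, population-density-related land use,
other land use — and, within a group, in families (one conceptual variable
across its buffer radii or distance cutoffs). Selection proceeds group by
group: within each group only the best variant per family (highest
univariate R-squared against the response) is eligible, candidates are
offered in decreasing univariate R-squared order, and a candidate enters
the model only if the adjusted R-squared improves by at least ``delta``
percentage points AND every coefficient in the augmented model keeps its
a-priori expected sign. A-priori variables (the regional background in the
large-area configuration) are entered first and are never removed. After
selection, variables are pruned backward: the highest-p-value variable is
dropped whenever its removal moves the adjusted R-squared by less than
``delta`` points, and the reduced model is preferred.

Effects are reported per interquartile range of the predictor in the
fitting table, which makes coefficients on very different native scales
(vehicle counts, log-metres, land-use fractions) comparable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


# ----------------------------------------------------------------- grouping

GROUP_ORDER = ("traffic", "traffic_landuse", "population_landuse", "other_landuse")

#: expected coefficient sign per family stem; distances enter as log-metres
#: and should reduce concentrations, source-type land uses raise them.
DEFAULT_SIGNS = {
    "traf_buf": +1,
    "heavy_buf": +1,
    "logdist": -1,
    "flow_near": +1,
    "heavy_near": +1,
    "lu_transport": +1,
    "lu_port": +1,
    "lu_industry": +1,
    "lu_residential": +1,
    "pop": +1,
    "lu_urban_green": -1,
    "lu_green": -1,
    "lu_forest": -1,
    "lu_agriculture": -1,
    "lu_water": -1,
    "background_no2": +1,
}

_RADIUS_RE = re.compile(r"_(\d+)$")


@dataclass
class VariableGroupPlan:
    """Maps predictor columns to (group, family, expected sign).

    ``families`` maps a family id to its ordered member columns; ``groups``
    maps each of the four group names to its family ids; ``signs`` maps a
    family to +1/-1.
    """

    groups: dict[str, list[str]]
    families: dict[str, list[str]]
    signs: dict[str, int]

    def sign_of(self, column: str) -> int:
        return self.signs[self.family_of(column)]

    def family_of(self, column: str) -> str:
        for fam, cols in self.families.items():
            if column in cols:
                return fam
        raise KeyError(column)


def _family_and_group(column: str) -> tuple[str, str, int]:
    """Classify one predictor column; returns (family, group, sign)."""
    base = _RADIUS_RE.sub("", column)
    if column.startswith(("traf_buf", "heavy_buf")):
        return base, "traffic", +1
    m = re.match(r"(flow_near|heavy_near)_(\w+?)_within_\d+$", column)
    if m:
        return f"{m.group(1)}_{m.group(2)}_within", "traffic", +1
    if column.startswith(("flow_near", "heavy_near")):
        return column, "traffic", +1  # one variant per road class
    if column.startswith("logdist"):
        return column, "traffic", -1
    if column.startswith("pop_"):
        return "pop", "population_landuse", +1
    if column.startswith("lu_"):
        sign = DEFAULT_SIGNS.get(base, +1)
        if base in ("lu_transport", "lu_port"):
            group = "traffic_landuse"
        elif base == "lu_residential":
            group = "population_landuse"
        else:
            group = "other_landuse"
        return base, group, sign
    raise KeyError(f"column {column!r} not covered by the default plan")


def default_plan(columns, sign_overrides: dict[str, int] | None = None) -> VariableGroupPlan:
    """Build the four-group plan for a predictor table's columns.

    Every column must map to exactly one family; ``background_no2`` is
    excluded (it enters a priori, not through selection).
    """
    groups: dict[str, list[str]] = {g: [] for g in GROUP_ORDER}
    families: dict[str, list[str]] = {}
    signs: dict[str, int] = {}
    for col in columns:
        if col == "background_no2":
            continue
        fam, group, sign = _family_and_group(col)
        families.setdefault(fam, []).append(col)
        signs[fam] = sign
        if fam not in groups[group]:
            groups[group].append(fam)
    if sign_overrides:
        signs.update(sign_overrides)
    return VariableGroupPlan(groups=groups, families=families, signs=signs)


# ---------------------------------------------------------------- the model

@dataclass
class LURModel:
    variables: list[str]  # ordered as selected; a-priori first
    a_priori: list[str]
    coefficients: dict[str, float]
    intercept: float
    r2: float
    adj_r2: float
    n: int
    signs: dict[str, int] = field(default_factory=dict)
    iqr: dict[str, float] = field(default_factory=dict)
    trace: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "variables": self.variables,
                "a_priori": self.a_priori,
                "coefficients": self.coefficients,
                "intercept": self.intercept,
                "r2": self.r2,
                "adj_r2": self.adj_r2,
                "n": self.n,
                "signs": self.signs,
                "iqr": self.iqr,
                "trace": self.trace,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "LURModel":
        d = json.loads(text)
        return cls(**d)


def _fit(y: np.ndarray, table: pd.DataFrame, variables: list[str]):
    # has_constant="add" keeps the intercept column even when a predictor is
    # degenerate (constant); OLS falls back to the pseudoinverse then
    X = (
        sm.add_constant(table[variables].to_numpy(float), has_constant="add")
        if variables
        else np.ones((len(y), 1))
    )
    return sm.OLS(np.asarray(y, dtype=float), X).fit()


def _adj_r2(res, n_vars: int) -> float:
    return float(res.rsquared_adj) if n_vars > 0 else 0.0


def univariate_r2(y, x) -> float:
    """Squared Pearson correlation between response and one predictor."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    r = np.corrcoef(y, x)[0, 1]
    return float(r * r)


def select_best_per_family(y, table: pd.DataFrame, family_columns: list[str]) -> str:
    """The family variant with the highest univariate R-squared.

    Ties go to the smaller radius / shorter cutoff (the trailing number in
    the column name), preferring the more local variable.
    """
    def radius_key(col: str) -> float:
        m = _RADIUS_RE.search(col)
        return float(m.group(1)) if m else 0.0

    scored = [(univariate_r2(y, table[c]), c) for c in family_columns]
    best_r2 = max(s for s, _ in scored)
    candidates = [c for s, c in scored if s >= best_r2 - 1e-12]
    return min(candidates, key=radius_key)


def _signs_ok(res, variables: list[str], signs: dict[str, int]) -> bool:
    """All coefficients (skipping the intercept) match their expected sign."""
    coefs = res.params[1:]
    for coef, var in zip(coefs, variables):
        expected = signs.get(var, 0)
        if expected and coef * expected < 0:
            return False
    return True


def _column_signs(plan: VariableGroupPlan, columns, a_priori: list[str]) -> dict[str, int]:
    out = {}
    for c in columns:
        if c in a_priori:
            out[c] = DEFAULT_SIGNS.get(_RADIUS_RE.sub("", c), +1)
        else:
            try:
                out[c] = plan.sign_of(c)
            except KeyError:
                out[c] = 0
    return out


def forward_build(
    y,
    table: pd.DataFrame,
    plan: VariableGroupPlan | None = None,
    a_priori: list[str] | None = None,
    delta: float = 1.0,
    rank_on_residual: bool = False,
) -> LURModel:
    """Run the supervised forward selection and return the fitted model.

    ``delta`` is in percentage points of adjusted R-squared (1.0 means the
    adjusted R-squared must rise by at least 0.01). Candidates rejected once
    are not revisited after later acceptances. With ``rank_on_residual``
    univariate ranking is computed against the response residualised on the
    a-priori variables instead of the raw response.
    """
    y = np.asarray(y, dtype=float)
    a_priori = list(a_priori or [])
    plan = plan or default_plan(table.columns)
    threshold = delta / 100.0

    selected = list(a_priori)
    signs = _column_signs(plan, list(table.columns), a_priori)
    res = _fit(y, table, selected)
    current_adj = _adj_r2(res, len(selected))
    trace: list[dict] = [
        {"step": "a_priori", "variables": list(a_priori), "adj_r2": current_adj}
    ]

    rank_y = y
    if rank_on_residual and a_priori:
        rank_y = y - _fit(y, table, a_priori).fittedvalues

    for group in GROUP_ORDER:
        fams = plan.groups.get(group, [])
        candidates = []
        for fam in fams:
            cols = [c for c in plan.families[fam] if c not in selected]
            if not cols:
                continue
            best = select_best_per_family(rank_y, table, cols)
            candidates.append((univariate_r2(rank_y, table[best]), best, fam))
        candidates.sort(key=lambda t: (-t[0], t[1]))

        for uni_r2, col, fam in candidates:
            if len(selected) + 2 >= len(y):
                trace.append({"step": "skip", "candidate": col, "reason": "n <= p"})
                continue
            trial = selected + [col]
            trial_res = _fit(y, table, trial)
            trial_adj = _adj_r2(trial_res, len(trial))
            gain = trial_adj - current_adj
            sign_ok = _signs_ok(trial_res, trial, signs)
            accept = gain >= threshold and sign_ok
            trace.append(
                {
                    "step": "offer",
                    "group": group,
                    "family": fam,
                    "candidate": col,
                    "univariate_r2": round(uni_r2, 6),
                    "delta_adj_r2": round(gain, 6),
                    "sign_ok": sign_ok,
                    "accepted": accept,
                }
            )
            if accept:
                selected = trial
                res = trial_res
                current_adj = trial_adj

    return _finalize(y, table, selected, a_priori, signs, trace)


def _finalize(y, table, selected, a_priori, signs, trace) -> LURModel:
    res = _fit(y, table, selected)
    coefs = dict(zip(selected, res.params[1:])) if selected else {}
    return LURModel(
        variables=list(selected),
        a_priori=list(a_priori),
        coefficients={k: float(v) for k, v in coefs.items()},
        intercept=float(res.params[0]),
        r2=float(res.rsquared) if selected else 0.0,
        adj_r2=_adj_r2(res, len(selected)),
        n=len(y),
        signs={c: signs.get(c, 0) for c in selected},
        iqr={c: float(np.subtract(*np.percentile(table[c], [75, 25]))) for c in selected},
        trace=trace,
    )


def backward_prune(model: LURModel, y, table: pd.DataFrame, delta: float = 1.0) -> LURModel:
    """Drop high-p-value variables whose removal barely moves adjusted R².

    A-priori variables are never candidates. Variables are examined in
    decreasing p-value order; the first whose removal changes the adjusted
    R-squared by less than ``delta`` percentage points is dropped, then the
    search restarts. The reduced model is preferred.
    """
    y = np.asarray(y, dtype=float)
    threshold = delta / 100.0
    selected = list(model.variables)
    trace = list(model.trace)

    while True:
        removable = [v for v in selected if v not in model.a_priori]
        if not removable:
            break
        res = _fit(y, table, selected)
        adj_full = _adj_r2(res, len(selected))
        pvals = dict(zip(selected, res.pvalues[1:]))
        dropped = False
        for var in sorted(removable, key=lambda v: -pvals[v]):
            reduced = [v for v in selected if v != var]
            adj_red = _adj_r2(_fit(y, table, reduced), len(reduced))
            if abs(adj_full - adj_red) < threshold:
                trace.append(
                    {"step": "prune", "dropped": var, "p_value": float(pvals[var]),
                     "delta_adj_r2": round(adj_red - adj_full, 6)}
                )
                selected = reduced
                dropped = True
                break
        if not dropped:
            break

    return _finalize(y, table, selected, model.a_priori, model.signs | _column_signs(
        default_plan_safe(table.columns), list(table.columns), model.a_priori), trace)


def default_plan_safe(columns) -> VariableGroupPlan:
    """Like :func:`default_plan` but skips columns it cannot classify."""
    ok = []
    for c in columns:
        if c == "background_no2":
            continue
        try:
            _family_and_group(c)
            ok.append(c)
        except KeyError:
            pass
    return default_plan(ok)


def per_iqr_effects(model: LURModel, y, table: pd.DataFrame) -> pd.DataFrame:
    """Per-IQR effect table: coefficient and SE scaled by the predictor IQR.

    A constant predictor (IQR 0) yields a zero effect. The refit on the
    supplied table provides the SEs and p-values.
    """
    res = _fit(np.asarray(y, dtype=float), table, model.variables)
    rows = []
    for i, var in enumerate(model.variables, start=1):
        iqr = float(np.subtract(*np.percentile(table[var], [75, 25])))
        rows.append(
            {
                "variable": var,
                "iqr": iqr,
                "coefficient": float(res.params[i]),
                "effect_per_iqr": float(res.params[i]) * iqr,
                "se_per_iqr": float(res.bse[i]) * iqr,
                "p_value": float(res.pvalues[i]),
            }
        )
    return pd.DataFrame(rows)


def fit_coefficients(y, table: pd.DataFrame, variables: list[str]):
    """Plain OLS refit of a fixed variable set; returns the statsmodels result."""
    return _fit(np.asarray(y, dtype=float), table, list(variables))


def predict(model: LURModel, table: pd.DataFrame) -> np.ndarray:
    """Evaluate the linear model on a predictor table (no truncation)."""
    missing = [v for v in model.variables if v not in table.columns]
    if missing:
        raise KeyError(f"predictor table lacks model variables: {missing}")
    out = np.full(len(table), model.intercept)
    for var in model.variables:
        out = out + model.coefficients[var] * table[var].to_numpy(float)
    return out
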