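"""Test statistics, the minimum-axiom decision rule, and reports.

The decision layer is deliberately thin: compute the scenario's two-sided
test statistic and P-value, then apply the single axiom

    reject H0  iff  P(observed data or more extreme | H0) < alpha.

What the layer *licenses* on rejection is exactly the real alternative —
the negation of the testable null — with the research hypothesis flagged
as merely one disjunct of its DNF.  On failure to reject, the only
statement emitted is that H0 was not rejected; "accept H0" never appears
in any rendered output, because the rejection axiom says nothing about
the complementary case.

Statistics are computed from their textbook formulas with scipy
distributions supplying the tail areas.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hypothesis_framework import (
    ConclusionReport,
    PremisePackage,
    alternative_dnf,
    conclude_with_premises,
    locate_research_hypothesis,
    real_alternative,
    testable_null,
)
from .logic_core import Formula, LogicError
from .nhst_semantics import (
    DEFAULT_UNIVERSE,
    MEANS,
    CauseUniverse,
    Scenario,
    render,
    to_ascii,
)

__all__ = [
    "SampleData",
    "TestResult",
    "Decision",
    "Report",
    "DegenerateDataError",
    "t_test",
    "chi2_test",
    "correlation_test",
    "run_test",
    "decide",
    "report",
    "load_samples",
]


class DegenerateDataError(ValueError):
    """Data carry no usable variation for the requested test."""


@dataclass
class SampleData:
    """Scenario-tagged payload.

    means: two numeric vectors (``groups``); proportions: an r x c count
    table (``table``); correlation: two equal-length vectors (``xy``).
    ``n_dropped`` counts missing values removed at load time.
    """

    scenario: str
    groups: tuple[np.ndarray, np.ndarray] | None = None
    table: np.ndarray | None = None
    xy: tuple[np.ndarray, np.ndarray] | None = None
    n_dropped: int = 0


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    pvalue: float
    family: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise LogicError("P-value must lie in [0, 1]")


def _as_clean_array(g: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(g, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise DegenerateDataError(f"{name} needs at least two numeric values")
    if not np.isfinite(arr).all():
        raise DegenerateDataError(f"{name} contains non-finite values")
    return arr


def t_test(
    g1: Sequence[float],
    g2: Sequence[float],
    variant: str = "pooled",
) -> TestResult:
    """Two-sample two-sided t test (pooled by default, Welch by flag)."""
    x = _as_clean_array(g1, "group 1")
    y = _as_clean_array(g2, "group 2")
    n1, n2 = x.size, y.size
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if v1 == 0.0 and v2 == 0.0:
        if diff == 0.0:
            raise DegenerateDataError("zero variance in both groups and no "
                                      "mean difference: t is undefined")
        # degenerate but directional: certainty at the resolution of the data
        return TestResult(math.copysign(math.inf, diff), float(n1 + n2 - 2),
                          0.0, "t")
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variant == "welch":
        se2_1, se2_2 = v1 / n1, v2 / n2
        se = math.sqrt(se2_1 + se2_2)
        df = (se2_1 + se2_2) ** 2 / (
            se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
        )
    else:
        raise LogicError(f"unknown t-test variant {variant!r}")
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)), "t")


def chi2_test(counts: Sequence[Sequence[float]], yates: bool = False) -> TestResult:
    """Pearson chi-squared test of independence on an r x c count table.

    No continuity correction by default; ``yates=True`` applies the Yates
    correction on 2 x 2 tables (a dialect choice, not a recommendation).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateDataError("count table must be at least 2 x 2")
    if (table < 0).any() or not np.isfinite(table).all():
        raise DegenerateDataError("counts must be finite and non-negative")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total <= 0 or (row == 0).any() or (col == 0).any():
        raise DegenerateDataError("zero margin in count table")
    expected = row @ col / total
    resid = np.abs(table - expected)
    if yates and table.shape == (2, 2):
        resid = np.maximum(resid - 0.5, 0.0)
    statistic = float((resid**2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return TestResult(statistic, float(df), p, "chi2")


def correlation_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with its t-based two-sided P-value.

    The reported ``statistic`` is r itself; the P-value comes from
    t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    xa = _as_clean_array(x, "x")
    ya = _as_clean_array(y, "y")
    if xa.size != ya.size:
        raise DegenerateDataError("x and y must have equal length")
    if xa.size < 3:
        raise DegenerateDataError("correlation needs at least three pairs")
    if xa.std() == 0.0 or ya.std() == 0.0:
        raise DegenerateDataError("constant vector: correlation undefined")
    xc, yc = xa - xa.mean(), ya - ya.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    df = xa.size - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(r, float(df), min(p, 1.0), "corr_t")


def run_test(data: SampleData, variant: str = "pooled",
             yates: bool = False) -> TestResult:
    """Dispatch to the scenario's conventional test."""
    if data.scenario == "means":
        assert data.groups is not None
        return t_test(data.groups[0], data.groups[1], variant)
    if data.scenario == "proportions":
        assert data.table is not None
        return chi2_test(data.table, yates=yates)
    if data.scenario == "correlation":
        assert data.xy is not None
        return correlation_test(data.xy[0], data.xy[1])
    raise LogicError(f"no test for scenario {data.scenario!r}")


# ---------------------------------------------------------------------------
# The decision rule


@dataclass
class Decision:
    """The asymmetric outcome of the minimum axiom set.

    ``outcome`` is ``reject_h0`` exactly when ``pvalue < alpha`` (strict:
    a P-value equal to alpha fails to reject).  On rejection the licensed
    conclusion is the real alternative; on failure the only licensed
    statement is that H0 was not rejected.
    """

    alpha: float
    pvalue: float
    outcome: str
    licensed_conclusion: Formula | None
    scenario: Scenario
    universe: CauseUniverse
    test: TestResult


def decide(
    t: TestResult,
    alpha: float,
    s: Scenario = MEANS,
    u: CauseUniverse = DEFAULT_UNIVERSE,
) -> Decision:
    if not (0.0 < alpha < 1.0):
        raise LogicError("alpha must lie strictly between 0 and 1")
    rejected = t.pvalue < alpha
    conclusion = real_alternative(testable_null(s, u)) if rejected else None
    return Decision(
        alpha=alpha,
        pvalue=t.pvalue,
        outcome="reject_h0" if rejected else "fail_to_reject_h0",
        licensed_conclusion=conclusion,
        scenario=s,
        universe=u,
        test=t,
    )


# ---------------------------------------------------------------------------
# Reports

_CAVEAT = (
    "A statistically significant result licenses only the conclusion that "
    "the data were not due to chance alone; it is not a licence to accept "
    "the research hypothesis."
)


@dataclass
class Report:
    decision: Decision
    package: PremisePackage | None
    conclusion_report: ConclusionReport | None
    text: str
    payload: dict

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=2, ensure_ascii=False)


def report(
    d: Decision,
    pkg: PremisePackage | None = None,
    ascii_mode: bool = False,
) -> Report:
    """Structured report of a decision, with the derivation appendix when a
    premise package is supplied and the rejection licenses one."""
    s, u = d.scenario, d.universe
    rend = (lambda f: to_ascii(render(f, s))) if ascii_mode else (
        lambda f: render(f, s)
    )
    h0 = testable_null(s, u)
    dnf = alternative_dnf(s, u, "research")
    loc = locate_research_hypothesis(dnf, u)

    lines = [
        f"Test: {d.test.family}  statistic={d.test.statistic:.6g}  "
        f"df={d.test.df:.6g}  P-value={d.test.pvalue:.6g}  alpha={d.alpha}",
        f"H0 (testable): {rend(h0)}",
        f"HA (real alternative): {rend(real_alternative(h0))}",
        f"HA as a disjunction: {rend(dnf)}",
        f"Research hypothesis H_T is disjunct {loc.index + 1} "
        f"({loc.relation}): {rend(loc.disjunct)}",
    ]
    payload: dict = {
        "statistic": d.test.statistic,
        "df": d.test.df,
        "pvalue": d.test.pvalue,
        "alpha": d.alpha,
        "outcome": d.outcome,
        "h0": rend(h0),
        "ha": rend(real_alternative(h0)),
        "ha_dnf": rend(dnf),
        "research_hypothesis_disjunct": loc.index,
        "research_hypothesis_relation": loc.relation,
    }

    conclusion_rep: ConclusionReport | None = None
    if d.outcome == "reject_h0":
        lines.append("Outcome: reject H0; conclude the real alternative — "
                     "the data were not due to chance alone.")
        if pkg is not None:
            conclusion_rep = conclude_with_premises(s, None, pkg)
            lines.append(f"Premise package {pkg.name!r}:")
            for i, p in enumerate(pkg.premises, 1):
                lines.append(f"  premise ({i}): {rend(p)}")
            lines.append(
                "Derived conclusion: " + rend(conclusion_rep.conclusion)
            )
            if conclusion_rep.reached_intended is not None:
                verdict = ("reached" if conclusion_rep.reached_intended
                           else "NOT reached")
                lines.append(f"Intended conclusion {verdict}.")
            payload["premises"] = [rend(p) for p in pkg.premises]
            payload["derived_conclusion"] = rend(conclusion_rep.conclusion)
            payload["reached_intended"] = conclusion_rep.reached_intended
        lines.append(_CAVEAT)
        payload["caveat"] = _CAVEAT
    else:
        lines.append("Outcome: fail to reject H0. No conclusion about H0's "
                     "truth is licensed; the premises below, if any, derive "
                     "nothing without a rejection.")
        if pkg is not None:
            payload["premises"] = [rend(p) for p in pkg.premises]
            for i, p in enumerate(pkg.premises, 1):
                lines.append(f"  premise ({i}) [unused]: {rend(p)}")
    text = "\n".join(lines)
    assert "accept H0" not in text and "accept the null" not in text
    return Report(
        decision=d,
        package=pkg,
        conclusion_report=conclusion_rep,
        text=text,
        payload=payload,
    )


# ---------------------------------------------------------------------------
# CSV input


def load_samples(path: str, scenario: str) -> SampleData:
    """Load scenario data from CSV.

    means: columns ``group,value`` (exactly two group labels);
    correlation: columns ``x,y``; proportions: a bare r x c integer grid
    (no header).  Missing values are dropped with a count, never imputed.
    """
    if scenario == "means":
        frame = pd.read_csv(path)
        if not {"group", "value"} <= set(frame.columns):
            raise LogicError("means CSV needs 'group' and 'value' columns")
        n0 = len(frame)
        frame = frame.dropna(subset=["group", "value"])
        labels = sorted(frame["group"].unique())
        if len(labels) != 2:
            raise LogicError(f"means CSV must have two groups, got {labels}")
        g1 = frame.loc[frame["group"] == labels[0], "value"].to_numpy(float)
        g2 = frame.loc[frame["group"] == labels[1], "value"].to_numpy(float)
        return SampleData("means", groups=(g1, g2), n_dropped=n0 - len(frame))
    if scenario == "correlation":
        frame = pd.read_csv(path)
        if not {"x", "y"} <= set(frame.columns):
            raise LogicError("correlation CSV needs 'x' and 'y' columns")
        n0 = len(frame)
        frame = frame.dropna(subset=["x", "y"])
        return SampleData(
            "correlation",
            xy=(frame["x"].to_numpy(float), frame["y"].to_numpy(float)),
            n_dropped=n0 - len(frame),
        )
    if scenario == "proportions":
        frame = pd.read_csv(path, header=None)
        return SampleData("proportions", table=frame.to_numpy(float))
    raise LogicError(f"unknown scenario {scenario!r}")
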