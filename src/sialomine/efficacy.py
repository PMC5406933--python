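"""Vaccine-trial parasitology statistics for a monoxene cattle tick.

Because the tick completes its parasitic cycle on one host, a trial is
read out by counting and weighing the engorged females dropping off each
animal and following their reproduction. Four per-animal parameters are
summarized: the number of engorged adult females (NT), mean engorged
female weight, oviposition (O, egg-mass weight per surviving tick) and
egg fertility (F, larvae weight per gram of eggs).

Overall vaccine efficacy combines the vaccinated/control ratios of tick
number, oviposition and fertility multiplicatively::

    E = 100 * [1 - (CRT * CRO * CRF)],   CRT = NT_V / NT_C, etc.

Tick weight is summarized and tested but does not enter E — reduced
weight manifests downstream as reduced oviposition and fertility.
E is computed from group means, matching standard reporting practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalogue import round_half_up

__all__ = [
    "PARAMETERS",
    "EFFICACY_PARAMETERS",
    "TestResult",
    "EfficacyResult",
    "read_trial",
    "summarize_groups",
    "percent_reduction",
    "two_sample_t",
    "compute_efficacy",
    "evaluate_trial",
    "report_table",
]

#: Per-animal trial parameters, in reporting order.
PARAMETERS = ("n_ticks", "tick_weight_mg", "egg_mass_mg_per_tick", "larvae_g_per_g_eggs")

#: The subset entering the multiplicative efficacy formula (NT, O, F).
EFFICACY_PARAMETERS = ("n_ticks", "egg_mass_mg_per_tick", "larvae_g_per_g_eggs")

GROUPS = ("vaccinated", "control")


class TestResult(tuple):
    """(t, df, p) with named access."""

    __slots__ = ()

    def __new__(cls, t: float, df: float, p: float):
        return super().__new__(cls, (t, df, p))

    t = property(lambda self: self[0])
    df = property(lambda self: self[1])
    p = property(lambda self: self[2])


@dataclass
class EfficacyResult:
    crt: float
    cro: float
    crf: float
    e_percent: float
    reductions: dict[str, float]
    tests: dict[str, TestResult]
    group_summary: Optional[pd.DataFrame] = None


def read_trial(path) -> pd.DataFrame:
    """Read a per-animal trial table (TSV).

    Columns: ``animal_id``, ``group`` (vaccinated/control), the four
    parameters, and optionally ``excluded`` (with ``exclusion_reason``).
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"animal_id", "group", *PARAMETERS} - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if "excluded" not in df.columns:
        df["excluded"] = False
    df["excluded"] = df["excluded"].fillna(False).astype(bool)
    bad = df.loc[~df["group"].isin(GROUPS), "group"]
    if not bad.empty:
        raise ValueError(f"unknown group label {bad.iloc[0]!r}")
    for p in PARAMETERS:
        if (df[p] < 0).any():
            raise ValueError(f"negative value in column {p}")
    return df


def _included(records: pd.DataFrame) -> pd.DataFrame:
    if "excluded" in records.columns:
        return records.loc[~records["excluded"].astype(bool)]
    return records


def summarize_groups(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error (sd/sqrt(n)) per parameter per group.

    Excluded animals never enter any statistic. Groups with fewer than
    two remaining animals are rejected.
    """
    inc = _included(records)
    rows = []
    for group in GROUPS:
        sub = inc.loc[inc["group"] == group]
        if len(sub) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 non-excluded animals")
        for p in PARAMETERS:
            vals = sub[p].astype(float)
            rows.append(
                {
                    "group": group,
                    "parameter": p,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
                }
            )
    return pd.DataFrame(rows)


def percent_reduction(v_mean: float, c_mean: float) -> float:
    """``100 * (1 - v/c)``; negative when the parameter increased."""
    if c_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (1.0 - v_mean / c_mean)


def two_sample_t(
    x: Sequence[float], y: Sequence[float], method: str = "welch"
) -> TestResult:
    """Two-sample t comparison, two-sided.

    ``student`` pools variances (df = n1 + n2 - 2); ``welch`` uses the
    Satterthwaite degrees of freedom and does not assume equal variances.
    Two constant samples with equal means give (0, df, 1) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if method not in ("student", "welch"):
        raise ValueError("method must be 'student' or 'welch'")
    equal_var = method == "student"
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        df = len(x) + len(y) - 2
        if np.mean(x) == np.mean(y):
            return TestResult(0.0, float(df), 1.0)
        return TestResult(np.inf if np.mean(x) > np.mean(y) else -np.inf, float(df), 0.0)
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue))


def compute_efficacy(group_means: Mapping[str, Mapping[str, float]]) -> EfficacyResult:
    """Efficacy and percent reductions from per-group parameter means.

    ``group_means`` maps ``vaccinated`` / ``control`` to per-parameter
    means (``n_ticks``, ``egg_mass_mg_per_tick``, ``larvae_g_per_g_eggs``
    are required; ``tick_weight_mg`` is optional and reported only as a
    reduction). Values are unrounded; see :func:`report_table` for the
    printed-precision rendering.
    """
    for g in GROUPS:
        if g not in group_means:
            raise ValueError(f"missing group {g!r}")
        for p in EFFICACY_PARAMETERS:
            if p not in group_means[g]:
                raise ValueError(f"missing parameter {p!r} for group {g!r}")
    v, c = group_means["vaccinated"], group_means["control"]
    for p in EFFICACY_PARAMETERS:
        if c[p] <= 0:
            raise ValueError(f"control mean for {p!r} must be positive")

    crt = v["n_ticks"] / c["n_ticks"]
    cro = v["egg_mass_mg_per_tick"] / c["egg_mass_mg_per_tick"]
    crf = v["larvae_g_per_g_eggs"] / c["larvae_g_per_g_eggs"]
    e = 100.0 * (1.0 - crt * cro * crf)

    reductions = {
        p: percent_reduction(v[p], c[p]) for p in PARAMETERS if p in v and p in c and c[p] > 0
    }
    return EfficacyResult(
        crt=crt, cro=cro, crf=crf, e_percent=e, reductions=reductions, tests={}
    )


def evaluate_trial(records: pd.DataFrame, t_method: str = "welch") -> EfficacyResult:
    """Full trial evaluation: summaries, reductions, t-tests, efficacy."""
    summary = summarize_groups(records)
    means = {
        g: {
            r["parameter"]: r["mean"]
            for _, r in summary.loc[summary["group"] == g].iterrows()
        }
        for g in GROUPS
    }
    result = compute_efficacy(means)
    inc = _included(records)
    for p in PARAMETERS:
        xv = inc.loc[inc["group"] == "vaccinated", p].astype(float)
        xc = inc.loc[inc["group"] == "control", p].astype(float)
        result.tests[p] = two_sample_t(xv, xc, method=t_method)
    result.group_summary = summary
    return result


def report_table(result: EfficacyResult) -> pd.DataFrame:
    """Printed-precision report: reductions to 1 decimal, E to integer."""
    rows = [
        {
            "parameter": p,
            "percent_reduction": round_half_up(result.reductions[p], 1),
            "t": round_half_up(result.tests[p].t, 3) if p in result.tests else None,
            "df": round_half_up(result.tests[p].df, 2) if p in result.tests else None,
            "p_value": result.tests[p].p if p in result.tests else None,
        }
        for p in result.reductions
    ]
    df = pd.DataFrame(rows)
    df.attrs["efficacy_percent"] = int(round_half_up(result.e_percent, 0))
    return df
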