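"""Digital differential expression of EST counts between host conditions.

Single-pass EST libraries yield one count per contig per library; with one
(pooled) library per condition there are no biological replicates, so the
classical test is a chi-square contrast of the observed counts against the
counts expected if the contig's ESTs were allocated to conditions in
proportion to total sequencing depth. Two statistics are offered:

* ``gof`` — goodness of fit of the contig's (a, b) counts against the
  depth-proportional expectation, df = k - 1;
* ``contingency_2x2`` — the 2x2 contingency statistic of (contig,
  all-other-ESTs) x (condition a, condition b), optionally with the
  Yates continuity correction.

These are asymptotically equivalent tests of the same null; with pooled
single libraries per condition the p-values are descriptive, not
replicate-based inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalogue import Catalogue

__all__ = [
    "Contrast",
    "DiffExpResult",
    "expected_counts",
    "chisq_gof",
    "chisq_2x2",
    "chisq_pvalue",
    "diff_table",
    "results_frame",
]


@dataclass
class Contrast:
    """Two disjoint sets of libraries to compare.

    By convention ``condition_a`` holds the resistant-host libraries and
    ``condition_b`` the susceptible-host ones; the reported direction
    ``up_in_susceptible`` refers to ``condition_b``.
    """

    name: str
    condition_a: frozenset[str]
    condition_b: frozenset[str]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.condition_a = frozenset(self.condition_a)
        self.condition_b = frozenset(self.condition_b)
        if not self.condition_a or not self.condition_b:
            raise ValueError("both condition library sets must be non-empty")
        if self.condition_a & self.condition_b:
            raise ValueError("condition library sets must be disjoint")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_catalogue(cls, catalogue: Catalogue, name: str = "resistant_vs_susceptible",
                       alpha: float = 0.05) -> "Contrast":
        """Build the resistant (a) vs susceptible (b) contrast from library metadata."""
        return cls(
            name=name,
            condition_a=frozenset(catalogue.libraries_for("resistant")),
            condition_b=frozenset(catalogue.libraries_for("susceptible")),
            alpha=alpha,
        )


@dataclass
class DiffExpResult:
    contig_id: str
    observed_a: int
    observed_b: int
    expected_a: float
    expected_b: float
    chi2: float
    df: int
    p_value: float
    direction: str  # up_in_susceptible | up_in_resistant | none
    significant: bool
    p_adjusted: Optional[float] = None


def expected_counts(contig_total: int, condition_totals: tuple[int, int]) -> tuple[float, float]:
    """Expected per-condition counts under depth-proportional allocation.

    ``expected_i = contig_total * N_i / (N_a + N_b)``; the pair sums to the
    contig total by construction.
    """
    na, nb = condition_totals
    if contig_total < 1:
        raise ValueError("contig_total must be >= 1")
    if na <= 0 or nb <= 0:
        raise ValueError("condition totals must be positive")
    n = na + nb
    return contig_total * na / n, contig_total * nb / n


def chisq_gof(observed: Sequence[float], expected: Sequence[float]) -> tuple[float, int]:
    """Pearson goodness-of-fit statistic ``sum((O-E)^2 / E)`` with df = k - 1."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and expected must be 1-d vectors of equal length >= 2")
    if np.any(exp <= 0):
        raise ValueError("expected counts must all be positive")
    if abs(obs.sum() - exp.sum()) > 1e-6:
        raise ValueError(
            f"observed sum {obs.sum()} != expected sum {exp.sum()}: wrong expectation model"
        )
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return chi2, obs.size - 1


def chisq_2x2(
    contig_counts: tuple[int, int],
    condition_totals: tuple[int, int],
    yates: bool = False,
) -> tuple[float, int]:
    """2x2 contingency chi-square of (contig, rest-of-library) x condition.

    With the Yates correction, 0.5 is subtracted from each cell's absolute
    deviation (floored at zero), which can only shrink the statistic.
    """
    a, b = contig_counts
    na, nb = condition_totals
    if a > na or b > nb:
        raise ValueError("contig counts cannot exceed condition totals")
    table = np.array([[a, b], [na - a, nb - b]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("2x2 table has a zero margin")
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    dev = np.abs(table - exp)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float(np.sum(dev**2 / exp))
    return chi2, 1


def chisq_pvalue(chi2: float, df: int) -> float:
    """Upper-tail chi-square probability, Q(df/2, chi2/2)."""
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(chi2, df))


def diff_table(
    catalogue: Catalogue,
    contrast: Contrast,
    method: str = "gof",
    min_count: int = 5,
    yates: bool = False,
    adjust: bool = False,
) -> list[DiffExpResult]:
    """Chi-square contrast of every sufficiently sampled contig.

    Condition totals are the column sums over *all* contigs (including the
    one under test), i.e. total sequencing depth per condition. Contigs
    with fewer than ``min_count`` ESTs across both conditions are excluded
    (the chi-square approximation is unreliable at very low counts).
    ``adjust=True`` adds Benjamini-Hochberg adjusted p-values and bases the
    ``significant`` flag on them; by default raw p-values are compared to
    ``contrast.alpha`` with no multiplicity correction.
    """
    if method not in ("gof", "contingency_2x2"):
        raise ValueError("method must be 'gof' or 'contingency_2x2'")
    known = set(catalogue.libraries)
    missing = (contrast.condition_a | contrast.condition_b) - known
    if missing:
        raise ValueError(f"contrast names unknown libraries: {sorted(missing)}")

    libs_a, libs_b = sorted(contrast.condition_a), sorted(contrast.condition_b)
    na = sum(catalogue.libraries[l].total_ests for l in libs_a)
    nb = sum(catalogue.libraries[l].total_ests for l in libs_b)
    if na <= 0 or nb <= 0:
        raise ValueError("each condition must contain at least one EST")

    results: list[DiffExpResult] = []
    for contig in catalogue.contigs.values():
        oa = sum(contig.counts.get(l, 0) for l in libs_a)
        ob = sum(contig.counts.get(l, 0) for l in libs_b)
        total = oa + ob
        if total < min_count:
            continue
        ea, eb = expected_counts(total, (na, nb))
        if method == "gof":
            chi2, df = chisq_gof([oa, ob], [ea, eb])
        else:
            chi2, df = chisq_2x2((oa, ob), (na, nb), yates=yates)
        p = chisq_pvalue(chi2, df)
        if ob / nb > oa / na:
            direction = "up_in_susceptible"
        elif ob / nb < oa / na:
            direction = "up_in_resistant"
        else:
            direction = "none"
        results.append(
            DiffExpResult(
                contig_id=contig.contig_id,
                observed_a=oa,
                observed_b=ob,
                expected_a=ea,
                expected_b=eb,
                chi2=chi2,
                df=df,
                p_value=p,
                direction=direction,
                significant=p < contrast.alpha,
            )
        )

    if adjust and results:
        padj = stats.false_discovery_control([r.p_value for r in results], method="bh")
        for r, q in zip(results, padj):
            r.p_adjusted = float(q)
            r.significant = q < contrast.alpha
    return results


def results_frame(results: Sequence[DiffExpResult]) -> pd.DataFrame:
    """Results as a table mirroring the observed/expected report layout."""
    return pd.DataFrame(
        [
            {
                "contig_id": r.contig_id,
                "observed_resistant": r.observed_a,
                "expected_resistant": r.expected_a,
                "observed_susceptible": r.observed_b,
                "expected_susceptible": r.expected_b,
                "chi2": r.chi2,
                "df": r.df,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "direction": r.direction,
                "significant": r.significant,
            }
            for r in results
        ]
    )
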