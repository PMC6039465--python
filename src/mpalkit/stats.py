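"""Statistical layer: contingency tests, rank tests, survival, enrichment.

The mutation–phenotype enrichment statistic is the Wald z-test on the log
odds ratio with a Haldane–Anscombe 0.5 correction whenever any cell of the
2×2 table is zero; the Fisher exact two-sided p (probability-mass
definition) is exposed alongside it for sensitivity analysis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps


@dataclass
class EnrichmentResult:
    label: str
    table: tuple[tuple[int, int], tuple[int, int]]
    log_odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str  # fisher_exact | wald_log_or
    haldane_applied: bool = False


def _check_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("2x2 table required")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table cells must be non-negative integers")
    return t


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables with the observed margins no more probable than the observed one.

    Zero-margin tables carry no information; they return p = 1.
    """
    t = _check_table(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(sps.fisher_exact(t.astype(int), alternative="two-sided")[1])


def wald_log_or(table, label: str = "", haldane_if_zero: bool = True) -> EnrichmentResult:
    """Wald z-test on ln(OR) with 95% CI; optional Haldane 0.5 correction."""
    t = _check_table(table)
    haldane = bool(haldane_if_zero and (t == 0).any())
    if not haldane and (t == 0).any():
        raise ValueError("zero cell without Haldane correction: OR undefined")
    # two zeros sharing a row/column leave the OR undefined even after correction
    for axis in (0, 1):
        if ((t == 0).sum(axis=axis) == 2).any():
            raise ValueError("degenerate table: a full row or column is zero")
    tc = t + 0.5 if haldane else t
    a, b = tc[0]
    c, d = tc[1]
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2 * sps.norm.sf(abs(z))
    return EnrichmentResult(
        label=label,
        table=tuple(map(tuple, np.asarray(table, dtype=int))),
        log_odds_ratio=log_or,
        ci_low=log_or - 1.959963984540054 * se,
        ci_high=log_or + 1.959963984540054 * se,
        p_value=float(p),
        method="wald_log_or",
        haldane_applied=haldane,
    )


def mutation_enrichment(
    mutation_carriers: dict[str, set[str]],
    group_a: set[str],
    group_b: set[str],
    min_carriers: int = 2,
) -> list[EnrichmentResult]:
    """Forest-plot data: per-gene log-OR of carrying a mutation in group A vs B."""
    out = []
    for gene, carriers in sorted(mutation_carriers.items()):
        a = len(carriers & group_a)
        b = len(group_a) - a
        c = len(carriers & group_b)
        d = len(group_b) - c
        if a + c < min_carriers:
            continue
        out.append(wald_log_or([[a, b], [c, d]], label=gene))
    return out


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x with mid-rank ties."""
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann–Whitney U with mid-rank ties.

    Exact null enumeration (over rank assignments, respecting ties) when
    n1 + n2 ≤ 12; otherwise the normal approximation with tie and continuity
    corrections.  Returns (U of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    u = _mann_whitney_u(x, y)
    if n1 + n2 <= 12:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        mu = n1 * n2 / 2
        obs_dev = abs(u - mu)
        total = more_extreme = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            r1 = ranks[list(idx)].sum()
            u_perm = r1 - n1 * (n1 + 1) / 2
            total += 1
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                more_extreme += 1
        return u, more_extreme / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    return u, float(res.pvalue)


@dataclass
class SurvivalComparison:
    km_curves: dict  # group -> DataFrame(time, survival)
    chi_square: float
    p_value: float
    n_per_group: dict


def km_logrank(
    times: Sequence[float], events: Sequence[bool], group_labels: Sequence[str]
) -> SurvivalComparison:
    """Kaplan–Meier curves per group plus the 1-df log-rank comparison."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(group_labels)
    if (times <= 0).any():
        raise ValueError("times must be positive")
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    curves = {}
    for g in groups:
        sel = labels == g
        if sel.sum() == 0:
            raise ValueError(f"group {g!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})
    sel = labels == groups[0]
    res = logrank_test(times[sel], times[~sel], events[sel], events[~sel])
    return SurvivalComparison(
        km_curves=curves,
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        n_per_group={g: int((labels == g).sum()) for g in groups},
    )


@dataclass
class MatchedTherapyResult:
    cr_table: tuple[tuple[int, int], tuple[int, int]]  # rows matched/unmatched, cols CR yes/no
    cr_fisher_p: float
    composite_cr_table: tuple[tuple[int, int], tuple[int, int]] | None
    composite_cr_fisher_p: float | None
    survival: SurvivalComparison | None
    n_matched: int
    n_unmatched: int
    degenerate: bool = False


def matched_therapy_analysis(
    clinical: Sequence, lineage_labels: dict[str, str]
) -> MatchedTherapyResult:
    """CR-rate comparison between patients whose induction regimen matched
    their methylation-defined lineage (AML-directed for AML-like, ALL-directed
    for ALL-like) and those whose did not, plus survival when available.
    """
    rows = []
    for c in clinical:
        if c.timepoint != "diagnosis" or c.cr_achieved is None:
            continue
        if c.therapy not in ("ALL_directed", "AML_directed"):
            continue
        lineage = lineage_labels.get(c.sample_id)
        if lineage is None:
            continue
        matched = (lineage == "AML_like" and c.therapy == "AML_directed") or (
            lineage == "ALL_like" and c.therapy == "ALL_directed"
        )
        rows.append((c, matched))
    if not rows:
        raise ValueError("no evaluable patients (need cr_achieved and directed therapy)")
    n_matched = sum(m for _, m in rows)
    n_unmatched = len(rows) - n_matched
    if n_matched == 0 or n_unmatched == 0:
        return MatchedTherapyResult(
            cr_table=((n_matched and sum(c.cr_achieved for c, m in rows if m), 0), (0, 0)),
            cr_fisher_p=float("nan"),
            composite_cr_table=None,
            composite_cr_fisher_p=None,
            survival=None,
            n_matched=n_matched,
            n_unmatched=n_unmatched,
            degenerate=True,
        )

    def table(flag_getter):
        a = sum(1 for c, m in rows if m and flag_getter(c))
        b = sum(1 for c, m in rows if m and not flag_getter(c))
        cc = sum(1 for c, m in rows if not m and flag_getter(c))
        d = sum(1 for c, m in rows if not m and not flag_getter(c))
        return ((a, b), (cc, d))

    cr_table = table(lambda c: bool(c.cr_achieved))
    composite = None
    composite_p = None
    if all(c.cr_composite is not None for c, _ in rows):
        composite = table(lambda c: bool(c.cr_composite))
        composite_p = fisher_exact_2x2(composite)
    survival = None
    with_surv = [(c, m) for c, m in rows if c.survival_time is not None]
    if len(with_surv) >= 4 and 0 < sum(m for _, m in with_surv) < len(with_surv):
        survival = km_logrank(
            [c.survival_time for c, _ in with_surv],
            [bool(c.event) for c, _ in with_surv],
            ["matched" if m else "unmatched" for _, m in with_surv],
        )
    return MatchedTherapyResult(
        cr_table=cr_table,
        cr_fisher_p=fisher_exact_2x2(cr_table),
        composite_cr_table=composite,
        composite_cr_fisher_p=composite_p,
        survival=survival,
        n_matched=n_matched,
        n_unmatched=n_unmatched,
    )
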