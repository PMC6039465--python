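"""Differential methylation and expression.

Differential methylation uses an empirical-Bayes moderated two-sample t
statistic: per-feature pooled variances are shrunk toward a prior fitted by
method of moments on the log-variance distribution (scaled-F model), and the
moderated t is referred to a t distribution with d0 + d degrees of freedom.
A probe is a DMP when FDR < 0.1 and |Δβ| > 0.15 jointly.

Differential expression is a deliberately simple stage: median-of-ratios
size factors, log2(normalized + 1), and the same moderated t on log values
— adequate for driving the methylation–expression starburst integration,
not a replacement for a count-model DE analysis.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, ProbeManifest
from .stats import fisher_exact_2x2

logger = logging.getLogger("mpalkit")

PROMOTER_CLASSES = ("TSS200", "TSS1500")


def _fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Fit the scaled inverse-chi-square prior (d0, s0²) for feature variances.

    Under the hierarchical model, z = log(s²) satisfies
    E[z] = log(s0²) + ψ(d/2) − ψ(d0/2) + log(d0/d) and
    Var[z] = ψ'(d/2) + ψ'(d0/2); d0 solves the variance equation by
    root-finding on the trigamma function (tolerance 1e-8).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    evar = z.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar <= 0:
        # observed variances less dispersed than chi-square sampling noise:
        # infinite prior df, fully pooled variance
        s0_log = z.mean() - special.polygamma(0, d / 2.0) + math.log(d / 2.0)
        return np.inf, math.exp(s0_log)
    f = lambda half_d0: special.polygamma(1, half_d0) - evar
    lo, hi = 1e-6, 10.0
    while f(hi) > 0:
        hi *= 2
    half_d0 = optimize.brentq(f, lo, hi, xtol=1e-8)
    d0 = 2 * half_d0
    s0_log = z.mean() - special.polygamma(0, d / 2.0) + math.log(d / 2.0) \
        + special.polygamma(0, half_d0) - math.log(half_d0)
    return d0, math.exp(s0_log)


def moderated_t(matrix: pd.DataFrame, group_labels) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t per feature (row).

    Returns a DataFrame with columns delta (group1 − group2 means), t, p, df.
    Group order follows the sorted unique labels.
    """
    labels = np.asarray(group_labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    sel1 = labels == groups[0]
    sel2 = labels == groups[1]
    n1, n2 = int(sel1.sum()), int(sel2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n ≥ 2")
    X = matrix.to_numpy(dtype=float)
    m1 = X[:, sel1].mean(axis=1)
    m2 = X[:, sel2].mean(axis=1)
    v1 = X[:, sel1].var(axis=1, ddof=1)
    v2 = X[:, sel2].var(axis=1, ddof=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    d0, s02 = _fit_variance_prior(s2, d)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    delta = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    if np.isinf(df_total):
        p = 2 * sps.norm.sf(np.abs(t))
    else:
        p = 2 * sps.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.DataFrame(
        {"delta": delta, "t": t, "p": p, "df": df_total}, index=matrix.index
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DmpRecord:
    probe_id: str
    mean_B: float
    mean_T: float
    delta_beta: float  # group B − group T, signed
    t_stat: float
    p_value: float
    fdr: float
    is_dmp: bool
    direction: str  # hyper_in_B | hyper_in_T


def call_dmps(
    beta: BetaMatrix,
    group_labels,
    fdr_threshold: float = 0.1,
    delta_threshold: float = 0.15,
    promoter_only: bool = False,
    manifest: ProbeManifest | None = None,
) -> list[DmpRecord]:
    """Differentially methylated probes between myeloid-B and myeloid-T.

    A probe is a DMP iff FDR < ``fdr_threshold`` and |Δβ| > ``delta_threshold``
    (strict inequalities on both).  ``promoter_only`` restricts testing to
    TSS200/TSS1500 probes before any statistics are computed.
    """
    if not (0 < fdr_threshold < 1 and 0 < delta_threshold < 1):
        raise ValueError("thresholds must be in (0,1)")
    labels = np.asarray(group_labels)
    vals = beta.values
    if promoter_only:
        if manifest is None:
            raise ValueError("promoter_only requires a manifest")
        keep = [
            p for p in vals.index
            if p in manifest and manifest[p].region_class in PROMOTER_CLASSES
        ]
        if not keep:
            raise ValueError("no promoter probes present")
        vals = vals.loc[keep]
    groups = sorted(set(labels.tolist()))
    res = moderated_t(vals, labels)
    fdr = bh_adjust(res["p"].to_numpy())
    sel1 = labels == groups[0]
    m1 = vals.loc[:, sel1].mean(axis=1)
    m2 = vals.loc[:, ~sel1].mean(axis=1)
    out = []
    for i, probe in enumerate(vals.index):
        delta = float(m1.iloc[i] - m2.iloc[i])
        is_dmp = bool(fdr[i] < fdr_threshold and abs(delta) > delta_threshold)
        out.append(
            DmpRecord(
                probe_id=probe,
                mean_B=float(m1.iloc[i]),
                mean_T=float(m2.iloc[i]),
                delta_beta=delta,
                t_stat=float(res["t"].iloc[i]),
                p_value=float(res["p"].iloc[i]),
                fdr=float(fdr[i]),
                is_dmp=is_dmp,
                direction="hyper_in_B" if delta > 0 else "hyper_in_T",
            )
        )
    return out


def dmps_to_frame(dmps: list[DmpRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(d) for d in dmps]).set_index("probe_id")


def mean_beta_summaries(
    beta: BetaMatrix, group_labels, top_fraction: float = 0.01
) -> dict:
    """Per-sample mean beta over all probes and over the top-fraction most
    variable probes, with a two-sided Mann–Whitney comparison per summary."""
    from .cluster import select_variable_probes
    from .stats import mann_whitney

    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0,1]")
    labels = np.asarray(group_labels)
    groups = sorted(set(labels.tolist()))
    all_means = beta.values.mean(axis=0)
    top = select_variable_probes(beta, fraction=top_fraction)
    top_means = beta.values.loc[top].mean(axis=0)
    out = {"all_probes": all_means, "top_variable": top_means}
    for key, means in list(out.items()):
        x = means[labels == groups[0]]
        y = means[labels == groups[1]]
        if np.allclose(x.std(ddof=0) + y.std(ddof=0), 0) and np.isclose(x.mean(), y.mean()):
            out[key + "_p"] = 1.0
        else:
            out[key + "_p"] = mann_whitney(x, y)[1]
    return out


@dataclass
class DeRecord:
    gene: str
    log2_fold_change: float
    p_value: float
    fdr: float


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference
    over genes with all-positive counts."""
    arr = counts.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any():
        bad = counts.columns[arr.sum(axis=0) == 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    log_ref = np.log(arr[positive]).mean(axis=1)
    ratios = np.log(arr[positive]) - log_ref[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    sf = sf / np.median(sf)  # median-1 normalization: a constant factor cancels in log2FC
    return pd.Series(sf, index=counts.columns)


def differential_expression(counts: pd.DataFrame, group_labels) -> list[DeRecord]:
    """Simplified DE: size-factor normalization, log2(x+1), moderated t."""
    sf = size_factors(counts)
    norm = counts.div(sf, axis=1)
    logx = np.log2(norm + 1.0)
    labels = np.asarray(group_labels)
    res = moderated_t(logx, labels)
    fdr = bh_adjust(res["p"].to_numpy())
    return [
        DeRecord(
            gene=g,
            log2_fold_change=float(res["delta"].iloc[i]),
            p_value=float(res["p"].iloc[i]),
            fdr=float(fdr[i]),
        )
        for i, g in enumerate(counts.index)
    ]


def starburst_integrate(
    dmps: list[DmpRecord],
    de: list[DeRecord],
    probe_to_gene: dict[str, str],
    expr_fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Quadrant table of promoter methylation vs expression per (probe, gene).

    Significant pairs need is_dmp AND expression FDR < threshold; quadrant
    combines methylation direction (hyper/hypo in B) with expression sign
    (up/down in B).  Unmapped probes are skipped with a warning count.
    """
    de_by_gene = {d.gene: d for d in de}
    rows = []
    skipped = 0
    for dmp in dmps:
        gene = probe_to_gene.get(dmp.probe_id)
        if gene is None or gene not in de_by_gene:
            skipped += 1
            continue
        d = de_by_gene[gene]
        if dmp.is_dmp and d.fdr < expr_fdr_threshold:
            meth = "hyper" if dmp.delta_beta > 0 else "hypo"
            expr = "up" if d.log2_fold_change > 0 else "down"
            quadrant = f"{meth}+{expr}"
        else:
            quadrant = "not significant"
        rows.append(
            {
                "probe_id": dmp.probe_id, "gene": gene,
                "delta_beta": dmp.delta_beta, "meth_fdr": dmp.fdr,
                "log2_fold_change": d.log2_fold_change, "expr_fdr": d.fdr,
                "quadrant": quadrant,
            }
        )
    if skipped:
        warnings.warn(f"{skipped} probes skipped (no gene mapping or no DE record)")
    return pd.DataFrame(rows)


def ora_fisher(
    hit_genes: set, universe: set, gene_sets: dict[str, set]
) -> pd.DataFrame:
    """Over-representation of hits in each gene set: 2×2 Fisher exact p and
    odds ratio per set, BH-adjusted across sets.  Sets disjoint from the
    universe are skipped with a warning."""
    if not universe:
        raise ValueError("empty universe")
    if not hit_genes <= universe:
        raise ValueError("hits must be a subset of the universe")
    rows = []
    for name in sorted(gene_sets):
        gs = gene_sets[name] & universe
        if not gs:
            warnings.warn(f"gene set {name!r} disjoint from universe; skipped")
            continue
        a = len(hit_genes & gs)
        b = len(hit_genes) - a
        c = len(gs) - a
        d = len(universe) - len(hit_genes) - c
        p = fisher_exact_2x2([[a, b], [c, d]])
        if b * c == 0:
            odds, or_unbounded = float("inf"), True
        else:
            odds = (a * d) / (b * c)
            or_unbounded = False
        rows.append(
            {"gene_set": name, "n_hits_in_set": a, "n_set": len(gs),
             "odds_ratio": odds, "or_unbounded": or_unbounded, "p": p}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df.set_index("gene_set") if len(df) else df
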