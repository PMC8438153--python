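"""Survival estimation and group-comparison statistics.

Kaplan-Meier / log-rank through lifelines, rank tests and exact tests through
scipy, plus the mutation-burden operations: per-sample TMB with a median
split, per-gene mutation-frequency contrasts (Fisher exact), the four-level
TMB x ICI stratified survival comparison, and the immunotherapy
response-rate comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io import MutationTable


@dataclass
class SurvivalFit:
    """Per-group product-limit estimates plus the log-rank comparison."""

    curves: dict[str, pd.DataFrame]  # per group: time, at_risk, events, survival
    statistic: float
    df: int
    p: float
    group_sizes: dict[str, int] = field(default_factory=dict)


def kaplan_meier(times, events, groups) -> SurvivalFit:
    """Product-limit estimate per group and the log-rank test across groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0 or 1")
    levels = [lv for lv in pd.unique(groups)]
    if any((groups == lv).sum() == 0 for lv in levels):
        raise ValueError("every group needs at least one subject")

    curves: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    for lv in levels:
        mask = groups == lv
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tbl = kmf.event_table
        curves[str(lv)] = pd.DataFrame(
            {
                "time": tbl.index.to_numpy(),
                "at_risk": tbl["at_risk"].to_numpy(),
                "events": tbl["observed"].to_numpy(),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            }
        )
        sizes[str(lv)] = int(mask.sum())

    if len(levels) == 1:
        return SurvivalFit(curves, 0.0, 0, 1.0, sizes)
    res = multivariate_logrank_test(times, groups, events)
    return SurvivalFit(curves, float(res.test_statistic), len(levels) - 1, float(res.p_value), sizes)


def rank_tests(values, groups) -> tuple[float, float]:
    """Wilcoxon rank-sum for 2 groups, Kruskal-Wallis for more (tie-corrected).

    Returns (statistic, p). All-identical values give (0, 1) by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    parts = [values[groups == lv] for lv in levels]
    if any(len(p) == 0 for p in parts):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    if len(levels) == 2:
        stat, p = stats.mannwhitneyu(parts[0], parts[1], alternative="two-sided", method="asymptotic")
        return float(stat), float(p)
    stat, p = stats.kruskal(*parts)
    return float(stat), float(p)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with the t-transform p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class MutationSummary:
    """Per-sample TMB, the cohort median split, and optional per-gene contrasts."""

    tmb: pd.Series
    tmb_group: pd.Series  # high / low
    median: float
    excluded_samples: list[str] = field(default_factory=list)
    gene_contrasts: pd.DataFrame | None = None


def tmb_and_split(mut: MutationTable, samples) -> MutationSummary:
    """TMB (raw mutation count) per covered sample and the median high/low split.

    Samples without a coverage declaration are excluded with a warning — an
    absent sample has *undefined* TMB, not zero.
    """
    samples = list(samples)
    covered = set(mut.covered_samples)
    excluded = [s for s in samples if s not in covered]
    if excluded:
        warnings.warn(
            f"{len(excluded)} sample(s) lack mutation coverage and are excluded from TMB"
        )
    kept = [s for s in samples if s in covered]
    if not kept:
        raise ValueError("no samples with mutation coverage")
    tmb = mut.tmb().reindex(kept)
    med = float(tmb.median())
    group = pd.Series(np.where(tmb > med, "high", "low"), index=tmb.index, name="tmb_group")
    return MutationSummary(tmb, group, med, excluded)


def gene_mutation_contrast(mut: MutationTable, group_labels: pd.Series) -> pd.DataFrame:
    """Per-gene mutation-frequency comparison between two groups.

    For each gene, samples are cross-tabulated as mutated/unmutated x group and
    compared with a two-sided Fisher exact test. Returns one row per gene:
    mutated counts, per-group frequencies, p.
    """
    levels = sorted(group_labels.unique().tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    g1, g2 = levels
    members = {lv: set(group_labels.index[group_labels == lv]) for lv in levels}
    n1, n2 = len(members[g1]), len(members[g2])
    in_scope = members[g1] | members[g2]
    recs = mut.records[mut.records["sample_id"].isin(in_scope)]
    rows = []
    for gene, sub in recs.groupby("gene_symbol"):
        carriers = set(sub["sample_id"])
        a = len(carriers & members[g1])
        b = len(carriers & members[g2])
        _, p = stats.fisher_exact([[a, n1 - a], [b, n2 - b]], alternative="two-sided")
        rows.append(
            {
                "gene": gene,
                f"mutated_{g1}": a,
                f"freq_{g1}": a / n1,
                f"mutated_{g2}": b,
                f"freq_{g2}": b / n2,
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("p", ignore_index=True)
    return out


@dataclass
class StratifiedResult:
    """Four-level TMB x ICI survival comparison plus within-stratum contrasts."""

    overall: SurvivalFit
    within_stratum: dict[str, SurvivalFit]
    strata_sizes: dict[str, int]


def stratified_km(times, events, tmb_group, ici_group) -> StratifiedResult:
    """KM over the 4 TMB x ICI groups (df=3 log-rank) and the ICI contrast
    within each TMB stratum."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    tmb_group = np.asarray(tmb_group)
    ici_group = np.asarray(ici_group)
    combined = np.array([f"TMB_{t}+ICI_{i}" for t, i in zip(tmb_group, ici_group)])
    overall = kaplan_meier(times, events, combined)
    within: dict[str, SurvivalFit] = {}
    for stratum in pd.unique(tmb_group):
        mask = tmb_group == stratum
        lv = pd.unique(ici_group[mask])
        if len(lv) < 2:
            warnings.warn(f"TMB stratum {stratum!r} has a single ICI level; contrast skipped")
            continue
        within[str(stratum)] = kaplan_meier(times[mask], events[mask], ici_group[mask])
    sizes = pd.Series(combined).value_counts().to_dict()
    return StratifiedResult(overall, within, {str(k): int(v) for k, v in sizes.items()})


def response_rate_compare(
    response_labels: pd.Series, ici_group: pd.Series, ici_scores: pd.Series | None = None
) -> dict:
    """Objective-response (CR/PR) rate per ICI group with a Fisher exact test;
    optionally the rank-sum of ICI score by responder status."""
    resp = response_labels.dropna()
    valid = resp.isin(["CR", "PR", "SD", "PD"])
    if not valid.all():
        raise ValueError("responses must be CR/PR/SD/PD")
    grp = ici_group.reindex(resp.index)
    levels = sorted(grp.dropna().unique().tolist())
    if len(levels) != 2:
        raise ValueError("need exactly two ICI groups with response data")
    responder = resp.isin(["CR", "PR"])
    counts = {}
    for lv in levels:
        mask = grp == lv
        if mask.sum() == 0:
            raise ValueError(f"ICI group {lv!r} has no response data")
        counts[lv] = (int(responder[mask].sum()), int(mask.sum()))
    table = [[counts[lv][0], counts[lv][1] - counts[lv][0]] for lv in levels]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    out = {
        "rates": {lv: counts[lv][0] / counts[lv][1] for lv in levels},
        "counts": counts,
        "fisher_p": float(p),
    }
    if ici_scores is not None:
        scores = ici_scores.reindex(resp.index)
        stat, rp = rank_tests(scores.to_numpy(), responder.to_numpy())
        out["responder_ranksum_stat"] = stat
        out["responder_ranksum_p"] = rp
    return out
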