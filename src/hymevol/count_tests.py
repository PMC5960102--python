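"""Chi-squared machinery for count comparisons and term overrepresentation.

Covers the recurring statistical needs of the comparative analyses:
goodness-of-fit of place counts against an equal-probability null, 2x2
tests with Yates continuity correction for pairwise species comparisons,
all-pairs post-hoc testing with multiple-testing adjustment, and
hypergeometric term-enrichment with Benjamini-Hochberg control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_P_FLOOR = np.nextafter(0, 1)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float
    correction: str = "none"
    comparison: str = ""

    def __post_init__(self):
        if not 0 < self.p <= 1:
            raise ValueError(f"p out of (0, 1]: {self.p}")


def chisq_gof(observed, expected_proportions=None, comparison: str = "") -> TestResult:
    """Pearson goodness-of-fit test of observed counts against proportions.

    ``expected_proportions`` defaults to uniform; expected counts must all
    be positive.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("need >= 2 observed cells")
    if (obs < 0).any():
        raise ValueError("negative counts")
    n = obs.sum()
    if expected_proportions is None:
        props = np.full(obs.size, 1.0 / obs.size)
    else:
        props = np.asarray(expected_proportions, dtype=float)
        if props.size != obs.size:
            raise ValueError("proportions length mismatch")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
    expected = n * props
    if (expected <= 0).any():
        raise ValueError("zero expected cell")
    stat, p = stats.chisquare(obs, f_exp=expected)
    return TestResult(float(stat), obs.size - 1, max(float(p), _P_FLOOR),
                      "none", comparison)


def chisq_2x2(table, continuity_correction: bool = True, comparison: str = "") -> TestResult:
    """2x2 chi-squared test of independence (Yates-corrected by default)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: test undefined")
    stat, p, df, _ = stats.chi2_contingency(t, correction=continuity_correction)
    label = "yates" if continuity_correction else "none"
    return TestResult(float(stat), int(df), max(float(p), _P_FLOOR), label, comparison)


def pairwise_posthoc(
    successes,
    totals,
    labels=None,
    correction_method: str = "fdr_bh",
    continuity_correction: bool = True,
) -> list[TestResult]:
    """All pairwise success-vs-failure 2x2 tests with adjusted p-values.

    Mirrors the post-hoc decomposition of a multi-group chi-squared test:
    each pair of groups is compared with a (corrected) 2x2 test of its
    success and failure counts, and the p-values are jointly adjusted by
    ``correction_method`` ("fdr_bh", "bonferroni" or "none").
    """
    succ = np.asarray(successes, dtype=float)
    tot = np.asarray(totals, dtype=float)
    if succ.size != tot.size or succ.size < 2:
        raise ValueError("need matched successes/totals for >= 2 groups")
    if (succ > tot).any():
        raise ValueError("successes exceed totals")
    if labels is None:
        labels = [f"group{i}" for i in range(succ.size)]
    if correction_method not in {"fdr_bh", "bonferroni", "none"}:
        raise ValueError(f"unknown correction method {correction_method!r}")
    raw = []
    pairs = []
    for i in range(succ.size):
        for j in range(i + 1, succ.size):
            table = [
                [succ[i], tot[i] - succ[i]],
                [succ[j], tot[j] - succ[j]],
            ]
            res = chisq_2x2(
                table,
                continuity_correction=continuity_correction,
                comparison=f"{labels[i]} vs {labels[j]}",
            )
            raw.append(res)
            pairs.append((i, j))
    pvals = np.array([r.p for r in raw])
    if correction_method == "none":
        adj = pvals
    else:
        adj = multipletests(pvals, method=correction_method)[1]
    return [
        TestResult(r.statistic, r.df, min(max(float(pa), _P_FLOOR), 1.0),
                   correction_method, r.comparison)
        for r, pa in zip(raw, adj)
    ]


def term_enrichment(
    study_ids,
    population_ids,
    term_map: dict,
    alpha: float = 0.05,
    correction_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of annotation terms in a study set.

    For each term the upper-tail hypergeometric probability of seeing at
    least the observed number of study genes carrying it is computed
    against the population background; p-values are adjusted jointly.
    Returns a DataFrame (term, study_count, pop_count, p, p_adj, enriched)
    sorted by adjusted p, where ``enriched`` marks terms below ``alpha``.
    """
    study = set(study_ids)
    pop = set(population_ids)
    if not study <= pop:
        raise ValueError(f"study ids outside population: {sorted(study - pop)[:5]}")
    terms = sorted({t for g in pop for t in term_map.get(g, ())})
    rows = []
    M, n = len(pop), len(study)
    for term in terms:
        carriers = {g for g in pop if term in term_map.get(g, ())}
        K = len(carriers)
        k = len(carriers & study)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append((term, k, K, min(max(p, _P_FLOOR), 1.0)))
    df = pd.DataFrame(rows, columns=["term", "study_count", "pop_count", "p"])
    if len(df):
        if correction_method == "none":
            df["p_adj"] = df["p"]
        else:
            df["p_adj"] = multipletests(df["p"], method=correction_method)[1]
        df["enriched"] = df["p_adj"] < alpha
        df = df.sort_values(["p_adj", "p", "term"], kind="stable").reset_index(drop=True)
    else:
        df["p_adj"] = []
        df["enriched"] = []
    return df
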