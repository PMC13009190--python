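"""Parcel-averaged statistics: hemisphere handling, age correlations, and
nested-model F-tests with false-discovery-rate control.

The central container is the long-format metric table with one row per
(participant, hemisphere, parcel, metric): columns ``participant``,
``age``, ``sex``, ``hemisphere``, ``parcel``, ``metric``, ``value``.

Analysis order follows the study design: hemisphere x age interactions
are tested first; when non-significant, hemispheres are averaged within
participant before any parcel-level statistic.  Age associations are
two-sided Pearson correlations with a significance ladder at 0.01 /
0.005 / 0.0005 (the 0.01 floor being the Bonferroni per-test alpha for
five subfield tests at family-wise 0.05).  Slope differences across sex,
hemisphere, or parcel are tested by comparing a full and a reduced
linear model with an F-test; p-values are Benjamini-Hochberg adjusted
within each declared metric family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "METRIC_TABLE_COLUMNS",
    "validate_metric_table",
    "hemisphere_average",
    "CorrelationResult",
    "age_correlation",
    "significance_stars",
    "bonferroni_alpha",
    "FTestResult",
    "nested_f_test",
    "hemisphere_interaction_tests",
    "fdr_bh",
]

METRIC_TABLE_COLUMNS = ("participant", "age", "sex", "hemisphere",
                        "parcel", "metric", "value")

# asterisk ladder: p < 0.01 (*), < 0.005 (**), < 0.0005 (***)
SIGNIFICANCE_LADDER = (0.01, 0.005, 0.0005)


def bonferroni_alpha(n_tests: int = 5, family_wise: float = 0.05) -> float:
    """Per-test alpha controlling the family-wise rate over ``n_tests``
    (0.05 / 5 = 0.01 for the five-subfield family)."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return family_wise / n_tests


def significance_stars(p: float) -> str:
    if p < SIGNIFICANCE_LADDER[2]:
        return "***"
    if p < SIGNIFICANCE_LADDER[1]:
        return "**"
    if p < SIGNIFICANCE_LADDER[0]:
        return "*"
    return "ns"


def validate_metric_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(METRIC_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"metric table missing columns {missing}")
    if table[["age", "sex"]].isna().any().any():
        raise ValueError("metric table has missing ages or sexes")
    key = ["participant", "hemisphere", "parcel", "metric"]
    if table.duplicated(subset=key).any():
        raise ValueError("metric table has duplicate key rows")
    return table


# --------------------------------------------------------------------------
# Hemisphere handling
# --------------------------------------------------------------------------

def hemisphere_average(table: pd.DataFrame,
                       interaction_results: pd.DataFrame | None = None,
                       alpha: float = 0.05,
                       force: bool = False) -> pd.DataFrame:
    """Average left/right hemisphere values within participant.

    Averaging is applied per metric only when its hemisphere x age
    interaction is non-significant (``interaction_results`` from
    :func:`hemisphere_interaction_tests`, compared at ``alpha`` on the
    adjusted p); metrics with a significant interaction keep both
    hemisphere rows.  With no interaction results (or ``force=True``) all
    metrics are averaged.  Participants missing a hemisphere for a metric
    are excluded from that metric with a log note.
    """
    import logging
    logger = logging.getLogger(__name__)
    validate_metric_table(table)
    keep_split = set()
    if interaction_results is not None and not force:
        sig = interaction_results[interaction_results["p_adj"] < alpha]
        keep_split = set(sig["metric"])
    out = []
    for metric, sub in table.groupby("metric", sort=False):
        if metric in keep_split:
            out.append(sub)
            continue
        counts = sub.groupby(["participant", "parcel"])["hemisphere"] \
            .nunique()
        incomplete = counts[counts < 2].index
        if len(incomplete):
            logger.info("hemisphere_average: excluding %d incomplete "
                        "participant-parcels for %s", len(incomplete), metric)
            bad = set(incomplete)
            sub = sub[~sub.set_index(["participant", "parcel"]).index
                      .isin(bad)]
        agg = (sub.groupby(["participant", "age", "sex", "parcel", "metric"],
                           sort=False, as_index=False)["value"].mean())
        agg["hemisphere"] = "LR"
        out.append(agg[list(table.columns)])
    return pd.concat(out, ignore_index=True)


# --------------------------------------------------------------------------
# Pearson age correlations
# --------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    parcel: str
    metric: str
    r: float
    p: float
    n: int
    stars: str


def age_correlation(table: pd.DataFrame, parcel: str,
                    metric: str) -> CorrelationResult:
    """Two-sided Pearson correlation between age and a parcel metric."""
    sub = table[(table["parcel"] == parcel) & (table["metric"] == metric)]
    if len(sub) < 3:
        raise ValueError("need at least 3 participants")
    x = sub["age"].to_numpy(float)
    y = sub["value"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(parcel=parcel, metric=metric, r=float(r),
                             p=float(p), n=len(sub),
                             stars=significance_stars(float(p)))


def age_correlation_table(table: pd.DataFrame) -> pd.DataFrame:
    """All (parcel, metric) age correlations as a tidy frame.

    Degenerate cells (zero variance, fewer than 3 rows) are skipped with
    a log note rather than failing the whole table.
    """
    import logging
    logger = logging.getLogger(__name__)
    rows = []
    for (parcel, metric), _ in table.groupby(["parcel", "metric"],
                                             sort=False):
        try:
            res = age_correlation(table, parcel, metric)
        except ValueError as exc:
            logger.info("skipping %s/%s: %s", parcel, metric, exc)
            continue
        rows.append(vars(res))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Nested-model F-tests
# --------------------------------------------------------------------------

@dataclass
class FTestResult:
    metric: str
    term: str
    f: float
    df_num: int
    df_den: int
    p: float
    p_adj: float = np.nan
    sse_full: float = np.nan
    sse_reduced: float = np.nan

    def __post_init__(self):
        if self.df_num <= 0 or self.df_den <= 0:
            raise ValueError("degrees of freedom must be positive")


def _terms_to_formula(terms) -> str:
    return "value ~ " + " + ".join(terms)


def nested_f_test(table: pd.DataFrame, full_terms, reduced_terms,
                  metric: str | None = None) -> FTestResult:
    """F-test between a full and a reduced linear model.

    Terms are model-formula fragments (e.g. ``["age", "C(parcel)", "sex",
    "age:C(parcel)", "sex:C(parcel)", "age:sex"]``); categoricals use
    treatment coding with alphabetical reference levels.  The statistic is
    F = ((SSE_red - SSE_full) / d_num) / (SSE_full / d_den) with the
    degrees of freedom taken from the fitted designs.  A full model that
    fits perfectly (SSE = 0) while the reduced does not yields infinite F
    with a warning.
    """
    if not set(reduced_terms) < set(full_terms):
        raise ValueError("reduced terms must be a strict subset of full")
    data = table if metric is None else table[table["metric"] == metric]
    full = smf.ols(_terms_to_formula(full_terms), data=data).fit()
    red = smf.ols(_terms_to_formula(reduced_terms), data=data).fit()
    if full.df_model <= red.df_model:
        raise ValueError("full model does not add parameters (rank "
                         "deficiency or identical designs)")
    df_num = int(full.df_model - red.df_model)
    df_den = int(full.df_resid)
    sse_full = float(full.ssr)
    sse_red = float(red.ssr)
    # numerically-zero residual: an exact fit up to float rounding
    zero_tol = 1e-12 * max(float(full.centered_tss), 1e-300)
    if sse_full <= zero_tol:
        import warnings
        if sse_red > 0:
            warnings.warn("full model fits perfectly; F is infinite",
                          RuntimeWarning)
            f = np.inf
            p = 0.0
        else:
            warnings.warn("both models fit perfectly; F undefined, "
                          "reported as 0", RuntimeWarning)
            f = 0.0
            p = 1.0
    else:
        f = ((sse_red - sse_full) / df_num) / (sse_full / df_den)
        p = float(stats.f.sf(f, df_num, df_den))
    term = ", ".join(sorted(set(full_terms) - set(reduced_terms)))
    name = metric if metric is not None else \
        (data["metric"].iloc[0] if "metric" in data else "")
    return FTestResult(metric=name, term=term, f=float(f), df_num=df_num,
                       df_den=df_den, p=p, sse_full=sse_full,
                       sse_reduced=sse_red)


# the three interaction families examined in the study design
INTERACTION_TERMS = {
    "age:sex": (["age", "C(parcel)", "sex", "age:C(parcel)",
                 "sex:C(parcel)", "age:sex"],
                ["age", "C(parcel)", "sex", "age:C(parcel)",
                 "sex:C(parcel)"]),
    "age:hemisphere": (["age", "C(parcel)", "hemisphere", "sex",
                        "age:C(parcel)", "age:hemisphere"],
                       ["age", "C(parcel)", "hemisphere", "sex",
                        "age:C(parcel)"]),
    "age:parcel": (["age", "C(parcel)", "sex", "sex:C(parcel)",
                    "age:C(parcel)"],
                   ["age", "C(parcel)", "sex", "sex:C(parcel)"]),
}


def interaction_f_tests(table: pd.DataFrame, interaction: str,
                        metrics=None) -> pd.DataFrame:
    """One nested F-test per metric for a named interaction family, with
    Benjamini-Hochberg adjustment across the family's metrics."""
    if interaction not in INTERACTION_TERMS:
        raise ValueError(f"unknown interaction {interaction!r}")
    full, red = INTERACTION_TERMS[interaction]
    metrics = list(metrics) if metrics is not None \
        else list(table["metric"].unique())
    results = [nested_f_test(table, full, red, metric=m) for m in metrics]
    padj = fdr_bh(np.array([r.p for r in results]))
    for r, pa in zip(results, padj):
        r.p_adj = float(pa)
    return pd.DataFrame([vars(r) for r in results])


def hemisphere_interaction_tests(table: pd.DataFrame,
                                 metrics=None) -> pd.DataFrame:
    """Age x hemisphere interaction per metric (decides averaging)."""
    return interaction_f_tests(table, "age:hemisphere", metrics=metrics)


# --------------------------------------------------------------------------
# FDR
# --------------------------------------------------------------------------

def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one family."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
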