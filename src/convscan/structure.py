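"""Structural context of predicted adaptive sites.

Relates per-site calls to predicted flexibility (B-factor profile),
secondary structure class and solvent exposure class: ordered quantile
normalisation of the B-factor, two-way Type III ANOVA on adaptiveness
factors, and exact conditional contingency tests where the expected counts
come from the predicted non-adaptive sites.  Unresolved, below-threshold and
gap-skipped sites are excluded from every contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm, rankdata

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import SiteReport

__all__ = [
    "StructureAnnotation",
    "read_annotation",
    "ordered_quantile_normalize",
    "bfactor_anova",
    "exact_contingency_test",
    "compare_site_context",
]

SS_CLASSES = ("helix", "sheet", "coil")
EXPOSURE_CLASSES = ("exposed", "interface", "buried")


@dataclass
class StructureAnnotation:
    site_index: int
    ss_class: str
    exposure_class: str
    bfactor: float

    def __post_init__(self):
        if self.ss_class not in SS_CLASSES:
            raise ValueError(f"invalid secondary structure class {self.ss_class!r}")
        if self.exposure_class not in EXPOSURE_CLASSES:
            raise ValueError(f"invalid exposure class {self.exposure_class!r}")
        if not np.isfinite(self.bfactor):
            raise ValueError("bfactor must be finite")


def read_annotation(path: str | Path) -> list[StructureAnnotation]:
    """Annotation TSV: site, ss_class, exposure_class, bfactor ('#' comments)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["site", "ss_class", "exposure_class", "bfactor"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"annotation must have columns {required}")
    return [
        StructureAnnotation(int(r.site), r.ss_class, r.exposure_class, float(r.bfactor))
        for r in df.itertuples()
    ]


def ordered_quantile_normalize(values) -> np.ndarray:
    """Rank-based inverse normal transform.

    The value of (average, for ties) rank r among n maps to the standard
    normal quantile at (r - 0.5) / n, so the output is monotone in the input
    and invariant to any monotone transformation of it.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    ranks = rankdata(values, method="average")
    return norm.ppf((ranks - 0.5) / len(values))


def bfactor_anova(
    annotations: list[StructureAnnotation],
    depth_adaptive: set[int],
    temp_adaptive: set[int],
) -> pd.DataFrame:
    """Two-way Type III ANOVA of normalised B-factor on adaptiveness factors.

    Model: normalised bfactor ~ depth * temperature with sum-to-zero
    contrasts; returns one row per term with sum_sq, df, F and p.
    """
    df = pd.DataFrame(
        {
            "bfactor": [a.bfactor for a in annotations],
            "depth": [
                "yes" if a.site_index in depth_adaptive else "no" for a in annotations
            ],
            "temperature": [
                "yes" if a.site_index in temp_adaptive else "no" for a in annotations
            ],
        }
    )
    for factor in ("depth", "temperature"):
        counts = df[factor].value_counts()
        for level in ("yes", "no"):
            if counts.get(level, 0) < 2:
                raise ValueError(
                    f"factor {factor!r} level {level!r} has fewer than 2 sites"
                )
    df["qnorm_bfactor"] = ordered_quantile_normalize(df["bfactor"].to_numpy())
    model = smf.ols(
        "qnorm_bfactor ~ C(depth, Sum) * C(temperature, Sum)", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=3)
    table = table.rename(
        index={
            "C(depth, Sum)": "depth",
            "C(temperature, Sum)": "temperature",
            "C(depth, Sum):C(temperature, Sum)": "depth:temperature",
        }
    )
    return table


# ---------------------------------------------------------------------------
# Exact conditional contingency tests


def _log_table_prob(table: np.ndarray, logfact_margin: float) -> float:
    return float(logfact_margin - gammaln(table + 1.0).sum())


def exact_contingency_test(table, max_total: int = 500) -> float:
    """Two-sided exact conditional p-value for an r x c count table.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed table
    (relative tolerance 1e-12 on the comparison).  This is Fisher's exact
    test generalised to r x c.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin in contingency table")
    total = int(table.sum())
    if total > max_total:
        raise ValueError(
            f"table total {total} exceeds {max_total}; use the Monte Carlo option"
        )

    # log P(T) = log[ prod(rows!) prod(cols!) / (N! prod(cells!)) ]
    logfact_margin = float(
        gammaln(rows + 1.0).sum() + gammaln(cols + 1.0).sum() - gammaln(total + 1.0)
    )
    log_p_obs = _log_table_prob(table, logfact_margin)

    r, c = table.shape
    log_p_sum = []

    def enumerate_tables(cell: int, remaining_rows, remaining_cols, partial_logfact):
        i, j = divmod(cell, c)
        if i == r - 1:
            # last row forced by column margins
            if j == 0:
                if np.any(remaining_cols < 0):
                    return
                lp = partial_logfact - gammaln(remaining_cols + 1.0).sum()
                # 1e-12 additive on the log scale ~ 1e-12 relative on probability
                if lp <= log_p_obs + 1e-12:
                    log_p_sum.append(lp)
                return
            raise AssertionError
        if j == c - 1:
            # last cell of row forced by row margin
            v = remaining_rows[i]
            if v < 0 or v > remaining_cols[j]:
                return
            rr = remaining_rows.copy()
            rr[i] = 0
            cc = remaining_cols.copy()
            cc[j] -= v
            enumerate_tables((i + 1) * c, rr, cc, partial_logfact - gammaln(v + 1.0))
            return
        hi = min(remaining_rows[i], remaining_cols[j])
        for v in range(int(hi) + 1):
            rr = remaining_rows.copy()
            rr[i] -= v
            cc = remaining_cols.copy()
            cc[j] -= v
            enumerate_tables(cell + 1, rr, cc, partial_logfact - gammaln(v + 1.0))

    enumerate_tables(0, rows.copy(), cols.copy(), logfact_margin)
    p = float(np.exp(np.array(log_p_sum)).sum())
    return min(p, 1.0)


def monte_carlo_contingency_test(
    table, n_samples: int, rng: np.random.Generator
) -> float:
    """Monte Carlo version of the exact test for large tables."""
    table = np.asarray(table, dtype=np.int64)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin in contingency table")
    total = int(table.sum())
    logfact_margin = float(
        gammaln(rows + 1.0).sum() + gammaln(cols + 1.0).sum() - gammaln(total + 1.0)
    )
    log_p_obs = _log_table_prob(table, logfact_margin)
    # sample tables with fixed margins by permutation
    row_labels = np.repeat(np.arange(len(rows)), rows)
    col_labels = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    for _ in range(n_samples):
        perm = rng.permutation(col_labels)
        sampled = np.zeros_like(table)
        np.add.at(sampled, (row_labels, perm), 1)
        if _log_table_prob(sampled, logfact_margin) <= log_p_obs + 1e-12:
            hits += 1
    return (hits + 1) / (n_samples + 1)


def compare_site_context(
    report: SiteReport, annotations: list[StructureAnnotation]
) -> dict[str, dict]:
    """Exact tests of structural-class composition, adaptive vs non-adaptive.

    Builds one (2 x classes) table per context axis (secondary structure,
    exposure).  The comparison group is every site predicted non-adaptive,
    i.e. bootstrap ``non_adaptive`` calls together with ``below_threshold``
    sites; unresolved and gap-skipped sites are omitted (their status is a
    sampling artifact).  Classes absent from both groups are dropped before
    testing.  Returns per-axis the table (as a DataFrame) and its exact
    p-value.
    """
    calls = report.calls()
    adaptive = [a for a in annotations if calls.get(a.site_index) == "adaptive"]
    non_adaptive = [
        a for a in annotations
        if calls.get(a.site_index) in ("non_adaptive", "below_threshold")
    ]
    if not adaptive:
        raise ValueError("no adaptive sites to compare")
    if not non_adaptive:
        raise ValueError("no non-adaptive sites to compare")

    results: dict[str, dict] = {}
    for axis, classes in (
        ("ss_class", SS_CLASSES),
        ("exposure_class", EXPOSURE_CLASSES),
    ):
        counts = np.array(
            [
                [sum(1 for a in group if getattr(a, axis) == cls) for cls in classes]
                for group in (adaptive, non_adaptive)
            ],
            dtype=np.int64,
        )
        keep = counts.sum(axis=0) > 0
        trimmed = counts[:, keep]
        kept_classes = [c for c, k in zip(classes, keep) if k]
        p = exact_contingency_test(trimmed)
        results[axis] = {
            "table": pd.DataFrame(
                trimmed, index=["adaptive", "non_adaptive"], columns=kept_classes
            ),
            "p_value": p,
        }
    return results
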