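"""Behavioral indices and factorial statistics.

Two tools used on categorization data: Wagner's unbiased hit rate H_u,
which corrects raw accuracy for response bias (H_u for a stimulus category
is the squared diagonal count divided by the product of the stimulus total
and the response total), and a two-way repeated-measures ANOVA with
Greenhouse-Geisser sphericity correction plus Bonferroni-adjusted pairwise
contrasts, for diagnostic-proportion and H_u designs (expression x body
part, both within subject).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg

__all__ = [
    "ConfusionTable",
    "HuScores",
    "AnovaResult",
    "confusion_table",
    "unbiased_hit_rate",
    "rm_anova_gg",
]


@dataclass
class ConfusionTable:
    """Stimulus x response count matrix."""

    counts: pd.DataFrame  # rows: stimulus category, cols: response category

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")

    @classmethod
    def from_trials(cls, stimulus, response, categories=None) -> "ConfusionTable":
        s = pd.Series(stimulus, dtype=object)
        r = pd.Series(response, dtype=object)
        cats = list(categories) if categories is not None else sorted(set(s) | set(r))
        counts = pd.crosstab(s, r).reindex(index=cats, columns=cats, fill_value=0)
        counts.index.name = "stimulus"
        counts.columns.name = "response"
        return cls(counts=counts)


def confusion_table(stimulus, response, categories=None) -> ConfusionTable:
    """Tabulate trial-level stimulus and response labels."""
    return ConfusionTable.from_trials(stimulus, response, categories)


@dataclass
class HuScores:
    """Per-category unbiased hit rates."""

    scores: pd.Series  # indexed by stimulus category


def unbiased_hit_rate(table: ConfusionTable) -> HuScores:
    """Wagner's H_u: n(s,s)^2 / (row_total(s) * column_total(s)).

    Equivalently the hit rate multiplied by the precision of the matching
    response; a category never chosen as a response scores 0.
    """
    c = table.counts
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    if (row == 0).any():
        missing = row.index[row == 0].tolist()
        raise ValueError(f"no presentations for categories {missing}")
    out = {}
    for cat in c.index:
        n_cc = float(c.loc[cat, cat]) if cat in c.columns else 0.0
        denom = float(row[cat]) * float(col.get(cat, 0.0))
        out[cat] = 0.0 if denom == 0 else n_cc * n_cc / denom
    return HuScores(scores=pd.Series(out))


@dataclass
class AnovaResult:
    """Two-way repeated-measures ANOVA with GG correction and contrasts.

    ``table`` has one row per effect with F, uncorrected and GG-corrected
    degrees of freedom and p-values, epsilon and partial eta squared.
    ``contrasts`` holds Bonferroni-adjusted pairwise comparisons within
    each factor level (the simple-effects readout used after a significant
    interaction).
    """

    table: pd.DataFrame
    contrasts: pd.DataFrame


def rm_anova_gg(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str,
) -> AnovaResult:
    """Two-way (or one-way) repeated-measures ANOVA on a long-format table.

    Requires a balanced complete within-subject design with at least three
    subjects.  Sphericity is handled with the Greenhouse-Geisser epsilon;
    pairwise contrasts are Bonferroni-adjusted.
    """
    if data[subject].nunique() < 3:
        raise ValueError("need at least 3 subjects")
    cells = data.groupby(within if len(within) > 1 else within[0], observed=True)[dv].count()
    if cells.nunique() != 1:
        raise ValueError("design is unbalanced: unequal cell counts")
    n_cells = int(np.prod([data[f].nunique() for f in within]))
    if len(data) != data[subject].nunique() * n_cells:
        raise ValueError("missing cells in the within-subject design")

    import warnings

    with warnings.catch_warnings():
        # pingouin flags its two-way epsilon as approximate on every call;
        # the approximation is documented here once instead
        warnings.filterwarnings("ignore", message="Epsilon values might be innaccurate")
        aov = pg.rm_anova(
            data=data,
            dv=dv,
            within=within if len(within) > 1 else within[0],
            subject=subject,
            correction=True,
            detailed=True,
            effsize="np2",
        )
    if "ddof1" in aov.columns:  # two-way layout
        table = aov.rename(
            columns={
                "Source": "effect",
                "ddof1": "df1",
                "ddof2": "df2",
                "p_unc": "p_uncorrected",
                "p_GG_corr": "p_gg",
                "np2": "partial_eta_sq",
            }
        )
    else:  # one-way layout: effect rows followed by an Error row
        err = aov[aov["Source"] == "Error"].iloc[0]
        table = aov[aov["Source"] != "Error"].rename(
            columns={
                "Source": "effect",
                "DF": "df1",
                "p_unc": "p_uncorrected",
                "p_GG_corr": "p_gg",
                "np2": "partial_eta_sq",
            }
        ).copy()
        table["df2"] = err["DF"]
    table["df1_gg"] = table["df1"] * table["eps"]
    table["df2_gg"] = table["df2"] * table["eps"]

    contrasts = pg.pairwise_tests(
        data=data,
        dv=dv,
        within=within if len(within) > 1 else within[0],
        subject=subject,
        padjust="bonf",
    )
    return AnovaResult(table=table, contrasts=contrasts)
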