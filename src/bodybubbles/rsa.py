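"""Representational similarity analysis: RDMs, candidate models, inference.

The 12 experimental conditions cross 3 expressions (anger, fear, neutral)
with 4 body-part types (whole body, torso with arms, legs, head).  A true
RDM is 1 minus the Pearson correlation between condition response
patterns.  Seven candidate models predict the dissimilarity structure:

``body_separate``      each part type is its own category (0/1);
``body_pattern1``      whole body and torso-with-arms share a category;
``emotion_separate``   each expression is its own category (0/1);
``emotion_pattern1``   expressions distinguished only among whole-body /
                       torso-with-arms conditions;
``body_pattern2``      ranked part-pair tiers (closest: torso-whole body
                       and torso-legs; then legs-whole body, head-torso,
                       head-legs; farthest: whole body-head);
``emotion_pattern2``   body_pattern2 with the whole-body / torso-with-arms
                       cells refined by emotion (ranks 0-6), the remaining
                       tiers shifted to ranks 7 and 8;
``random``             symmetric uniform noise (seeded).

Rank models are normalized to [0, 1] before comparison.  Model-to-data
relatedness uses Kendall's tau-a (no tie correction) with one-sided
Wilcoxon signed-rank tests across subjects; model pairs are compared with
two-sided signed-rank tests; both families are FDR-controlled
(Benjamini-Hochberg).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RDM",
    "ModelComparison",
    "OverlapResult",
    "EXPRESSIONS",
    "PARTS",
    "default_conditions",
    "true_rdm",
    "group_rdm",
    "candidate_rdms",
    "kendall_tau_a",
    "relatedness_test",
    "pairwise_model_test",
    "fdr_correct",
    "mds_2d",
    "dendrogram",
    "dice_overlap",
    "compare_models",
    "rdms_from_table",
]

EXPRESSIONS = ("anger", "fear", "neutral")
PARTS = ("whole_body", "torso_with_arms", "legs", "head")


def default_conditions() -> list[tuple[str, str]]:
    """The 12-condition design in canonical order (part-major)."""
    return [(e, p) for p in PARTS for e in EXPRESSIONS]


@dataclass
class RDM:
    """A condition x condition dissimilarity matrix.

    ``kind`` is "true" for data RDMs (entries in [0, 2], i.e. 1 - r) or
    "candidate" for models (entries rank-normalized to [0, 1]).
    """

    values: np.ndarray
    conditions: list[tuple[str, str]]
    kind: str = "true"
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RDM must be square")
        if v.shape[0] != len(self.conditions):
            raise ValueError("condition labels do not match the matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("RDM diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def lower_triangle(self) -> np.ndarray:
        """Lower-triangle entries (the dissimilarity vector used for tau)."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def reorder(self, conditions: list[tuple[str, str]]) -> "RDM":
        idx = [self.conditions.index(c) for c in conditions]
        return RDM(
            values=self.values[np.ix_(idx, idx)],
            conditions=list(conditions),
            kind=self.kind,
            name=self.name,
        )


def true_rdm(patterns: np.ndarray, conditions, subject=None) -> RDM:
    """True RDM: 1 - Pearson correlation between condition patterns.

    ``patterns`` is (n_conditions, n_units).
    """
    x = np.asarray(patterns, dtype=float)
    if x.ndim != 2:
        raise ValueError("patterns must be a 2-D condition x unit array")
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 conditions and 2 units")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [conditions[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance pattern for condition(s) {bad}")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return RDM(values=d, conditions=list(conditions), kind="true")


def group_rdm(rdms) -> RDM:
    """Entrywise mean of per-subject RDMs (identical condition order required)."""
    rdms = list(rdms)
    if not rdms:
        raise ValueError("no RDMs to average")
    conds = rdms[0].conditions
    for r in rdms[1:]:
        if r.conditions != conds:
            raise ValueError("condition orderings do not match across RDMs")
    return RDM(
        values=np.mean([r.values for r in rdms], axis=0),
        conditions=list(conds),
        kind=rdms[0].kind,
        name="group",
    )


def rdms_from_table(table: pd.DataFrame, value_col: str = "value") -> dict:
    """Per-subject true RDMs from a long table (subject, condition, voxel, value).

    Condition labels are "emotion:part" strings; the output RDMs use the
    canonical condition order.
    """
    conds = default_conditions()
    labels = [f"{e}:{p}" for e, p in conds]
    out = {}
    for subject, df in table.groupby("subject"):
        wide = df.pivot(index="condition", columns="voxel", values=value_col)
        missing = set(labels) - set(wide.index)
        if missing:
            raise ValueError(f"subject {subject} is missing conditions {sorted(missing)}")
        out[subject] = true_rdm(wide.loc[labels].to_numpy(), conds, subject=subject)
    return out


# ---------------------------------------------------------------------------
# candidate models

_EMO_SET = frozenset({"whole_body", "torso_with_arms"})


def _emo_rank(e1: str, e2: str) -> int:
    """0 same emotion, 1 anger-fear, 2 any pair involving neutral."""
    if e1 == e2:
        return 0
    if "neutral" not in (e1, e2):
        return 1
    return 2


def _normalize(m: np.ndarray) -> np.ndarray:
    top = m.max()
    return m / top if top > 0 else m


def candidate_rdms(conditions=None, seed: int = 0) -> dict[str, RDM]:
    """The seven candidate models over the 12-condition design.

    ``seed`` controls the random model only.  All models are returned
    rank-normalized to [0, 1].
    """
    conds = list(conditions) if conditions is not None else default_conditions()
    if sorted(conds) != sorted(default_conditions()):
        raise ValueError("conditions must enumerate the 3 x 4 expression-part design")
    n = len(conds)
    models: dict[str, np.ndarray] = {k: np.zeros((n, n)) for k in (
        "body_separate",
        "body_pattern1",
        "emotion_separate",
        "emotion_pattern1",
        "body_pattern2",
        "emotion_pattern2",
    )}
    # ranked part-pair tiers of body_pattern2
    bp2_tier = {
        frozenset({"torso_with_arms", "whole_body"}): 1,
        frozenset({"torso_with_arms", "legs"}): 1,
        frozenset({"legs", "whole_body"}): 2,
        frozenset({"head", "torso_with_arms"}): 2,
        frozenset({"head", "legs"}): 2,
        frozenset({"whole_body", "head"}): 3,
    }
    for i, (e1, p1) in enumerate(conds):
        for j, (e2, p2) in enumerate(conds):
            if i == j:
                continue
            models["body_separate"][i, j] = 0.0 if p1 == p2 else 1.0
            cat1 = "merged" if p1 in _EMO_SET else p1
            cat2 = "merged" if p2 in _EMO_SET else p2
            models["body_pattern1"][i, j] = 0.0 if cat1 == cat2 else 1.0
            models["emotion_separate"][i, j] = 0.0 if e1 == e2 else 1.0
            if p1 in _EMO_SET and p2 in _EMO_SET:
                models["emotion_pattern1"][i, j] = 0.0 if e1 == e2 else 1.0
            else:
                models["emotion_pattern1"][i, j] = 1.0
            if p1 == p2:
                models["body_pattern2"][i, j] = 0.0
            else:
                models["body_pattern2"][i, j] = bp2_tier[frozenset({p1, p2})]
            # emotion_pattern2: emotion-refined ranks 0-6 inside the
            # whole-body / torso-with-arms cells, then the remaining
            # body_pattern2 tiers shifted to 7 and 8
            if p1 in _EMO_SET and p2 in _EMO_SET:
                rank = 2 * _emo_rank(e1, e2) + (0 if p1 == p2 else 1)
            elif p1 == p2:
                rank = 0
            else:
                tier = bp2_tier[frozenset({p1, p2})]
                rank = {1: 6, 2: 7, 3: 8}[tier]
            models["emotion_pattern2"][i, j] = rank

    rng = np.random.default_rng(seed)
    rand = rng.uniform(0.0, 1.0, size=(n, n))
    rand = np.triu(rand, k=1)
    rand = rand + rand.T
    models["random"] = rand

    return {
        name: RDM(values=_normalize(m), conditions=conds, kind="candidate", name=name)
        for name, m in models.items()
    }


# ---------------------------------------------------------------------------
# inference

def kendall_tau_a(x, y) -> float:
    """Kendall's tau-a: (concordant - discordant) / (n(n-1)/2).

    Ties are counted in the denominator but never as concordant or
    discordant, which is the convention recommended for comparing model
    RDMs that predict tied ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two entries")
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    s = dx[iu] * dy[iu]
    return float(s.sum() / (n * (n - 1) / 2.0))


def relatedness_test(taus) -> float:
    """One-sided Wilcoxon signed-rank p for positive model-data relatedness.

    Exact null distribution for n <= 25 (no ties); an all-zero sample is
    degenerate and returns p = 1.
    """
    taus = np.asarray(taus, dtype=float)
    if len(taus) < 5:
        raise ValueError("need at least 5 subjects")
    if np.all(taus == 0.0):
        return 1.0
    method = "exact" if len(taus) <= 25 else "auto"
    return float(stats.wilcoxon(taus, alternative="greater", method=method).pvalue)


def pairwise_model_test(taus_a, taus_b) -> float:
    """Two-sided Wilcoxon signed-rank p for a paired model-tau difference."""
    a = np.asarray(taus_a, dtype=float)
    b = np.asarray(taus_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tau vectors must be paired by subject")
    d = a - b
    if np.all(d == 0.0):
        return 1.0
    method = "exact" if len(d) <= 25 else "auto"
    return float(stats.wilcoxon(d, alternative="two-sided", method=method).pvalue)


def fdr_correct(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up; returns (flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flags, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return flags, p_adj


@dataclass
class ModelComparison:
    """Result of comparing candidate models against per-subject true RDMs."""

    taus: pd.DataFrame  # subjects x models
    relatedness_p: pd.Series
    relatedness_sig: dict[float, pd.Series] = field(default_factory=dict)
    pairwise_p: pd.DataFrame | None = None
    pairwise_sig: dict[float, pd.DataFrame] = field(default_factory=dict)

    @property
    def mean_taus(self) -> pd.Series:
        return self.taus.mean(axis=0)

    @property
    def best_model(self) -> str:
        return str(self.mean_taus.idxmax())


def compare_models(
    subject_rdms,
    candidates: dict[str, RDM] | None = None,
    q_levels=(0.05, 0.01),
    test: str = "signed-rank",
) -> ModelComparison:
    """Full model-comparison inference for one ROI.

    For each subject and candidate, Kendall's tau-a between the lower
    triangles of the subject's true RDM and the candidate.  Relatedness is
    tested one-sided against zero, model pairs two-sided on paired
    differences; both families are FDR-corrected at each level in
    ``q_levels``.  ``test`` selects "signed-rank" (default) or "t".
    """
    if candidates is None:
        candidates = candidate_rdms()
    if isinstance(subject_rdms, dict):
        subjects = list(subject_rdms)
        rdms = [subject_rdms[s] for s in subjects]
    else:
        rdms = list(subject_rdms)
        subjects = list(range(len(rdms)))
    names = list(candidates)
    cand_vecs = {
        m: candidates[m].reorder(rdms[0].conditions).lower_triangle() for m in names
    }
    taus = pd.DataFrame(
        [
            [kendall_tau_a(r.lower_triangle(), cand_vecs[m]) for m in names]
            for r in rdms
        ],
        index=subjects,
        columns=names,
    )
    if test == "signed-rank":
        rel_p = pd.Series({m: relatedness_test(taus[m].to_numpy()) for m in names})
    elif test == "t":
        rel_p = pd.Series(
            {m: float(stats.ttest_1samp(taus[m], 0.0).pvalue) for m in names}
        )
    else:
        raise ValueError("test must be 'signed-rank' or 't'")

    pair_p = pd.DataFrame(np.nan, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        if test == "signed-rank":
            p = pairwise_model_test(taus[a].to_numpy(), taus[b].to_numpy())
        else:
            p = float(stats.ttest_rel(taus[a], taus[b]).pvalue)
        pair_p.loc[a, b] = pair_p.loc[b, a] = p

    result = ModelComparison(taus=taus, relatedness_p=rel_p, pairwise_p=pair_p)
    iu = np.triu_indices(len(names), k=1)
    pair_vec = pair_p.to_numpy()[iu]
    for q in q_levels:
        flags, _ = fdr_correct(rel_p.to_numpy(), q=q)
        result.relatedness_sig[q] = pd.Series(flags, index=names)
        pflags, _ = fdr_correct(pair_vec, q=q)
        sig = pd.DataFrame(False, index=names, columns=names)
        m = sig.to_numpy()
        m[iu] = pflags
        sig = pd.DataFrame(m | m.T, index=names, columns=names)
        result.pairwise_sig[q] = sig
    return result


# ---------------------------------------------------------------------------
# visualization-support summaries

def mds_2d(rdm: RDM) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates from a dissimilarity matrix.

    Double-centers the squared dissimilarities and keeps the top two
    eigen-dimensions; the sign of each axis is fixed so the first
    condition's coordinate is non-negative.
    """
    d = rdm.values
    n = d.shape[0]
    if n < 3:
        import warnings

        warnings.warn("fewer than 3 conditions: MDS embedding is degenerate")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:2]
    coords = v[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
    for k in range(coords.shape[1]):
        if coords[0, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


def dendrogram(rdm: RDM) -> np.ndarray:
    """Single-linkage (nearest-neighbor) merge tree, as a SciPy linkage matrix."""
    return linkage(squareform(rdm.values, checks=False), method="single")


@dataclass
class OverlapResult:
    """Sorensen-Dice overlap between two binary maps."""

    v1: int
    v2: int
    v_overlap: int
    r_overlap: float


def dice_overlap(map_a: np.ndarray, map_b: np.ndarray) -> OverlapResult:
    """Dice coefficient R = 2 * V_overlap / (V1 + V2); empty-vs-empty gives 0."""
    a = np.asarray(map_a, dtype=bool)
    b = np.asarray(map_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    v1, v2 = int(a.sum()), int(b.sum())
    vo = int((a & b).sum())
    r = 0.0 if v1 + v2 == 0 else 2.0 * vo / (v1 + v2)
    return OverlapResult(v1=v1, v2=v2, v_overlap=vo, r_overlap=r)
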