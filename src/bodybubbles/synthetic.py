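"""Synthetic stimuli, observers and voxel patterns for desk-scale runs.

Real whole-body emotion stimuli and fMRI recordings are not redistributable,
so this module supplies stand-ins with the structural properties the two
analysis arms consume:

* :func:`make_body_set` -- geometric body silhouettes (ellipse head,
  trapezoid torso with arm bars, two leg bars) on a uniform gray
  background, with disjoint part masks and an expression-specific texture
  planted inside a diagnostic sub-region of the torso;
* :func:`make_observer` / :class:`ObserverTemplate` -- a template-matching
  observer whose accuracy rises with the amount of diagnostic content a
  bubble mask reveals;
* :func:`simulate_patterns` -- subject x condition x voxel response tables
  whose pairwise pattern correlations follow a chosen candidate
  dissimilarity model plus independent noise.

Everything is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import rsa as _rsa

__all__ = [
    "SyntheticBody",
    "ObserverTemplate",
    "PatternSpec",
    "EXPRESSIONS",
    "BODY_PARTS",
    "make_body_set",
    "make_observer",
    "observer_respond",
    "simulate_patterns",
]

EXPRESSIONS = ("anger", "fear", "neutral")
#: the four part types of the scanner experiment (whole body plus 3 splits)
BODY_PARTS = ("whole_body", "torso_with_arms", "legs", "head")

BACKGROUND = 128.0
_FILL = 145.0  # silhouette gray level
_TEXTURE_AMP = 55.0  # emotional texture contrast
_NEUTRAL_AMP = 30.0  # diffuse neutral texture contrast


@dataclass
class SyntheticBody:
    """A geometric body image with labeled part masks.

    ``part_masks`` holds three mutually disjoint boolean planes (head,
    torso_with_arms, legs); ``diagnostic_mask`` marks the planted
    expression-diagnostic sub-region (inside the torso for emotional
    expressions, diffuse over the whole silhouette for neutral).
    """

    body_id: str
    actor: int
    emotion: str
    image: np.ndarray
    part_masks: dict[str, np.ndarray]
    diagnostic_mask: np.ndarray

    @property
    def silhouette(self) -> np.ndarray:
        out = np.zeros(self.image.shape, dtype=bool)
        for m in self.part_masks.values():
            out |= m
        return out


def _ellipse(shape, cy, cx, ry, rx) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _actor_geometry(shape: tuple[int, int], jitter: np.ndarray):
    """Part masks for one actor; ``jitter`` perturbs sizes by a few percent."""
    h, w = shape
    j = 1.0 + 0.06 * jitter  # 6 multipliers in [0.94, 1.06]
    head = _ellipse(shape, 0.13 * h, 0.50 * w, 0.075 * h * j[0], 0.10 * w * j[1])

    torso = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[:h, :w]
    top, bot = 0.22 * h, 0.60 * h
    half_top, half_bot = 0.13 * w * j[2], 0.17 * w * j[3]
    frac = np.clip((yy - top) / (bot - top), 0.0, 1.0)
    half = half_top + (half_bot - half_top) * frac
    torso |= (yy >= top) & (yy <= bot) & (np.abs(xx - 0.5 * w) <= half)
    # arm bars flanking the torso
    arm_half = 0.045 * w * j[4]
    for side in (-1.0, 1.0):
        cx = 0.5 * w + side * (half_bot + arm_half + 0.02 * w)
        torso |= (
            (yy >= 0.24 * h)
            & (yy <= 0.58 * h)
            & (np.abs(xx - cx) <= arm_half)
        )

    legs = np.zeros(shape, dtype=bool)
    leg_half = 0.05 * w * j[5]
    for side in (-1.0, 1.0):
        cx = 0.5 * w + side * 0.085 * w
        legs |= (yy >= 0.62 * h) & (yy <= 0.95 * h) & (np.abs(xx - cx) <= leg_half)

    torso &= ~head
    legs &= ~(head | torso)
    return {"head": head, "torso_with_arms": torso, "legs": legs}


def _diagnostic_box(shape: tuple[int, int]) -> np.ndarray:
    """Fixed torso-interior box shared by all actors (emotional expressions)."""
    h, w = shape
    box = np.zeros(shape, dtype=bool)
    box[int(0.28 * h) : int(0.50 * h), int(0.36 * w) : int(0.64 * w)] = True
    return box


def _texture(shape: tuple[int, int], emotion: str) -> np.ndarray:
    """Expression-specific texture plane (same phase for every actor).

    Anger and fear carry mutually orthogonal gratings of 6 px period;
    neutral carries a coarser diagonal grating at lower contrast.
    """
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    if emotion == "anger":
        return _TEXTURE_AMP * np.sin(2.0 * math.pi * xx / 6.0)
    if emotion == "fear":
        return _TEXTURE_AMP * np.sin(2.0 * math.pi * yy / 6.0)
    return _NEUTRAL_AMP * np.sin(2.0 * math.pi * (xx + yy) / 20.0)


def make_body_set(
    n_actors: int = 4,
    expressions=EXPRESSIONS,
    image_size: tuple[int, int] = (310, 245),
    seed: int = 0,
) -> list[SyntheticBody]:
    """Generate ``n_actors`` x ``len(expressions)`` synthetic bodies.

    Emotional bodies carry their texture inside a fixed torso-interior
    diagnostic region; neutral bodies carry a low-contrast texture spread
    over the whole silhouette (their diagnostic mask is the silhouette).
    """
    if n_actors < 1:
        raise ValueError("need at least one actor")
    h, w = image_size
    if h < 64 or w < 64:
        raise ValueError("image too small to contain three body parts (min 64 x 64)")
    rng = np.random.default_rng(seed)
    bodies: list[SyntheticBody] = []
    for actor in range(n_actors):
        jitter = rng.uniform(-1.0, 1.0, size=6)
        parts = _actor_geometry(image_size, jitter)
        silhouette = parts["head"] | parts["torso_with_arms"] | parts["legs"]
        for emotion in expressions:
            image = np.full(image_size, BACKGROUND)
            image[silhouette] = _FILL
            if emotion == "neutral":
                diag = silhouette.copy()
            else:
                diag = _diagnostic_box(image_size) & parts["torso_with_arms"]
            image[diag] += _texture(image_size, emotion)[diag]
            np.clip(image, 0.0, 255.0, out=image)
            bodies.append(
                SyntheticBody(
                    body_id=f"actor{actor:02d}_{emotion}",
                    actor=actor,
                    emotion=emotion,
                    image=image,
                    part_masks={k: v.copy() for k, v in parts.items()},
                    diagnostic_mask=diag,
                )
            )
    return bodies


@dataclass
class ObserverTemplate:
    """Template-matching observer.

    One template plane per expression (the mean background-subtracted
    diagnostic-region content of that expression's bodies).  A response is
    the expression whose template correlates best with the stimulus over
    the template's support, after adding Gaussian internal noise to each
    correlation; with probability ``guess_rate`` the response is replaced
    by a uniform guess.
    """

    templates: dict[str, np.ndarray]
    supports: dict[str, np.ndarray]
    internal_noise_sd: float
    guess_rate: float
    background_level: float = BACKGROUND

    @property
    def expressions(self) -> list[str]:
        return list(self.templates)

    def respond(self, stimulus: np.ndarray, rng: np.random.Generator) -> str:
        return observer_respond(self, stimulus, rng)


def make_observer(
    bodies,
    internal_noise_sd: float = 0.15,
    guess_rate: float = 0.05,
    seed: int = 0,
) -> ObserverTemplate:
    """Build the template observer from a body set.

    The template for expression ``e`` is the mean of
    ``(image - background) * diagnostic_mask`` over the bodies showing
    ``e``; its support is every pixel covered by any of those diagnostic
    masks.  ``seed`` is accepted for interface symmetry (template
    construction itself is deterministic).
    """
    if internal_noise_sd < 0:
        raise ValueError("internal_noise_sd must be non-negative")
    if not 0.0 <= guess_rate <= 1.0:
        raise ValueError("guess_rate must lie in [0, 1]")
    bodies = list(bodies)
    by_expr: dict[str, list[SyntheticBody]] = {}
    for b in bodies:
        by_expr.setdefault(b.emotion, []).append(b)
    for e in EXPRESSIONS:
        if e not in by_expr:
            raise ValueError(f"body set is missing expression {e!r}")
    templates, supports = {}, {}
    for e, group in by_expr.items():
        acc = np.zeros(group[0].image.shape)
        sup = np.zeros(group[0].image.shape, dtype=bool)
        for b in group:
            acc += (b.image - BACKGROUND) * b.diagnostic_mask
            sup |= b.diagnostic_mask
        templates[e] = acc / len(group)
        supports[e] = sup
    return ObserverTemplate(
        templates=templates,
        supports=supports,
        internal_noise_sd=float(internal_noise_sd),
        guess_rate=float(guess_rate),
    )


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def observer_respond(
    observer: ObserverTemplate,
    stimulus: np.ndarray,
    rng: np.random.Generator,
    true_emotion: str | None = None,
) -> str:
    """One simulated categorization response (``true_emotion`` is unused by
    the decision rule and accepted only for logging symmetry)."""
    exprs = observer.expressions
    scores = []
    for e in exprs:
        sup = observer.supports[e]
        r = _corr(
            np.asarray(stimulus, dtype=float)[sup] - observer.background_level,
            observer.templates[e][sup],
        )
        scores.append(r + rng.normal(0.0, observer.internal_noise_sd))
    choice = exprs[int(np.argmax(scores))]
    if observer.guess_rate > 0.0 and rng.random() < observer.guess_rate:
        choice = exprs[rng.integers(len(exprs))]
    return choice


@dataclass
class PatternSpec:
    """Specification for simulated ROI voxel patterns.

    ``generating_model`` names one of the seven candidate dissimilarity
    models; ``signal_scale`` sets the spread of target between-condition
    correlations (r = 1 - signal_scale * model dissimilarity) and
    ``noise_sd`` the per-voxel noise added on top of unit-variance
    condition patterns.
    """

    generating_model: str = "emotion_pattern2"
    n_subjects: int = 20
    n_voxels: int = 200
    n_conditions: int = 12
    signal_scale: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0


def simulate_patterns(spec: PatternSpec) -> pd.DataFrame:
    """Simulate subject x condition x voxel response values.

    Construction: the generating model's rank-normalized dissimilarities
    are mapped affinely to a target correlation matrix
    ``R = 1 - signal_scale * D``.  For each subject, condition mean
    patterns are built as ``M = sqrtm(R) @ Q.T`` with ``Q`` an orthonormal,
    column-centered random basis, so the noise-free patterns realize ``R``
    as their *exact* sample correlation matrix; independent Gaussian noise
    is then added per voxel.  Returns a long table with columns
    ``subject, condition, voxel, value``.
    """
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    candidates = _rsa.candidate_rdms(seed=spec.seed)
    if spec.generating_model not in candidates:
        raise ValueError(
            f"unknown generating model {spec.generating_model!r}; "
            f"choose from {sorted(candidates)}"
        )
    model = candidates[spec.generating_model]
    if spec.n_conditions != len(model.conditions):
        raise ValueError("n_conditions must match the 12-condition design")
    if spec.n_voxels <= spec.n_conditions:
        raise ValueError("need more voxels than conditions")
    d = model.values
    r_target = 1.0 - spec.signal_scale * d
    w, v = np.linalg.eigh(r_target)
    if w.min() < -1e-10:
        raise ValueError(
            "target correlation matrix is not positive semi-definite; "
            "lower signal_scale"
        )
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T

    rng = np.random.default_rng(spec.seed)
    n_c, n_v = spec.n_conditions, spec.n_voxels
    rows = []
    for s in range(spec.n_subjects):
        z = rng.standard_normal((n_v, n_c))
        z -= z.mean(axis=0, keepdims=True)
        q, _ = np.linalg.qr(z)
        m = (root @ q.T) * math.sqrt(n_v)  # rows: unit-variance condition patterns
        if spec.noise_sd > 0:
            m = m + rng.normal(0.0, spec.noise_sd, size=m.shape)
        rows.append(m)
    conds = [f"{e}:{p}" for e, p in model.conditions]
    frames = []
    for s, m in enumerate(rows):
        df = pd.DataFrame(m, index=conds)
        df.index.name = "condition"
        long = df.stack().reset_index()
        long.columns = ["condition", "voxel", "value"]
        long.insert(0, "subject", s)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)
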