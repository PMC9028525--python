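"""Classification images: proportion maps, smoothed z-maps, cluster inference.

The reverse-correlation readout of a Bubbles session: bubble masks are
summed separately for correct and error trials, divided pixelwise into a
proportion image per SF band, smoothed, standardized, and tested for
supra-threshold clusters with the Gaussian random-field cluster-extent
test (the procedure popularized for classification images by the Stat4Ci
toolbox).  Diagnostic summaries report the proportion of significant
pixels per band and per labeled body part.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .bubbles import FWHM_PER_SIGMA, BandSpec, TrialRecord

__all__ = [
    "MaskAccumulator",
    "ProportionImage",
    "ZMap",
    "Cluster",
    "ClusterResult",
    "DiagnosticSummary",
    "accumulate",
    "proportion_image",
    "smooth_plane",
    "smooth_z",
    "cluster_test",
    "diagnostic_proportion_by_band",
    "diagnostic_proportion_by_part",
    "analyze_trials",
    "effective_fwhm_px",
]


@dataclass
class MaskAccumulator:
    """Per-band sums of bubble masks split by response correctness."""

    correct_sum: list[np.ndarray]
    error_sum: list[np.ndarray]
    n_correct: int = 0
    n_error: int = 0

    @property
    def n_bands(self) -> int:
        return len(self.correct_sum)


def accumulate(trials: list[TrialRecord]) -> MaskAccumulator:
    """Sum rendered bubble masks over correct and over error trials."""
    trials = list(trials)
    if not trials:
        raise ValueError("no trials to accumulate")
    first = trials[0].mask
    n_bands = len(first.centers)
    shape = first.shape
    acc = MaskAccumulator(
        correct_sum=[np.zeros(shape) for _ in range(n_bands)],
        error_sum=[np.zeros(shape) for _ in range(n_bands)],
    )
    for t in trials:
        if t.mask.shape != shape or len(t.mask.centers) != n_bands:
            raise ValueError("all trial masks must share the band structure")
        target = acc.correct_sum if t.correct else acc.error_sum
        for k in range(n_bands):
            target[k] += t.mask.render_band(k)
        if t.correct:
            acc.n_correct += 1
        else:
            acc.n_error += 1
    return acc


@dataclass
class ProportionImage:
    """Pixelwise correct / (correct + error) mask proportion, per band.

    Pixels never covered by any bubble are NaN (undefined), not an error.
    """

    planes: list[np.ndarray]

    @property
    def n_bands(self) -> int:
        return len(self.planes)


def proportion_image(acc: MaskAccumulator) -> ProportionImage:
    planes = []
    for c, e in zip(acc.correct_sum, acc.error_sum):
        denom = c + e
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(denom > 0, c / np.where(denom > 0, denom, 1.0), np.nan)
        planes.append(p)
    return ProportionImage(planes=planes)


@dataclass
class ZMap:
    """Smoothed, plane-standardized proportion images."""

    planes: list[np.ndarray]
    sigma_px: float

    @property
    def n_bands(self) -> int:
        return len(self.planes)


def smooth_plane(plane: np.ndarray, sigma_px: float, pad_value: float = 0.0) -> np.ndarray:
    """Gaussian smoothing of one plane (borders padded with ``pad_value``)."""
    return ndimage.gaussian_filter(
        np.asarray(plane, dtype=float), sigma=sigma_px, mode="constant", cval=pad_value
    )


def smooth_z(prop: ProportionImage, sigma_px: float = 8.0) -> ZMap:
    """Gaussian-smooth each proportion plane and standardize it to z scores.

    Undefined (never-sampled) pixels are imputed with the plane's defined
    mean before smoothing, and the border is padded with the same mean so
    edge pixels are damped toward it rather than variance-inflated.
    Standardization uses the plane's own mean and standard deviation; a
    zero-variance plane maps to all zeros.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    planes = []
    for p in prop.planes:
        defined = np.isfinite(p)
        if not defined.any():
            raise ValueError("proportion plane has no sampled pixels")
        mean = p[defined].mean()
        filled = np.where(defined, p, mean)
        sm = smooth_plane(filled, sigma_px, pad_value=mean)
        sd = sm.std()
        planes.append(np.zeros_like(sm) if sd == 0 else (sm - sm.mean()) / sd)
    return ZMap(planes=planes, sigma_px=float(sigma_px))


@dataclass
class Cluster:
    """One supra-threshold cluster and its extent p-value."""

    label: int
    size: int
    p_value: float
    pixels: np.ndarray  # boolean plane


@dataclass
class ClusterResult:
    """Cluster-test outcome for one z plane."""

    sig_mask: np.ndarray
    clusters: list[Cluster]
    t_threshold: float
    alpha: float
    fwhm_px: float


def _rft_cluster_p(size: int, area: float, fwhm_px: float, t: float) -> float:
    """Gaussian random-field cluster-extent p-value in 2-D.

    Expected cluster count from the Euler-characteristic density, expected
    supra-threshold area from the Gaussian tail, exponential approximation
    for the cluster-size distribution, Poisson clumping for the family-wise
    bound (Friston et al.'s cluster-level inference, as used by Stat4Ci).
    """
    e_m = (
        area
        * (4.0 * math.log(2.0))
        * t
        * math.exp(-0.5 * t * t)
        / ((2.0 * math.pi) ** 1.5 * fwhm_px**2)
    )
    e_n = area * stats.norm.sf(t)
    if e_m <= 0 or e_n <= 0:
        return 1.0
    beta = e_m / e_n  # Gamma(D/2+1)^(2/D) * E[m]/E[N] with D = 2
    p_ge = math.exp(-beta * size)
    return float(1.0 - math.exp(-e_m * p_ge))


def cluster_test(
    z: np.ndarray,
    t_threshold: float = 2.7,
    alpha: float = 0.05,
    fwhm_px: float = 8.0 * FWHM_PER_SIGMA,
) -> ClusterResult:
    """Cluster-extent test on one standardized plane.

    Pixels with z > ``t_threshold`` are grouped by 8-connectivity; each
    cluster's family-wise p-value comes from 2-D Gaussian random-field
    theory at the stated smoothness, and clusters with p <= ``alpha`` are
    reported significant.
    """
    z = np.asarray(z, dtype=float)
    # sanity check only: analytically scaled stationary fields have sample
    # moments that fluctuate around (0, 1), so the tolerance is loose
    if abs(float(z.mean())) > 0.5 or abs(float(z.std()) - 1.0) > 0.5:
        if z.std() != 0.0 or z.mean() != 0.0:  # all-zero planes are legal
            raise ValueError("input is not standardized (mean 0, sd 1 expected)")
    labels, n_lab = ndimage.label(z > t_threshold, structure=np.ones((3, 3), dtype=int))
    area = float(z.size)
    clusters: list[Cluster] = []
    sig = np.zeros(z.shape, dtype=bool)
    for lab in range(1, n_lab + 1):
        pix = labels == lab
        size = int(pix.sum())
        p = _rft_cluster_p(size, area, fwhm_px, t_threshold)
        if p <= alpha:
            clusters.append(Cluster(label=lab, size=size, p_value=p, pixels=pix))
            sig |= pix
    return ClusterResult(
        sig_mask=sig,
        clusters=clusters,
        t_threshold=float(t_threshold),
        alpha=float(alpha),
        fwhm_px=float(fwhm_px),
    )


def effective_fwhm_px(smoothing_sigma_px: float, bubble_sigma_px: float = 0.0) -> float:
    """Smoothness (FWHM, px) of a proportion plane after smoothing.

    Both the bubbles themselves and the explicit smoothing kernel are
    Gaussian, so the effective kernel applied to the underlying binomial
    noise is Gaussian with variance equal to the sum of the two.
    """
    return FWHM_PER_SIGMA * math.hypot(smoothing_sigma_px, bubble_sigma_px)


def diagnostic_proportion_by_band(results: list[ClusterResult]) -> np.ndarray:
    """Significant-pixel count / plane size, per SF band."""
    return np.array([r.sig_mask.sum() / r.sig_mask.size for r in results])


def diagnostic_proportion_by_part(
    results: list[ClusterResult], part_masks: dict[str, np.ndarray]
) -> dict[str, float]:
    """Per-part proportion of significant pixels, pooled across bands.

    A pixel counts once if it is significant in any band (the pooled
    significance mask); the denominator is the part's pixel count.
    """
    pooled = np.zeros(results[0].sig_mask.shape, dtype=bool)
    for r in results:
        pooled |= r.sig_mask
    out = {}
    for name, mask in part_masks.items():
        mask = np.asarray(mask, dtype=bool)
        total = int(mask.sum())
        if total == 0:
            raise ValueError(f"part mask {name!r} is empty")
        out[name] = float((pooled & mask).sum() / total)
    return out


def shuffle_null_fwer(
    trials: list[TrialRecord],
    spec: BandSpec,
    band: int = 1,
    n_shuffles: int = 200,
    rng: np.random.Generator | None = None,
    sigma_px: float = 8.0,
    t_threshold: float = 2.7,
    alpha: float = 0.05,
) -> float:
    """Family-wise false-alarm rate of the cluster test under label shuffling.

    Repeatedly permutes the correct/error labels of a trial log, recomputes
    the proportion image of one band, and asks whether the cluster test
    reports any significant cluster.  Under the permutation null there is
    no pixel-response association, so the returned rate estimates the
    test's family-wise error.  ``band`` is a 0-based band index; masks for
    that band are rendered once and reused across shuffles.
    """
    if rng is None:
        rng = np.random.default_rng()
    trials = list(trials)
    n = len(trials)
    if n == 0:
        raise ValueError("no trials")
    planes = np.stack([t.mask.render_band(band) for t in trials]).reshape(n, -1)
    planes = planes.astype(np.float32)
    total = planes.sum(axis=0, dtype=np.float64)
    n_correct = int(sum(t.correct for t in trials))
    fwhm = effective_fwhm_px(sigma_px, spec.sigmas_px[band])
    labels = np.zeros(n, dtype=np.float32)
    labels[:n_correct] = 1.0
    hits = 0
    shape = trials[0].mask.shape
    for _ in range(n_shuffles):
        rng.shuffle(labels)
        correct = (labels @ planes).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(total > 0, correct / np.where(total > 0, total, 1.0), np.nan)
        prop = ProportionImage(planes=[p.reshape(shape)])
        z = smooth_z(prop, sigma_px=sigma_px)
        res = cluster_test(z.planes[0], t_threshold=t_threshold, alpha=alpha, fwhm_px=fwhm)
        hits += bool(res.clusters)
    return hits / n_shuffles


@dataclass
class DiagnosticSummary:
    """Per-band and per-part diagnostic proportions for one analysis."""

    by_band: np.ndarray
    by_part: dict[str, float]
    pooled_sig_mask: np.ndarray
    cluster_results: list[ClusterResult] = field(repr=False, default_factory=list)
    zmap: ZMap | None = field(repr=False, default=None)
    proportion: ProportionImage | None = field(repr=False, default=None)


def analyze_trials(
    trials: list[TrialRecord],
    spec: BandSpec,
    part_masks: dict[str, np.ndarray],
    expression: str | None = None,
    sigma_px: float = 8.0,
    t_threshold: float = 2.7,
    alpha: float = 0.05,
) -> DiagnosticSummary:
    """End-to-end classification-image analysis of a trial log.

    Optionally restricted to trials of one true expression (the analysis
    is normally run per expression; passing a collection pools several,
    e.g. both emotional expressions when they share a diagnostic region).
    The cluster test uses a per-band effective smoothness combining the
    smoothing kernel with that band's bubble size.
    """
    if expression is not None:
        wanted = {expression} if isinstance(expression, str) else set(expression)
        trials = [t for t in trials if t.expression in wanted]
    acc = accumulate(trials)
    prop = proportion_image(acc)
    zmap = smooth_z(prop, sigma_px=sigma_px)
    results = [
        cluster_test(
            zmap.planes[k],
            t_threshold=t_threshold,
            alpha=alpha,
            fwhm_px=effective_fwhm_px(sigma_px, spec.sigmas_px[k]),
        )
        for k in range(zmap.n_bands)
    ]
    pooled = np.zeros(spec.shape, dtype=bool)
    for r in results:
        pooled |= r.sig_mask
    return DiagnosticSummary(
        by_band=diagnostic_proportion_by_band(results),
        by_part=diagnostic_proportion_by_part(results, part_masks),
        pooled_sig_mask=pooled,
        cluster_results=results,
        zmap=zmap,
        proportion=prop,
    )
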