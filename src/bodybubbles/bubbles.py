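"""Bubbles engine: spatial-frequency decomposition, bubble masks, adaptive sessions.

The Bubbles paradigm samples an image through randomly positioned Gaussian
apertures ("bubbles"), independently within each of several one-octave
spatial-frequency (SF) bands, and relates the revealed content to the
observer's categorization response.  This module implements the stimulus
side of the paradigm:

* :func:`band_cutoffs` / :func:`bubble_sigmas` -- the octave band table and
  the per-band bubble sizes (a fixed number of cycles per bubble);
* :func:`decompose_sf` -- a recursive low-pass "peeling" pyramid whose band
  planes sum exactly back to the input;
* :func:`sample_mask` / :func:`compose_stimulus` -- per-band bubble masks
  and the sparse stimulus they reveal;
* :class:`DensityState` / :func:`update_density` -- a per-expression
  multiplicative staircase that holds categorization accuracy at a target;
* :func:`run_session` -- a closed-loop simulated session producing trial
  records for classification-image analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BandSpec",
    "SFBandStack",
    "BubbleMask",
    "DensityState",
    "TrialRecord",
    "band_cutoffs",
    "bubble_sigmas",
    "decompose_sf",
    "sample_mask",
    "compose_stimulus",
    "update_density",
    "split_counts",
    "run_session",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ~2.3548


@dataclass(frozen=True)
class BandSpec:
    """Geometry of the SF-band decomposition and the bubble sizes.

    ``cutoffs_cpi`` holds ``n_bands + 1`` values: the upper cut-off of each
    band followed by the lower bound of the coarsest band, in cycles per
    image width.  Band ``k`` covers ``(cutoffs_cpi[k+1], cutoffs_cpi[k]]``.
    ``sigmas_deg``/``sigmas_px`` are the per-band bubble standard
    deviations, fine to coarse.
    """

    n_bands: int
    width_px: int
    height_px: int
    width_deg: float
    height_deg: float
    cycles_per_bubble: float
    cutoffs_cpi: np.ndarray
    cutoffs_cdeg: np.ndarray
    sigmas_deg: np.ndarray
    sigmas_px: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    @property
    def px_per_deg(self) -> float:
        return self.width_px / self.width_deg


def band_cutoffs(
    width_px: int,
    width_deg: float,
    n_bands: int,
    *,
    height_px: int | None = None,
    height_deg: float | None = None,
    cycles_per_bubble: float = 3.0,
) -> BandSpec:
    """Build the one-octave band table for a stimulus of given size.

    The finest band's upper cut-off is the horizontal Nyquist frequency,
    ``width_px / 2`` cycles per image width (one cycle per 2 x 2 pixels);
    each subsequent cut-off halves it.  Cut-offs in cycles/degree divide by
    the horizontal visual angle.  Bubble sigmas follow from
    ``cycles_per_bubble`` (see :func:`bubble_sigmas`).
    """
    if width_px <= 0 or (height_px is not None and height_px <= 0):
        raise ValueError("image dimensions must be positive")
    if width_deg <= 0:
        raise ValueError("visual angle must be positive")
    if n_bands < 1:
        raise ValueError("need at least one band")
    if height_px is None:
        height_px = width_px
    if height_deg is None:
        height_deg = width_deg * height_px / width_px
    cpi = (width_px / 2.0) * 0.5 ** np.arange(n_bands + 1)
    cdeg = cpi / width_deg
    sig_deg = cycles_per_bubble / cdeg[:n_bands]
    sig_px = sig_deg * (width_px / width_deg)
    return BandSpec(
        n_bands=n_bands,
        width_px=int(width_px),
        height_px=int(height_px),
        width_deg=float(width_deg),
        height_deg=float(height_deg),
        cycles_per_bubble=float(cycles_per_bubble),
        cutoffs_cpi=cpi,
        cutoffs_cdeg=cdeg,
        sigmas_deg=sig_deg,
        sigmas_px=sig_px,
    )


def bubble_sigmas(spec: BandSpec, cycles_per_bubble: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-band bubble standard deviations, in degrees and pixels.

    Each bubble reveals a fixed number of cycles at its band's upper
    cut-off: ``sigma_deg[k] = cycles_per_bubble / cutoff_cdeg[k]``.
    """
    if cycles_per_bubble <= 0:
        raise ValueError("cycles_per_bubble must be positive")
    cdeg = spec.cutoffs_cdeg[: spec.n_bands]
    if np.any(cdeg <= 0):
        raise ValueError("band cut-offs must be positive")
    sig_deg = cycles_per_bubble / cdeg
    sig_px = sig_deg * spec.px_per_deg
    return sig_deg, sig_px


@dataclass
class SFBandStack:
    """Band planes plus the low-pass residual of one image.

    ``background_level`` is subtracted before decomposition, so
    ``background_level + sum(bands) + residual`` reconstructs the source
    exactly (the pyramid is a telescoping sum).
    """

    bands: list[np.ndarray]
    residual: np.ndarray
    background_level: float = 0.0

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def shape(self) -> tuple[int, int]:
        return self.residual.shape

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for b in self.bands:
            out += b
        return out + self.background_level


def _lowpass_gain(shape: tuple[int, int], cutoff_cpi: float, width_px: int) -> np.ndarray:
    """Frequency-domain Gaussian low-pass with half-amplitude at ``cutoff_cpi``.

    Radial frequency is isotropic in cycles/pixel; the cut-off is specified
    on the horizontal axis (cycles per image width).
    """
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.rfftfreq(w)[None, :]
    r2 = fx * fx + fy * fy  # (cycles/px)^2
    fc = cutoff_cpi / width_px
    return np.exp(-math.log(2.0) * r2 / (fc * fc))


def decompose_sf(image: np.ndarray, spec: BandSpec, background_level: float = 0.0) -> SFBandStack:
    """Decompose an image into octave SF bands by recursive low-pass peeling.

    At each level the current plane is split into a low-pass part (Gaussian
    transfer function with half-amplitude at the band's lower cut-off) and
    the band plane that remains; the low-pass part seeds the next level.
    The final low-pass plane is the residual.  Reconstruction is exact.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != spec.shape:
        raise ValueError(f"image shape {image.shape} does not match spec {spec.shape}")
    current = image - background_level
    bands: list[np.ndarray] = []
    for k in range(spec.n_bands):
        gain = _lowpass_gain(current.shape, spec.cutoffs_cpi[k + 1], spec.width_px)
        low = np.fft.irfft2(np.fft.rfft2(current) * gain, s=current.shape)
        bands.append(current - low)
        current = low
    return SFBandStack(bands=bands, residual=current, background_level=float(background_level))


@dataclass
class BubbleMask:
    """Per-band bubble apertures for one trial.

    Stored compactly as bubble center coordinates (row, col floats); the
    aperture planes are rendered on demand by :meth:`render`.  Overlapping
    bubbles combine as a sum clipped at 1, so every plane lies in [0, 1].
    """

    centers: list[np.ndarray]  # per band, (n_k, 2) float arrays
    shape: tuple[int, int]
    sigmas_px: np.ndarray
    trial: int = -1

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(c) for c in self.centers])

    def render(self) -> list[np.ndarray]:
        return [
            _render_band(c, self.shape, s)
            for c, s in zip(self.centers, self.sigmas_px)
        ]

    def render_band(self, k: int) -> np.ndarray:
        return _render_band(self.centers[k], self.shape, self.sigmas_px[k])


def _render_band(centers: np.ndarray, shape: tuple[int, int], sigma_px: float) -> np.ndarray:
    """Sum of unit-peak Gaussians at ``centers``, clipped to 1."""
    h, w = shape
    plane = np.zeros(shape)
    if len(centers) == 0:
        return plane
    radius = int(math.ceil(4.0 * sigma_px))
    inv2s2 = 1.0 / (2.0 * sigma_px * sigma_px)
    for cy, cx in centers:
        y0 = max(0, int(math.floor(cy)) - radius)
        y1 = min(h, int(math.ceil(cy)) + radius + 1)
        x0 = max(0, int(math.floor(cx)) - radius)
        x1 = min(w, int(math.ceil(cx)) + radius + 1)
        gy = np.exp(-((np.arange(y0, y1) - cy) ** 2) * inv2s2)
        gx = np.exp(-((np.arange(x0, x1) - cx) ** 2) * inv2s2)
        plane[y0:y1, x0:x1] += gy[:, None] * gx[None, :]
    np.clip(plane, 0.0, 1.0, out=plane)
    return plane


def sample_mask(counts, spec: BandSpec, rng: np.random.Generator, trial: int = -1) -> BubbleMask:
    """Sample a bubble mask with the given per-band bubble counts.

    Centers are uniform over the full image plane (background included).
    """
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (spec.n_bands,):
        raise ValueError("need one bubble count per band")
    if np.any(counts < 0):
        raise ValueError("bubble counts must be non-negative")
    h, w = spec.shape
    centers = []
    for n in counts:
        c = np.empty((int(n), 2))
        c[:, 0] = rng.uniform(0, h, size=int(n))
        c[:, 1] = rng.uniform(0, w, size=int(n))
        centers.append(c)
    return BubbleMask(centers=centers, shape=spec.shape, sigmas_px=spec.sigmas_px.copy(), trial=trial)


def compose_stimulus(
    stack: SFBandStack,
    mask: BubbleMask | list[np.ndarray],
    background_level: float | None = None,
    clip: tuple[float, float] | None = (0.0, 255.0),
) -> np.ndarray:
    """Compose the sparse stimulus: background + residual + sum(band * mask).

    The low-pass residual is always shown unmasked.  ``background_level``
    defaults to the level stored in the stack.
    """
    planes = mask.render() if isinstance(mask, BubbleMask) else mask
    if len(planes) != stack.n_bands:
        raise ValueError("mask band count does not match the stack")
    bg = stack.background_level if background_level is None else background_level
    out = stack.residual + bg
    scratch = np.empty_like(out)
    for band, plane in zip(stack.bands, planes):
        if plane.shape != band.shape:
            raise ValueError("mask plane shape does not match the band")
        np.multiply(band, plane, out=scratch)
        out += scratch
    if clip is not None:
        np.clip(out, *clip, out=out)
    return out


@dataclass
class DensityState:
    """Per-expression bubble-count controller targeting a fixed accuracy.

    A multiplicative staircase: after each trial of expression ``e`` the
    (continuous) count is multiplied by ``1 + eta * (target - correct)``,
    then clamped to ``bounds``.  Correct responses therefore shrink the
    count and errors grow it; the fixed point of the expected update is the
    bubble count at which accuracy equals ``target``.
    """

    counts: dict[str, float]
    target: float = 0.75
    eta: float = 0.1
    bounds: tuple[float, float] = (1.0, 500.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.target < 1.0:
            raise ValueError("target accuracy must lie in (0, 1)")
        lo, hi = self.bounds
        for e in self.counts:
            self.counts[e] = float(min(max(self.counts[e], lo), hi))

    @classmethod
    def uniform(cls, expressions, initial: float = 40.0, **kw) -> "DensityState":
        return cls(counts={e: float(initial) for e in expressions}, **kw)

    def rounded(self, expression: str) -> int:
        return max(1, int(round(self.counts[expression])))


def update_density(state: DensityState, expression: str, correct: bool) -> DensityState:
    """Apply one staircase update for ``expression``; returns ``state``."""
    if expression not in state.counts:
        raise ValueError(f"unknown expression {expression!r}")
    factor = 1.0 + state.eta * (state.target - (1.0 if correct else 0.0))
    lo, hi = state.bounds
    state.counts[expression] = float(min(max(state.counts[expression] * factor, lo), hi))
    return state


@dataclass
class TrialRecord:
    """One Bubbles trial: what was shown and how it was answered."""

    trial: int
    body_id: str
    expression: str
    response: str
    correct: bool
    mask: BubbleMask
    n_bubbles: int
    band_counts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def split_counts(total: int, spec: BandSpec, rng: np.random.Generator) -> np.ndarray:
    """Allocate a total bubble count across bands.

    Counts are drawn multinomially with weights proportional to
    ``1 / sigma_px**2``, so every band reveals the same expected area per
    trial (the standard Bubbles allocation); a uniform split would let the
    coarse bands' large apertures saturate their mask planes.
    """
    w = 1.0 / spec.sigmas_px**2
    return rng.multinomial(int(total), w / w.sum())


def run_session(
    bodies,
    observer,
    n_trials: int,
    spec: BandSpec,
    controller: DensityState,
    seed: int,
    stacks: dict[str, SFBandStack] | None = None,
    background_level: float = 128.0,
) -> list[TrialRecord]:
    """Run a closed-loop Bubbles session against a simulated observer.

    Bodies are presented equally often (when ``n_trials`` is not a multiple
    of the body count, the remainder is filled with distinct randomly drawn
    bodies) in a globally shuffled order.  Each trial: draw the per-expression bubble
    count from the controller, sample and render a mask, compose the sparse
    stimulus, query the observer, then update the controller from the
    single-trial correctness.
    """
    bodies = list(bodies)
    if not bodies:
        raise ValueError("empty body set")
    rng = np.random.default_rng(seed)
    reps, rem = divmod(n_trials, len(bodies))
    if reps < 1:
        raise ValueError("n_trials smaller than the body count")
    order = np.repeat(np.arange(len(bodies)), reps)
    if rem:
        order = np.concatenate([order, rng.choice(len(bodies), size=rem, replace=False)])
    rng.shuffle(order)
    if stacks is None:
        stacks = {
            b.body_id: decompose_sf(b.image, spec, background_level=background_level)
            for b in bodies
        }
    records: list[TrialRecord] = []
    for t, idx in enumerate(order):
        body = bodies[idx]
        expr = body.emotion
        total = controller.rounded(expr)
        counts = split_counts(total, spec, rng)
        mask = sample_mask(counts, spec, rng, trial=t)
        stimulus = compose_stimulus(stacks[body.body_id], mask)
        response = observer.respond(stimulus, rng)
        correct = response == expr
        update_density(controller, expr, correct)
        records.append(
            TrialRecord(
                trial=t,
                body_id=body.body_id,
                expression=expr,
                response=response,
                correct=correct,
                mask=mask,
                n_bubbles=total,
                band_counts=counts,
            )
        )
    return records
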