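"""Experiment-design enumeration and timing arithmetic.

Stimulus-inventory crossing (actors x expressions x part types), balanced
Bubbles trial schedules with break markers, and the timing of scanner
runs (lead-in, jittered fixation, stimulus, scheduled rests) and of a
block-design localizer.  All durations use exact rational arithmetic
(:class:`fractions.Fraction`), so millisecond-grain totals never drift;
volume counts that do not divide the TR are reported as fractions with a
warning rather than rounded silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "StimulusInventory",
    "RunTiming",
    "enumerate_stimuli",
    "bubbles_session_plan",
    "fmri_run_timing",
    "localizer_timing",
]


@dataclass
class StimulusInventory:
    """The full crossing of actors, expressions and part types."""

    actors: list[int]
    expressions: list[str]
    part_types: list[str]
    stimuli: pd.DataFrame = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.stimuli)


def enumerate_stimuli(n_actors: int, expressions, part_types) -> StimulusInventory:
    """Enumerate actors x expressions x part types with stable ordering."""
    expressions = list(expressions)
    part_types = list(part_types)
    if n_actors < 1 or not expressions or not part_types:
        raise ValueError("inputs must be non-empty")
    if len(set(expressions)) != len(expressions) or len(set(part_types)) != len(part_types):
        raise ValueError("duplicate labels")
    rows = [
        (a, e, p, f"actor{a:02d}_{e}_{p}")
        for a in range(n_actors)
        for e in expressions
        for p in part_types
    ]
    df = pd.DataFrame(rows, columns=["actor", "expression", "part_type", "stimulus_id"])
    return StimulusInventory(
        actors=list(range(n_actors)),
        expressions=expressions,
        part_types=part_types,
        stimuli=df,
    )


def bubbles_session_plan(
    n_bodies: int,
    repetitions: int,
    block_size: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Balanced shuffled trial schedule with a break marker every block.

    Returns a frame with columns ``trial``, ``body``, ``break_after``; a
    break follows every ``block_size`` trials except after the last trial.
    """
    if n_bodies < 1 or repetitions < 1 or block_size < 1:
        raise ValueError("counts must be positive")
    order = np.repeat(np.arange(n_bodies), repetitions)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    n = len(order)
    breaks = [(i + 1) % block_size == 0 and (i + 1) < n for i in range(n)]
    return pd.DataFrame({"trial": np.arange(n), "body": order, "break_after": breaks})


@dataclass
class RunTiming:
    """Timing breakdown of one scanner run."""

    lead_in_s: Fraction
    trial_s: Fraction  # total across trials
    rest_s: Fraction  # total across scheduled rests
    total_s: Fraction
    tr_s: Fraction
    volumes: Fraction
    fractional_volumes: bool

    @property
    def total_seconds(self) -> float:
        return float(self.total_s)


def _volumes(total: Fraction, tr: Fraction) -> tuple[Fraction, bool]:
    vols = total / tr
    fractional = vols.denominator != 1
    if fractional:
        warnings.warn(
            f"run length {total} s is not a whole number of TRs "
            f"({float(vols):g} volumes at TR {tr} s)"
        )
    return vols, fractional


def fmri_run_timing(
    n_trials: int = 108,
    mean_fixation_s=4,
    stim_s=2,
    lead_in_s=6,
    rest_every: int = 36,
    rest_s=10,
    tr_s=2,
) -> RunTiming:
    """Expected duration of one event-related run.

    Lead-in, then ``n_trials`` of (jittered fixation at its mean duration +
    stimulus), with a scheduled rest inserted after every ``rest_every``
    trials (including after the final block, which the printed volume
    count implies).
    """
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    fix = Fraction(mean_fixation_s)
    stim = Fraction(stim_s)
    lead = Fraction(lead_in_s)
    rest = Fraction(rest_s)
    tr = Fraction(tr_s)
    trial_total = n_trials * (fix + stim)
    n_rests = n_trials // rest_every if n_trials else 0
    rest_total = n_rests * rest
    total = lead + trial_total + rest_total
    vols, fractional = _volumes(total, tr)
    return RunTiming(
        lead_in_s=lead,
        trial_s=trial_total,
        rest_s=rest_total,
        total_s=total,
        tr_s=tr,
        volumes=vols,
        fractional_volumes=fractional,
    )


def localizer_timing(
    n_blocks: int = 25,
    images_per_block: int = 14,
    image_s=Fraction(4, 5),
    isi_s=Fraction(1, 5),
    fix_s=1,
    lead_in_s=6,
    gap_s=4,
    tr_s=2,
) -> RunTiming:
    """Duration of the block-design localizer.

    Each block: fixation, then ``images_per_block`` images (one of the 13
    distinct images repeats once, hence 14 presentations) of
    ``image_s + isi_s`` each; one inter-block gap follows every block.
    With the default parameters the total is 481 s (8 min 1 s), which is
    half a TR longer than a whole number of 2-s volumes; the fractional
    volume count is reported as-is.
    """
    if n_blocks < 1 or images_per_block < 1:
        raise ValueError("counts must be positive")
    image = Fraction(image_s)
    isi = Fraction(isi_s)
    fix = Fraction(fix_s)
    lead = Fraction(lead_in_s)
    gap = Fraction(gap_s)
    tr = Fraction(tr_s)
    block = fix + images_per_block * (image + isi)
    total = lead + n_blocks * block + n_blocks * gap
    vols, fractional = _volumes(total, tr)
    return RunTiming(
        lead_in_s=lead,
        trial_s=n_blocks * block,
        rest_s=n_blocks * gap,
        total_s=total,
        tr_s=tr,
        volumes=vols,
        fractional_volumes=fractional,
    )
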