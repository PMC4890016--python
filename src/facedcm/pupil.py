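"""Pupillometry preprocessing and the per-block slow pupil-change metric.

The preprocessing order is fixed: (1) blink spans are replaced by cubic
spline interpolation over neighbouring valid samples, (2) the trace is
z-normalized over the whole session, (3) high-frequency noise is suppressed
by a centered moving-average ("sliding square") window of 50 ms.  Each
block is then summarized by the mean pupil size in a late window 9-11 s
after onset minus the mean over the first 50 ms ("baseline").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

from .paradigm import CONDITIONS, BlockDesign

__all__ = ["PupilTrace", "preprocess", "block_metric", "condition_averages"]

#: Stimulus category and hemifield factors of the condition table.
STIMULI = ("F", "O", "S")
HEMIFIELDS = ("LVF", "RVF")


@dataclass
class PupilTrace:
    """Fixed-rate pupil samples with blink annotations and block onsets.

    ``blink_intervals`` are half-open ``[start_s, end_s)`` spans flagged by
    the tracker; ``block_onsets`` pairs (onset_s, condition).
    """

    samples: np.ndarray
    fs: float = 500.0
    blink_intervals: list[tuple[float, float]] = field(default_factory=list)
    block_onsets: list[tuple[float, str]] = field(default_factory=list)
    session_id: str = ""
    preprocessing: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        dur = self.samples.size / self.fs
        for a, b in self.blink_intervals:
            if not (0 <= a < b <= dur + 1e-9):
                raise ValueError(f"blink interval [{a}, {b}) outside the trace")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def blink_mask(self) -> np.ndarray:
        mask = np.zeros(self.samples.size, dtype=bool)
        for a, b in self.blink_intervals:
            i0 = int(np.ceil(a * self.fs - 1e-9))
            i1 = int(np.ceil(b * self.fs - 1e-9))
            mask[i0:i1] = True
        return mask


def preprocess(trace: PupilTrace, smooth_ms: float = 50.0) -> PupilTrace:
    """Interpolate blinks, z-normalize over the session, box-smooth.

    Blink spans are filled with a cubic spline through the valid samples;
    blinks touching the trace boundaries are extended with the nearest
    valid value first (spline extrapolation is unstable).  Normalization
    uses the mean and s.d. of all (interpolated) samples.  Smoothing is a
    centered moving average of ``smooth_ms`` width (rounded to an odd
    number of samples).
    """
    x = trace.samples.copy()
    mask = trace.blink_mask()
    valid = ~mask
    if not valid.any():
        raise ValueError("no valid (non-blink) samples")
    idx = np.arange(x.size)
    first, last = idx[valid][0], idx[valid][-1]
    if mask[:first].any():
        x[:first] = x[first]
        mask[:first] = False
    if mask[last + 1:].any():
        x[last + 1:] = x[last]
        mask[last + 1:] = False
    valid = ~mask
    if mask.any():
        cs = CubicSpline(idx[valid], x[valid])
        x[mask] = cs(idx[mask])

    sd = x.std()
    if sd <= 0:
        raise ValueError("constant trace: z-normalization undefined (sd = 0)")
    x = (x - x.mean()) / sd

    win = max(1, int(round(smooth_ms / 1000.0 * trace.fs)))
    if win % 2 == 0:
        win += 1
    x = uniform_filter1d(x, size=win, mode="nearest")

    return replace(
        trace, samples=x,
        preprocessing=trace.preprocessing
        + ["interpolate_blinks", "znormalize", f"boxsmooth_{win}samples"],
    )


def _window_mean(trace: PupilTrace, t0: float, t1: float) -> float:
    """Mean over samples with t0 <= k/fs < t1 (half-open, left-aligned)."""
    i0 = int(np.ceil(t0 * trace.fs - 1e-9))
    i1 = int(np.ceil(t1 * trace.fs - 1e-9))
    if i1 > trace.samples.size:
        raise ValueError(
            f"block at {t0:.2f} s truncated: needs samples up to {t1:.2f} s"
        )
    return float(trace.samples[i0:i1].mean())


def block_metric(trace: PupilTrace, onset_s: float,
                 baseline_s: float = 0.05,
                 late_window_s: tuple[float, float] = (9.0, 11.0)) -> float:
    """Slow pupil change of one block: late-window mean minus baseline.

    Mean over [onset+9 s, onset+11 s) minus mean over the first 50 ms of
    the block.  Blocks not extending through the late window are rejected.
    """
    late = _window_mean(trace, onset_s + late_window_s[0],
                        onset_s + late_window_s[1])
    base = _window_mean(trace, onset_s, onset_s + baseline_s)
    return late - base


def condition_averages(
    trace: PupilTrace, design: BlockDesign | None = None
) -> pd.DataFrame:
    """Per-condition mean block metric as a 3 stimulus x 2 hemifield table.

    Block onsets/conditions come from the design when given, else from the
    trace annotations.  Rows are stimulus categories (F, O, S), columns
    hemifields (LVF, RVF) — the layout the 3-way group ANOVA consumes.
    """
    if design is not None:
        blocks = [(b.onset_s, b.condition) for b in design.stimulus_blocks]
    else:
        blocks = list(trace.block_onsets)
    values: dict[str, list[float]] = {c: [] for c in CONDITIONS}
    for onset, cond in blocks:
        if cond not in values:
            continue
        values[cond].append(block_metric(trace, onset))
    missing = [c for c, v in values.items() if not v]
    if missing:
        raise ValueError(f"no blocks for conditions: {missing}")
    table = pd.DataFrame(
        [[np.mean(values[f"{s}_{h}"]) for h in HEMIFIELDS] for s in STIMULI],
        index=list(STIMULI), columns=list(HEMIFIELDS),
    )
    return table
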