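"""ChIP metaprofile aggregation and ChIP-qPCR percent-of-input arithmetic.

Metaprofiles aggregate per-element occupancy tracks in an anchored coordinate
system (anchor = element/GAG start at 0), positionwise sum or mean.  qPCR
recovery expresses the immunoprecipitated signal as a percentage of the total
chromatin via the base-2 Cq relation, with a no-antibody mock subtracted to
give the actual recovery.  The boundary contrast (upstream vs downstream
primer positions) is an unpaired t test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class OccupancyTrack:
    """Occupancy values on an anchored coordinate grid.

    ``start`` is the anchored coordinate of ``values[0]``; the grid step is
    1 bp.  Values must be finite and non-negative.
    """

    element_id: str
    start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError(f"track {self.element_id}: values must be finite and >= 0")

    @property
    def end(self) -> int:
        return self.start + len(self.values)

    def window(self, lo: int, hi: int) -> np.ndarray:
        if lo < self.start or hi > self.end:
            raise ValueError(
                f"track {self.element_id} covers {self.start}..{self.end}, "
                f"window {lo}..{hi} not covered"
            )
        return self.values[lo - self.start : hi - self.start]


@dataclass(frozen=True)
class MetaProfile:
    positions: np.ndarray  # anchored coordinates
    values: np.ndarray
    n_elements: int
    mode: str


@dataclass(frozen=True)
class QpcrSample:
    """One qPCR measurement.

    ``dilution_ratio`` is the fraction of the sheared chromatin the sample
    represents (1.0 for an IP measured neat; e.g. 0.1 for a 10% input).
    """

    cq: float
    role: str  # 'input' | 'ip_plus_ab' | 'ip_no_ab'
    dilution_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.cq <= 0:
            raise ValueError("cq must be > 0")
        if not 0 < self.dilution_ratio <= 1:
            raise ValueError("dilution_ratio must be in (0, 1]")
        if self.role not in {"input", "ip_plus_ab", "ip_no_ab"}:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class RecoveryResult:
    recovery_plus_ab: float
    recovery_no_ab: float
    actual_recovery: float
    below_background: bool


@dataclass(frozen=True)
class ContrastResult:
    ratio_of_means: float
    t_statistic: float
    p_value: float
    tail: str
    equal_var: bool


def anchor_and_aggregate(
    tracks: Sequence[OccupancyTrack],
    mode: str = "sum",
    window: tuple[int, int] | None = None,
) -> MetaProfile:
    """Positionwise sum or mean of anchored occupancy tracks over a window.

    ``window`` is (lo, hi) half-open in anchored coordinates; by default the
    intersection of all tracks.  A track not covering the window raises an
    error naming it.
    """
    if mode not in {"sum", "mean"}:
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    if not tracks:
        lo, hi = window if window else (0, 0)
        return MetaProfile(np.arange(lo, hi), np.zeros(max(hi - lo, 0)), 0, mode)
    if window is None:
        lo = max(t.start for t in tracks)
        hi = min(t.end for t in tracks)
        if hi <= lo:
            raise ValueError("tracks have no common window")
    else:
        lo, hi = window
    mat = np.stack([t.window(lo, hi) for t in tracks])
    agg = mat.sum(axis=0) if mode == "sum" else mat.mean(axis=0)
    return MetaProfile(np.arange(lo, hi), agg, len(tracks), mode)


def percent_recovery(input_sample: QpcrSample, ip_sample: QpcrSample) -> float:
    """Percent of total chromatin recovered by the IP.

    recovery = 2^(Cq_input + log2(dilution_ratio) - Cq_IP) x 100: the input Cq
    is first projected to the Cq of the undiluted chromatin (an input that is
    a fraction d of the material runs log2(d) cycles late), then each cycle
    the IP lags costs a factor of two.
    """
    if input_sample.role != "input":
        raise ValueError("first sample must have role 'input'")
    exponent = (
        input_sample.cq + math.log2(input_sample.dilution_ratio) - ip_sample.cq
    )
    return 100.0 * 2.0**exponent


def actual_recovery(plus_ab: float, no_ab: float) -> RecoveryResult:
    """Background-subtracted recovery; negative results are kept and flagged."""
    actual = plus_ab - no_ab
    return RecoveryResult(plus_ab, no_ab, actual, below_background=actual < 0)


def position_contrast(
    group1: Sequence[float],
    group2: Sequence[float],
    tail: str = "two",
    equal_var: bool = True,
) -> ContrastResult:
    """Unpaired t test between two groups of recoveries.

    ``tail`` 'two' or 'one'; the one-tailed p is for the observed direction.
    Student's equal-variance t by default, Welch with ``equal_var=False``.
    Raises on degenerate (zero) variance in both groups with unequal means,
    where the t statistic is undefined.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if tail not in {"one", "two"}:
        raise ValueError("tail must be 'one' or 'two'")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return ContrastResult(
                _safe_ratio(a.mean(), b.mean()), 0.0, 1.0, tail, equal_var
            )
        raise ValueError("degenerate zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(res.pvalue)
    if tail == "one":
        p = p / 2.0
    return ContrastResult(
        ratio_of_means=_safe_ratio(a.mean(), b.mean()),
        t_statistic=float(res.statistic),
        p_value=p,
        tail=tail,
        equal_var=equal_var,
    )


def _safe_ratio(x: float, y: float) -> float:
    return float(x / y) if y != 0 else float("nan")
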