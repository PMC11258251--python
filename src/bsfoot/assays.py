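"""Transformation-efficiency and reference-normalized expression calculators.

Transformation efficiency compares homologous-recombination integration at two
target positions straddling the boundary: colonies at position 1 over colonies
at position 2, as a percentage.  Expression is quantified relative to the
ACT1 reference transcript by the delta-Cq method (normalization to ACT1 within
condition only; no second, between-condition normalization is applied).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .chromatin import ContrastResult, position_contrast


@dataclass(frozen=True)
class TfAssayCounts:
    colonies_pos1: int
    colonies_pos2: int
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.colonies_pos1 < 0 or self.colonies_pos2 < 0:
            raise ValueError("colony counts must be >= 0")


@dataclass(frozen=True)
class RelExpression:
    target_cq: float
    reference_cq: float
    relative_amount: float


def tf_efficiency(counts: TfAssayCounts) -> float:
    """Transformation efficiency (%) = pos1 colonies / pos2 colonies x 100."""
    if counts.colonies_pos2 == 0:
        raise ZeroDivisionError(
            f"replicate {counts.replicate_id!r}: no colonies at position 2; "
            "efficiency undefined"
        )
    return 100.0 * counts.colonies_pos1 / counts.colonies_pos2


def relative_mrna(target_cq: float, act1_cq: float, efficiency: float = 2.0) -> RelExpression:
    """Target abundance relative to ACT1: efficiency^(Cq_ACT1 - Cq_target)."""
    if target_cq <= 0 or act1_cq <= 0:
        raise ValueError("Cq values must be > 0")
    if efficiency <= 1:
        raise ValueError("efficiency must be > 1")
    return RelExpression(target_cq, act1_cq, efficiency ** (act1_cq - target_cq))


def group_compare(
    group1: Sequence[float],
    group2: Sequence[float],
    tail: str = "two",
    equal_var: bool = True,
) -> ContrastResult:
    """Unpaired t test between two replicate groups (see position_contrast)."""
    return position_contrast(group1, group2, tail=tail, equal_var=equal_var)
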