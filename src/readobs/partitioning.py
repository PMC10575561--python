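"""Unique and shared cross-validated explained variation for two or three
explanation sets, by inclusion-exclusion over the scores of all model
combinations fit on shared folds.

Partitions sum to the joint model's score by construction. Under
cross-validation individual partitions can be negative (overfitting); they
are reported as-is and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PartitionResult:
    labels: tuple[str, ...]
    partitions: dict[str, float]
    joint_score: float

    @property
    def has_negative(self) -> bool:
        return any(v < 0 for v in self.partitions.values())

    def total(self) -> float:
        return sum(self.partitions.values())


def partition_two(
    score_a: float, score_b: float, score_ab: float, labels: tuple[str, str] = ("A", "B")
) -> PartitionResult:
    """Two-set partition: uniques are joint minus the other partial model;
    the intersection is the sum of partials minus the joint."""
    a, b = labels
    parts = {
        f"{a}*": score_ab - score_b,
        f"{b}*": score_ab - score_a,
        f"{a}&{b}": score_a + score_b - score_ab,
    }
    return PartitionResult(labels=tuple(labels), partitions=parts, joint_score=score_ab)


def partition_three(
    score_a: float,
    score_b: float,
    score_c: float,
    score_ab: float,
    score_ac: float,
    score_bc: float,
    score_abc: float,
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> PartitionResult:
    """Three-set partition from the seven model scores: one triple overlap,
    three pairwise overlaps excluding the third set, three uniques."""
    a, b, c = labels
    triple = score_abc + score_a + score_b + score_c - score_ab - score_ac - score_bc
    parts = {
        f"{a}*": score_abc - score_bc,
        f"{b}*": score_abc - score_ac,
        f"{c}*": score_abc - score_ab,
        f"{a}&{b}": score_a + score_b - score_ab - triple,
        f"{a}&{c}": score_a + score_c - score_ac - triple,
        f"{b}&{c}": score_b + score_c - score_bc - triple,
        f"{a}&{b}&{c}": triple,
    }
    return PartitionResult(labels=tuple(labels), partitions=parts, joint_score=score_abc)
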