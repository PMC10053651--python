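"""End-to-end annotation pipeline for one satellite array.

decompose -> pairwise similarity + identical-block merging -> threshold
sweep (Louvain monomers + HTRM + HOR assembly per threshold) -> pick the
coverage-maximising threshold -> score, rank, project.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .decompose import Block, MonomerTemplate, decompose
from .hors import Annotation, annotate_monomer_sequence, select_threshold
from .monomers import ThresholdSchedule, sweep_thresholds
from .similarity import MergedBlockSet, merge_identical

__all__ = ["RunConfig", "PipelineResult", "annotate_array"]


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of a run (similarity thresholds, repeat-unit bound, seed)."""

    min_similarity: float = 0.94
    step: float = 0.005
    max_unit_len: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_similarity < 1.0:
            raise ValueError("min_similarity must be in (0, 1)")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.max_unit_len < 1:
            raise ValueError("max_unit_len must be >= 1")

    @property
    def schedule(self) -> ThresholdSchedule:
        return ThresholdSchedule(t_min=self.min_similarity, step=self.step)


@dataclass
class PipelineResult:
    """Selected annotation plus everything needed to interpret or dump it."""

    annotation: Annotation
    blocks: list[Block]
    merged: MergedBlockSet
    sweep: list[Annotation] = field(repr=False, default_factory=list)


def annotate_array(
    sequence: str,
    template: MonomerTemplate,
    config: RunConfig = RunConfig(),
) -> PipelineResult:
    """Annotate one array sequence with monomers and HORs.

    The threshold sweep stops early once a threshold reaches full HOR
    coverage: no later threshold can exceed it and coverage ties select
    the lowest threshold, so the chosen annotation is unchanged.
    """
    blocks = decompose(sequence, template)
    merged = merge_identical(blocks)
    annotations = []
    for assignment, mono_seq in sweep_thresholds(
        merged, config.schedule, seed=config.seed
    ):
        annotations.append(
            annotate_monomer_sequence(
                mono_seq,
                threshold=assignment.threshold,
                monomer_count=assignment.monomer_count,
                max_unit_len=config.max_unit_len,
            )
        )
        if annotations[-1].coverage >= 1.0 - 1e-12:
            break
    best = select_threshold(annotations)
    return PipelineResult(
        annotation=best, blocks=blocks, merged=merged, sweep=annotations
    )
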