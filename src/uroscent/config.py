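"""Shared configuration and sample metadata for the analysis pipeline.

A study is described by a set of :class:`SampleRecord` entries (which
samples exist, their biopsy cohort, and which assay arms each one entered)
plus a :class:`PipelineConfig` holding every scalar setting used anywhere
downstream, so that a serialized results file together with its config echo
fully determines the numbers it contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

COHORTS = ("cancer", "control")
ASSAYS = ("canine", "gcms", "microbiome")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class FormatError(ValueError):
    """Raised when an on-disk file does not follow its expected layout."""


@dataclass(frozen=True)
class SampleRecord:
    """One study sample: an opaque id, its cohort, and the assays it entered."""

    sample_id: str
    cohort: str
    assays: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be a non-empty string")
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"cohort must be one of {COHORTS}, got {self.cohort!r}"
            )
        bad = set(self.assays) - set(ASSAYS)
        if bad:
            raise ValidationError(f"unknown assays: {sorted(bad)}")


def check_unique_ids(records: Iterable[SampleRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.sample_id in seen:
            raise ValidationError(f"duplicate sample_id {r.sample_id!r}")
        seen.add(r.sample_id)


@dataclass
class PipelineConfig:
    """Scalar settings for every pipeline stage.

    Defaults follow the study protocol this package re-implements: a 3%
    prevalence floor and liberal 0.2 screening cutoff for the VOC arm,
    10-fold cross-validation, rarefaction to 2,700 clean sequences and a
    strict Spearman cutoff of 0.30 for the microbiome arm, and a 205-input,
    32-hidden-node sigmoid network trained with learning rate 0.1 and
    momentum 0.03 to an RMS error of 0.15 for the neural-network arm.
    """

    prevalence_min: float = 0.03
    screen_alpha: float = 0.2
    da_alpha: float = 0.05
    cv_folds: int = 10
    rarefaction_depth: int = 2700
    spearman_cutoff: float = 0.30
    rt_window: tuple[float, float] = (10.0, 14.0)
    n_input: int = 205
    n_hidden: int = 32
    lr: float = 0.1
    momentum: float = 0.03
    rms_target: float = 0.15
    scale_margin: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_min < 1.0:
            raise ValidationError("prevalence_min must lie in (0, 1)")
        lo, hi = self.rt_window
        if not lo < hi:
            raise ValidationError("rt_window must satisfy min < max")
        for name in ("cv_folds", "rarefaction_depth", "n_input", "n_hidden"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.lr <= 0:
            raise ValidationError("lr must be positive")
        if not 0.0 <= self.scale_margin < 0.5:
            raise ValidationError("scale_margin must lie in [0, 0.5)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rt_window"] = list(self.rt_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "rt_window" in d:
            d["rt_window"] = tuple(d["rt_window"])
        return cls(**d)
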