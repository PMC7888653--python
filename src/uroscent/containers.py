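"""In-memory containers shared across the pipeline arms.

Tables are thin wrappers over numpy arrays with explicit id axes rather
than bare DataFrames, so that invariants (non-negative abundances, integer
counts, unique ids, label consistency) are checked once at construction
and every downstream operation can rely on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import COHORTS, ValidationError


@dataclass
class Chromatogram:
    """One sample's total-ion trace: retention times (minutes) vs abundance."""

    retention_times: np.ndarray
    abundances: np.ndarray
    sample_id: str

    def __post_init__(self) -> None:
        self.retention_times = np.asarray(self.retention_times, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.retention_times.shape != self.abundances.shape:
            raise ValidationError("retention times and abundances differ in length")
        if self.retention_times.ndim != 1 or self.retention_times.size < 2:
            raise ValidationError("a chromatogram needs at least two points")
        if not np.all(np.diff(self.retention_times) > 0):
            raise ValidationError("retention times must be strictly increasing")
        if np.any(self.abundances < 0):
            raise ValidationError("abundances must be non-negative")

    def __len__(self) -> int:
        return self.retention_times.size

    @property
    def spacing(self) -> float:
        return float(np.median(np.diff(self.retention_times)))

    def is_uniform(self, tol: float = 1e-6) -> bool:
        d = np.diff(self.retention_times)
        return bool(np.all(np.abs(d - d[0]) <= tol))


def _check_labels(labels, n: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    if labels.shape != (n,):
        raise ValidationError("labels length does not match number of samples")
    bad = set(labels) - set(COHORTS)
    if bad:
        raise ValidationError(f"unknown cohort labels: {sorted(bad)}")
    return labels


@dataclass
class VocTable:
    """Samples × compounds abundance matrix keyed by CAS registry number."""

    sample_ids: list[str]
    compound_ids: list[str]
    abundances: np.ndarray  # shape (n_samples, n_compounds)
    labels: np.ndarray  # "cancer"/"control" per sample

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        n_s, n_c = len(self.sample_ids), len(self.compound_ids)
        if self.abundances.shape != (n_s, n_c):
            raise ValidationError(
                f"abundance matrix shape {self.abundances.shape} does not match "
                f"{n_s} samples x {n_c} compounds"
            )
        if len(set(self.sample_ids)) != n_s:
            raise ValidationError("sample ids must be unique")
        if len(set(self.compound_ids)) != n_c:
            raise ValidationError("compound ids must be unique")
        if np.any(self.abundances < 0):
            raise ValidationError("abundances must be non-negative")
        self.labels = _check_labels(self.labels, n_s)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def select_compounds(self, keep: np.ndarray) -> "VocTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return VocTable(
            sample_ids=list(self.sample_ids),
            compound_ids=[self.compound_ids[i] for i in keep],
            abundances=self.abundances[:, keep],
            labels=self.labels.copy(),
        )

    def select_samples(self, keep: np.ndarray) -> "VocTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return VocTable(
            sample_ids=[self.sample_ids[i] for i in keep],
            compound_ids=list(self.compound_ids),
            abundances=self.abundances[keep, :],
            labels=self.labels[keep],
        )


@dataclass
class TaxaTable:
    """Species × samples integer count table with negative-control flags.

    ``labels`` holds the cohort for true samples and ``None`` for negative
    (blank extraction) controls.
    """

    species_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_species, n_samples), integer
    is_negative_control: np.ndarray  # bool per sample
    labels: np.ndarray  # cohort per sample, None for negative controls

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        n_sp, n_s = len(self.species_ids), len(self.sample_ids)
        if self.counts.shape != (n_sp, n_s):
            raise ValidationError("count matrix shape does not match id axes")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if len(set(self.species_ids)) != n_sp:
            raise ValidationError("species ids must be unique")
        if any(not s for s in self.species_ids):
            raise ValidationError("species names must be non-empty")
        if len(set(self.sample_ids)) != n_s:
            raise ValidationError("sample ids must be unique")
        self.is_negative_control = np.asarray(self.is_negative_control, dtype=bool)
        if self.is_negative_control.shape != (n_s,):
            raise ValidationError("negative-control flags must match samples")
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (n_s,):
            raise ValidationError("labels length does not match samples")
        for flag, lab in zip(self.is_negative_control, self.labels):
            if flag and lab is not None:
                raise ValidationError("negative controls must carry no cohort label")
            if not flag and lab not in COHORTS:
                raise ValidationError(
                    f"true samples need a cohort label in {COHORTS}, got {lab!r}"
                )

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def true_sample_mask(self) -> np.ndarray:
        return ~self.is_negative_control

    def genus(self, species_id: str) -> str:
        return species_id.split()[0]

    def relative_abundances(self) -> np.ndarray:
        """Per-sample relative abundances; all-zero samples stay zero."""
        totals = self.counts.sum(axis=0).astype(float)
        totals[totals == 0] = 1.0
        return self.counts / totals

    def drop_species(self, species: set[str]) -> "TaxaTable":
        keep = [i for i, s in enumerate(self.species_ids) if s not in species]
        return TaxaTable(
            species_ids=[self.species_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            counts=self.counts[keep, :],
            is_negative_control=self.is_negative_control.copy(),
            labels=self.labels.copy(),
        )

    def select_samples(self, keep: np.ndarray) -> "TaxaTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return TaxaTable(
            species_ids=list(self.species_ids),
            sample_ids=[self.sample_ids[i] for i in keep],
            counts=self.counts[:, keep],
            is_negative_control=self.is_negative_control[keep],
            labels=self.labels[keep],
        )
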