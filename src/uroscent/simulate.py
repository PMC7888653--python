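"""Synthetic study data with the statistical structure the analyses assume.

The generators emulate a pilot case/control urine study: total-ion
chromatograms with group-specific excess peaks and depletions, zero-inflated
VOC abundance tables with a handful of differential compounds, species count
tables with reagent-contaminant structure tied to negative extraction
controls, and four-pot carousel scent trials with a configurable dog.

Every generator is a pure function of its design and seed: calling it twice
with the same arguments yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm as norm_dist

from .config import SampleRecord, ValidationError
from .containers import Chromatogram, TaxaTable, VocTable
from .microbiome import DEFAULT_CONTAMINANT_GENERA as CONTAMINANT_GENERA
from .trial import FALSE_CALL, NO_CALL, TARGET, RunOutcome, SetRecord, TrialRecord

GROUP_EFFECTS = ("case_excess", "case_depletion", "shared")

# Retention times (minutes) of the planted case-specific features: a pair of
# excess peaks near 13.18/13.56 min and depletions near 12.70 min with lesser
# depletions at 10.56, 10.90 and 11.47 min, mirroring the anomalies the
# auto-associative analysis is expected to recover.
EXCESS_RTS = (13.177, 13.563)
DEPLETION_RTS = (12.698, 10.561, 10.899, 11.473)


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian elute peak and how it differs between cohorts."""

    rt_center: float
    width: float  # Gaussian sigma, minutes
    amplitude: float  # abundance units
    group_effect: str = "shared"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("peak width must be positive")
        if self.amplitude < 0:
            raise ValidationError("peak amplitude must be non-negative")
        if self.group_effect not in GROUP_EFFECTS:
            raise ValidationError(f"group_effect must be in {GROUP_EFFECTS}")


def default_peak_specs() -> list[PeakSpec]:
    """Peak layout used by the default design.

    Shared urinary background peaks across the run, the two case-excess
    peaks, and the four case-depletion peaks (the one at 12.698 min largest,
    the remaining three lesser).
    """
    shared = [
        PeakSpec(3.4, 0.05, 90.0),
        PeakSpec(6.8, 0.05, 140.0),
        PeakSpec(9.2, 0.04, 70.0),
        PeakSpec(10.2, 0.04, 60.0),
        PeakSpec(11.9, 0.05, 110.0),
        PeakSpec(12.3, 0.04, 55.0),
        PeakSpec(13.9, 0.05, 65.0),
        PeakSpec(16.5, 0.06, 120.0),
        PeakSpec(21.0, 0.06, 80.0),
        PeakSpec(25.8, 0.07, 95.0),
    ]
    excess = [PeakSpec(rt, 0.03, 60.0, "case_excess") for rt in EXCESS_RTS]
    depletion = [PeakSpec(DEPLETION_RTS[0], 0.03, 50.0, "case_depletion")]
    depletion += [
        PeakSpec(rt, 0.03, 25.0, "case_depletion") for rt in DEPLETION_RTS[1:]
    ]
    return shared + excess + depletion


@dataclass
class SimulationDesign:
    """Study-design parameters for all four generators.

    Defaults mirror the pilot study being emulated: 12 cancer / 38
    biopsy-negative samples overall, six blank extraction negative controls
    with ten indicator contaminant species in the microbiome arm, a
    1,157-compound zero-inflated volatilome with seven differential
    compounds, a chromatogram grid whose 10–14 minute window holds exactly
    205 points, and a four-pot carousel trial.
    """

    n_case: int = 12
    n_control: int = 38
    rt_span: tuple[float, float] = (0.0, 31.0)
    n_points: int = 1589
    noise_sd: float = 2.0
    baseline: float = 5.0
    amp_jitter: float = 0.25
    zero_inflation: float = 0.3
    n_voc: int = 1157
    n_effect_voc: int = 7
    effect_log_fc: float = 2.0
    n_species: int = 120
    n_contaminant: int = 15
    indicator_species: int = 10
    n_differential_species: int = 4
    species_effect_log_fc: float = 1.5
    n_negative_controls: int = 6
    n_low_depth: int = 1
    rarefaction_depth: int = 2700
    dog_sensitivity: float = 0.7
    dog_specificity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("zero_inflation", "dog_sensitivity", "dog_specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        for name in ("n_case", "n_control", "n_points", "n_voc", "n_species"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_effect_voc > self.n_voc:
            raise ValidationError("n_effect_voc cannot exceed n_voc")
        if self.n_contaminant + self.indicator_species > self.n_species:
            raise ValidationError(
                "contaminant plus indicator species cannot exceed n_species"
            )
        if self.rt_span[0] >= self.rt_span[1]:
            raise ValidationError("rt_span must satisfy min < max")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    @property
    def n_true_samples(self) -> int:
        return self.n_case + self.n_control

    def rt_grid(self) -> np.ndarray:
        lo, hi = self.rt_span
        return lo + np.arange(self.n_points) * (hi - lo) / self.n_points

    def labels(self) -> np.ndarray:
        return np.array(
            ["cancer"] * self.n_case + ["control"] * self.n_control, dtype=object
        )

    def sample_records(self, assays: tuple[str, ...] = ()) -> list[SampleRecord]:
        recs = [
            SampleRecord(f"case{i + 1:02d}", "cancer", assays)
            for i in range(self.n_case)
        ]
        recs += [
            SampleRecord(f"ctrl{i + 1:02d}", "control", assays)
            for i in range(self.n_control)
        ]
        return recs

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rt_span"] = list(self.rt_span)
        return d


def _gaussian_peak(grid: np.ndarray, spec: PeakSpec) -> np.ndarray:
    """Peak profile truncated at 4 sigma so distant points are exactly zero."""
    out = np.zeros_like(grid)
    mask = np.abs(grid - spec.rt_center) <= 4.0 * spec.width
    z = (grid[mask] - spec.rt_center) / spec.width
    out[mask] = spec.amplitude * np.exp(-0.5 * z * z)
    return out


def simulate_chromatograms(
    design: SimulationDesign,
    peak_specs: list[PeakSpec] | None = None,
    seed: int | None = None,
) -> tuple[list[Chromatogram], list[SampleRecord]]:
    """Generate one chromatogram per sample from the planted peak layout.

    Shared peaks appear in every sample; case-excess peaks only in cancer
    samples; case-depletion peaks only in controls (they are depleted in
    cases).  Each peak's amplitude is scaled per sample by a log-normal
    factor with sigma ``design.amp_jitter``, emulating inter-individual
    variability, on top of additive Gaussian baseline noise with
    ``design.noise_sd`` (clipped at zero).
    """
    if peak_specs is None:
        peak_specs = default_peak_specs()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    grid = design.rt_grid()
    lo, hi = design.rt_span
    for spec in peak_specs:
        if not lo <= spec.rt_center <= hi:
            raise ValidationError(
                f"peak at {spec.rt_center} min lies outside the run span {design.rt_span}"
            )

    unit_profiles = [(s, _gaussian_peak(grid, s)) for s in peak_specs]
    records = design.sample_records(assays=("gcms",))
    chroms = []
    for rec in records:
        trace = np.full(grid.size, design.baseline)
        jitter = (
            np.exp(rng.normal(0.0, design.amp_jitter, size=len(unit_profiles)))
            if design.amp_jitter > 0
            else np.ones(len(unit_profiles))
        )
        for (spec, profile), factor in zip(unit_profiles, jitter):
            if spec.group_effect == "case_excess" and rec.cohort != "cancer":
                continue
            if spec.group_effect == "case_depletion" and rec.cohort == "cancer":
                continue
            trace = trace + factor * profile
        if design.noise_sd > 0:
            trace = trace + rng.normal(0.0, design.noise_sd, size=grid.size)
        trace = np.clip(trace, 0.0, None)
        chroms.append(Chromatogram(grid.copy(), trace, rec.sample_id))
    return chroms, records


def simulate_voc_table(
    design: SimulationDesign, seed: int | None = None
) -> VocTable:
    """Zero-inflated log-normal VOC abundance table.

    Log-abundances are normal around a per-compound level; values falling
    below a per-compound detection limit are recorded as zero.  The limit
    is placed at the ``zero_inflation`` quantile of the compound's null
    distribution, so every non-differential compound is zero with
    probability ``zero_inflation`` exactly.  The first ``n_effect_voc``
    compounds carry a group shift of ``effect_log_fc`` on the log scale,
    alternating in sign (elevated / reduced in cancer); through the
    detection limit the shift also changes how often the compound is seen
    at all, as in real GC-MS data where presence and abundance signal
    together.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n, p = design.n_true_samples, design.n_voc
    labels = design.labels()
    is_case = labels == "cancer"

    base_mu = rng.uniform(2.0, 6.0, size=p)
    log_ab = base_mu[None, :] + rng.normal(0.0, 1.0, size=(n, p))
    for j in range(design.n_effect_voc):
        sign = 1.0 if j % 2 == 0 else -1.0
        log_ab[is_case, j] += sign * design.effect_log_fc
    if design.zero_inflation >= 1.0:
        detection_limit = np.full(p, np.inf)
    else:
        detection_limit = base_mu + norm_dist.ppf(design.zero_inflation)
    ab = np.exp(log_ab)
    ab[log_ab <= detection_limit[None, :]] = 0.0

    sample_ids = [r.sample_id for r in design.sample_records()]
    compound_ids = [_fake_cas(j) for j in range(p)]
    return VocTable(sample_ids, compound_ids, ab, labels)


def _fake_cas(j: int) -> str:
    """Syntactic CAS-registry-style identifier for simulated compound j."""
    return f"{10000 + j}-{j % 100:02d}-{j % 10}"


_URINARY_GENERA = (
    "Lactobacillus",
    "Streptococcus",
    "Corynebacterium",
    "Gardnerella",
    "Prevotella",
    "Staphylococcus",
    "Dolosigranulum",
    "Enterococcus",
    "Actinomyces",
    "Veillonella",
    "Finegoldia",
    "Anaerococcus",
)


def simulate_taxa_table(
    design: SimulationDesign, seed: int | None = None
) -> tuple[TaxaTable, dict]:
    """Species count table with reagent-contaminant structure.

    Indicator and contaminant species share a per-sample reagent load
    factor, so across true samples contaminants are Spearman-correlated
    with the indicator set; in blank extraction negative controls they
    dominate while biological species are near-absent.  The first
    ``n_differential_species`` biological species carry a cohort shift on
    the log scale.  Returns the table plus a ground-truth dict naming the
    planted indicator, contaminant, and differential species.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n_ind, n_con = design.indicator_species, design.n_contaminant
    n_bio = design.n_species - n_ind - n_con
    if design.n_differential_species > n_bio:
        raise ValidationError("more differential species than biological species")

    species = []
    for i in range(n_ind + n_con):
        genus = CONTAMINANT_GENERA[i % len(CONTAMINANT_GENERA)]
        species.append(f"{genus} sp{i + 1:03d}")
    for i in range(n_bio):
        genus = _URINARY_GENERA[i % len(_URINARY_GENERA)]
        species.append(f"{genus} sp{n_ind + n_con + i + 1:03d}")
    indicator_ids = species[:n_ind]
    contaminant_ids = species[n_ind : n_ind + n_con]
    bio_ids = species[n_ind + n_con :]
    differential_ids = bio_ids[: design.n_differential_species]

    n_true = design.n_true_samples
    n_neg = design.n_negative_controls
    labels_true = design.labels()
    is_case = labels_true == "cancer"

    # Reagent load shared by indicator+contaminant species within a sample.
    load_true = np.exp(rng.normal(0.0, 0.7, size=n_true))
    load_neg = np.exp(rng.normal(1.0, 0.4, size=n_neg))

    level_con = np.exp(rng.normal(3.0, 0.8, size=n_ind + n_con))  # mean counts
    level_bio = np.exp(rng.normal(4.5, 1.0, size=n_bio))

    counts_true = np.zeros((design.n_species, n_true))
    con_noise = np.exp(rng.normal(0.0, 0.4, size=(n_ind + n_con, n_true)))
    counts_true[: n_ind + n_con, :] = (
        level_con[:, None] * load_true[None, :] * con_noise
    )
    # Biological species: log-normal mean structure + NB-like sampling noise.
    bio_mu = np.log(level_bio)[:, None] * np.ones((1, n_true))
    for k in range(design.n_differential_species):
        sign = 1.0 if k % 2 == 0 else -1.0
        bio_mu[k, is_case] += sign * design.species_effect_log_fc
    bio_mean = np.exp(bio_mu + rng.normal(0.0, 0.6, size=(n_bio, n_true)))
    counts_true[n_ind + n_con :, :] = rng.poisson(bio_mean)

    counts_neg = np.zeros((design.n_species, n_neg))
    if n_neg:
        neg_noise = np.exp(rng.normal(0.0, 0.4, size=(n_ind + n_con, n_neg)))
        counts_neg[: n_ind + n_con, :] = (
            60.0 * level_con[:, None] * load_neg[None, :] * neg_noise
        )
        # trace carry-over of biological material into blanks
        counts_neg[n_ind + n_con :, :] = rng.poisson(
            0.05, size=(n_bio, n_neg)
        )

    counts = np.floor(np.hstack([counts_true, counts_neg])).astype(np.int64)

    # Scale true samples so they clear the rarefaction depth (negative
    # controls stay low-biomass as extracted), then mark n_low_depth
    # control samples as sequencing dropouts.
    depth = design.rarefaction_depth
    totals = counts.sum(axis=0)
    for j in range(n_true):
        if totals[j] < 4 * depth:
            scale = int(np.ceil(4 * depth / max(totals[j], 1)))
            counts[:, j] *= scale
    low = []
    if design.n_low_depth > 0 and design.n_control > 0:
        ctrl_cols = np.arange(design.n_case, n_true)
        low = list(rng.choice(ctrl_cols, size=design.n_low_depth, replace=False))
        for j in low:
            tot = counts[:, j].sum()
            target = max(depth // 3, 1)
            counts[:, j] = np.floor(counts[:, j] * (target / tot)).astype(np.int64)

    sample_ids = [r.sample_id for r in design.sample_records()]
    sample_ids += [f"NEG_blank{i + 1}" for i in range(n_neg)]
    labels = np.concatenate([labels_true, np.array([None] * n_neg, dtype=object)])
    flags = np.array([False] * n_true + [True] * n_neg)

    table = TaxaTable(species, sample_ids, counts, flags, labels)
    truth = {
        "indicator_species": indicator_ids,
        "contaminant_species": contaminant_ids,
        "differential_species": differential_ids,
        "low_depth_samples": [sample_ids[j] for j in low],
    }
    return table, truth


def simulate_trial(
    design: SimulationDesign,
    n_sets: int,
    dog: str = "SimDog",
    max_runs: int = 4,
    seed: int | None = None,
) -> tuple[TrialRecord, dict]:
    """Simulate a carousel trial for one dog.

    Each set holds one target among three controls at a uniformly random
    position.  On each pass the dog sniffs the remaining pots in order,
    indicating the target with probability ``dog_sensitivity`` and a
    control with probability ``1 - dog_specificity``.  A false call
    replaces that control with a blank (never indicated thereafter); a
    second false call ends the set; a pass without indication is re-run up
    to ``max_runs`` passes.

    Returns the trial record plus ground truth with per-presentation
    counters for recovering the dog's operating point.
    """
    if n_sets < 1:
        raise ValidationError("n_sets must be at least 1")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    truth = {
        "target_positions": [],
        "target_presentations": 0,
        "target_indications": 0,
        "control_presentations": 0,
        "control_indications": 0,
    }
    sets = []
    for _ in range(n_sets):
        target_pos = int(rng.integers(1, 5))
        truth["target_positions"].append(target_pos)
        # pot state per position: "target", "control", or "blank"
        pots = {
            p: ("target" if p == target_pos else "control") for p in range(1, 5)
        }
        runs: list[RunOutcome] = []
        false_calls = 0
        done = False
        for _pass in range(max_runs):
            call = NO_CALL
            indicated_pos = None
            for pos in range(1, 5):
                kind = pots[pos]
                if kind == "blank":
                    continue
                if kind == "target":
                    truth["target_presentations"] += 1
                    if rng.random() < design.dog_sensitivity:
                        truth["target_indications"] += 1
                        call = TARGET
                        break
                else:
                    truth["control_presentations"] += 1
                    if rng.random() >= design.dog_specificity:
                        truth["control_indications"] += 1
                        call = FALSE_CALL
                        indicated_pos = pos
                        break
            if call == TARGET:
                runs.append(RunOutcome(TARGET))
                done = True
            elif call == FALSE_CALL:
                false_calls += 1
                runs.append(RunOutcome(FALSE_CALL, f"pos{indicated_pos}"))
                pots[indicated_pos] = "blank"
                done = false_calls >= 2
            else:
                runs.append(RunOutcome(NO_CALL))
            if done:
                break
        sets.append(SetRecord(target_pos, runs))
    return TrialRecord(dog=dog, sets=sets), truth


def simulate_canine_calls(
    labels: np.ndarray,
    sensitivity: float = 1.0,
    specificity: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-sample canine indication ("positive"/"negative") given cohorts.

    With default perfect accuracy the calls equal the biopsy cohorts; lower
    values emulate the dog's per-presentation error process.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object)
    calls = np.empty(labels.shape, dtype=object)
    for i, lab in enumerate(labels):
        if lab == "cancer":
            calls[i] = "positive" if rng.random() < sensitivity else "negative"
        else:
            calls[i] = "negative" if rng.random() < specificity else "positive"
    return calls
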