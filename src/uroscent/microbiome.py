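"""Urinary microbiota analysis: contaminant removal, diversity, abundance.

Low-biomass 16S studies are dominated by reagent and laboratory
contamination, so species tables pass through three removal phases before
any ecology is computed: (1) species over-represented in blank extraction
negative controls relative to true samples, (2) species whose relative
abundance is Spearman-correlated (strictly > 0.30 by default) with a panel
of ten indicator contaminant species across true samples, and (3) species
from a blacklist of common reagent-contaminant genera.  Cleaned tables are
rarefied to a common depth, compared by Bray-Curtis and unweighted UniFrac
beta diversity with principal coordinates analysis, and tested per species
for differential abundance with the Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .config import ValidationError
from .containers import TaxaTable
from .voc import rank_sum_test

#: Genera routinely reported as reagent/kit contaminants in low-biomass
#: sequencing; packaged default for the phase-3 blacklist, user-overridable.
DEFAULT_CONTAMINANT_GENERA = (
    "Ralstonia",
    "Bradyrhizobium",
    "Sphingomonas",
    "Burkholderia",
    "Methylobacterium",
    "Acinetobacter",
    "Pseudomonas",
    "Herbaspirillum",
    "Stenotrophomonas",
    "Cupriavidus",
    "Delftia",
    "Comamonas",
    "Phyllobacterium",
)


@dataclass
class ContaminantReport:
    """Which species each removal phase flagged, with per-species evidence."""

    phase1_flagged: set[str] = field(default_factory=set)
    phase2_flagged: set[str] = field(default_factory=set)
    phase3_flagged: set[str] = field(default_factory=set)
    evidence: dict[str, dict] = field(default_factory=dict)

    @property
    def removed(self) -> set[str]:
        return self.phase1_flagged | self.phase2_flagged | self.phase3_flagged


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-10):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(self.matrix < -1e-12):
            raise ValidationError("distances must be non-negative")


# ------------------------------------------------------------ phase filters


def phase1_negative_control_filter(
    table: TaxaTable,
    ratio_threshold: float = 1.0,
    min_control_fraction: float = 1 / 3,
) -> tuple[set[str], dict[str, dict]]:
    """Flag species over-represented in blank extraction controls.

    A species is flagged when its mean relative abundance across negative
    controls is at least ``ratio_threshold`` times its mean relative
    abundance across true samples, and it appears in at least
    ``min_control_fraction`` of the controls.  Returns the flagged set and
    per-species evidence.
    """
    neg = table.is_negative_control
    if not neg.any():
        warnings.warn("no negative controls present; phase 1 skipped")
        return set(), {}
    rel = table.relative_abundances()
    mean_neg = rel[:, neg].mean(axis=1)
    mean_true = rel[:, ~neg].mean(axis=1)
    n_neg = int(neg.sum())
    need = max(1, int(np.ceil(min_control_fraction * n_neg)))
    prev_neg = (table.counts[:, neg] > 0).sum(axis=1)

    flagged, evidence = set(), {}
    for i, sp in enumerate(table.species_ids):
        if mean_neg[i] == 0:
            continue
        ratio = mean_neg[i] / mean_true[i] if mean_true[i] > 0 else np.inf
        if ratio >= ratio_threshold and prev_neg[i] >= need:
            flagged.add(sp)
            evidence[sp] = {
                "control_abundance_ratio": float(ratio),
                "control_prevalence": int(prev_neg[i]),
            }
    return flagged, evidence


def phase2_indicator_correlation(
    table: TaxaTable,
    indicators: list[str],
    cutoff: float = 0.30,
) -> tuple[set[str], dict[str, dict]]:
    """Flag species Spearman-correlated with indicator contaminants.

    Mid-rank Spearman correlation is computed on relative abundances
    across true samples only (contaminant covariation is a reagent effect
    across real specimens); any non-indicator species with correlation
    strictly greater than ``cutoff`` against ANY indicator is flagged.
    Constant species have undefined correlation and are never flagged.
    """
    missing = [s for s in indicators if s not in table.species_ids]
    if missing:
        raise ValidationError(f"indicator species absent from table: {missing}")
    rel = table.relative_abundances()[:, table.true_sample_mask]
    idx = {s: i for i, s in enumerate(table.species_ids)}
    ranks = np.apply_along_axis(rankdata, 1, rel)
    sd = ranks.std(axis=1)

    ind_rows = np.array([idx[s] for s in indicators])
    flagged, evidence = set(), {}
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    for i, sp in enumerate(table.species_ids):
        if sp in indicators or sd[i] == 0:
            continue
        best = -np.inf
        best_ind = None
        for r in ind_rows:
            if sd[r] == 0:
                continue
            rho = float(
                (centered[i] @ centered[r])
                / (rel.shape[1] * sd[i] * sd[r])
            )
            if rho > best:
                best, best_ind = rho, table.species_ids[r]
        if best_ind is None:
            continue
        evidence[sp] = {"max_spearman": best, "against": best_ind}
        if best > cutoff:
            flagged.add(sp)
    return flagged, evidence


def phase3_genus_blacklist(
    table: TaxaTable,
    genera: tuple[str, ...] | list[str] = DEFAULT_CONTAMINANT_GENERA,
) -> tuple[set[str], dict[str, dict]]:
    """Flag every species whose genus token is on the blacklist."""
    genera = set(genera)
    flagged, evidence = set(), {}
    for sp in table.species_ids:
        g = table.genus(sp)
        if g in genera:
            flagged.add(sp)
            evidence[sp] = {"blacklist_genus": g}
    return flagged, evidence


def remove_contaminants(
    table: TaxaTable,
    indicators: list[str],
    genera: tuple[str, ...] | list[str] = DEFAULT_CONTAMINANT_GENERA,
    ratio_threshold: float = 1.0,
    min_control_fraction: float = 1 / 3,
    spearman_cutoff: float = 0.30,
) -> tuple[TaxaTable, ContaminantReport]:
    """Run all three phases and drop the union of flagged species.

    Phases are computed on the original table, so their union is
    order-independent; samples are never dropped here.
    """
    report = ContaminantReport()
    report.phase1_flagged, ev1 = phase1_negative_control_filter(
        table, ratio_threshold, min_control_fraction
    )
    report.phase2_flagged, ev2 = phase2_indicator_correlation(
        table, indicators, spearman_cutoff
    )
    report.phase3_flagged, ev3 = phase3_genus_blacklist(table, genera)
    for ev in (ev1, ev2, ev3):
        for sp, d in ev.items():
            report.evidence.setdefault(sp, {}).update(d)
    return table.drop_species(report.removed), report


# ------------------------------------------------------------ normalization


def rarefy(
    table: TaxaTable, depth: int = 2700, seed: int = 0
) -> tuple[TaxaTable, list[str]]:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total falls below the depth are dropped and reported
    (never resampled with replacement).  Returns the rarefied table and
    the dropped sample ids.
    """
    if depth < 1:
        raise ValidationError("rarefaction depth must be at least 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if not keep.any():
        raise ValidationError("every sample falls below the rarefaction depth")
    sub = table.select_samples(keep)
    new_counts = np.empty_like(sub.counts)
    for j in range(sub.n_samples):
        new_counts[:, j] = rng.multivariate_hypergeometric(
            sub.counts[:, j], depth
        )
    return (
        TaxaTable(
            species_ids=list(sub.species_ids),
            sample_ids=list(sub.sample_ids),
            counts=new_counts,
            is_negative_control=sub.is_negative_control.copy(),
            labels=sub.labels.copy(),
        ),
        dropped,
    )


# ------------------------------------------------------------ beta diversity


def bray_curtis(table: TaxaTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: 1 - 2*sum(min)/sum(totals) per pair."""
    X = table.counts.T.astype(float)
    zero = X.sum(axis=1) == 0
    if zero.any():
        warnings.warn("all-zero samples present; their distances are set to 0")
    with np.errstate(invalid="ignore"):
        D = squareform(pdist(X, metric="braycurtis"))
    D = np.nan_to_num(D, nan=0.0)
    return DistanceMatrix(list(table.sample_ids), D)


def unweighted_unifrac(table: TaxaTable, tree) -> DistanceMatrix:
    """Unweighted UniFrac: unique branch length over spanned branch length.

    ``tree`` is an ``skbio.TreeNode`` or a newick string/path; every
    species in the table must be a tree tip.  Unrooted trees are rooted at
    their midpoint with a warning.
    """
    from skbio import TreeNode
    from skbio.diversity import beta_diversity

    if not isinstance(tree, TreeNode):
        tree = TreeNode.read(str(tree)) if _looks_like_path(tree) else TreeNode.read(
            [str(tree)]
        )
    tips = {t.name for t in tree.tips()}
    missing = [s for s in table.species_ids if s not in tips]
    if missing:
        raise ValidationError(f"species missing from tree: {missing}")
    if len(tree.children) > 2:
        warnings.warn("unrooted tree; rooting at midpoint")
        tree = tree.root_at_midpoint()
    counts = table.counts.T
    try:
        dm = beta_diversity(
            "unweighted_unifrac", counts, ids=table.sample_ids,
            taxa=table.species_ids, tree=tree,
        )
    except TypeError:  # older scikit-bio keyword
        dm = beta_diversity(
            "unweighted_unifrac", counts, ids=table.sample_ids,
            otu_ids=table.species_ids, tree=tree,
        )
    return DistanceMatrix(list(table.sample_ids), dm.data)


def _looks_like_path(obj) -> bool:
    s = str(obj)
    return ("(" not in s) and (s.endswith(".nwk") or s.endswith(".tree") or "/" in s)


@dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples × positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    negative_eigenvalues: np.ndarray


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Principal coordinates analysis via Gower double-centering.

    B = -1/2 * J D^2 J is eigendecomposed; coordinates are eigenvectors
    scaled by the square root of their (positive) eigenvalues.  Axes with
    non-positive eigenvalues are reported but omitted from coordinates.
    """
    D = dist.matrix
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10 * max(1.0, abs(vals[0]))
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    return PcoaResult(
        sample_ids=list(dist.sample_ids),
        coordinates=coords,
        eigenvalues=vals,
        negative_eigenvalues=vals[vals < 0],
    )


# ------------------------------------------------------------ group contrasts


def differential_abundance(table: TaxaTable) -> pd.DataFrame:
    """Mann-Whitney U differential abundance per species.

    Computed on relative abundances across all true samples.  Mean percent
    abundance is reported over the samples positive for the species in
    each group (0 when no sample is positive); species absent everywhere
    are skipped.
    """
    sub = table.select_samples(table.true_sample_mask)
    y = np.array([lab == "cancer" for lab in sub.labels])
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValidationError("need at least 2 samples per group")
    rel = sub.relative_abundances()
    rows = []
    for i, sp in enumerate(sub.species_ids):
        v = rel[i]
        if np.all(v == 0):
            continue
        p, u = rank_sum_test(v[y], v[~y])
        pos_cancer, pos_ctrl = v[y][v[y] > 0], v[~y][v[~y] > 0]
        rows.append(
            {
                "species": sp,
                "U": u,
                "p_value": p,
                "mean_percent_cancer": 100.0 * pos_cancer.mean() if pos_cancer.size else 0.0,
                "mean_percent_control": 100.0 * pos_ctrl.mean() if pos_ctrl.size else 0.0,
                "prevalence_cancer": float((v[y] > 0).mean()),
                "prevalence_control": float((v[~y] > 0).mean()),
            }
        )
    return pd.DataFrame(rows)


def profile_separation(table: TaxaTable, k: int = 2) -> dict:
    """Whole-profile clustering diagnostics against the cohort labels.

    Hierarchical clustering (average linkage, Euclidean) of log-transformed
    relative abundances, as in unsupervised-profile heatmap analyses, plus
    the silhouette of the true labels.  Values near zero say the complete
    profile does not separate the cohorts.
    """
    from sklearn.metrics import adjusted_rand_score, silhouette_score

    sub = table.select_samples(table.true_sample_mask)
    X = np.log(sub.relative_abundances().T + 1e-6)
    labels = np.array([1 if lab == "cancer" else 0 for lab in sub.labels])
    Z = linkage(X, method="average", metric="euclidean")
    clusters = fcluster(Z, t=k, criterion="maxclust")
    return {
        "silhouette_vs_labels": float(silhouette_score(X, labels)),
        "adjusted_rand": float(adjusted_rand_score(labels, clusters)),
    }
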