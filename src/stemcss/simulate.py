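"""Synthetic single-cell, bulk, clinical, and mutation data generators.

Every downstream stage of the pipeline is exercised against data with a
planted ground truth.  The single-cell generator emulates a tumor
epithelial landscape with two stem-like subpopulations — an LGR5-type
cluster carrying a WNT-like marker program and a LAPTM4B-type cluster
restricted to microsatellite-stable patients that carries a uniform
expression gain across all chromosome-8q genes — plus non-stem tumor and
normal epithelial clusters.  The bulk generator mixes the two programs
into four subtype profiles (low/low, LAPTM4B-high, high/high, LGR5-high),
attaches exponential survival with subtype-specific hazards, and draws
per-gene mutation indicators with subtype-specific frequencies.

Counts follow a negative-binomial model with shared dispersion (scRNA
counts are overdispersed; NB is the minimal such model).  All randomness
flows from one explicit seed through ``numpy.random.SeedSequence`` spawns,
one stream per component, so changing one part of a config does not
perturb unrelated draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSignature

__all__ = [
    "ClusterSpec",
    "ScSimConfig",
    "ProgramSpec",
    "SurvSimSpec",
    "BulkSimConfig",
    "SimulatedSingleCell",
    "SimulatedBulk",
    "simulate_sc",
    "simulate_bulk",
    "simulate_two_group_survival",
    "simulate_two_marker_cohort",
    "default_sc_config",
    "null_sc_config",
    "default_bulk_config",
    "CSS_ORDER",
]

CSS_ORDER = ("CSS1", "CSS2", "CSS3", "CSS4")

# Default planted gene programs.  The LGR5-type program seeds the named
# members of the published signature and pads with synthetic WNT-program
# gene names; the LAPTM4B-type program is five 8q-specific markers.
DEFAULT_LGR5_PROGRAM: tuple[str, ...] = (
    "LGR5",
    "OLFM4",
    "TMEM19",
    "TMEM238",
    "CCL20",
) + tuple(f"WNTP{i:02d}" for i in range(1, 26))

DEFAULT_LAPTM4B_PROGRAM: tuple[str, ...] = (
    "LAPTM4B",
    "MYCP02",
    "MYCP03",
    "MYCP04",
    "MYCP05",
)


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ClusterSpec:
    """One simulated cell cluster.

    ``marker_genes`` have their negative-binomial mean multiplied by
    ``marker_fold`` in this cluster only.  ``has_arm_gain`` marks the
    cluster carrying the chromosome-8q-wide expression gain; its marker
    genes are placed on 8q.  ``msi_restriction`` of ``"MSS-only"``
    confines the cluster's cells to microsatellite-stable patients.
    """

    name: str
    fraction: float
    marker_genes: tuple[str, ...] = ()
    marker_fold: float = 1.0
    tissue: str = "tumor"
    msi_restriction: str | None = None
    has_arm_gain: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError(f"cluster {self.name}: fraction must be in (0, 1]")
        if self.tissue not in ("tumor", "normal"):
            raise ValueError(f"cluster {self.name}: tissue must be 'tumor' or 'normal'")
        if self.msi_restriction not in (None, "MSS-only"):
            raise ValueError(f"cluster {self.name}: unknown msi_restriction")
        if self.marker_genes and self.marker_fold <= 1:
            raise ValueError(f"cluster {self.name}: marker_fold must be > 1 for planted markers")


@dataclass(frozen=True)
class ScSimConfig:
    """Single-cell simulation configuration."""

    n_genes: int = 2000
    n_cells: int = 3000
    clusters: tuple[ClusterSpec, ...] = ()
    baseline_mean: float = 0.5
    nb_dispersion: float = 2.0
    frac_8q_genes: float = 0.1
    arm_gain_factor: float = 2.0
    seed: int = 0
    n_patients: int = 12
    msi_fraction: float = 0.3
    marker_base_mean: float = 1.5

    def __post_init__(self) -> None:
        if not self.clusters:
            raise ValueError("at least one cluster must be specified")
        total = sum(c.fraction for c in self.clusters)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cluster fractions sum to {total}, not 1")
        if not 0 < self.frac_8q_genes < 1:
            raise ValueError("frac_8q_genes must be in (0, 1)")
        if self.n_genes * self.frac_8q_genes < 50:
            raise ValueError("need at least 50 genes on 8q (n_genes * frac_8q_genes >= 50)")
        if self.arm_gain_factor < 1:
            raise ValueError("arm_gain_factor must be >= 1")
        if self.baseline_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("baseline_mean and nb_dispersion must be positive")
        all_markers: list[str] = []
        for c in self.clusters:
            all_markers.extend(c.marker_genes)
        if len(set(all_markers)) != len(all_markers):
            raise ValueError("marker gene lists must be disjoint across clusters")
        if len(all_markers) > self.n_genes:
            raise ValueError(
                f"marker lists reference {len(all_markers)} genes but n_genes={self.n_genes}"
            )
        if sum(1 for c in self.clusters if c.has_arm_gain) > 1:
            raise ValueError("at most one cluster may carry the arm gain")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")


@dataclass(frozen=True)
class ProgramSpec:
    """A bulk expression program: gene list plus additive log-scale effect."""

    genes: tuple[str, ...]
    effect: float = 1.0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("program gene list must be non-empty")


@dataclass(frozen=True)
class SurvSimSpec:
    """Exponential survival with subtype-specific proportional hazards.

    ``log_hr_per_subtype`` lists the log hazard ratios for CSS1..CSS4
    (the reference subtype carries 0).  Censoring is uniform over
    ``(0, horizon_months)`` for a ``censor_rate`` fraction of samples,
    with administrative censoring at the horizon for the remainder.
    """

    baseline_hazard: float = 0.012
    log_hr_per_subtype: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    censor_rate: float = 0.25
    horizon_months: float = 36.0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")
        if len(self.log_hr_per_subtype) != 4:
            raise ValueError("log_hr_per_subtype must have 4 entries")


@dataclass(frozen=True)
class BulkSimConfig:
    """Bulk cohort simulation configuration.

    ``mutation_freqs`` maps gene -> per-subtype mutation probabilities
    (CSS1..CSS4).  ``tmb_means`` are per-subtype Poisson means for the
    total nonsilent mutation count (CSS1 is the hypermutated, MSI-enriched
    subtype).
    """

    n_samples: int = 400
    subtype_proportions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    lgr5_program: ProgramSpec = field(
        default_factory=lambda: ProgramSpec(DEFAULT_LGR5_PROGRAM, effect=1.0)
    )
    laptm4b_program: ProgramSpec = field(
        default_factory=lambda: ProgramSpec(
            DEFAULT_LAPTM4B_PROGRAM + ("TNNC2", "EREG", "C4orf48"), effect=1.5
        )
    )
    n_genes: int = 500
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    noise_sd: float = 0.6
    survival: SurvSimSpec = field(default_factory=SurvSimSpec)
    mutation_freqs: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )
    tmb_means: tuple[float, float, float, float] = (45.0, 10.0, 10.0, 10.0)
    msi_prob: tuple[float, float, float, float] = (0.5, 0.05, 0.05, 0.05)
    pole_prob: tuple[float, float, float, float] = (0.15, 0.02, 0.02, 0.02)
    left_side_prob: tuple[float, float, float, float] = (0.4, 0.67, 0.5, 0.73)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.subtype_proportions) != 4:
            raise ValueError("subtype_proportions must have 4 entries")
        total = sum(self.subtype_proportions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype_proportions sum to {total}, not 1")
        for gene, probs in self.mutation_freqs.items():
            if len(probs) != 4 or not all(0 <= p <= 1 for p in probs):
                raise ValueError(f"mutation_freqs[{gene}] must be 4 probabilities in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------
@dataclass
class SimulatedSingleCell:
    counts: ExpressionMatrix
    cells: pd.DataFrame
    loci: pd.DataFrame
    truth: dict


@dataclass
class SimulatedBulk:
    expression: ExpressionMatrix
    clinical: pd.DataFrame
    mutations: pd.DataFrame
    truth: pd.Series


# ---------------------------------------------------------------------------
# Default configurations (the package's reference study conditions)
# ---------------------------------------------------------------------------
def default_sc_config(seed: int = 0) -> ScSimConfig:
    """Reference single-cell conditions: 3,000 cells, 2,000 genes, two
    stem-like clusters (one with a 2x 8q-wide gain and five planted
    8q-specific markers at 4-fold), two non-stem tumor clusters and two
    normal epithelial clusters."""
    clusters = (
        ClusterSpec("stem_lgr5", 0.20, DEFAULT_LGR5_PROGRAM, 4.0, "tumor"),
        ClusterSpec(
            "stem_laptm4b",
            0.15,
            DEFAULT_LAPTM4B_PROGRAM,
            4.0,
            "tumor",
            msi_restriction="MSS-only",
            has_arm_gain=True,
        ),
        ClusterSpec("tumor_proliferative", 0.25, ("PCNA", "MKI67"), 3.0, "tumor"),
        ClusterSpec("tumor_secretory", 0.15, ("MUC2", "MUC4"), 3.0, "tumor"),
        ClusterSpec("normal_enterocyte", 0.15, ("FABP1", "CA2"), 3.0, "normal"),
        ClusterSpec("normal_goblet", 0.10, ("TFF3", "AGR2"), 3.0, "normal"),
    )
    return ScSimConfig(clusters=clusters, seed=seed)


def null_sc_config(seed: int = 0) -> ScSimConfig:
    """Null conditions: identically distributed clusters, no markers, no
    arm gain.  Cluster labels are retained so enrichment and CNV calls can
    be checked against a flat truth."""
    clusters = (
        ClusterSpec("q1", 0.25, (), 1.0, "tumor"),
        ClusterSpec("q2", 0.25, (), 1.0, "tumor"),
        ClusterSpec("ref1", 0.25, (), 1.0, "normal"),
        ClusterSpec("ref2", 0.25, (), 1.0, "normal"),
    )
    return ScSimConfig(clusters=clusters, arm_gain_factor=1.0, seed=seed)


def default_bulk_config(seed: int = 0) -> BulkSimConfig:
    """Reference bulk conditions: 400 samples, four equiprobable subtype
    profiles, exponential DFS with the LAPTM4B-dominant subtype at hazard
    ratio 2.31 versus the LGR5-dominant reference, and subtype-dependent
    mutation frequencies (APC highest in the LGR5-enriched subtypes,
    TP53 75% in the LAPTM4B-dominant subtype)."""
    survival = SurvSimSpec(
        baseline_hazard=0.012,
        log_hr_per_subtype=(0.35, math.log(2.31), 0.45, 0.0),
        censor_rate=0.25,
        horizon_months=36.0,
    )
    mutation_freqs = {
        "TP53": (0.40, 0.75, 0.60, 0.40),
        "APC": (0.50, 0.70, 0.84, 0.78),
        "KRAS": (0.45, 0.40, 0.40, 0.35),
        "BRAF": (0.25, 0.05, 0.03, 0.05),
        "PIK3CA": (0.30, 0.20, 0.15, 0.20),
    }
    return BulkSimConfig(survival=survival, mutation_freqs=mutation_freqs, seed=seed)


# ---------------------------------------------------------------------------
# Single-cell generator
# ---------------------------------------------------------------------------
def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float, shape) -> np.ndarray:
    """Negative binomial with var = mu + mu^2 / size_param."""
    mean = np.broadcast_to(mean, shape)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=shape)


def _build_gene_universe(config: ScSimConfig) -> list[str]:
    names: list[str] = []
    for c in config.clusters:
        names.extend(c.marker_genes)
    fill = [f"G{i:04d}" for i in range(config.n_genes - len(names))]
    return names + fill


def _assign_loci(
    config: ScSimConfig, genes: list[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, list[str]]:
    """Place genes on chromosome arms; the gain cluster's markers plus a
    random fill sit on 8q, the remainder round-robin over the other arms."""
    n_8q = round(config.n_genes * config.frac_8q_genes)
    gain_markers = [g for c in config.clusters if c.has_arm_gain for g in c.marker_genes]
    other_markers = {g for c in config.clusters if not c.has_arm_gain for g in c.marker_genes}
    eligible = [g for g in genes if g not in gain_markers and g not in other_markers]
    extra = list(rng.choice(eligible, size=n_8q - len(gain_markers), replace=False))
    genes_8q = set(gain_markers) | set(extra)

    arms = [(str(c), a) for c in range(1, 23) for a in ("p", "q") if not (c == 8 and a == "q")]
    rows = []
    arm_counters = {arm: 0 for arm in arms}
    counter_8q = 0
    j = 0  # round-robin position over the non-8q arms
    for g in genes:
        if g in genes_8q:
            counter_8q += 1
            rows.append({"gene": g, "chrom": "8", "arm": "q", "start": counter_8q * 100_000 + 1})
        else:
            chrom, arm = arms[j % len(arms)]
            arm_counters[(chrom, arm)] += 1
            rows.append(
                {
                    "gene": g,
                    "chrom": chrom,
                    "arm": arm,
                    "start": arm_counters[(chrom, arm)] * 100_000 + 1,
                }
            )
            j += 1
    return pd.DataFrame(rows), sorted(genes_8q)


def simulate_sc(config: ScSimConfig) -> SimulatedSingleCell:
    """Simulate a single-cell count matrix with planted cluster structure.

    Returns raw NB counts (cells x genes), a cell annotation table
    (patient, tissue, cluster, msi, side), a gene locus table and a
    planted-truth record.  Identical config and seed give bit-identical
    output.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_loci, rng_cells, rng_counts, rng_patients = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    genes = _build_gene_universe(config)
    loci, genes_8q = _assign_loci(config, genes, rng_loci)

    # per-gene base means: lognormal spread around baseline_mean, planted
    # markers pinned at marker_base_mean so their fold changes are stable
    base = config.baseline_mean * np.exp(rng_genes.normal(0.0, 1.0, size=config.n_genes))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for c in config.clusters:
        for g in c.marker_genes:
            base[gene_idx[g]] = config.marker_base_mean

    # patients
    n_msi = round(config.n_patients * config.msi_fraction)
    patient_ids = [f"PT{i:02d}" for i in range(1, config.n_patients + 1)]
    msi_status = np.array(["MSI"] * n_msi + ["MSS"] * (config.n_patients - n_msi))
    sides = np.where(rng_patients.random(config.n_patients) < 0.5, "left", "right")
    mss_patients = np.flatnonzero(msi_status == "MSS")
    if len(mss_patients) == 0:
        raise ValueError("MSS-only clusters require at least one MSS patient")

    # cells
    fractions = np.array([c.fraction for c in config.clusters])
    cluster_of = rng_cells.choice(len(config.clusters), size=config.n_cells, p=fractions)
    patient_of = np.empty(config.n_cells, dtype=int)
    for i, ci in enumerate(cluster_of):
        spec = config.clusters[ci]
        if spec.msi_restriction == "MSS-only":
            patient_of[i] = rng_cells.choice(mss_patients)
        else:
            patient_of[i] = rng_cells.integers(config.n_patients)

    # per-cluster mean vectors
    counts = np.empty((config.n_cells, config.n_genes), dtype=np.int64)
    idx_8q = np.array([gene_idx[g] for g in genes_8q])
    for ci, spec in enumerate(config.clusters):
        mu = base.copy()
        if spec.marker_genes:
            marker_idx = [gene_idx[g] for g in spec.marker_genes]
            mu[marker_idx] *= spec.marker_fold
        if spec.has_arm_gain:
            mu[idx_8q] *= config.arm_gain_factor
        cells_in = np.flatnonzero(cluster_of == ci)
        if len(cells_in):
            counts[cells_in] = _nb_draw(
                rng_counts, mu, config.nb_dispersion, (len(cells_in), config.n_genes)
            )

    cell_ids = [f"C{i:05d}" for i in range(config.n_cells)]
    cells = pd.DataFrame(
        {
            "patient": [patient_ids[p] for p in patient_of],
            "tissue": [config.clusters[c].tissue for c in cluster_of],
            "cluster": [config.clusters[c].name for c in cluster_of],
            "msi": msi_status[patient_of],
            "side": sides[patient_of],
        },
        index=pd.Index(cell_ids, name="cell"),
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=cells.index, columns=genes), is_log=False
    )
    gain_clusters = [c.name for c in config.clusters if c.has_arm_gain]
    truth = {
        "markers": {c.name: list(c.marker_genes) for c in config.clusters},
        "gain_cluster": gain_clusters[0] if gain_clusters else None,
        "arm_gain_factor": config.arm_gain_factor,
        "genes_8q": genes_8q,
        "tumor_clusters": [c.name for c in config.clusters if c.tissue == "tumor"],
        "normal_clusters": [c.name for c in config.clusters if c.tissue == "normal"],
    }
    return SimulatedSingleCell(matrix, cells, loci, truth)


# ---------------------------------------------------------------------------
# Survival draw shared by the bulk generator and the calibration helper
# ---------------------------------------------------------------------------
def _draw_survival(
    subtype_idx: np.ndarray, spec: SurvSimSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    hazards = spec.baseline_hazard * np.exp(np.asarray(spec.log_hr_per_subtype)[subtype_idx])
    t_event = rng.exponential(1.0 / hazards)
    censor_time = np.full(len(subtype_idx), spec.horizon_months)
    is_random_censor = rng.random(len(subtype_idx)) < spec.censor_rate
    censor_time[is_random_censor] = rng.uniform(0, spec.horizon_months, is_random_censor.sum())
    time = np.minimum(t_event, censor_time)
    event = (t_event <= censor_time).astype(int)
    # guard against zero durations from extreme draws
    time = np.maximum(time, 1e-6)
    return time, event


def simulate_bulk(
    config: BulkSimConfig,
    signatures: tuple[GeneSignature, GeneSignature] | None = None,
) -> SimulatedBulk:
    """Simulate a bulk cohort with four planted subtype profiles.

    Each sample's log expression is a per-gene Gaussian baseline plus the
    LGR5 program effect (subtypes CSS3/CSS4), plus the LAPTM4B program
    effect (CSS2/CSS3), plus noise.  Survival follows
    :class:`SurvSimSpec`; mutation indicators are Bernoulli with
    subtype-specific frequencies.

    Parameters
    ----------
    signatures:
        Optional ``(lgr5_signature, laptm4b_signature)`` pair whose gene
        lists replace the configured program genes — used to plant the
        very programs a discovered signature will be scored with.
    """
    lgr5_genes = tuple(signatures[0]) if signatures else config.lgr5_program.genes
    laptm4b_genes = tuple(signatures[1]) if signatures else config.laptm4b_program.genes
    overlap = set(lgr5_genes) & set(laptm4b_genes)
    if overlap:
        raise ValueError(f"program gene lists overlap: {sorted(overlap)}")

    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_subtypes, rng_expr, rng_surv, rng_mut, rng_clin = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    program = list(lgr5_genes) + list(laptm4b_genes)
    n_background = config.n_genes - len(program)
    if n_background < 0:
        raise ValueError("n_genes smaller than the combined program size")
    background = [f"B{i:04d}" for i in range(n_background)]
    genes = program + background

    subtype_idx = rng_subtypes.choice(4, size=config.n_samples, p=config.subtype_proportions)
    mu = rng_genes.normal(config.baseline_log_mean, config.baseline_log_sd, size=len(genes))

    effect = np.zeros((4, len(genes)))
    lgr5_cols = np.arange(len(lgr5_genes))
    laptm4b_cols = np.arange(len(lgr5_genes), len(program))
    # CSS3/CSS4 carry the LGR5 program; CSS2/CSS3 carry the LAPTM4B program
    effect[np.ix_([2, 3], lgr5_cols)] = config.lgr5_program.effect
    effect[np.ix_([1, 2], laptm4b_cols)] = config.laptm4b_program.effect

    noise = rng_expr.normal(0.0, config.noise_sd, size=(config.n_samples, len(genes)))
    x = mu[None, :] + effect[subtype_idx] + noise
    sample_ids = pd.Index([f"S{i:04d}" for i in range(config.n_samples)], name="sample")
    expression = ExpressionMatrix(
        pd.DataFrame(x, index=sample_ids, columns=genes), is_log=True
    )

    time, event = _draw_survival(subtype_idx, config.survival, rng_surv)
    msi = rng_clin.random(config.n_samples) < np.asarray(config.msi_prob)[subtype_idx]
    pole = rng_clin.random(config.n_samples) < np.asarray(config.pole_prob)[subtype_idx]
    left = rng_clin.random(config.n_samples) < np.asarray(config.left_side_prob)[subtype_idx]
    tmb = rng_mut.poisson(np.asarray(config.tmb_means)[subtype_idx])
    clinical = pd.DataFrame(
        {
            "dfs_months": time,
            "dfs_event": event,
            "msi": np.where(msi, "MSI", "MSS"),
            "pole": np.where(pole, "mutant", "wild-type"),
            "stage": rng_clin.choice(["I", "II", "III", "IV"], size=config.n_samples),
            "side": np.where(left, "left", "right"),
            "tmb": tmb,
        },
        index=sample_ids,
    )

    mut_cols = {}
    for gene, probs in config.mutation_freqs.items():
        p = np.asarray(probs)[subtype_idx]
        mut_cols[gene] = (rng_mut.random(config.n_samples) < p).astype(int)
    mutations = pd.DataFrame(mut_cols, index=sample_ids)

    truth = pd.Series(
        [CSS_ORDER[i] for i in subtype_idx], index=sample_ids, name="subtype"
    )
    return SimulatedBulk(expression, clinical, mutations, truth)


def simulate_two_marker_cohort(
    n: int = 400,
    delta_laptm4b: float = 0.75,
    delta_lgr5: float = 0.75,
    noise_sd: float = 1.0,
    recurrence_rate: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-marker recurrence cohort with opposing planted effects.

    Log-scale LAPTM4B expression is shifted up by ``delta_laptm4b`` in
    recurrent samples while LGR5 is shifted down by ``delta_lgr5`` —
    the opposing prognostic directions of the two stem-like markers.
    Under this binormal model the combined score (LAPTM4B - LGR5) has
    separation ``delta_laptm4b + delta_lgr5`` against noise
    ``sqrt(2) * noise_sd``, so its ROC AUC strictly exceeds either
    single marker's whenever both deltas are positive.

    Returns columns ``laptm4b, lgr5, recurrence``.
    """
    if not 0 < recurrence_rate < 1:
        raise ValueError("recurrence_rate must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    recur = (rng.random(n) < recurrence_rate).astype(int)
    laptm4b = rng.normal(0.0, noise_sd, n) + delta_laptm4b * recur
    lgr5 = rng.normal(0.0, noise_sd, n) - delta_lgr5 * recur
    return pd.DataFrame({"laptm4b": laptm4b, "lgr5": lgr5, "recurrence": recur})


def simulate_two_group_survival(
    n: int,
    hr: float,
    seed: int = 0,
    baseline_hazard: float = 0.012,
    censor_rate: float = 0.25,
    horizon_months: float = 36.0,
) -> pd.DataFrame:
    """Two equal groups with exponential hazards differing by ``hr``.

    A small helper for Cox/log-rank calibration studies; group 1 carries
    hazard ``baseline_hazard * hr``, group 0 the baseline.
    """
    spec = SurvSimSpec(
        baseline_hazard=baseline_hazard,
        log_hr_per_subtype=(0.0, math.log(hr), 0.0, 0.0),
        censor_rate=censor_rate,
        horizon_months=horizon_months,
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    group = np.repeat([0, 1], [n - n // 2, n // 2])
    time, event = _draw_survival(group, spec, rng)
    return pd.DataFrame({"time": time, "event": event, "group": group})
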