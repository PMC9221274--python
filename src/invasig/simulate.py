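"""Synthetic fixtures with planted ground truth.

Three generators emulate the statistical structure the analysis stages
assume:

* ``gen_bulk`` -- four bulk RNA-seq count matrices (invaded / noninvaded
  cells, each with and without the ER degrader ICI), negative-binomial
  counts with condition-specific planted log fold changes;
* ``gen_sc`` -- a droplet single-cell UMI matrix with mitochondrial
  genes, discrete clusters, a planted enriched gene set, cell-cycle
  phase structure, and explicitly planted low-quality barcodes;
* ``gen_cohort`` -- a patient cohort with rare high-expression outliers
  (z > 3), group-dependent survival hazards, and shifted clinical
  category frequencies.

Fixing the config seed fixes every output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlantedGene",
    "BulkSimConfig",
    "ScSimConfig",
    "CohortSimConfig",
    "gen_bulk",
    "gen_sc",
    "gen_cohort",
    "default_bulk_config",
    "default_sc_config",
    "default_cohort_config",
    "BULK_CONDITIONS",
]

#: the four bulk conditions: (invasion status, treatment)
BULK_CONDITIONS = [("INV+", "none"), ("INV+", "ici"), ("INV-", "none"), ("INV-", "ici")]

_CONTRASTS = ("INV+", "INV-", "both")
_MODULES = ("proliferation", "trafficking", "none")


@dataclass(frozen=True)
class PlantedGene:
    """A gene with a planted ICI effect in one or both invasion contrasts."""

    gene_id: str
    contrast: str  # "INV+", "INV-" or "both"
    log2fc: float
    module_label: str = "none"

    def __post_init__(self) -> None:
        if self.contrast not in _CONTRASTS:
            raise ValueError(f"contrast must be one of {_CONTRASTS}")
        if self.module_label not in _MODULES:
            raise ValueError(f"module_label must be one of {_MODULES}")
        if not np.isfinite(self.log2fc):
            raise ValueError("log2fc must be finite")


@dataclass
class BulkSimConfig:
    """Study conditions for the bulk generator.

    The NB dispersion ``dispersion`` shares its meaning with the DE
    engine (variance = mu + phi mu^2).  Per-gene baseline means scatter
    log-normally around ``baseline_mean`` and library sizes scatter
    uniformly inside ``lib_size_range``.
    """

    n_genes: int = 2000
    n_reps_per_group: int = 5
    baseline_mean: float = 200.0
    dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (0.8, 1.2)
    gene_mean_log_sd: float = 0.7
    planted: list[PlantedGene] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps_per_group < 2:
            raise ValueError("exact test needs at least 2 replicates per group")
        if self.n_genes < len(self.planted):
            raise ValueError("n_genes must cover all planted genes")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid lib_size_range")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, phi) sample via Gamma-Poisson mixing; phi = 0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    return rng.poisson(rng.gamma(shape, mean * phi))


def gen_bulk(config: BulkSimConfig):
    """Generate the four condition matrices plus the planted-truth table.

    Returns ``(matrices, truth)`` where ``matrices`` maps each
    ``(invasion, treatment)`` pair of :data:`BULK_CONDITIONS` to a
    genes x replicates integer DataFrame and ``truth`` lists every
    planted gene with its contrast, log2fc and module label.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    planted_named = []
    for k, pg in enumerate(config.planted):
        gid = pg.gene_id if pg.gene_id else genes[k]
        planted_named.append(PlantedGene(gid, pg.contrast, pg.log2fc, pg.module_label))
    # planted gene ids not of the default form replace leading universe slots
    for k, pg in enumerate(planted_named):
        if pg.gene_id not in genes:
            genes[k] = pg.gene_id
    lfc = {pg.gene_id: pg for pg in planted_named}

    base = config.baseline_mean * np.exp(rng.normal(0.0, config.gene_mean_log_sd, config.n_genes))
    matrices = {}
    for inv, treat in BULK_CONDITIONS:
        fc = np.ones(config.n_genes)
        if treat == "ici":
            for i, g in enumerate(genes):
                pg = lfc.get(g)
                if pg is not None and pg.contrast in (inv, "both"):
                    fc[i] = 2.0 ** pg.log2fc
        lib = rng.uniform(*config.lib_size_range, size=config.n_reps_per_group)
        mean = base[:, None] * fc[:, None] * lib[None, :]
        counts = _nb_draw(rng, mean, config.dispersion)
        cols = [f"{inv}_{treat}_r{j + 1}" for j in range(config.n_reps_per_group)]
        matrices[(inv, treat)] = pd.DataFrame(counts, index=genes, columns=cols)

    truth = pd.DataFrame(
        [(pg.gene_id, pg.contrast, pg.log2fc, pg.module_label) for pg in planted_named],
        columns=["gene_id", "contrast", "log2fc", "module_label"],
    )
    return matrices, truth


def default_bulk_config(seed: int = 0) -> BulkSimConfig:
    """Reference bulk fixture: 30 invasion-specific ICI-regulated genes
    (10 of them proliferation-labelled) plus 10 genes shared by both
    contrasts, |log2fc| = 2, on a 2000-gene universe with 5 replicates."""
    planted = []
    for i in range(30):
        label = "proliferation" if i < 10 else ("trafficking" if i < 20 else "none")
        sign = 1.0 if i % 2 else -1.0
        planted.append(PlantedGene(f"G{i:05d}", "INV+", sign * 2.0, label))
    for i in range(30, 40):
        planted.append(PlantedGene(f"G{i:05d}", "both", 2.0 if i % 2 else -2.0, "none"))
    return BulkSimConfig(planted=planted, seed=seed)


@dataclass
class ScSimConfig:
    """Study conditions for the single-cell generator.

    Each cluster carries a disjoint block of ``markers_per_cluster``
    genes elevated ``2**marker_log2fc``-fold; the ``enriched_cluster``
    additionally elevates ``enriched_gene_set`` by
    ``2**enrichment_log2fc``.  Cells in S or G2M phase double the
    expression of the respective phase gene block.  A
    ``low_quality_fraction`` of barcodes is planted to fail exactly one
    QC rule each (low total, low gene complexity, or high mitochondrial
    load).
    """

    n_cells: int = 600
    n_genes: int = 2500
    n_clusters: int = 5
    mito_gene_count: int = 10
    mito_fraction_range: tuple[float, float] = (0.02, 0.10)
    enriched_cluster: int = 4
    enriched_gene_set: tuple[str, ...] = ()
    enrichment_log2fc: float = 1.5
    n_enriched_genes: int = 50
    phase_structure: dict[int, tuple[float, float, float]] | None = None
    depth_range: tuple[int, int] = (8000, 15000)
    markers_per_cluster: int = 40
    marker_log2fc: float = 2.0
    phase_gene_count: int = 40
    gene_weight_log_sd: float = 0.5
    low_quality_fraction: float = 0.0
    cluster_proportions: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.enriched_cluster < self.n_clusters):
            raise ValueError("enriched_cluster out of range")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("mito_fraction_range must lie in [0, 1]")
        if not (0 <= self.low_quality_fraction < 1):
            raise ValueError("low_quality_fraction must lie in [0, 1)")
        if self.phase_structure is not None:
            for c, props in self.phase_structure.items():
                if not (0 <= c < self.n_clusters):
                    raise ValueError("phase_structure cluster id out of range")
                if abs(sum(props) - 1.0) > 1e-9:
                    raise ValueError("phase proportions must sum to 1")

    def gene_names(self) -> list[str]:
        """Gene universe: mito genes use the hg38 'MT-' prefix convention."""
        mito = [f"MT-{i + 1}" for i in range(self.mito_gene_count)]
        rest = [f"GENE{i:05d}" for i in range(self.n_genes - self.mito_gene_count)]
        return mito + rest


PHASES = ("G1", "S", "G2M")


def default_sc_config(seed: int = 0, **overrides) -> ScSimConfig:
    """Reference single-cell fixture: 600 cells, 5 clusters, cluster 4
    enriched for a 50-gene planted set at log2fc 1.5 and composed of
    S/G2M cells at 53%/47%, mirroring the proliferative invasive
    subpopulation the pipeline is meant to detect.  The remaining
    clusters carry the mixed phase composition of an actively dividing
    culture (60% G1, 25% S, 15% G2M)."""
    phase = {c: (0.60, 0.25, 0.15) for c in range(5)}
    phase[4] = (0.0, 0.53, 0.47)
    cfg = ScSimConfig(phase_structure=phase, seed=seed, **overrides)
    return cfg


def _resolve_sc_sets(config: ScSimConfig):
    genes = config.gene_names()
    non_mito = genes[config.mito_gene_count:]
    s_genes = non_mito[: config.phase_gene_count]
    g2m_genes = non_mito[config.phase_gene_count: 2 * config.phase_gene_count]
    offset = 2 * config.phase_gene_count
    markers = {}
    for c in range(config.n_clusters):
        markers[c] = non_mito[offset + c * config.markers_per_cluster:
                              offset + (c + 1) * config.markers_per_cluster]
    offset += config.n_clusters * config.markers_per_cluster
    if config.enriched_gene_set:
        missing = set(config.enriched_gene_set) - set(genes)
        if missing:
            raise ValueError(f"enriched_gene_set not in gene universe: {sorted(missing)[:5]}")
        enriched = list(config.enriched_gene_set)
    else:
        enriched = non_mito[offset: offset + config.n_enriched_genes]
    return genes, s_genes, g2m_genes, markers, enriched


def gen_sc(config: ScSimConfig):
    """Generate a raw barcode UMI matrix and per-cell truth labels.

    Returns ``(adata, truth)``: ``adata`` holds cells x genes integer
    counts with an ``is_mito`` gene flag and the planted S/G2M gene
    lists in ``uns``; ``truth`` records each barcode's cluster, phase,
    realized mitochondrial fraction and low-quality defect (or "ok").
    """
    rng = np.random.default_rng(config.seed)
    genes, s_genes, g2m_genes, markers, enriched = _resolve_sc_sets(config)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_mito = config.mito_gene_count

    base_w = np.exp(rng.normal(0.0, config.gene_weight_log_sd, config.n_genes))
    props = config.cluster_proportions or tuple([1.0 / config.n_clusters] * config.n_clusters)
    clusters = rng.choice(config.n_clusters, size=config.n_cells, p=np.asarray(props) / sum(props))

    phase_struct = config.phase_structure or {}
    phases = np.empty(config.n_cells, dtype=object)
    for i, c in enumerate(clusters):
        p = phase_struct.get(int(c), (1.0, 0.0, 0.0))
        phases[i] = PHASES[rng.choice(3, p=p)]

    n_lq = int(round(config.low_quality_fraction * config.n_cells))
    lq_idx = rng.choice(config.n_cells, size=n_lq, replace=False)
    defects = np.array(["ok"] * config.n_cells, dtype=object)
    for j, i in enumerate(sorted(lq_idx)):
        defects[i] = ("low_total", "low_complexity", "high_mito")[j % 3]

    counts = np.zeros((config.n_cells, config.n_genes), dtype=np.int64)
    mito_frac = np.zeros(config.n_cells)
    for i in range(config.n_cells):
        w = base_w.copy()
        for g in markers[int(clusters[i])]:
            w[gene_idx[g]] *= 2.0 ** config.marker_log2fc
        if clusters[i] == config.enriched_cluster:
            for g in enriched:
                w[gene_idx[g]] *= 2.0 ** config.enrichment_log2fc
        phase_set = s_genes if phases[i] == "S" else (g2m_genes if phases[i] == "G2M" else [])
        for g in phase_set:
            w[gene_idx[g]] *= 2.0

        if defects[i] == "high_mito":
            m_target = rng.uniform(0.25, 0.50)
        else:
            m_target = rng.uniform(*config.mito_fraction_range)
        w[:n_mito] = 0.0
        p = w / w.sum() * (1.0 - m_target)
        p[:n_mito] = m_target / n_mito

        depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
        if defects[i] == "low_total":
            depth = int(rng.integers(50, 450))
        elif defects[i] == "low_complexity":
            # collapse expression onto few genes: < 2000 detected at full depth
            keep = rng.choice(np.arange(n_mito, config.n_genes), size=300, replace=False)
            mask = np.zeros(config.n_genes)
            mask[keep] = p[keep]
            mask[:n_mito] = p[:n_mito]
            p = mask / mask.sum()
        counts[i] = rng.multinomial(depth, p)
        tot = counts[i].sum()
        mito_frac[i] = counts[i, :n_mito].sum() / tot if tot else 0.0

    barcodes = [f"CELL{i:04d}" for i in range(config.n_cells)]
    var = pd.DataFrame({"is_mito": [g.startswith("MT-") for g in genes]}, index=genes)
    adata = ad.AnnData(X=counts, obs=pd.DataFrame(index=barcodes), var=var,
                       uns={"s_genes": list(s_genes), "g2m_genes": list(g2m_genes),
                            "enriched_gene_set": list(enriched)})
    truth = pd.DataFrame({
        "barcode": barcodes,
        "cluster": clusters.astype(int),
        "phase": phases,
        "mito_fraction": mito_frac,
        "defect": defects,
    }).set_index("barcode")
    truth["low_quality"] = truth["defect"] != "ok"
    return adata, truth


@dataclass
class CohortSimConfig:
    """Study conditions for the cohort generator.

    Gene z-scores are truncated standard normal inside (-3, 3) except
    for planted outliers, whose z is uniform on [3.2, 6]; a patient
    carries an outlier with probability ``outlier_rate``.  Survival
    times are exponential with the hazard multiplied by
    ``hazard_ratio`` in the outlier-positive group.
    ``categorical_shift`` moves probability mass between category
    levels for the positive group (per variable, per level, summing
    to 0).
    """

    n_patients: int = 1000
    n_genes: int = 20
    outlier_rate: float = 0.15
    hazard_ratio: float = 2.5
    censor_rate: float = 0.3
    categorical_shift: dict[str, dict[str, float]] = field(default_factory=dict)
    os_scale_months: float = 120.0
    rfs_scale_months: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.outlier_rate <= 1):
            raise ValueError("outlier_rate must lie in [0, 1]")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")


_SUBTYPE_BASE = {"LumA": 0.50, "LumB": 0.25, "Her2": 0.13, "Basal": 0.12}
_GRADE_BASE = {"1": 0.20, "2": 0.45, "3": 0.35}


def default_cohort_config(seed: int = 0, **overrides) -> CohortSimConfig:
    """Reference cohort: the outlier-positive group skews LumB over LumA
    and toward grade 3, echoing the clinical associations the
    stratification stage is meant to recover."""
    shift = {
        "subtype": {"LumA": -0.20, "LumB": 0.20},
        "grade": {"1": -0.10, "2": -0.10, "3": 0.20},
    }
    kwargs = {"categorical_shift": shift, **overrides}
    return CohortSimConfig(seed=seed, **kwargs)


def _shifted(base: dict[str, float], shift: dict[str, float]) -> np.ndarray:
    p = np.array([max(base[k] + shift.get(k, 0.0), 0.0) for k in base])
    return p / p.sum()


def gen_cohort(config: CohortSimConfig):
    """Generate a cohort table and the truth group labels.

    Returns ``(cohort, truth)``.  ``cohort`` has one row per patient:
    ``z_<gene>`` expression z-score columns, ``subtype``, ``grade``,
    ``vital_status`` and (time, event) pairs for overall and
    relapse-free survival.  ``truth`` holds the planted group ("+"
    iff the patient carries an outlier gene).
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_patients, config.n_genes
    genes = [f"SIG{i:03d}" for i in range(g)]

    # background z truncated to (-3, 3) so only planted outliers cross the 3-SD rule
    z = stats.truncnorm.rvs(-3.0, 3.0, size=(n, g), random_state=rng)
    is_plus = rng.random(n) < config.outlier_rate
    for i in np.flatnonzero(is_plus):
        z[i, rng.integers(g)] = rng.uniform(3.2, 6.0)

    subtype = np.empty(n, dtype=object)
    grade = np.empty(n, dtype=object)
    shifts = config.categorical_shift
    p_sub = {False: _shifted(_SUBTYPE_BASE, {}),
             True: _shifted(_SUBTYPE_BASE, shifts.get("subtype", {}))}
    p_gr = {False: _shifted(_GRADE_BASE, {}),
            True: _shifted(_GRADE_BASE, shifts.get("grade", {}))}
    sub_levels, gr_levels = list(_SUBTYPE_BASE), list(_GRADE_BASE)
    for i in range(n):
        subtype[i] = sub_levels[rng.choice(len(sub_levels), p=p_sub[bool(is_plus[i])])]
        grade[i] = gr_levels[rng.choice(len(gr_levels), p=p_gr[bool(is_plus[i])])]

    def survival(scale: float):
        # exponential event times; independent exponential censoring tuned so
        # the reference (negative) group is censored at ~censor_rate
        lam = np.where(is_plus, config.hazard_ratio / scale, 1.0 / scale)
        t = rng.exponential(1.0 / lam)
        if config.censor_rate > 0:
            lam_c = (config.censor_rate / (1.0 - config.censor_rate)) / scale
            c = rng.exponential(1.0 / lam_c, size=n)
        else:
            c = np.full(n, np.inf)
        event = (t <= c).astype(int)
        return np.minimum(t, c), event

    os_time, os_event = survival(config.os_scale_months)
    rfs_time, rfs_event = survival(config.rfs_scale_months)

    ids = [f"PT{i:04d}" for i in range(n)]
    cohort = pd.DataFrame({f"z_{gene}": z[:, j] for j, gene in enumerate(genes)}, index=ids)
    cohort["subtype"] = subtype
    cohort["grade"] = grade
    cohort["vital_status"] = np.where(os_event == 1, "Died", "Living")
    cohort["os_time"] = os_time
    cohort["os_event"] = os_event
    cohort["rfs_time"] = rfs_time
    cohort["rfs_event"] = rfs_event
    truth = pd.DataFrame({"group": np.where(is_plus, "+", "-")}, index=ids)
    return cohort, truth
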