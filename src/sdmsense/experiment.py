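"""Factorial decision-sensitivity experiment.

The study design crosses three modeling decisions — occurrence-bias
treatment (biased vs spatially thinned), training extent (full region vs
the region actually surveyed), and binarization threshold (generous vs
conservative) — over a roster of virtual species, and measures for every
cell of the grid the statistics a reader would use to judge the model:
maximum predicted probability, train and test AUC, similarity of the
predicted current range to the (known) reference range, percent change in
area between current and future projections, and the loser / non-loser
trend label.  A summary table reports per-cell means and standard errors
across species, and the AUC-vs-similarity rank correlation quantifies how
well the conventional precision metric tracks real-world accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import shapely
import yaml

from .environment import (
    EnvStack,
    ExtentMask,
    GridSpec,
    extent_from_polygon,
    extract_covariates,
    mask_extent,
    sample_background,
)
from .evaluation import (
    apply_threshold,
    classify_trend,
    compare_to_reference,
    compute_auc,
    range_change,
    spearman_rho,
)
from .exceptions import SdmError
from .maxent import build_features, fit_maxent, project
from .occurrences import OccurrenceSet, split_train_test, thin_occurrences
from .synthetic import (
    SamplingBiasSpec,
    VirtualSpeciesSpec,
    generate_env_stack,
    generate_future_stack,
    sample_occurrences,
    true_suitability,
)

__all__ = [
    "DecisionSpec",
    "EvaluationRecord",
    "ExperimentConfig",
    "SpeciesData",
    "SummaryTable",
    "default_decisions",
    "generate_study_system",
    "run_single",
    "run_decision_grid",
    "summarize",
    "correlate_auc_similarity",
    "run_full_experiment",
    "records_to_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DecisionSpec:
    """One cell of the factorial decision grid."""

    occurrence_mode: str  # "biased" | "unbiased"
    extent_label: str  # "full" | "restricted"
    threshold: float

    def __post_init__(self) -> None:
        if self.occurrence_mode not in ("biased", "unbiased"):
            raise ValueError(f"unknown occurrence_mode {self.occurrence_mode!r}")
        if self.extent_label not in ("full", "restricted"):
            raise ValueError(f"unknown extent_label {self.extent_label!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


def default_decisions(thresholds=(0.1, 0.4)) -> list[DecisionSpec]:
    """The full 2 × 2 × len(thresholds) factorial, in a stable order."""
    return [
        DecisionSpec(mode, extent, t)
        for mode in ("biased", "unbiased")
        for extent in ("full", "restricted")
        for t in thresholds
    ]


@dataclass
class EvaluationRecord:
    """Measured outcomes of one (species, decision) cell."""

    species: str
    decision: DecisionSpec
    max_probability: float = float("nan")
    train_auc: float = float("nan")
    test_auc: float = float("nan")
    similarity: float = float("nan")
    pct_predicted_in_reference: float = float("nan")
    pct_reference_covered: float = float("nan")
    change_in_area: float = float("nan")
    trend: str = ""
    n_train: int = 0
    n_test: int = 0
    status: str = "ok"
    message: str = ""


@dataclass
class ExperimentConfig:
    """Every default of the study in one place.

    Grid and generator settings describe the synthetic study system; the
    modeling settings mirror the conventional defaults of maximum-entropy
    SDM practice (hinge features on, regularization multiplier 1,
    convergence tolerance 1e-6, iteration cap 500, 30% test split,
    thresholds 0.1 and 0.4).
    """

    # study-system grid
    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 1.0
    # covariates
    n_layers: int = 6
    n_informative: int = 2
    autocorr_length: float = 15.0
    # virtual species roster
    n_species: int = 6
    max_suitability: float = 1.0
    occupancy_threshold: float = 0.1
    optimum_range: tuple[float, float] = (-1.0, 1.0)
    breadth_range: tuple[float, float] = (0.35, 0.7)
    # occurrence sampling
    n_occurrences: int = 3000
    n_clusters: int = 3
    cluster_sd: float = 5.0
    cluster_weight: float = 0.9
    survey_x_fraction: float = 0.55
    # future climate
    future_shift: float = 0.5
    gradient_axis: str = "north-south"
    # treatments
    thinning_cell_size: float = 2.5
    test_fraction: float = 0.3
    thresholds: tuple[float, ...] = (0.1, 0.4)
    # model
    background_size: int = 10_000
    reg_multiplier: float = 1.0
    use_linear: bool = True
    use_quadratic: bool = True
    use_hinge: bool = True
    hinge_knots: int = 10
    convergence_tol: float = 1e-6
    max_iterations: int = 500
    tau: float = 0.5

    def grid(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            x_origin=0.0,
            y_origin=self.n_rows * self.cell_size,
            cell_size=self.cell_size,
        )

    def bias_spec(self) -> SamplingBiasSpec:
        return SamplingBiasSpec(
            mode="clustered",
            n_clusters=self.n_clusters,
            cluster_sd=self.cluster_sd,
            cluster_weight=self.cluster_weight,
        )

    def thinning_grid(self) -> GridSpec:
        s = self.thinning_cell_size
        return GridSpec(
            n_rows=int(np.ceil(self.n_rows * self.cell_size / s)),
            n_cols=int(np.ceil(self.n_cols * self.cell_size / s)),
            x_origin=0.0,
            y_origin=self.n_rows * self.cell_size,
            cell_size=s,
        )

    def to_file(self, path) -> None:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["optimum_range"] = list(self.optimum_range)
        d["breadth_range"] = list(self.breadth_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("thresholds", "optimum_range", "breadth_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SpeciesData:
    """Everything the pipeline needs for one species: data plus truth."""

    spec: VirtualSpeciesSpec
    occurrences: OccurrenceSet  # the raw, spatially clumped ("biased") sample
    reference_range: "object"  # BinaryRange — the stand-in published range
    current_stack: EnvStack
    future_stack: EnvStack


def _child_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def generate_study_system(config: ExperimentConfig, seed: int) -> list[SpeciesData]:
    """Build the synthetic study system: stacks, species, samples, truth.

    One current/future stack pair is shared by all species (as one climate
    is shared by all real species); each species gets its own niche,
    reference range and clumped occurrence sample.  Observer effort covers
    only the western ``survey_x_fraction`` of the map, leaving an
    unsurveyed region that the "restricted" training extent excludes and
    the projection step still covers.
    """
    seeds = _child_seeds(seed, 2 + 2 * config.n_species)
    grid = config.grid()
    current = generate_env_stack(grid, config.n_layers, config.autocorr_length, seeds[0])
    future = generate_future_stack(
        current, [config.future_shift] * config.n_layers, config.gradient_axis
    )
    effort = np.zeros(grid.shape, dtype=bool)
    effort[:, : max(1, int(round(config.survey_x_fraction * config.n_cols)))] = True

    rng = np.random.default_rng(seeds[1])
    species = []
    for i in range(config.n_species):
        optima, breadths = [], []
        for k in range(config.n_layers):
            if k < config.n_informative:
                optima.append(float(rng.uniform(*config.optimum_range)))
                breadths.append(float(rng.uniform(*config.breadth_range)))
            else:
                optima.append(0.0)
                breadths.append(float("inf"))
        spec = VirtualSpeciesSpec(
            name=f"species_{i + 1}",
            optima=tuple(optima),
            breadths=tuple(breadths),
            max_suitability=config.max_suitability,
            occupancy_threshold=config.occupancy_threshold,
        )
        truth, reference = true_suitability(spec, current)
        occ = sample_occurrences(
            truth,
            config.n_occurrences,
            config.bias_spec(),
            seed=seeds[2 + 2 * i],
            species=spec.name,
            effort_mask=effort,
        )
        species.append(
            SpeciesData(
                spec=spec,
                occurrences=occ,
                reference_range=reference,
                current_stack=current,
                future_stack=future,
            )
        )
    return species


def _restricted_extent(train: OccurrenceSet, grid: GridSpec) -> ExtentMask:
    """Convex region actually covered by the training sample, one cell padded."""
    pts = shapely.MultiPoint([tuple(p) for p in train.coords()])
    hull = pts.convex_hull.buffer(grid.cell_size)
    return extent_from_polygon(hull, grid, label="restricted")


def _fit_block(species_data: SpeciesData, occurrence_mode: str, extent_label: str,
               config: ExperimentConfig, seed: int):
    """Fit and project once for a (species, occurrence, extent) block.

    Thresholds are applied downstream, so every threshold row of the block
    shares bit-identical fit-level metrics (max probability, AUCs).
    """
    seeds = _child_seeds(seed, 3)
    occ = species_data.occurrences
    if occurrence_mode == "unbiased":
        occ = thin_occurrences(occ, config.thinning_grid(), seeds[0])
    train, test = split_train_test(occ, config.test_fraction, seeds[1])

    current = species_data.current_stack
    if extent_label == "restricted":
        extent = _restricted_extent(train, current.grid)
        training_stack = mask_extent(current, extent)
    else:
        training_stack = current

    features = build_features(
        training_stack,
        use_linear=config.use_linear,
        use_quadratic=config.use_quadratic,
        use_hinge=config.use_hinge,
        hinge_knots=config.hinge_knots,
    )
    n_bg = min(config.background_size, training_stack.n_valid)
    _, bg_table = sample_background(training_stack, n_bg, seeds[2])

    pres_table = extract_covariates(training_stack, train.coords())
    n_dropped = int((~pres_table["valid"]).sum())
    if n_dropped:
        log.info("%s/%s/%s: %d training presences fall outside the training "
                 "region and are dropped", species_data.spec.name, occurrence_mode,
                 extent_label, n_dropped)
    pres_table = pres_table[pres_table["valid"]]

    model = fit_maxent(
        pres_table,
        bg_table,
        features,
        reg_multiplier=config.reg_multiplier,
        convergence_tol=config.convergence_tol,
        max_iterations=config.max_iterations,
        tau=config.tau,
    )
    current_surface = project(model, species_data.current_stack, clamp=True)
    future_surface = project(model, species_data.future_stack, clamp=True)

    bg_scores = current_surface.probability[bg_table["row"], bg_table["col"]]
    train_scores = current_surface.scores_at(train.coords())
    test_scores = current_surface.scores_at(test.coords())
    train_scores = train_scores[np.isfinite(train_scores)]
    test_scores = test_scores[np.isfinite(test_scores)]
    return {
        "model": model,
        "current_surface": current_surface,
        "future_surface": future_surface,
        "max_probability": current_surface.max_probability,
        "train_auc": compute_auc(train_scores, bg_scores),
        "test_auc": compute_auc(test_scores, bg_scores),
        "n_train": len(train),
        "n_test": len(test),
    }


def _evaluate_threshold(block, species_data: SpeciesData, decision: DecisionSpec
                        ) -> EvaluationRecord:
    record = EvaluationRecord(species=species_data.spec.name, decision=decision,
                              max_probability=block["max_probability"],
                              train_auc=block["train_auc"], test_auc=block["test_auc"],
                              n_train=block["n_train"], n_test=block["n_test"])
    current_bin = apply_threshold(block["current_surface"], decision.threshold)
    future_bin = apply_threshold(block["future_surface"], decision.threshold)
    cmp = compare_to_reference(current_bin, species_data.reference_range)
    record.similarity = cmp.similarity
    record.pct_predicted_in_reference = cmp.pct_predicted_in_reference
    record.pct_reference_covered = cmp.pct_reference_covered
    change = range_change(current_bin, future_bin)
    record.change_in_area = change.change_in_area
    record.trend = classify_trend(change.change_in_area)
    return record


def run_single(species_data: SpeciesData, decision: DecisionSpec,
               config: ExperimentConfig, seed: int) -> EvaluationRecord:
    """Run one cell of the decision grid end to end.

    ``seed`` governs thinning, the train/test split and the background
    sample; it must not depend on the threshold, so threshold-only
    contrasts share identical fits.
    """
    try:
        block = _fit_block(species_data, decision.occurrence_mode,
                           decision.extent_label, config, seed)
        return _evaluate_threshold(block, species_data, decision)
    except SdmError as exc:
        log.warning("cell (%s, %s) failed: %s", species_data.spec.name, decision, exc)
        return EvaluationRecord(species=species_data.spec.name, decision=decision,
                                status="failed", message=str(exc))


def run_decision_grid(species_list: list[SpeciesData],
                      decisions: list[DecisionSpec] | None = None,
                      config: ExperimentConfig | None = None,
                      master_seed: int = 0) -> list[EvaluationRecord]:
    """Run the full factorial: every species × every decision, once each.

    Per-species seeds are derived deterministically from the master seed
    and shared across that species' decisions, so contrasts between cells
    isolate the decision rather than sampling noise.  A failed cell yields
    a record with ``status="failed"`` instead of aborting the grid.
    """
    config = config or ExperimentConfig()
    if decisions is None:
        decisions = default_decisions(config.thresholds)
    if not species_list or not decisions:
        raise ValueError("need at least one species and one decision")
    species_seeds = _child_seeds(master_seed, len(species_list))
    records: list[EvaluationRecord] = []
    for sp, sp_seed in zip(species_list, species_seeds):
        blocks: dict[tuple[str, str], dict] = {}
        for decision in decisions:
            key = (decision.occurrence_mode, decision.extent_label)
            try:
                if key not in blocks:
                    blocks[key] = _fit_block(sp, *key, config, sp_seed)
                records.append(_evaluate_threshold(blocks[key], sp, decision))
            except SdmError as exc:
                log.warning("cell (%s, %s) failed: %s", sp.spec.name, decision, exc)
                records.append(EvaluationRecord(species=sp.spec.name, decision=decision,
                                                status="failed", message=str(exc)))
    return records


def records_to_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    """Flatten records into a table mirroring the classic summary layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "species": r.species,
                "occurrence_mode": r.decision.occurrence_mode,
                "extent": r.decision.extent_label,
                "threshold": r.decision.threshold,
                "max_probability": r.max_probability,
                "train_auc": r.train_auc,
                "test_auc": r.test_auc,
                "similarity": r.similarity,
                "pct_predicted_in_reference": r.pct_predicted_in_reference,
                "pct_reference_covered": r.pct_reference_covered,
                "change_in_area": r.change_in_area,
                "trend": r.trend,
                "n_train": r.n_train,
                "n_test": r.n_test,
                "status": r.status,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SummaryTable:
    """Per-decision means and standard errors across the species roster."""

    table: pd.DataFrame
    n_species: int


_METRICS = ["max_probability", "train_auc", "test_auc", "similarity", "change_in_area"]


def summarize(records: list[EvaluationRecord]) -> SummaryTable:
    """Aggregate a factorial run into the per-decision summary table.

    Standard errors use n = number of species contributing to the cell
    (sd/√n); failed cells reduce n and the reduction is visible in the
    ``n`` column.
    """
    df = records_to_frame(records)
    ok = df[df["status"] == "ok"]
    if ok.empty:
        raise SdmError("no successful records to summarize")
    if len(ok) < len(df):
        log.warning("summary excludes %d failed cell(s)", len(df) - len(ok))
    keys = ["occurrence_mode", "extent", "threshold"]
    rows = []
    for key_vals, grp in ok.groupby(keys, sort=False):
        row = dict(zip(keys, key_vals))
        n = len(grp)
        row["n"] = n
        for metric in _METRICS:
            row[f"{metric}_mean"] = grp[metric].mean()
            row[f"{metric}_se"] = grp[metric].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        row["losers"] = int((grp["change_in_area"] < 100.0).sum())
        rows.append(row)
    table = pd.DataFrame(rows)
    return SummaryTable(table=table, n_species=int(df["species"].nunique()))


def correlate_auc_similarity(records: list[EvaluationRecord]):
    """Rank correlation of AUC with range similarity over all grid cells.

    Returns ``(rho_train, rho_test, n)``.  A negative correlation means the
    cells a reader would prefer on AUC grounds are the ones whose predicted
    ranges least resemble the reference range.
    """
    df = records_to_frame(records)
    ok = df[df["status"] == "ok"]
    if len(ok) < 3:
        raise SdmError("need at least 3 successful records to correlate")
    rho_train, n = spearman_rho(ok["train_auc"], ok["similarity"])
    rho_test, _ = spearman_rho(ok["test_auc"], ok["similarity"])
    return rho_train, rho_test, n


@dataclass
class ExperimentResult:
    records: list[EvaluationRecord]
    summary: SummaryTable
    rho_train: float
    rho_test: float
    n: int


def run_full_experiment(config: ExperimentConfig | None = None,
                        master_seed: int = 0) -> ExperimentResult:
    """Generate a study system and run the full factorial on it."""
    config = config or ExperimentConfig()
    seeds = _child_seeds(master_seed, 2)
    species = generate_study_system(config, seeds[0])
    records = run_decision_grid(species, None, config, seeds[1])
    summary = summarize(records)
    rho_train, rho_test, n = correlate_auc_similarity(records)
    return ExperimentResult(records=records, summary=summary,
                            rho_train=rho_train, rho_test=rho_test, n=n)
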