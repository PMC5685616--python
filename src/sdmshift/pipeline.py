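"""End-to-end orchestration: simulate -> prepare -> fit/evaluate ->
project -> richness -> pa-assess, with deterministic seeding, a run
manifest, and on-disk stage outputs so stages can be re-run individually.

Every tool parameter carries the study defaults: k = 10 cross-validation
replicates, 10000 background points, 1000 optimizer iterations, the 10%
training-presence threshold, strict-majority consensus, a 50-km reserve
buffer with 2000 random pixels, VIF threshold 10, and the inclusion
filters (>= 10 spatially separate records, mean AUC >= 0.7).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .change import apply_no_dispersal, binarize, consensus, stack_richness, summarize_change
from .errors import ConfigError
from .evaluation import evaluate_species, filter_species
from .grid import (
    OccurrenceSet,
    PredictorStack,
    RasterGrid,
    read_occurrences_csv,
    read_pas_geojson,
    read_raster,
    write_occurrences_csv,
    write_pas_geojson,
    write_raster,
)
from .maxent import build_features, sample_background
from .pa import assess_protected_areas
from .predictors import derive_ndvi_layers, vif_report_frame, vif_select
from .synth import (
    SyntheticWorldConfig,
    make_ndvi_stack,
    make_predictor_stack,
    make_protected_areas,
    make_species_set,
)

logger = logging.getLogger(__name__)

_CSV_FLOAT = "%.6g"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelSettings:
    classes: str = "LQPT"
    n_knots: int = 10
    beta0: float = 1.0
    max_iter: int = 1000
    background_n: int = 10000
    clamp: bool = True


@dataclass
class EvaluationSettings:
    k: int = 10
    auc_floor: float = 0.7
    min_records: int = 10
    threshold_percent: float = 10.0


@dataclass
class PrepareSettings:
    vif_threshold: float = 10.0
    vif_sample_n: int = 5000


@dataclass
class PASettings:
    n_random_pixels: int = 2000
    buffer_km: float = 50.0
    #: optional explicit reserve selection (the "oldest and largest" list)
    pa_ids: list[str] | None = None


@dataclass
class RunConfig:
    seed: int = 0
    simulate: SyntheticWorldConfig = field(default_factory=SyntheticWorldConfig)
    model: ModelSettings = field(default_factory=ModelSettings)
    evaluation: EvaluationSettings = field(default_factory=EvaluationSettings)
    prepare: PrepareSettings = field(default_factory=PrepareSettings)
    pa: PASettings = field(default_factory=PASettings)
    dispersal_modes: tuple[str, ...] = ("unlimited", "none")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc or {})
        sim_block = doc.get("simulate") or {}
        sim_seed_given = isinstance(sim_block, dict) and "seed" in sim_block
        kwargs = {}
        blocks = {
            "simulate": SyntheticWorldConfig,
            "model": ModelSettings,
            "evaluation": EvaluationSettings,
            "prepare": PrepareSettings,
            "pa": PASettings,
        }
        for key, klass in blocks.items():
            sub = doc.pop(key, {})
            kwargs[key] = _build_block(klass, sub, key)
        if "seed" in doc:
            kwargs["seed"] = int(doc.pop("seed"))
        if "dispersal_modes" in doc:
            modes = tuple(doc.pop("dispersal_modes"))
            for m in modes:
                if m not in ("unlimited", "none"):
                    raise ConfigError(f"unknown dispersal mode {m!r}")
            kwargs["dispersal_modes"] = modes
        if doc:
            raise ConfigError(f"unknown config key(s): {sorted(doc)}")
        cfg = cls(**kwargs)
        # a single master seed drives everything unless simulate.seed is set
        if not sim_seed_given:
            cfg.simulate.seed = cfg.seed
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _build_block(klass, sub: dict, block: str):
    if not isinstance(sub, dict):
        raise ConfigError(f"config block {block!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(klass)}
    unknown = set(sub) - names
    if unknown:
        raise ConfigError(f"unknown config key(s) in {block!r}: {sorted(unknown)}")
    coerced = dict(sub)
    for key in ("collinear_pairs",):
        if key in coerced and coerced[key] is not None:
            coerced[key] = [tuple(p) for p in coerced[key]]
    for key in ("times",):
        if key in coerced and coerced[key] is not None:
            coerced[key] = tuple(coerced[key])
    return klass(**coerced)


def species_seed(master_seed: int, index: int, stream: int = 0) -> int:
    """Per-species sub-seed independent of execution order (< 2**31)."""
    return int((master_seed * 1000003 + 7919 * index + 104729 * stream) % (2**31 - 1))


# ---------------------------------------------------------------------------
# World container
# ---------------------------------------------------------------------------

@dataclass
class World:
    """Everything the synthetic study region provides to the pipeline."""

    current: PredictorStack
    futures: dict[tuple[int, str], PredictorStack]
    ndvi: list[RasterGrid]
    occurrences: dict[str, OccurrenceSet]
    pas: list
    truth_eta: dict[str, np.ndarray]
    truth_suitability: dict[str, RasterGrid]


def simulate_world(cfg: RunConfig) -> World:
    """Generate the full synthetic world for a run configuration."""
    scfg = cfg.simulate
    current, futures = make_predictor_stack(scfg)
    ndvi = make_ndvi_stack(scfg)
    species, occurrences = make_species_set(current, scfg)
    hint = None
    if scfg.pa_placement == "richness-biased":
        total = np.sum([sp.true_suitability.values for sp in species], axis=0)
        hint = current.grid.like(total, mask=~current.land_mask)
    pas = make_protected_areas(scfg, current.grid, richness_hint=hint,
                               land_mask=current.land_mask)
    return World(
        current=current,
        futures=futures,
        ndvi=ndvi,
        occurrences=occurrences,
        pas=pas,
        truth_eta={sp.species_id: sp.true_eta for sp in species},
        truth_suitability={sp.species_id: sp.true_suitability for sp in species},
    )


# ---------------------------------------------------------------------------
# Stages (in-memory, with disk mirrors for the CLI)
# ---------------------------------------------------------------------------

def prepare_stack(world: World, cfg: RunConfig):
    """Derive the vegetation layers, append them to every stack, and run
    VIF elimination on the current stack; future stacks are subset to the
    retained predictors (vegetation layers held constant in the future)."""
    ndvi_max, ndvi_diff = derive_ndvi_layers(world.ndvi)

    def extended(stack: PredictorStack) -> PredictorStack:
        return PredictorStack(
            layers=stack.layers + [ndvi_max, ndvi_diff],
            names=stack.names + ["ndvi_max", "ndvi_diff"],
            kinds=stack.kinds + ["continuous", "continuous"],
        )

    current = extended(world.current)
    report = vif_select(
        current,
        threshold=cfg.prepare.vif_threshold,
        n_sample=cfg.prepare.vif_sample_n,
        seed=species_seed(cfg.seed, 0, stream=1),
    )
    current_sel = current.subset(report.retained)
    futures_sel = {
        key: extended(stack).subset(report.retained)
        for key, stack in world.futures.items()
    }
    return current_sel, futures_sel, report


def fit_and_evaluate(world: World, current: PredictorStack, cfg: RunConfig):
    """Cross-validate every species on the prepared current stack.

    Returns (evaluations, included, background_cells, features). A failure
    for one species is logged and that species excluded, without aborting
    the run.
    """
    bg = sample_background(
        current, n=cfg.model.background_n, seed=species_seed(cfg.seed, 0, stream=2)
    )
    features = build_features(
        current,
        classes=cfg.model.classes,
        n_knots=cfg.model.n_knots,
        background_values=current.values_at(bg),
    )
    evaluations = []
    for i, sid in enumerate(sorted(world.occurrences)):
        occ = world.occurrences[sid]
        if len(occ.cells) < cfg.evaluation.min_records:
            from .evaluation import SpeciesEvaluation

            evaluations.append(SpeciesEvaluation(species_id=sid, n_cells=len(occ.cells)))
            continue
        try:
            ev = evaluate_species(
                sid,
                occ.cells,
                bg,
                current,
                features,
                k=cfg.evaluation.k,
                beta0=cfg.model.beta0,
                max_iter=cfg.model.max_iter,
                threshold_percent=cfg.evaluation.threshold_percent,
                seed=species_seed(cfg.seed, i, stream=3),
            )
            evaluations.append(ev)
        except Exception:
            logger.exception("species %s failed; skipping", sid)
            from .evaluation import SpeciesEvaluation

            ev = SpeciesEvaluation(species_id=sid, n_cells=len(occ.cells))
            ev.included = False
            ev.exclusion_reason = "error"
            evaluations.append(ev)
    included, exclusions = filter_species(
        evaluations,
        min_records=cfg.evaluation.min_records,
        auc_floor=cfg.evaluation.auc_floor,
    )
    if exclusions:
        logger.info("excluded species: %s", exclusions)
    return evaluations, included, bg, features


def _stack_logistic_matrix(models, stack: PredictorStack, clamp: bool) -> np.ndarray:
    """Logistic predictions for several replicate models sharing features
    and scaling (same training background): the scaled feature matrix is
    built once per stack."""
    land = stack.land_mask
    cells = np.nonzero(land)
    X = np.column_stack([lyr.values[cells] for lyr in stack.layers])
    ref = models[0]
    G = ref.scaled_features(X, clamp=clamp)
    out = np.empty((len(models), G.shape[0]))
    for r, model in enumerate(models):
        q = np.exp(G @ model.lam - model.log_Z)
        qe = q * np.exp(model.entropy_H)
        out[r] = qe / (1.0 + qe)
    return out


def project_consensus(
    included,
    current: PredictorStack,
    futures: dict[tuple[int, str], PredictorStack],
    cfg: RunConfig,
):
    """Per-species consensus maps for the current stack and each future
    time x scenario, under both dispersal assumptions.

    Each replicate map is binarized at that replicate's own training
    threshold before the strict-majority vote.
    """
    grid = current.grid
    land = current.land_mask
    consensus_current: dict[str, RasterGrid] = {}
    consensus_future: dict[tuple[int, str, str], dict[str, RasterGrid]] = {
        (t, s, d): {} for (t, s) in futures for d in cfg.dispersal_modes
    }

    def vote(scores: np.ndarray, thresholds: np.ndarray) -> RasterGrid:
        binary = scores >= thresholds[:, None]
        counts = binary.sum(axis=0)
        vals = np.zeros(grid.shape)
        vals[np.nonzero(land)] = counts > len(thresholds) / 2.0
        return grid.like(vals, mask=~land)

    for ev in included:
        models = [r.model for r in ev.replicates]
        thresholds = np.array([r.threshold for r in ev.replicates])
        cur_scores = _stack_logistic_matrix(models, current, clamp=False)
        cur_map = vote(cur_scores, thresholds)
        consensus_current[ev.species_id] = cur_map
        for (t, s), fstack in futures.items():
            fut_scores = _stack_logistic_matrix(models, fstack, clamp=cfg.model.clamp)
            fut_map = vote(fut_scores, thresholds)
            for d in cfg.dispersal_modes:
                consensus_future[(t, s, d)][ev.species_id] = (
                    fut_map if d == "unlimited" else apply_no_dispersal(cur_map, fut_map)
                )
    return consensus_current, consensus_future


def richness_and_change(consensus_current, consensus_future, cfg: RunConfig):
    """Stack per-species maps into richness and change summaries.

    Produces the current richness map plus one future richness map per
    time x scenario x dispersal combination (12 for the default three
    times, two scenarios, two dispersal assumptions).
    """
    richness_maps = {"current": stack_richness(consensus_current)}
    summaries = []
    for (t, s, d), maps in consensus_future.items():
        tag = f"{t}_{s}_{d}"
        summary = summarize_change(consensus_current, maps, scenario_tag=f"{t}_{s}",
                                   dispersal=d)
        richness_maps[tag] = summary.richness_future
        summaries.append((t, s, d, summary))
    rows = []
    for t, s, d, summary in sorted(summaries, key=lambda r: (r[0], r[1], r[2])):
        row = {"time": t, "scenario": s, "dispersal": d}
        row.update(summary.means())
        rows.append(row)
    change_summary = pd.DataFrame(
        rows,
        columns=["time", "scenario", "dispersal", "mean_richness", "mean_gain",
                 "mean_loss", "mean_turnover"],
    )
    return richness_maps, summaries, change_summary


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    output_hashes: dict[str, str]
    species_log: list[dict]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


@dataclass
class RunResult:
    world: World
    vif_report: object
    evaluations: list
    included: list
    richness_maps: dict[str, RasterGrid]
    change_summary: pd.DataFrame
    pa_comparisons: pd.DataFrame
    pa_ttests: pd.DataFrame
    manifest: RunManifest


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None,
                 write_rasters: bool = False) -> RunResult:
    """Execute the whole analysis for one configuration.

    When `outdir` is given the CSV outputs and the run manifest are
    written there (rasters too with write_rasters=True; they are bulky and
    off by default). CSVs use fixed column order and 6-significant-digit
    floats so reruns with the same master seed are byte-identical.
    """
    world = simulate_world(cfg)
    current, futures, vif_report = prepare_stack(world, cfg)
    evaluations, included, bg, features = fit_and_evaluate(world, current, cfg)
    cons_cur, cons_fut = project_consensus(included, current, futures, cfg)
    richness_maps, summaries, change_summary = richness_and_change(
        cons_cur, cons_fut, cfg
    )
    pas = world.pas
    if cfg.pa.pa_ids is not None:
        keep = set(cfg.pa.pa_ids)
        pas = [p for p in pas if p.pa_id in keep]
    pa_comparisons, pa_ttests = assess_protected_areas(
        richness_maps,
        pas,
        current.land_mask,
        n_random_pixels=min(cfg.pa.n_random_pixels, int(current.land_mask.sum())),
        buffer_km=cfg.pa.buffer_km,
        seed=species_seed(cfg.seed, 0, stream=4),
    )

    species_log = [
        {
            "species": ev.species_id,
            "n_cells": ev.n_cells,
            "mean_auc": ev.mean_auc,
            "mean_tss": ev.mean_tss,
            "included": ev.included,
            "reason": ev.exclusion_reason,
            "background_n": len(bg),
            "converged": all(r.model.converged for r in ev.replicates)
            if ev.replicates else None,
        }
        for ev in evaluations
    ]

    hashes: dict[str, str] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        eval_df = evaluation_frame(evaluations)
        tables = {
            "species_evaluation.csv": eval_df,
            "vif_report.csv": vif_report_frame(vif_report),
            "change_summary.csv": change_summary,
            "pa_comparison.csv": pa_comparisons,
            "pa_ttest.csv": pa_ttests,
        }
        for name, df in tables.items():
            path = outdir / name
            df.to_csv(path, index=False, float_format=_CSV_FLOAT)
            hashes[name] = _sha256(path)
        write_occurrences_csv(
            outdir / "occurrences.csv",
            {sid: occ.records for sid, occ in world.occurrences.items()},
        )
        hashes["occurrences.csv"] = _sha256(outdir / "occurrences.csv")
        write_pas_geojson(outdir / "pas.geojson", world.pas)
        if write_rasters:
            rdir = outdir / "richness"
            rdir.mkdir(exist_ok=True)
            for tag, rmap in richness_maps.items():
                write_raster(rmap, rdir / f"richness_{tag}.asc")

    manifest = RunManifest(
        config=_config_echo(cfg),
        seed=cfg.seed,
        version=__version__,
        output_hashes=hashes,
        species_log=species_log,
    )
    if outdir is not None:
        manifest.to_json(Path(outdir) / "run_manifest.json")
    return RunResult(
        world=world,
        vif_report=vif_report,
        evaluations=evaluations,
        included=included,
        richness_maps=richness_maps,
        change_summary=change_summary,
        pa_comparisons=pa_comparisons,
        pa_ttests=pa_ttests,
        manifest=manifest,
    )


def evaluation_frame(evaluations) -> pd.DataFrame:
    rows = []
    for ev in evaluations:
        rows.append(
            {
                "species": ev.species_id,
                "n_cells": ev.n_cells,
                "mean_auc": ev.mean_auc,
                "sd_auc": ev.sd_auc,
                "mean_tss": ev.mean_tss,
                "thresholds": ";".join(
                    f"{r.threshold:.6g}" for r in ev.replicates
                ),
                "included": ev.included,
                "reason": ev.exclusion_reason or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["species", "n_cells", "mean_auc", "sd_auc", "mean_tss",
                 "thresholds", "included", "reason"],
    )


def _config_echo(cfg: RunConfig) -> dict:
    doc = dataclasses.asdict(cfg)
    doc["simulate"]["scenarios"] = dict(doc["simulate"]["scenarios"])
    return doc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Disk helpers for individual CLI stages
# ---------------------------------------------------------------------------

def write_world(world: World, outdir: str | Path) -> None:
    """Mirror a simulated world to disk (rasters, occurrences, reserves,
    and the truth tables) for the `simulate` CLI stage."""
    outdir = Path(outdir)
    (outdir / "current").mkdir(parents=True, exist_ok=True)
    for name, layer in zip(world.current.names, world.current.layers):
        write_raster(layer, outdir / "current" / f"{name}.asc")
    for (t, s), stack in world.futures.items():
        d = outdir / f"future_{t}_{s}"
        d.mkdir(exist_ok=True)
        for name, layer in zip(stack.names, stack.layers):
            write_raster(layer, d / f"{name}.asc")
    nd = outdir / "ndvi"
    nd.mkdir(exist_ok=True)
    for i, comp in enumerate(world.ndvi):
        write_raster(comp, nd / f"ndvi_{i:02d}.asc")
    write_occurrences_csv(
        outdir / "occurrences.csv",
        {sid: occ.records for sid, occ in world.occurrences.items()},
    )
    write_pas_geojson(outdir / "pas.geojson", world.pas)
    eta = pd.DataFrame(
        [
            {"species": sid, **{f"eta{i}": v for i, v in enumerate(vec)}}
            for sid, vec in sorted(world.truth_eta.items())
        ]
    )
    eta.to_csv(outdir / "truth_eta.csv", index=False, float_format=_CSV_FLOAT)
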