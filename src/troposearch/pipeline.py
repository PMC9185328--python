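"""End-to-end orchestration: data -> preprocessing -> GTO search -> reports.

A run takes a class-per-folder dataset (or a synthetic specification),
optionally SNR-cleans it, resizes and splits it, then drives the gorilla
troops optimizer over the 16-element hyperparameter space with the training
harness as the fitness function.  Artifacts per backbone: the decoded best
configuration, the full metric report and confusion counts of the best
solution, a per-iteration history CSV, an evaluation ledger (one JSON line
per trained solution), a log file, and a checkpoint that makes interrupted
runs resumable from the last completed iteration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitness import TrainConfig, evaluate_fitness
from .gto import (
    GTOParams,
    GorillaPopulation,
    exploration_step,
    exploitation_step,
    greedy_update,
    initialize_population,
)
from .preprocessing import (
    DatasetBundle,
    clean_dataset,
    load_image_tree,
    resize_to_input,
    split_dataset,
    write_manifest,
)
from .search_space import build_default_space
from .synthetic import SyntheticSpec, generate

__all__ = ["RunConfig", "RunResult", "run"]

logger = logging.getLogger("troposearch")


@dataclass
class RunConfig:
    """Everything a full optimization run needs.

    Defaults follow the study conditions: population 10, 10 iterations,
    5 epochs, 15% test share, SNR threshold 1.15, 128 x 128 x 3 inputs.
    """

    dataset_path: str | None = None
    synthetic: SyntheticSpec | None = None
    backbones: list[str] = field(default_factory=lambda: ["toy_cnn"])
    population: int = 10
    iterations: int = 10
    epochs: int = 5
    test_fraction: float = 0.15
    validation_fraction: float = 0.10
    snr_threshold: float | None = 1.15
    apply_cleaning: bool = True
    input_size: tuple[int, int, int] = (128, 128, 3)
    eval_on: str = "full"
    seed: int = 0
    output_dir: str = "runs/latest"
    resume: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.synthetic, dict):
            syn = dict(self.synthetic)
            if "image_size" in syn:
                syn["image_size"] = tuple(syn["image_size"])
            self.synthetic = SyntheticSpec(**syn)
        self.input_size = tuple(self.input_size)
        if self.dataset_path is None and self.synthetic is None:
            raise ValueError("either dataset_path or a synthetic spec is required")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        if self.synthetic is not None:
            d["synthetic"]["image_size"] = list(self.synthetic.image_size)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RunResult:
    """Outcome of one backbone's optimization."""

    backbone: str
    best_solution: np.ndarray
    best_fitness: float
    best_config: dict
    metric_report: dict
    confusion: dict | None
    history: pd.DataFrame
    output_dir: Path


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (outdir / "run.log").resolve()
        for h in logger.handlers
    ):
        fh = logging.FileHandler(outdir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)


def _prepare_bundle(config: RunConfig, outdir: Path) -> DatasetBundle:
    if config.dataset_path is not None:
        bundle = load_image_tree(config.dataset_path)
        logger.info("loaded %d images from %s", len(bundle), config.dataset_path)
    else:
        bundle, manifest = generate(config.synthetic)
        manifest.to_csv(outdir / "synthetic_manifest.csv", index=False)
        logger.info("generated %d synthetic images (K=%d)", len(bundle), bundle.n_classes)
    if config.apply_cleaning and config.snr_threshold is not None:
        write_manifest(bundle, outdir / "cleaning_manifest.csv", config.snr_threshold)
        bundle, removed = clean_dataset(bundle, config.snr_threshold)
        logger.info("SNR cleaning at %.2f removed %d images", config.snr_threshold, removed)
    bundle = DatasetBundle(
        images=[resize_to_input(img, config.input_size) for img in bundle.images],
        labels=bundle.labels,
        class_names=bundle.class_names,
        paths=bundle.paths,
    )
    split_dataset(
        bundle,
        test_fraction=config.test_fraction,
        validation_fraction=config.validation_fraction,
        seed=config.seed,
    )
    return bundle


def _save_checkpoint(path: Path, t: int, pop: GorillaPopulation, rng) -> None:
    state = {
        "t": t,
        "X": pop.X.tolist(),
        "fitness": pop.fitness.tolist(),
        "silverback": pop.silverback,
        "history": pop.history,
        "rng_state": rng.bit_generator.state,
    }
    tmp = path.with_suffix(".tmp")
    tmp.write_text(json.dumps(state))
    tmp.replace(path)


def _load_checkpoint(path: Path, rng) -> tuple[int, GorillaPopulation]:
    state = json.loads(path.read_text())
    X = np.asarray(state["X"], dtype=float)
    pop = GorillaPopulation(
        X=X,
        GX=X.copy(),
        fitness=np.asarray(state["fitness"], dtype=float),
        silverback=int(state["silverback"]),
        history=list(state["history"]),
    )
    rng.bit_generator.state = state["rng_state"]
    return int(state["t"]), pop


def _optimize_backbone(
    backbone: str, bundle: DatasetBundle, config: RunConfig, outdir: Path
) -> RunResult:
    space = build_default_space()
    params = GTOParams(
        N=config.population, Tmax=config.iterations, D=space.D, seed=config.seed
    )
    train_cfg = TrainConfig(
        epochs=config.epochs, input_size=config.input_size,
        seed=config.seed, eval_on=config.eval_on,
    )
    eval_log = open(outdir / "evaluations.jsonl", "a")

    def fitness_fn(x: np.ndarray) -> float:
        result = evaluate_fitness(x, bundle, backbone, train_cfg, space)
        eval_log.write(
            json.dumps(
                {
                    "solution": [round(v, 10) for v in np.asarray(x).tolist()],
                    "fitness": result.fitness,
                    "config": result.config.to_dict(),
                    "accuracy": result.metric_report.get("Accuracy"),
                }
            )
            + "\n"
        )
        return result.fitness

    rng = np.random.default_rng(config.seed)
    ckpt = outdir / "checkpoint.json"
    history_rows: list[dict] = []
    if config.resume and ckpt.exists():
        t0, pop = _load_checkpoint(ckpt, rng)
        logger.info("[%s] resumed from checkpoint at iteration %d", backbone, t0)
    else:
        pop = initialize_population(params, rng=rng)
        for i in range(params.N):
            val = fitness_fn(pop.X[i])
            pop.fitness[i] = val if np.isfinite(val) else np.inf
        pop.silverback = int(np.argmin(pop.fitness))
        pop.history.append(pop.best_fitness)
        t0 = 0
        _save_checkpoint(ckpt, t0, pop, rng)
        logger.info("[%s] initial best fitness %.4f", backbone, pop.best_fitness)

    for t in range(t0 + 1, params.Tmax + 1):
        exploration_step(pop, params, t, rng)
        greedy_update(pop, fitness_fn)
        exploitation_step(pop, params, t, rng)
        greedy_update(pop, fitness_fn)
        _save_checkpoint(ckpt, t, pop, rng)
        logger.info("[%s] iteration %d/%d best fitness %.4f",
                    backbone, t, params.Tmax, pop.best_fitness)

    per_iter = _per_iteration_best(pop.history)
    solution_json = json.dumps([round(v, 10) for v in pop.best_solution.tolist()])
    for t, best in enumerate(per_iter):
        history_rows.append(
            {"iteration": t, "best_fitness": best,
             "silverback_solution": solution_json if t == len(per_iter) - 1 else ""}
        )
    eval_log.close()

    best = evaluate_fitness(pop.best_solution, bundle, backbone, train_cfg, space)
    best.config.to_json(outdir / "best_config.json")
    from .metrics import write_report

    write_report(best.metric_report, outdir / "metrics.json", outdir / "metrics.csv")
    if best.confusion is not None:
        (outdir / "best_confusion.json").write_text(
            json.dumps(best.confusion.to_dict(), indent=2)
        )
    history = pd.DataFrame(history_rows)
    history.to_csv(outdir / "history.csv", index=False)
    logger.info("[%s] final best fitness %.4f", backbone, pop.best_fitness)
    return RunResult(
        backbone=backbone,
        best_solution=pop.best_solution,
        best_fitness=pop.best_fitness,
        best_config=best.config.to_dict(),
        metric_report=best.metric_report,
        confusion=None if best.confusion is None else best.confusion.to_dict(),
        history=history,
        output_dir=outdir,
    )


def _per_iteration_best(history: list[float]) -> list[float]:
    """Collapse the greedy-update trace (2 entries/iteration after the
    initial one) to one best-fitness value per iteration, iteration 0 being
    the initial population."""
    if not history:
        return []
    per_iter = [history[0]]
    per_iter.extend(history[i] for i in range(2, len(history), 2))
    return per_iter


def run(config: RunConfig) -> dict[str, RunResult]:
    """Execute the full loop for every configured backbone.

    Returns a mapping backbone name -> :class:`RunResult`; artifacts land in
    ``output_dir/<backbone>/``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    bundle = _prepare_bundle(config, outdir)
    results: dict[str, RunResult] = {}
    for backbone in config.backbones:
        sub = outdir / backbone
        sub.mkdir(parents=True, exist_ok=True)
        results[backbone] = _optimize_backbone(backbone, bundle, config, sub)
    return results
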