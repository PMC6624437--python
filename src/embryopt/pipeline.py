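"""End-to-end orchestration: simulate, split, train, evaluate, sensitivity,
optimize, and in-silico validation, with a JSON run report.

The validation stage replaces the original wet-lab confirmation experiment:
the noise-free generator truth is evaluated at the selected optimum and
reported beside the model's prediction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from embryopt import anfis, metrics, nsga2, sensitivity, simulate
from embryopt.simulate import FEATURES, RESPONSES

logger = logging.getLogger("embryopt")

_MAX_SPLIT_ATTEMPTS = 100


@dataclass
class PipelineConfig:
    generator: simulate.GeneratorConfig = field(default_factory=simulate.GeneratorConfig)
    train: anfis.TrainConfig = field(default_factory=anfis.TrainConfig)
    nsga: nsga2.NsgaConfig = field(default_factory=nsga2.NsgaConfig)
    split_fraction: float = 0.75
    split_seed: int = 0
    run_sensitivity: bool = True
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = simulate.config_from_dict(d["generator"])
        if "train" in d:
            d["train"] = anfis.TrainConfig(**d["train"])
        if "nsga" in d:
            d["nsga"] = nsga2.NsgaConfig(**d["nsga"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = {
            "generator": simulate.config_to_dict(self.generator),
            "train": dataclasses.asdict(self.train),
            "nsga": dataclasses.asdict(self.nsga),
            "split_fraction": self.split_fraction,
            "split_seed": self.split_seed,
            "run_sensitivity": self.run_sensitivity,
            "output_dir": self.output_dir,
        }
        if d["nsga"]["bounds"] is not None:
            d["nsga"]["bounds"] = np.asarray(d["nsga"]["bounds"]).tolist()
        # JSON-native types throughout (tuples become lists)
        return json.loads(json.dumps(d))


def split(
    dataset: pd.DataFrame, fraction: float = 0.75, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shuffle-split with a train-covers-test range check per feature.

    Training size is floor(fraction * N).  If any continuous feature has a
    test value outside the training min/max, the split is redrawn with an
    incremented seed, failing loudly after 100 attempts.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(dataset)
    if n < 8:
        raise ValueError("dataset must have at least 8 rows")
    n_train = int(np.floor(fraction * n))
    for attempt in range(_MAX_SPLIT_ATTEMPTS):
        rng = np.random.default_rng(seed + attempt)
        perm = rng.permutation(n)
        train = dataset.iloc[perm[:n_train]]
        test = dataset.iloc[perm[n_train:]]
        tr, te = train[FEATURES], test[FEATURES]
        if (tr.min() <= te.min()).all() and (tr.max() >= te.max()).all():
            if attempt:
                logger.info("split coverage satisfied after %d redraws", attempt)
            return train.reset_index(drop=True), test.reset_index(drop=True)
    raise RuntimeError(
        f"could not achieve train-range coverage of the test set in "
        f"{_MAX_SPLIT_ATTEMPTS} attempts; the dataset likely has a unique extreme row"
    )


def validate_in_silico(
    ideal_x, generator_config: simulate.GeneratorConfig | None = None
) -> tuple[float, float]:
    """Noise-free generator truth (EF, NSE) at a candidate optimum."""
    _, ef, nse = simulate.true_response(ideal_x, generator_config)
    return ef, nse


def _clip_prediction(output_name: str, values: np.ndarray) -> np.ndarray:
    if output_name in ("cf", "ef"):
        return np.clip(values, 0.0, 100.0)
    return np.clip(values, 0.0, None)


def run(config: PipelineConfig | None = None) -> dict:
    """Execute the full pipeline and return the run report dictionary.

    Stages: generate, split, fit one model per output, fit reports,
    sensitivity per output, NSGA-II over the EF/NSE surrogates with bounds
    from the training data, ideal-point selection against observed maxima,
    and noise-free in-silico validation at the selected point.  If
    ``config.output_dir`` is set all artifacts are written there.
    """
    cfg = config or PipelineConfig()
    stage = "generate"
    try:
        dataset = simulate.generate(cfg.generator)

        stage = "split"
        train, test = split(dataset, cfg.split_fraction, cfg.split_seed)
        X_train = train[FEATURES].to_numpy()
        X_test = test[FEATURES].to_numpy()
        X_all = dataset[FEATURES].to_numpy()

        stage = "train"
        models: dict[str, anfis.AnfisModel] = {}
        traces: dict[str, list[float]] = {}
        fit_reports: list[metrics.FitReport] = []
        for name in RESPONSES:
            logger.info("fitting %s model", name.upper())
            model, trace = anfis.fit(
                X_train,
                train[name].to_numpy(),
                cfg.train,
                input_names=FEATURES,
                output_name=name,
            )
            models[name] = model
            traces[name] = trace
            for part, frame, X in (("train", train, X_train), ("test", test, X_test)):
                pred = _clip_prediction(name, model.predict(X))
                fit_reports.append(metrics.fit_report(name, part, frame[name].to_numpy(), pred))

        stage = "sensitivity"
        sens_reports: list[sensitivity.SensitivityReport] = []
        if cfg.run_sensitivity:
            y_all = {name: dataset[name].to_numpy() for name in RESPONSES}
            for name in RESPONSES:
                logger.info("sensitivity analysis for %s", name.upper())
                sens_reports.append(
                    sensitivity.sensitivity_report(
                        X_train,
                        train[name].to_numpy(),
                        X_all,
                        y_all[name],
                        FEATURES,
                        name,
                        cfg.train,
                    )
                )

        stage = "optimize"
        bounds = np.stack([X_train.min(axis=0), X_train.max(axis=0)], axis=1)
        nsga_cfg = dataclasses.replace(cfg.nsga, bounds=bounds)
        ef_model, nse_model = models["ef"], models["nse"]

        def objective(x: np.ndarray) -> tuple[float, float]:
            ef = float(_clip_prediction("ef", np.asarray([ef_model.predict(x)]))[0])
            nse = float(_clip_prediction("nse", np.asarray([nse_model.predict(x)]))[0])
            return ef, nse

        logger.info("running NSGA-II (%d x %d)", nsga_cfg.pop_size, nsga_cfg.n_generations)
        front = nsga2.evolve(objective, nsga_cfg)
        m = float(dataset["ef"].max())
        n_ref = float(dataset["nse"].max())
        ideal = nsga2.select_ideal_point(front, m, n_ref)

        stage = "validate"
        true_ef, true_nse = validate_in_silico(ideal.selected.x, cfg.generator)

        report = {
            "config": cfg.to_dict(),
            "seeds": {
                "generator": cfg.generator.seed,
                "split": cfg.split_seed,
                "train": cfg.train.seed,
                "nsga": cfg.nsga.seed,
            },
            "versions": {
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "dataset": {"n_rows": int(len(dataset)), "n_train": int(len(train)), "n_test": int(len(test))},
            "fit_reports": [r.to_dict() for r in fit_reports],
            "loss_traces": traces,
            "sensitivity": [r.to_dict() for r in sens_reports],
            "front": {
                "size": len(front),
                "max_ef": max(ind.objectives[0] for ind in front),
                "max_nse": max(ind.objectives[1] for ind in front),
            },
            "ideal_point": {
                "x": {k: float(v) for k, v in zip(FEATURES, ideal.selected.x)},
                "predicted_ef": ideal.selected.objectives[0],
                "predicted_nse": ideal.selected.objectives[1],
                "m": ideal.m,
                "n_ref": ideal.n_ref,
                "distance": ideal.distance,
            },
            "validation_in_silico": {"true_ef": true_ef, "true_nse": true_nse},
        }
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        simulate.write_csv(dataset, out / "dataset.csv")
        for name, model in models.items():
            model.save_json(out / f"model_{name.upper()}.json")
        with open(out / "fit_report.json", "w") as fh:
            json.dump([r.to_dict() for r in fit_reports], fh, indent=1)
        if sens_reports:
            pd.concat([r.to_frame() for r in sens_reports]).to_csv(
                out / "sensitivity.csv", index=False
            )
        front_df = pd.DataFrame(
            [
                {**{k: v for k, v in zip(FEATURES, ind.x)},
                 "ef": ind.objectives[0], "nse": ind.objectives[1],
                 "rank": ind.rank, "crowding": ind.crowding}
                for ind in front
            ]
        )
        front_df.to_csv(out / "pareto_front.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)

    return report
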