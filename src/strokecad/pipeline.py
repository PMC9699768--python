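"""End-to-end orchestration: simulate -> preprocess -> extract -> train ->
evaluate, driven by a schema-validated YAML-able config with one global
seed fanned out to per-stage substreams.

Every artifact the pipeline writes embeds (JSON key or leading ``#``
comment line) the SHA-256 hash of the config that produced it, and the
feature table and trained model are cached under that hash so a rerun
with an unchanged config resumes instead of recomputing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import evaluation, features, fixtures, preprocess, sae
from .errors import InputError, StrokeCADError
from .optim import SBOConfig

log = logging.getLogger("strokecad")


class FixturesStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = "images"  # "images" or "features"
    n_per_class: list[int] = Field(default_factory=lambda: list(fixtures.DEFAULT_CLASS_SIZES))
    image_size: tuple[int, int] = (64, 64)
    noise_sd: float = 0.05
    class_contrast: float = 1.0
    # feature-table mode
    n_features: int = 10
    separation: float = 6.0


class PreprocessStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: str = "otsu"
    fixed_value: float | None = None
    literal_binary: bool = False


class FeaturesStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    backend: str = features.BUILTIN_EXTRACTOR
    fusion: str = "concat"


class SBOStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 20
    iterations: int = 30
    trust_radius: float = 0.5
    alpha: float = 0.94
    z: float = 0.02
    mutation_prob: float = 0.05


class TrainStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hidden: list[int] = Field(default_factory=lambda: [64, 32])
    activation: str = "sigmoid"
    pretrain_epochs: int = 100
    finetune_epochs: int = 400
    learning_rate: float = 0.2
    test_fraction: float = 0.2
    standardize: bool = True
    sbo_mode: str = "weights"  # "off", "weights"
    sbo: SBOStage = Field(default_factory=SBOStage)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    workdir: str = "strokecad_run"
    verbose: bool = False
    stages: list[str] = Field(
        default_factory=lambda: ["fixtures", "preprocess", "extract", "train", "evaluate"]
    )
    fixtures: FixturesStage = Field(default_factory=FixturesStage)
    preprocess: PreprocessStage = Field(default_factory=PreprocessStage)
    features: FeaturesStage = Field(default_factory=FeaturesStage)
    train: TrainStage = Field(default_factory=TrainStage)

    def config_hash(self) -> str:
        # workdir/verbose do not affect results, so they don't enter the hash
        payload = self.model_dump(mode="json", exclude={"workdir", "verbose"})
        canonical = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)


def stage_seed(seed: int, stage: str) -> int:
    """Fan the global seed out to a per-stage substream (stable across
    platforms, always < 2**31)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _write_csv_with_hash(df, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def _stratified_split(labels: np.ndarray, test_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        k = max(1, int(round(test_fraction * idx.size)))
        test_idx.extend(idx[:k])
    mask = np.zeros(labels.size, dtype=bool)
    mask[test_idx] = True
    return ~mask, mask


def _build_feature_table(config: PipelineConfig) -> fixtures.LabeledFeatureTable:
    fx = config.fixtures
    if fx.mode == "features":
        return fixtures.generate_feature_table(
            fx.n_per_class, fx.n_features, fx.separation, seed=stage_seed(config.seed, "fixtures")
        )
    if fx.mode != "images":
        raise InputError(f"unknown fixtures mode {fx.mode!r}")
    spec = fixtures.FixtureSpec(
        n_per_class=tuple(fx.n_per_class),
        image_size=fx.image_size,
        noise_sd=fx.noise_sd,
        class_contrast=fx.class_contrast,
        seed=stage_seed(config.seed, "fixtures"),
    )
    image_set = fixtures.generate_images(spec)
    pp = config.preprocess
    processed = [
        preprocess.preprocess_image(
            img, method=pp.method, fixed_value=pp.fixed_value, literal_binary=pp.literal_binary
        )
        for img in image_set.images
    ]
    spec_x = features.ExtractorSpec(name=config.features.backend)
    matrix = features.extract_table(processed, [spec_x], strategy=config.features.fusion)
    return fixtures.LabeledFeatureTable(matrix=matrix, labels=np.asarray(image_set.labels))


def run_pipeline(config: PipelineConfig) -> tuple[evaluation.MetricsReport | None, dict]:
    """Execute the configured stages in order; returns the held-out metrics
    report and a manifest of artifacts written."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}
    if config.verbose:
        logging.basicConfig(level=logging.INFO)

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                log.info("stage %s: %.3fs (seed %d)", name, timings[name], stage_seed(config.seed, name))

        return _T()

    try:
        if "fixtures" in config.stages and config.fixtures.mode == "images":
            with timed("fixtures"):
                spec = fixtures.FixtureSpec(
                    n_per_class=tuple(config.fixtures.n_per_class),
                    image_size=config.fixtures.image_size,
                    noise_sd=config.fixtures.noise_sd,
                    class_contrast=config.fixtures.class_contrast,
                    seed=stage_seed(config.seed, "fixtures"),
                )
                sidecar = fixtures.save_images(fixtures.generate_images(spec), workdir / "images")
            artifacts["images"] = str(sidecar)

        needs_features = bool({"extract", "train", "evaluate"} & set(config.stages))
        if not needs_features:
            manifest = {
                "config_hash": chash,
                "seed": config.seed,
                "timings": timings,
                "artifacts": artifacts,
            }
            (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            return None, manifest

        # preprocess + extract, cached by config hash
        features_csv = workdir / "features.csv"
        table = None
        if features_csv.exists():
            first = features_csv.open().readline().strip()
            if first == f"# config_hash={chash}":
                import pandas as pd

                df = pd.read_csv(features_csv, comment="#")
                labels = df.pop("label").to_numpy(dtype=int)
                table = fixtures.LabeledFeatureTable(matrix=df.to_numpy(float), labels=labels)
                log.info("extract: reusing cached %s", features_csv)
        if table is None:
            with timed("extract"):
                table = _build_feature_table(config)
            import pandas as pd

            df = pd.DataFrame(table.matrix, columns=[f"f{i}" for i in range(table.matrix.shape[1])])
            df["label"] = table.labels
            _write_csv_with_hash(df, features_csv, chash)
        artifacts["features"] = str(features_csv)

        report = None
        if "train" in config.stages:
            tr = config.train
            with timed("train"):
                train_mask, test_mask = _stratified_split(
                    table.labels, tr.test_fraction, stage_seed(config.seed, "split")
                )
                X_train, y_train = table.matrix[train_mask], table.labels[train_mask]
                X_test, y_test = table.matrix[test_mask], table.labels[test_mask]
                if tr.standardize:
                    stats = features.FusionStats.fit(X_train)
                    X_train = np.vstack([stats.apply(r) for r in X_train])
                    X_test = np.vstack([stats.apply(r) for r in X_test])
                n_classes = int(table.labels.max()) + 1
                arch = sae.SAEArchitecture(
                    layer_sizes=(X_train.shape[1], *tr.hidden),
                    head_classes=n_classes,
                    activation=tr.activation,
                    pretrain_epochs=tr.pretrain_epochs,
                    finetune_epochs=tr.finetune_epochs,
                    learning_rate=tr.learning_rate,
                )
                model = sae.pretrain(X_train, arch, seed=stage_seed(config.seed, "pretrain"))
                model = sae.fine_tune(model, X_train, y_train, seed=stage_seed(config.seed, "finetune"))
                if tr.sbo_mode == "weights":
                    model = sae.sbo_optimize(
                        model,
                        X_train,
                        y_train,
                        sbo_config=SBOConfig(
                            n=tr.sbo.n,
                            iterations=tr.sbo.iterations,
                            seed=stage_seed(config.seed, "sbo"),
                            alpha=tr.sbo.alpha,
                            z=tr.sbo.z,
                            mutation_prob=tr.sbo.mutation_prob,
                        ),
                        trust_radius=tr.sbo.trust_radius,
                    )
                elif tr.sbo_mode != "off":
                    raise InputError(f"unknown sbo_mode {tr.sbo_mode!r}")
            model_path = workdir / "model.json"
            payload = json.loads(model.to_json())
            payload["config_hash"] = chash
            model_path.write_text(json.dumps(payload))
            artifacts["model"] = str(model_path)

            if "evaluate" in config.stages:
                with timed("evaluate"):
                    pred, _ = sae.predict(model, X_test)
                    cm = evaluation.confusion(y_test, pred, n_classes)
                    report = evaluation.evaluate_confusion(cm, epoch_tag="held-out")
                report_json = workdir / "report.json"
                rep_payload = json.loads(evaluation.report_to_json([report]))
                report_json.write_text(
                    json.dumps({"config_hash": chash, "reports": rep_payload}, indent=2)
                )
                _write_csv_with_hash(
                    evaluation.report_frame([report]), workdir / "report.csv", chash
                )
                artifacts["report"] = str(report_json)
    except StrokeCADError:
        raise
    except Exception as exc:  # attribute failures to their stage
        stage = next(reversed(timings), "setup")
        raise StrokeCADError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in ("fixtures", "split", "pretrain", "finetune", "sbo")},
        "timings": timings,
        "artifacts": artifacts,
    }
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report, manifest
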