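"""YAML-driven workflow configuration.

One YAML file governs the whole pipeline: spectrum admission (``msp``),
fingerprint type (``fingerprint``), m/z tokenization (``tokenizer``), network
hyperparameters (``model``), optimization (``train``), and decoding
(``predict``), plus a top-level ``task`` selecting train or predict. Missing
keys fall back to documented defaults; unknown keys warn; invalid values raise
:class:`~ms2fp.errors.ConfigError` naming the offending key. The fully
resolved configuration is echoed into the output directory as a provenance
log, and the echo re-parses to an equal configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ms2fp.errors import ConfigError
from ms2fp.fingerprints import FingerprintSpec
from ms2fp.model import ModelConfig
from ms2fp.msp_io import DEFAULT_FINGERPRINT_KEY, DEFAULT_PRECURSOR_ALIASES
from ms2fp.tokenizer import BIT_TOKEN_OFFSET, TokenVocabulary
from ms2fp.training import TrainConfig

CONFIG_ECHO_FILENAME = "config_echo.yaml"


@dataclass
class MspOptions:
    paths: tuple[str, ...] = ()
    min_coverage_fraction: float = 0.9
    precursor_aliases: tuple[str, ...] = DEFAULT_PRECURSOR_ALIASES
    fingerprint_key: str = DEFAULT_FINGERPRINT_KEY

    def __post_init__(self):
        if not 0 <= self.min_coverage_fraction <= 1:
            raise ConfigError("msp.min_coverage_fraction must be in [0, 1]")


@dataclass
class TokenizerOptions:
    use_entropy: bool = False
    precursor_pseudo_intensity: float = 2.0
    max_seq_len: int = 512


@dataclass
class PredictOptions:
    checkpoint: str | None = None
    beam_width: int = 5
    max_bits: int | None = None
    top_k: int = 5
    candidates: str | None = None
    output: str | None = None

    def __post_init__(self):
        if self.beam_width < 1:
            raise ConfigError("predict.beam_width must be at least 1")


@dataclass
class WorkflowConfig:
    task: str
    msp: MspOptions
    fingerprint: FingerprintSpec
    vocabulary: TokenVocabulary
    tokenizer: TokenizerOptions
    model: ModelConfig
    train: TrainConfig
    predict: PredictOptions


_KNOWN_SECTIONS = {"task", "msp", "fingerprint", "tokenizer", "model", "train", "predict"}


def _section(data: dict, name: str) -> dict:
    section = data.get(name, {}) or {}
    if not isinstance(section, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    return dict(section)


def _take(section: dict, section_name: str, known: set[str]) -> None:
    for key in section:
        if key not in known:
            warnings.warn(f"unknown configuration key {section_name}.{key}", stacklevel=3)


def load_yaml_config(path: str | Path, write_echo: bool = True) -> WorkflowConfig:
    """Parse and validate a workflow YAML file.

    When ``write_echo`` is set and the configuration names an output directory
    (``train.output_directory`` for training, the directory of
    ``predict.output`` for prediction), the resolved configuration is written
    there as ``config_echo.yaml``.
    """
    path = Path(path)
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    for key in data:
        if key not in _KNOWN_SECTIONS:
            warnings.warn(f"unknown configuration section {key!r}", stacklevel=2)

    task = data.get("task")
    if task is None:
        raise ConfigError("missing required key: task")
    if task not in ("train", "predict"):
        raise ConfigError(f"task must be 'train' or 'predict', got {task!r}")

    msp_raw = _section(data, "msp")
    _take(msp_raw, "msp", {"path", "paths", "min_coverage_fraction", "precursor_aliases", "fingerprint_key"})
    paths = msp_raw.get("paths", msp_raw.get("path", ()))
    if isinstance(paths, str):
        paths = (paths,)
    try:
        msp = MspOptions(
            paths=tuple(paths),
            min_coverage_fraction=float(msp_raw.get("min_coverage_fraction", 0.9)),
            precursor_aliases=tuple(msp_raw.get("precursor_aliases", DEFAULT_PRECURSOR_ALIASES)),
            fingerprint_key=str(msp_raw.get("fingerprint_key", DEFAULT_FINGERPRINT_KEY)),
        )
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid msp section: {err}") from err

    fp_raw = _section(data, "fingerprint")
    _take(fp_raw, "fingerprint", {"kind", "radius", "n_bits"})
    if "kind" not in fp_raw:
        raise ConfigError("missing required key: fingerprint.kind")
    try:
        fingerprint = FingerprintSpec(
            kind=str(fp_raw["kind"]),
            radius=int(fp_raw.get("radius", 2)),
            n_bits=int(fp_raw.get("n_bits", 166 if fp_raw["kind"] == "maccs" else 2048)),
        )
    except ValueError as err:
        raise ConfigError(f"invalid fingerprint section: {err}") from err

    tok_raw = _section(data, "tokenizer")
    _take(
        tok_raw,
        "tokenizer",
        {"mz_low", "mz_high", "interval", "use_entropy", "precursor_pseudo_intensity", "max_seq_len"},
    )
    try:
        vocabulary = TokenVocabulary(
            mz_low=float(tok_raw.get("mz_low", 50.0)),
            mz_high=float(tok_raw.get("mz_high", 1000.0)),
            interval=float(tok_raw.get("interval", 0.01)),
        )
    except ValueError as err:
        raise ConfigError(f"invalid tokenizer section: {err}") from err
    tokenizer = TokenizerOptions(
        use_entropy=bool(tok_raw.get("use_entropy", False)),
        precursor_pseudo_intensity=float(tok_raw.get("precursor_pseudo_intensity", 2.0)),
        max_seq_len=int(tok_raw.get("max_seq_len", 512)),
    )

    model_raw = _section(data, "model")
    _take(
        model_raw,
        "model",
        {
            "d_model",
            "n_heads",
            "n_encoder_layers",
            "n_decoder_layers",
            "d_feedforward",
            "dropout",
            "classic_pe",
            "scale_embedding",
        },
    )
    try:
        model = ModelConfig(
            encoder_vocab_size=vocabulary.vocab_size,
            decoder_vocab_size=fingerprint.n_bits + BIT_TOKEN_OFFSET,
            d_model=int(model_raw.get("d_model", 512)),
            n_heads=int(model_raw.get("n_heads", 2)),
            n_encoder_layers=int(model_raw.get("n_encoder_layers", 4)),
            n_decoder_layers=int(model_raw.get("n_decoder_layers", 4)),
            d_feedforward=int(model_raw.get("d_feedforward", 2048)),
            dropout=float(model_raw.get("dropout", 0.1)),
            max_seq_len=tokenizer.max_seq_len,
            classic_pe=bool(model_raw.get("classic_pe", False)),
            scale_embedding=bool(model_raw.get("scale_embedding", True)),
        )
    except ValueError as err:
        raise ConfigError(f"invalid model section: {err}") from err

    train_raw = _section(data, "train")
    _take(
        train_raw,
        "train",
        {
            "epochs",
            "batch_size",
            "label_smoothing",
            "learning_rate",
            "adam_betas",
            "weight_decay",
            "seed",
            "device",
            "output_directory",
        },
    )
    try:
        train = TrainConfig(
            epochs=int(train_raw.get("epochs", 10)),
            batch_size=int(train_raw.get("batch_size", 8)),
            label_smoothing=float(train_raw.get("label_smoothing", 0.1)),
            learning_rate=float(train_raw.get("learning_rate", 1e-4)),
            adam_betas=tuple(float(b) for b in train_raw.get("adam_betas", (0.9, 0.98))),
            weight_decay=float(train_raw.get("weight_decay", 0.0)),
            seed=int(train_raw.get("seed", 42)),
            device=str(train_raw.get("device", "cpu")),
            output_directory=train_raw.get("output_directory"),
        )
    except ValueError as err:
        raise ConfigError(f"invalid train section: {err}") from err

    predict_raw = _section(data, "predict")
    _take(
        predict_raw,
        "predict",
        {"checkpoint", "beam_width", "max_bits", "top_k", "candidates", "output"},
    )
    predict = PredictOptions(
        checkpoint=predict_raw.get("checkpoint"),
        beam_width=int(predict_raw.get("beam_width", 5)),
        max_bits=predict_raw.get("max_bits"),
        top_k=int(predict_raw.get("top_k", 5)),
        candidates=predict_raw.get("candidates"),
        output=predict_raw.get("output"),
    )

    config = WorkflowConfig(
        task=task,
        msp=msp,
        fingerprint=fingerprint,
        vocabulary=vocabulary,
        tokenizer=tokenizer,
        model=model,
        train=train,
        predict=predict,
    )
    if write_echo:
        echo_dir = None
        if task == "train" and train.output_directory:
            echo_dir = Path(train.output_directory)
        elif task == "predict" and predict.output:
            echo_dir = Path(predict.output).parent
        if echo_dir is not None:
            echo_dir.mkdir(parents=True, exist_ok=True)
            write_config_echo(config, echo_dir / CONFIG_ECHO_FILENAME)
    return config


def write_config_echo(config: WorkflowConfig, path: str | Path) -> None:
    """Write the resolved configuration back out as valid workflow YAML."""
    data = {
        "task": config.task,
        "msp": {
            "paths": list(config.msp.paths),
            "min_coverage_fraction": config.msp.min_coverage_fraction,
            "precursor_aliases": list(config.msp.precursor_aliases),
            "fingerprint_key": config.msp.fingerprint_key,
        },
        "fingerprint": asdict(config.fingerprint),
        "tokenizer": {
            "mz_low": config.vocabulary.mz_low,
            "mz_high": config.vocabulary.mz_high,
            "interval": config.vocabulary.interval,
            "use_entropy": config.tokenizer.use_entropy,
            "precursor_pseudo_intensity": config.tokenizer.precursor_pseudo_intensity,
            "max_seq_len": config.tokenizer.max_seq_len,
        },
        "model": {
            "d_model": config.model.d_model,
            "n_heads": config.model.n_heads,
            "n_encoder_layers": config.model.n_encoder_layers,
            "n_decoder_layers": config.model.n_decoder_layers,
            "d_feedforward": config.model.d_feedforward,
            "dropout": config.model.dropout,
            "classic_pe": config.model.classic_pe,
            "scale_embedding": config.model.scale_embedding,
        },
        "train": {
            "epochs": config.train.epochs,
            "batch_size": config.train.batch_size,
            "label_smoothing": config.train.label_smoothing,
            "learning_rate": config.train.learning_rate,
            "adam_betas": list(config.train.adam_betas),
            "weight_decay": config.train.weight_decay,
            "seed": config.train.seed,
            "device": config.train.device,
            "output_directory": config.train.output_directory,
        },
        "predict": {
            "checkpoint": config.predict.checkpoint,
            "beam_width": config.predict.beam_width,
            "max_bits": config.predict.max_bits,
            "top_k": config.predict.top_k,
            "candidates": config.predict.candidates,
            "output": config.predict.output,
        },
    }
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=False)
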