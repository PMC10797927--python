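"""End-to-end train/predict drivers behind the YAML configuration."""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from ms2fp.config import WorkflowConfig, load_yaml_config
from ms2fp.errors import (
    AnnotationError,
    ConfigError,
    DegenerateSpectrumError,
    StructureError,
    TokenizationError,
)
from ms2fp.fingerprints import resolve_target_bits
from ms2fp.inference import predict_file
from ms2fp.model import MintModel
from ms2fp.msp_io import coverage_filter, parse_msp
from ms2fp.tokenizer import encode_spectrum, encode_target
from ms2fp.training import CHECKPOINT_FILENAME, TrainLog, train


def build_dataset(config: WorkflowConfig):
    """Parse, filter and tokenize all configured .msp files into training pairs."""
    spectra = []
    for msp_path in config.msp.paths:
        with open(msp_path) as handle:
            parsed = parse_msp(
                handle,
                precursor_aliases=config.msp.precursor_aliases,
                fingerprint_key=config.msp.fingerprint_key,
            )
        if parsed.skipped_no_precursor or parsed.record_errors:
            warnings.warn(
                f"{msp_path}: skipped {parsed.skipped_no_precursor} blocks without "
                f"precursor m/z, {len(parsed.record_errors)} malformed blocks"
            )
        spectra.extend(parsed.spectra)

    kept, dropped = coverage_filter(
        spectra,
        config.msp.min_coverage_fraction,
        config.vocabulary.mz_low,
        config.vocabulary.mz_high,
    )
    if dropped:
        warnings.warn(f"{dropped} spectra dropped by the fragment-coverage filter")

    dataset = []
    n_unresolvable = 0
    for spectrum in kept:
        try:
            bits = resolve_target_bits(spectrum, config.fingerprint)
            tokens = encode_spectrum(
                spectrum,
                config.vocabulary,
                use_entropy=config.tokenizer.use_entropy,
                precursor_pseudo_intensity=config.tokenizer.precursor_pseudo_intensity,
                max_seq_len=config.tokenizer.max_seq_len,
            )
        except (AnnotationError, StructureError, TokenizationError, DegenerateSpectrumError):
            n_unresolvable += 1
            continue
        dataset.append((tokens, encode_target(bits)))
    if n_unresolvable:
        warnings.warn(f"{n_unresolvable} spectra without resolvable targets were skipped")
    return dataset


def run_train(config: WorkflowConfig) -> tuple[MintModel, TrainLog]:
    if not config.msp.paths:
        raise ConfigError("missing required key: msp.paths (training needs input spectra)")
    if not config.train.output_directory:
        raise ConfigError("missing required key: train.output_directory")
    dataset = build_dataset(config)
    if not dataset:
        raise ConfigError("no trainable spectra survived parsing and filtering")
    model = MintModel(config.model, seed=config.train.seed)
    model, log = train(
        dataset,
        model,
        config.train,
        vocab=config.vocabulary,
        fingerprint_spec=config.fingerprint,
    )
    out_dir = Path(config.train.output_directory)
    pd.DataFrame(
        {"epoch": range(len(log.epoch_losses)), "mean_loss": log.epoch_losses}
    ).to_csv(out_dir / "train_log.tsv", sep="\t", index=False)
    return model, log


def run_predict(config: WorkflowConfig) -> pd.DataFrame:
    if not config.msp.paths:
        raise ConfigError("missing required key: msp.paths (prediction needs input spectra)")
    checkpoint = config.predict.checkpoint
    if checkpoint is None and config.train.output_directory:
        checkpoint = str(Path(config.train.output_directory) / CHECKPOINT_FILENAME)
    if checkpoint is None:
        raise ConfigError("missing required key: predict.checkpoint")
    tables = []
    for msp_path in config.msp.paths:
        tables.append(
            predict_file(
                msp_path,
                checkpoint,
                beam_width=config.predict.beam_width,
                max_bits=config.predict.max_bits,
                min_coverage_fraction=config.msp.min_coverage_fraction,
                use_entropy=config.tokenizer.use_entropy,
                precursor_pseudo_intensity=config.tokenizer.precursor_pseudo_intensity,
                max_seq_len=config.tokenizer.max_seq_len,
                fingerprint_key=config.msp.fingerprint_key,
            )
        )
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    if config.predict.output:
        out_path = Path(config.predict.output)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_path, sep="\t", index=False)
    return table


def run(yaml_path: str) -> None:
    """Dispatch on the YAML task key; the single entry point behind the CLI."""
    config = load_yaml_config(yaml_path)
    if config.task == "train":
        _, log = run_train(config)
        print(
            f"training finished: best loss {log.best_loss:.6f} at epoch "
            f"{log.best_epoch} ({len(log.epoch_losses)} epochs)"
        )
    else:
        table = run_predict(config)
        n_ok = int((table["status"] == "ok").sum()) if len(table) else 0
        print(f"prediction finished: {n_ok}/{len(table)} spectra decoded")
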