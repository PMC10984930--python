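"""File-in/file-out workflows tying the modules into runnable pipelines.

These are the library-level equivalents of shell subcommands: each function
takes a :class:`RunConfig` (or explicit paths), reads tables through
:mod:`anrs.data_model`, runs the classifier or a generator, and writes its
artifact (JSON report, labeled CSV/ARFF table, simulated signal CSV).
All randomness is seed-controlled, so repeated invocations with the same
configuration produce byte-identical outputs.  Logging goes through the
``anrs`` logger, never into data files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .classify import CVReport, evaluate_kfold, predict, radius_sweep
from .data_model import (
    HybridSchema,
    HybridTable,
    read_arff,
    read_csv,
    write_arff,
    write_csv,
)
from .distance import fit_distance_params
from .errors import ConfigurationError
from .neighborhood import DEFAULT_RADIUS, class_approximations
from .synthetic import (
    SyntheticSpec,
    generate_hybrid_dataset,
    signal_to_frame,
    simulate_tremor_signal,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration shared by the file workflows.

    Defaults are the method's chosen settings: r = 0.002, k = 10,
    length-normalized Levenshtein on.
    """

    input: str
    format: str = "csv"  # "arff" | "csv"
    decision: Optional[str] = None
    r: float = DEFAULT_RADIUS
    k: int = 10
    seed: int = 0
    weights: Optional[dict[str, float]] = None
    normalize_lev: bool = True
    output: Optional[str] = None

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ConfigurationError("r must be nonnegative")
        if self.k < 2:
            raise ConfigurationError("k must be at least 2")
        if self.format not in ("arff", "csv"):
            raise ConfigurationError(f"unknown format {self.format!r}")


def load_table(config: RunConfig) -> HybridTable:
    path = Path(config.input)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    if config.format == "arff":
        return read_arff(path, decision=config.decision)
    if config.decision is None:
        raise ConfigurationError("CSV input requires a decision attribute name")
    return read_csv(path, decision=config.decision)


def run_cv(config: RunConfig) -> CVReport:
    """k-fold cross-validation; writes the report as JSON when output is set."""
    table = load_table(config)
    report = evaluate_kfold(
        table,
        k=config.k,
        r=config.r,
        seed=config.seed,
        weights=config.weights,
        normalize_lev=config.normalize_lev,
    )
    if config.output:
        Path(config.output).write_text(report.to_json() + "\n", encoding="utf-8")
        logger.info("wrote CV report to %s", config.output)
    return report


def run_predict(config: RunConfig, queries_path: str, output: str) -> HybridTable:
    """Label a query table with a model trained on ``config.input``.

    The queries file may lack the decision column; its condition attributes
    must match the training schema.  Writes the queries plus a predicted
    label column, row order preserved.
    """
    train = load_table(config)
    qpath = Path(queries_path)
    if not qpath.exists():
        raise ConfigurationError(f"queries file not found: {qpath}")
    schema = train.schema
    if config.format == "arff":
        queries = read_arff(qpath, decision=None)
        qschema = queries.schema
        q_names = set(qschema.condition_names) | {qschema.decision}
    else:
        import pandas as pd

        df = pd.read_csv(qpath, dtype=str, keep_default_na=False)
        q_names = set(df.columns)
        missing = [n for n in schema.condition_names if n not in q_names]
        if missing:
            raise ConfigurationError(f"queries missing attribute {missing[0]!r}")
        qschema = HybridSchema(attributes=schema.attributes, decision=schema.decision)
        from .data_model import _coerce_raw, apply_missing_policy  # shared policy

        keep = [c for c in df.columns if c in set(schema.condition_names) | {schema.decision}]
        queries = apply_missing_policy(_coerce_raw(qschema, df[keep]))
    missing = [n for n in schema.condition_names if n not in q_names]
    if missing:
        raise ConfigurationError(f"queries missing attribute {missing[0]!r}")

    params = fit_distance_params(
        train, weights=config.weights, normalize_lev=config.normalize_lev
    )
    predicted = [
        predict(queries.record(i), train, params, config.r).label
        for i in range(len(queries))
    ]
    out_df = queries.df[list(schema.condition_names)].copy()
    out_df["predicted_" + schema.decision] = predicted
    out_df.to_csv(output, index=False)
    logger.info("wrote %d predictions to %s", len(predicted), output)
    labeled = HybridTable(
        HybridSchema(attributes=schema.attributes, decision="predicted_" + schema.decision),
        out_df,
    )
    return labeled


def run_sweep(config: RunConfig, radii: Sequence[float]) -> dict[float, float]:
    """Radius sweep with identical folds; writes a JSON map when output set."""
    table = load_table(config)
    result = radius_sweep(
        table,
        radii,
        k=config.k,
        seed=config.seed,
        weights=config.weights,
        normalize_lev=config.normalize_lev,
    )
    if config.output:
        payload = {str(r): acc for r, acc in result.items()}
        Path(config.output).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return result


def run_approx(config: RunConfig) -> dict:
    """Dump lower/upper/boundary index sets of the input table as JSON-able dict."""
    table = load_table(config)
    params = fit_distance_params(
        table, weights=config.weights, normalize_lev=config.normalize_lev
    )
    approx = class_approximations(table, params, r=config.r)
    payload = {
        "lower": {c: sorted(v) for c, v in approx.lower.items()},
        "upper": {c: sorted(v) for c, v in approx.upper.items()},
        "boundary": sorted(approx.boundary),
    }
    if config.output:
        Path(config.output).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return payload


def run_simulate_table(spec: SyntheticSpec, output: str, fmt: str = "csv") -> HybridTable:
    """Generate a synthetic hybrid table and write it as CSV or ARFF."""
    table = generate_hybrid_dataset(spec)
    if fmt == "arff":
        write_arff(table, output, relation="synthetic_hybrid")
    elif fmt == "csv":
        write_csv(table, output)
    else:
        raise ConfigurationError(f"unknown format {fmt!r}")
    logger.info("wrote %d-row synthetic table to %s", len(table), output)
    return table


def run_simulate_signal(
    output: str,
    duration: float = 4.0,
    fs: float = 62.5,
    tremor_freq: float = 5.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
):
    """Simulate one tri-axial tremor signal and write it as (t, x, y, z) CSV."""
    sig = simulate_tremor_signal(
        duration=duration,
        fs=fs,
        tremor_freq=tremor_freq,
        amplitude=amplitude,
        noise_sd=noise_sd,
        seed=seed,
    )
    signal_to_frame(sig).to_csv(output, index=False)
    return sig
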