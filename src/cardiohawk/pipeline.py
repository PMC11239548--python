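"""End-to-end training loop: preprocessing, hyperparameter search space,
fitness evaluation, chaotic-hawk-driven model selection, and prediction.

The trainable object is a reservoir-style attention-GRU feature extractor
(weights fixed by seed) with a closed-form ELM head; the hawk optimizer
searches the hyperparameter box (architecture sizes and ELM regularization,
plus training-schedule fields kept for interface fidelity) by maximizing the
mean of validation accuracy, precision, recall and F1.  Because the only fit
step is a linear solve, each candidate evaluation is cheap and fully
deterministic given the master seed.

Preprocessing follows the sensor-cohort conventions: z-score normalization of
age/ecg/bp (population-SD convention), male=1/female=0 encoding, and
regression-based imputation in which records with missing or outlying sensor
values (|externally studentized residual| > 2.5) receive a prediction from a
linear model fitted on the complete cases.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from . import neural_model as nm
from .chaos_opt import Bounds, ChaoticState, LevyConfig, OptimizerConfig, optimize
from .evaluation import MetricSet, confusion, metrics

BUNDLE_VERSION = 1
NUMERIC_FEATURES = ("age", "ecg", "bp")
STUDENTIZED_CUTOFF = 2.5


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def normalize(
    records: pd.DataFrame, stats: Optional[dict] = None
) -> tuple[pd.DataFrame, dict]:
    """Z-score age/ecg/bp (SD with n denominator) and encode gender male=1.

    When ``stats`` is supplied it is applied unchanged (no leakage from new
    data); otherwise mean/SD are computed from the input.  A zero-variance
    numeric feature is degenerate and raises.
    """
    out = records.copy()
    if stats is None:
        stats = {}
        for col in NUMERIC_FEATURES:
            vals = out[col].to_numpy(dtype=float)
            mean, sd = float(np.mean(vals)), float(np.std(vals))
            if sd == 0.0:
                raise ValueError(f"zero-variance feature {col!r}")
            stats[col] = {"mean": mean, "sd": sd}
    for col in NUMERIC_FEATURES:
        out[col] = (out[col].astype(float) - stats[col]["mean"]) / stats[col]["sd"]
    out["gender"] = (out["gender"] == "Male").astype(float)
    return out, stats


def _studentized_model(records: pd.DataFrame, target: str, predictors: list[str]):
    """Flag outliers on the complete-case fit, then refit without them.

    The externally studentized (leave-one-out) residuals of the complete-case
    OLS identify non-meaningful entries; the model used for prediction is
    refit on the clean subset so a gross outlier cannot contaminate its own
    replacement value.
    """
    complete = records.dropna(subset=[target] + predictors)
    if len(complete) < 10:
        raise ValueError(
            f"need >= 10 complete records to fit the {target} imputation model, "
            f"have {len(complete)}"
        )
    X = sm.add_constant(complete[predictors].astype(float))
    model = sm.OLS(complete[target].astype(float), X).fit()
    resid = np.asarray(OLSInfluence(model).resid_studentized_external)
    outliers = np.abs(resid) > STUDENTIZED_CUTOFF
    if outliers.any() and (~outliers).sum() >= 10:
        clean = complete.iloc[~outliers]
        Xc = sm.add_constant(clean[predictors].astype(float))
        model = sm.OLS(clean[target].astype(float), Xc).fit()
    return model, complete.index, resid


def impute_studentized(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Fill missing ecg/bp and replace outlying values by regression predictions.

    ecg is regressed on bp+age and bp on ecg+age over the complete cases.
    Missing entries get the model prediction; complete entries whose
    externally studentized (leave-one-out) residual exceeds 2.5 in magnitude
    are flagged non-meaningful and likewise replaced.  Returns the imputed
    frame and a report with per-field imputation/outlier counts.
    """
    out = records.copy()
    report = {}
    plans = {"ecg": ["bp", "age"], "bp": ["ecg", "age"]}
    fitted = {}
    for target, predictors in plans.items():
        fitted[target] = _studentized_model(out, target, predictors)
    for target, predictors in plans.items():
        model, complete_idx, resid = fitted[target]
        missing_idx = out.index[out[target].isna() & out[predictors].notna().all(axis=1)]
        outlier_idx = complete_idx[np.abs(resid) > STUDENTIZED_CUTOFF]
        for idx_set, kind in ((missing_idx, "missing"), (outlier_idx, "outlier")):
            if len(idx_set):
                X = sm.add_constant(
                    out.loc[idx_set, predictors].astype(float), has_constant="add"
                )
                out.loc[idx_set, target] = model.predict(X).to_numpy()
        report[target] = {
            "imputed_missing": int(len(missing_idx)),
            "replaced_outliers": int(len(outlier_idx)),
        }
    still_missing = out[list(plans)].isna().any(axis=1)
    if still_missing.any():
        # both sensors absent: fall back to the complete-case column means
        for target in plans:
            col_mean = float(records[target].dropna().mean())
            out.loc[out[target].isna(), target] = col_mean
        report["mean_fallback"] = int(still_missing.sum())
    return out, report


def build_sequences(
    records: pd.DataFrame,
    window: int,
    streams: Optional[pd.DataFrame] = None,
    stats: Optional[dict] = None,
) -> np.ndarray:
    """Per-record (window, 4) sequences of (age, gender, ecg, bp) features.

    The ecg channel follows the record's sensor stream when one is available
    (normalized with the same ecg stats); otherwise the static feature vector
    is replicated across the window.  Records must already be normalized via
    :func:`normalize`, whose ``stats`` are needed to scale stream samples.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(records)
    base = records[["age", "gender", "ecg", "bp"]].to_numpy(dtype=float)
    seqs = np.repeat(base[:, None, :], window, axis=1)
    if streams is not None and len(streams):
        if stats is None:
            raise ValueError("normalization stats required to scale stream samples")
        mean, sd = stats["ecg"]["mean"], stats["ecg"]["sd"]
        grouped = streams.sort_values("sample_index").groupby("patient_id")["value"]
        stream_map = {pid: vals.to_numpy(dtype=float) for pid, vals in grouped}
        for row, pid in enumerate(records["patient_id"]):
            vals = stream_map.get(pid)
            if vals is None:
                continue
            if len(vals) < window:
                raise ValueError(
                    f"record {pid}: window {window} exceeds {len(vals)} stream samples"
                )
            seqs[row, :, 2] = (vals[:window] - mean) / sd
    return seqs


# ---------------------------------------------------------------------------
# Hyperparameter space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldSpec:
    lower: float
    upper: float
    integer: bool = False
    log: bool = False  # affine in log10 space

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("require lower < upper")
        if self.log and self.lower <= 0:
            raise ValueError("log-scaled field needs positive bounds")


@dataclass(frozen=True)
class HyperparamVector:
    epochs: int
    gru_cells: int
    hidden_units: int
    learning_rate: float
    batch_size: int
    dropout: float
    elm_regularization: float


@dataclass(frozen=True)
class HyperparamSpace:
    """Ordered per-field bounds; the optimizer works on the unit cube."""

    fields: dict = field(
        default_factory=lambda: {
            "epochs": FieldSpec(50, 300, integer=True),
            "gru_cells": FieldSpec(1, 3, integer=True),
            "hidden_units": FieldSpec(8, 64, integer=True),
            "learning_rate": FieldSpec(1e-4, 1e-2, log=True),
            "batch_size": FieldSpec(16, 128, integer=True),
            "dropout": FieldSpec(0.0, 0.5),
            "elm_regularization": FieldSpec(1e-2, 1e3, log=True),
        }
    )

    @property
    def dim(self) -> int:
        return len(self.fields)

    def bounds(self) -> Bounds:
        return Bounds.cube(0.0, 1.0, self.dim)

    def contains(self, hyper: HyperparamVector) -> bool:
        for name, spec in self.fields.items():
            v = getattr(hyper, name)
            if not (spec.lower - 1e-12 <= v <= spec.upper + 1e-12):
                return False
        return True


def decode_position(position: np.ndarray, space: HyperparamSpace) -> HyperparamVector:
    """Affine map from the optimizer's unit cube into the hyperparameter box.

    Log-scaled fields interpolate in log10 space; integral fields round
    half-up and are clipped into range.
    """
    position = np.asarray(position, dtype=float)
    if position.shape != (space.dim,):
        raise ValueError(f"position must have shape ({space.dim},)")
    values = {}
    for coord, (name, spec) in zip(position, space.fields.items()):
        frac = min(max(float(coord), 0.0), 1.0)
        if spec.log:
            lo, hi = np.log10(spec.lower), np.log10(spec.upper)
            val = 10.0 ** (lo + frac * (hi - lo))
        else:
            val = spec.lower + frac * (spec.upper - spec.lower)
        if spec.integer:
            val = int(min(max(np.floor(val + 0.5), spec.lower), spec.upper))
        values[name] = val
    return HyperparamVector(**values)


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitnessReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    fitness: float  # mean of accuracy, precision, recall, f1

    @classmethod
    def from_metrics(cls, m: MetricSet) -> "FitnessReport":
        return cls(
            accuracy=m.accuracy,
            precision=m.precision,
            recall=m.recall,
            specificity=m.specificity,
            f1=m.f1,
            fitness=(m.accuracy + m.precision + m.recall + m.f1) / 4.0,
        )


def _one_hot(labels: Sequence[str]) -> np.ndarray:
    pos = np.asarray([str(l) != "normal" for l in labels], dtype=int)
    out = np.zeros((len(pos), 2))
    out[np.arange(len(pos)), pos] = 1.0
    return out


def _build_extractor(hyper: HyperparamVector, d_in: int, seed: int):
    rng = np.random.default_rng(seed)
    layers = nm.init_layers(
        d_in, hyper.hidden_units, hyper.hidden_units, hyper.gru_cells, rng
    )
    return layers, rng


def evaluate_fitness(
    hyper: HyperparamVector,
    train: tuple[np.ndarray, Sequence[str]],
    validation: tuple[np.ndarray, Sequence[str]],
    seed: int,
    elm_width: int = 100,
    mode: str = "binary",
) -> FitnessReport:
    """Score one hyperparameter vector: seeded build, ELM fit, validation metrics.

    ``train``/``validation`` are (sequences, labels) pairs of already
    normalized (n, T, 4) arrays.  Fitness is the mean of validation accuracy,
    precision, recall and F1, bounded in [0, 1].
    """
    X_tr, y_tr = train
    X_va, y_va = validation
    if len(y_tr) == 0 or len(y_va) == 0:
        raise ValueError("both splits must be non-empty")
    layers, rng = _build_extractor(hyper, X_tr.shape[2], seed)
    head = nm.create_elm_head(hyper.hidden_units, elm_width, hyper.elm_regularization, rng)
    F_tr = nm.forward_features(X_tr, layers)
    head = nm.elm_fit(F_tr, _one_hot(y_tr), head)
    scores = nm.elm_predict(nm.forward_features(X_va, layers), head)
    preds = [nm.decide_class(row, mode=mode) for row in scores]
    return FitnessReport.from_metrics(metrics(confusion(list(y_va), preds)))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    variant: str = "lc_hhoa"
    population: int = 6
    iterations: int = 10
    patience: Optional[int] = None
    validation_fraction: float = 0.3
    window: int = 16
    elm_width: int = 100
    mode: str = "binary"
    seed: int = 0
    # accepted for interface fidelity; inert in the reservoir-style model
    momentum: float = 0.01
    max_depth: Optional[int] = None


@dataclass
class TrainedModel:
    layers: list
    head: nm.ELMHead
    normalization_stats: dict
    hyperparams: HyperparamVector
    fitness_trace: np.ndarray  # best validation fitness per optimizer iteration
    mode: str
    window: int
    model_seed: int
    search_report: dict = field(default_factory=dict)


def _split_records(
    records: pd.DataFrame, validation_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    labels = records["label"].to_numpy()
    val_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = min(max(int(round(validation_fraction * len(idx))), 1), len(idx) - 1)
        val_idx.extend(idx[:n_val].tolist())
    mask = np.zeros(len(records), dtype=bool)
    mask[val_idx] = True
    return np.flatnonzero(~mask), np.flatnonzero(mask)


def train(
    records: pd.DataFrame,
    streams: Optional[pd.DataFrame] = None,
    space: Optional[HyperparamSpace] = None,
    config: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Hawk-optimized model selection followed by a refit on all given records.

    The labeled cohort is imputed, split (stratified) into fit/validation
    parts, and the optimizer minimizes the negated validation fitness of
    decoded hyperparameter vectors.  Normalization stats and the imputation
    models are computed from the given records only — the caller's held-out
    test data never enters.  The selected configuration is refit on
    fit+validation and returned with the full validation-fitness trace.
    """
    if records["label"].isna().any():
        raise ValueError("all records must be labeled for training")
    if space is None:
        space = HyperparamSpace()
    if not space.fields:
        raise ValueError("empty hyperparameter space")

    seed_root = np.random.default_rng(config.seed)
    split_seed, opt_seed, model_seed = (
        int(s) for s in seed_root.integers(0, 2**31 - 1, size=3)
    )

    imputed, impute_report = impute_studentized(records.reset_index(drop=True))
    fit_idx, val_idx = _split_records(
        imputed, config.validation_fraction, np.random.default_rng(split_seed)
    )
    fit_part, val_part = imputed.iloc[fit_idx], imputed.iloc[val_idx]

    fit_norm, stats = normalize(fit_part)
    val_norm, _ = normalize(val_part, stats=stats)
    X_fit = build_sequences(fit_norm, config.window, streams, stats)
    X_val = build_sequences(val_norm, config.window, streams, stats)
    y_fit = fit_part["label"].tolist()
    y_val = val_part["label"].tolist()

    cache: dict[HyperparamVector, float] = {}

    def objective(position: np.ndarray) -> float:
        hyper = decode_position(position, space)
        if hyper not in cache:
            report = evaluate_fitness(
                hyper, (X_fit, y_fit), (X_val, y_val), model_seed,
                elm_width=config.elm_width, mode=config.mode,
            )
            cache[hyper] = -report.fitness
        return cache[hyper]

    opt_config = OptimizerConfig(
        population=config.population,
        max_iterations=config.iterations,
        variant=config.variant,
        seed=opt_seed,
        patience=config.patience,
    )
    result = optimize(objective, space.bounds(), opt_config)
    best_hyper = decode_position(result.best_position, space)

    # refit on fit+validation with stats recomputed over all training records
    all_norm, all_stats = normalize(imputed)
    X_all = build_sequences(all_norm, config.window, streams, all_stats)
    y_all = imputed["label"].tolist()
    layers, rng = _build_extractor(best_hyper, X_all.shape[2], model_seed)
    head = nm.create_elm_head(
        best_hyper.hidden_units, config.elm_width, best_hyper.elm_regularization, rng
    )
    head = nm.elm_fit(nm.forward_features(X_all, layers), _one_hot(y_all), head)

    return TrainedModel(
        layers=layers,
        head=head,
        normalization_stats=all_stats,
        hyperparams=best_hyper,
        fitness_trace=-result.trace,  # validation fitness, non-decreasing
        mode=config.mode,
        window=config.window,
        model_seed=model_seed,
        search_report={
            "evaluations": result.evaluations,
            "unique_candidates": len(cache),
            "best_validation_fitness": -result.best_fitness,
            "imputation": impute_report,
        },
    )


def predict(
    model: TrainedModel,
    records: pd.DataFrame,
    streams: Optional[pd.DataFrame] = None,
) -> list[str]:
    """Apply stored normalization and the forward path; never mutates the model."""
    if len(records) == 0:
        return []
    missing = [c for c in ("patient_id", "age", "gender", "ecg", "bp") if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    if records[["ecg", "bp"]].isna().any().any():
        raise ValueError("prediction records must be complete; impute first")
    norm, _ = normalize(records, stats=model.normalization_stats)
    X = build_sequences(norm, model.window, streams, model.normalization_stats)
    scores = nm.elm_predict(nm.forward_features(X, model.layers), model.head)
    return [nm.decide_class(row, mode=model.mode) for row in scores]


# ---------------------------------------------------------------------------
# Model bundle serialization (pure-text JSON; bit-exact round trip)
# ---------------------------------------------------------------------------


def _array_to_list(a: np.ndarray):
    return np.asarray(a, dtype=float).tolist()


def save_model(model: TrainedModel, path) -> None:
    """Single-file JSON bundle; float repr round-trips bit-exactly."""
    layers_payload = []
    for gru_w, attn in model.layers:
        layers_payload.append(
            {
                "gru": {k: _array_to_list(getattr(gru_w, k)) for k in (
                    "input_update", "input_reset", "input_candidate",
                    "recur_update", "recur_reset", "recur_candidate",
                    "bias_update", "bias_reset", "bias_candidate",
                )},
                "attention": {k: _array_to_list(getattr(attn, k)) for k in (
                    "query_proj", "key_proj", "value_proj",
                )},
            }
        )
    payload = {
        "version": BUNDLE_VERSION,
        "mode": model.mode,
        "window": model.window,
        "model_seed": model.model_seed,
        "normalization_stats": model.normalization_stats,
        "hyperparams": asdict(model.hyperparams),
        "fitness_trace": _array_to_list(model.fitness_trace),
        "layers": layers_payload,
        "head": {
            "hidden_proj": _array_to_list(model.head.hidden_proj),
            "hidden_bias": _array_to_list(model.head.hidden_bias),
            "regularization": model.head.regularization,
            "output_weights": _array_to_list(model.head.output_weights),
        },
        "search_report": model.search_report,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_model(path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {payload.get('version')!r}")
    layers = []
    for entry in payload["layers"]:
        gru_w = nm.GRUWeights(**{k: np.array(v, dtype=float) for k, v in entry["gru"].items()})
        attn = nm.AttentionParams(
            **{k: np.array(v, dtype=float) for k, v in entry["attention"].items()}
        )
        layers.append((gru_w, attn))
    head = nm.ELMHead(
        hidden_proj=np.array(payload["head"]["hidden_proj"], dtype=float),
        hidden_bias=np.array(payload["head"]["hidden_bias"], dtype=float),
        regularization=float(payload["head"]["regularization"]),
        output_weights=np.array(payload["head"]["output_weights"], dtype=float),
    )
    return TrainedModel(
        layers=layers,
        head=head,
        normalization_stats=payload["normalization_stats"],
        hyperparams=HyperparamVector(**payload["hyperparams"]),
        fitness_trace=np.array(payload["fitness_trace"], dtype=float),
        mode=payload["mode"],
        window=payload["window"],
        model_seed=payload["model_seed"],
        search_report=payload.get("search_report", {}),
    )
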