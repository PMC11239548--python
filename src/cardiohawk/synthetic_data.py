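"""Synthetic BAN-IoT cardiac cohort generator and CSV round-trip I/O.

Emulates the statistical structure of a wearable-sensor study cohort: 1,672
subjects aged 22-65 of whom 887 are healthy; diseased subjects carry systolic
blood pressure above 130 mmHg with high probability; healthy heart rate is
leptokurtic (heavy-peaked, Student-t) and capped near 160 bpm while diseased
heart rate is capped near 150 bpm; the scalar "ECG value" is a noisy summary
of a short per-record heart-rate sample stream, which also gives the
downstream recurrent feature extractor genuine temporal input.

Records travel as a pandas DataFrame with columns
``patient_id, age, gender, ecg, bp, label`` (the cohort CSV dialect);
streams as a long DataFrame ``patient_id, sample_index, value``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as _st

COHORT_COLUMNS = ["patient_id", "age", "gender", "ecg", "bp", "label"]
STREAM_COLUMNS = ["patient_id", "sample_index", "value"]
VALID_GENDERS = ("Male", "Female")
VALID_LABELS = ("normal", "disease", "disease1", "disease2")


class CohortFormatError(ValueError):
    """Malformed cohort CSV; message carries 1-based file line numbers."""


@dataclass(frozen=True)
class HeartRateSpec:
    """Location/scale (and optional t-distribution df) of a class's heart rate."""

    loc: float
    scale: float
    cap: float
    df: Optional[float] = None  # Student-t df for leptokurtic draws; None = normal
    floor: float = 40.0


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated study: 1,672 subjects (887 healthy), ages
    22-65, diseased systolic BP exceeding 130 mmHg with probability 0.8,
    heart-rate caps 160 (healthy) / 150 (diseased) with a heavy-peaked
    healthy distribution, and a 16-sample per-record heart-rate stream whose
    noisy mean is the ECG column.
    """

    n_total: int = 1672
    n_healthy: int = 887
    age_range: tuple[int, int] = (22, 65)
    healthy_bp: tuple[float, float] = (112.0, 8.0)  # mean, SD (mmHg)
    diseased_bp: tuple[float, float] = (142.0, 12.0)
    bp_threshold: float = 130.0
    diseased_bp_exceed_prob: float = 0.8
    healthy_hr: HeartRateSpec = field(default_factory=lambda: HeartRateSpec(72.0, 5.0, 160.0, df=5.0))
    diseased_hr: HeartRateSpec = field(default_factory=lambda: HeartRateSpec(96.0, 8.0, 150.0))
    ecg_noise_sd: float = 2.0
    stream_noise_sd: float = 3.0
    missing_rate: float = 0.0
    stream_length: int = 16
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.n_healthy <= self.n_total):
            raise ValueError("require 0 <= n_healthy <= n_total")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.healthy_bp[1] <= 0 or self.diseased_bp[1] <= 0:
            raise ValueError("BP SDs must be positive")
        if not (0.0 <= self.diseased_bp_exceed_prob <= 1.0):
            raise ValueError("diseased_bp_exceed_prob must lie in [0, 1]")
        if self.stream_length < 1:
            raise ValueError("stream_length must be >= 1")


def _truncated_normal(
    rng: np.random.Generator, loc: float, scale: float, low: float, high: float, size: int
) -> np.ndarray:
    a, b = (low - loc) / scale, (high - loc) / scale
    dist = _st.truncnorm(a, b, loc=loc, scale=scale)
    return dist.ppf(rng.uniform(size=size))


def _heart_rate_baselines(rng: np.random.Generator, spec: HeartRateSpec, size: int) -> np.ndarray:
    """Per-subject baseline heart rates, truncated to [floor, cap] by resampling."""
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        k = int(need.sum())
        if spec.df is not None:
            draws = spec.loc + spec.scale * rng.standard_t(spec.df, size=k)
        else:
            draws = rng.normal(spec.loc, spec.scale, size=k)
        out[need] = draws
        need = (out < spec.floor) | (out > spec.cap)
    return out


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; returns (records, streams) DataFrames.

    Exactly ``n_healthy`` records are labeled normal; row order is a seeded
    permutation so the classes interleave.  Each record's stream holds
    ``stream_length`` heart-rate samples around the subject's baseline, and
    the ECG column is the stream mean plus sensor noise.
    """
    rng = np.random.default_rng(spec.seed)
    n, n_healthy = spec.n_total, spec.n_healthy
    n_diseased = n - n_healthy

    labels = np.array(["normal"] * n_healthy + ["disease"] * n_diseased)
    labels = labels[rng.permutation(n)]
    healthy = labels == "normal"

    ages = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n)
    genders = np.where(rng.uniform(size=n) < 0.5, "Male", "Female")

    bp = np.empty(n)
    bp[healthy] = rng.normal(*spec.healthy_bp, size=int(healthy.sum()))
    # diseased BP: exceed the clinical threshold with the configured probability
    mu, sd = spec.diseased_bp
    exceed = rng.uniform(size=n_diseased) < spec.diseased_bp_exceed_prob
    d_bp = np.empty(n_diseased)
    if exceed.any():
        d_bp[exceed] = _truncated_normal(rng, mu, sd, spec.bp_threshold, np.inf, int(exceed.sum()))
    if (~exceed).any():
        d_bp[~exceed] = _truncated_normal(rng, mu, sd, -np.inf, spec.bp_threshold, int((~exceed).sum()))
    bp[~healthy] = d_bp

    baselines = np.empty(n)
    baselines[healthy] = _heart_rate_baselines(rng, spec.healthy_hr, int(healthy.sum()))
    baselines[~healthy] = _heart_rate_baselines(rng, spec.diseased_hr, n_diseased)

    caps = np.where(healthy, spec.healthy_hr.cap, spec.diseased_hr.cap)
    floors = np.where(healthy, spec.healthy_hr.floor, spec.diseased_hr.floor)
    samples = baselines[:, None] + rng.normal(0.0, spec.stream_noise_sd, size=(n, spec.stream_length))
    samples = np.clip(samples, floors[:, None], caps[:, None])
    ecg = samples.mean(axis=1) + rng.normal(0.0, spec.ecg_noise_sd, size=n)

    width = max(3, len(str(n)))
    ids = [f"ID{i + 1:0{width}d}" for i in range(n)]

    records = pd.DataFrame(
        {
            "patient_id": ids,
            "age": ages.astype(int),
            "gender": genders,
            "ecg": np.round(ecg, 4),
            "bp": np.round(bp, 4),
            "label": labels,
        }
    )
    streams = pd.DataFrame(
        {
            "patient_id": np.repeat(ids, spec.stream_length),
            "sample_index": np.tile(np.arange(spec.stream_length), n),
            "value": np.round(samples.ravel(), 4),
        }
    )
    if spec.missing_rate > 0:
        records, _ = inject_missing(records, spec.missing_rate, seed=rng.integers(2**31 - 1))
    return records, streams


def inject_missing(
    records: pd.DataFrame, rate: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask ecg/bp entries independently with probability ``rate``.

    Returns the masked copy and a shadow table of the original values
    (columns patient_id, field, value) for imputation-error scoring.
    """
    if not (0.0 <= rate <= 0.5):
        raise ValueError("rate must lie in [0, 0.5]")
    out = records.copy()
    rng = np.random.default_rng(seed)
    shadow_rows = []
    for col in ("ecg", "bp"):
        mask = rng.uniform(size=len(out)) < rate
        for pid, val in zip(out.loc[mask, "patient_id"], out.loc[mask, col]):
            shadow_rows.append({"patient_id": pid, "field": col, "value": val})
        out.loc[mask, col] = np.nan
    shadow = pd.DataFrame(shadow_rows, columns=["patient_id", "field", "value"])
    return out, shadow


def write_cohort(records: pd.DataFrame, path, streams: Optional[pd.DataFrame] = None,
                 streams_path=None) -> None:
    """Write the cohort CSV (and optional stream sidecar); NaN -> empty field."""
    out = records.reindex(columns=COHORT_COLUMNS)
    out.to_csv(path, index=False, na_rep="")
    if streams is not None:
        if streams_path is None:
            raise ValueError("streams given but no streams_path")
        streams.reindex(columns=STREAM_COLUMNS).to_csv(streams_path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Parse and validate a cohort CSV; empty ecg/bp/label fields mean missing."""
    try:
        raw = pd.read_csv(
            path,
            dtype={"patient_id": str, "gender": str, "label": str},
            keep_default_na=False,
            na_values=[""],
        )
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise CohortFormatError(f"{path}: {exc}") from exc
    missing_cols = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise CohortFormatError(f"{path}: missing columns {missing_cols}")
    errors = []
    for idx, row in raw.iterrows():
        line = idx + 2  # header is line 1
        if not isinstance(row["patient_id"], str) or not row["patient_id"].startswith("ID"):
            errors.append(f"line {line}: bad patient_id {row['patient_id']!r}")
        if row["gender"] not in VALID_GENDERS:
            errors.append(f"line {line}: bad gender {row['gender']!r}")
        if pd.notna(row["label"]) and row["label"] not in VALID_LABELS:
            errors.append(f"line {line}: bad label {row['label']!r}")
        for col in ("age", "ecg", "bp"):
            val = row[col]
            if pd.notna(val):
                try:
                    float(val)
                except (TypeError, ValueError):
                    errors.append(f"line {line}: non-numeric {col} {val!r}")
    if errors:
        raise CohortFormatError("; ".join(errors))
    out = raw.copy()
    out["age"] = pd.to_numeric(out["age"]).astype(int)
    out["ecg"] = pd.to_numeric(out["ecg"])
    out["bp"] = pd.to_numeric(out["bp"])
    return out[COHORT_COLUMNS]


def read_streams(path) -> pd.DataFrame:
    streams = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in STREAM_COLUMNS if c not in streams.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing stream columns {missing}")
    return streams[STREAM_COLUMNS]
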