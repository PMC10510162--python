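"""Synthetic single-snapshot vitals datasets for early-warning-score work.

Two tables are produced, 1,000 patients each by default:

* the *vitals* dataset — exactly the union of the inputs NEWS, the six-item
  MEWS and qSOFA require (respiratory rate, SpO2, supplemental oxygen, body
  temperature, systolic blood pressure, heart rate, AVPU, GCS, urine
  output); and
* the *distractor* dataset — the same columns plus clinical/demographic
  features (age, sex, weight, diastolic pressure, ward, pain score) that no
  score uses, for testing that ontology-driven retrieval ignores them.

Numeric vitals are drawn from a normal distribution parameterized by median
and IQR (sigma recovered from the IQR via the standard-normal quartile) and
truncated to an extreme range by rejection sampling, which preserves the
interior shape of the distribution.  GCS is never sampled: it is derived
from the sampled AVPU category through the published AVPU-to-GCS mapping.
Temperatures are recorded per patient in Fahrenheit or Celsius by a seeded
coin; missingness is independent per cell (a temperature and its unit tag
blank together).  Identical configuration and seed reproduce the dataset
byte for byte.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DatasetParseError, GenerationError
from .unit_conversion import CELSIUS, FAHRENHEIT, avpu_to_gcs, celsius_to_fahrenheit

#: 2 * Phi^-1(0.75): the width of the standard normal IQR.
_NORMAL_IQR_WIDTH = 2.0 * 0.6744897501960817

_REJECTION_CAP = 10_000  # max draws per accepted value before giving up

ID_COLUMN = "patient_id"
TEMPERATURE_COLUMN = "body_temperature"
TEMPERATURE_UNIT_COLUMN = "body_temperature_unit"

#: Fixed column order of the vitals dataset.
VITALS_COLUMNS = [
    ID_COLUMN,
    "respiratory_rate",
    "oxygen_saturation",
    "supplemental_oxygen",
    TEMPERATURE_COLUMN,
    TEMPERATURE_UNIT_COLUMN,
    "systolic_blood_pressure",
    "heart_rate",
    "avpu",
    "gcs",
    "urine_output",
]


@dataclass(frozen=True)
class VitalDistributionSpec:
    """Generative parameters for one dataset column."""

    name: str
    unit: str | None = None
    value_kind: str = "continuous"  # continuous | integer | categorical
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    range_min: float | None = None
    range_max: float | None = None
    precision: int = 0
    category_probs: dict[str, float] | None = None

    def __post_init__(self):
        if self.value_kind == "categorical":
            if not self.category_probs:
                raise ConfigurationError(f"{self.name}: categorical spec needs category_probs")
            total = sum(self.category_probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"{self.name}: category probabilities sum to {total}, not 1"
                )
        else:
            vals = (self.range_min, self.q1, self.median, self.q3, self.range_max)
            if any(v is None for v in vals):
                raise ConfigurationError(f"{self.name}: numeric spec incomplete")
            if not (self.range_min <= self.q1 <= self.median <= self.q3 <= self.range_max):
                raise ConfigurationError(
                    f"{self.name}: expected range_min <= q1 <= median <= q3 <= range_max"
                )


@dataclass
class DatasetConfig:
    """Everything a dataset generation run depends on, except the seed."""

    vitals: list[VitalDistributionSpec]
    distractors: list[VitalDistributionSpec] = field(default_factory=list)
    n_patients: int = 1000
    missing_rate: float = 0.05
    fahrenheit_fraction: float = 0.5

    def spec(self, name: str) -> VitalDistributionSpec:
        for s in self.vitals + self.distractors:
            if s.name == name:
                return s
        raise KeyError(name)


def _parse_spec(row: dict) -> VitalDistributionSpec:
    return VitalDistributionSpec(
        name=row["name"],
        unit=row.get("unit"),
        value_kind=row.get("value_kind", "continuous"),
        median=row.get("median"),
        q1=row.get("q1"),
        q3=row.get("q3"),
        range_min=row.get("range_min"),
        range_max=row.get("range_max"),
        precision=int(row.get("precision", 0)),
        category_probs={str(k): float(v) for k, v in row["category_probs"].items()}
        if row.get("category_probs")
        else None,
    )


def load_config(path: str | Path | None = None) -> DatasetConfig:
    """Load a generation config; defaults to the packaged distribution table."""
    if path is None:
        path = Path(str(resources.files("ewsso.data") / "distributions.yaml"))
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return DatasetConfig(
        vitals=[_parse_spec(r) for r in cfg.get("vitals", [])],
        distractors=[_parse_spec(r) for r in cfg.get("distractors", [])],
        n_patients=int(cfg.get("n_patients", 1000)),
        missing_rate=float(cfg.get("missing_rate", 0.05)),
        fahrenheit_fraction=float(cfg.get("fahrenheit_fraction", 0.5)),
    )


# ---------------------------------------------------------------------------
# primitive samplers
# ---------------------------------------------------------------------------

def sigma_from_iqr(q1: float, q3: float) -> float:
    """Standard deviation of the normal whose quartiles are (q1, q3)."""
    if q3 <= q1:
        raise ValueError(f"q3 ({q3}) must exceed q1 ({q1})")
    return (q3 - q1) / _NORMAL_IQR_WIDTH


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_truncated_normal(
    spec: VitalDistributionSpec, n: int, seed
) -> np.ndarray:
    """Draw *n* values from the spec's truncated normal, rounded to its
    recording precision (integer kinds yield whole numbers).

    Truncation is by rejection: out-of-range draws are resampled, which
    keeps the interior distribution shape intact (clipping would pile mass
    on the bounds).  Raises :class:`GenerationError` if the range excludes
    essentially all central mass.
    """
    if spec.value_kind == "categorical":
        raise ValueError(f"{spec.name} is categorical; use sample_categories")
    rng = _as_rng(seed)
    mu, sigma = float(spec.median), sigma_from_iqr(spec.q1, spec.q3)
    out = np.empty(0, dtype=float)
    attempts = 0
    while out.size < n:
        budget = max(n - out.size, 16) * 2
        draws = rng.normal(mu, sigma, size=budget)
        attempts += budget
        kept = draws[(draws >= spec.range_min) & (draws <= spec.range_max)]
        out = np.concatenate([out, kept])
        if attempts > _REJECTION_CAP * max(n, 1) and out.size == 0:
            raise GenerationError(
                f"{spec.name}: truncation to [{spec.range_min}, {spec.range_max}] "
                f"rejected all {attempts} draws"
            )
    out = out[:n]
    out = np.round(out, spec.precision)
    # rounding can step just past a bound (e.g. 44.96 -> 45.0 is fine but
    # 45.04 -> 45.0 was already rejected); clip the rounded grid back in
    out = np.clip(out, spec.range_min, spec.range_max)
    if spec.value_kind == "integer":
        return out.astype(int)
    return out


def sample_categories(
    probs: dict[str, float], n: int, seed
) -> list[str]:
    """Draw *n* category labels with the given probabilities (seeded)."""
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"category probabilities sum to {total}, not 1")
    rng = _as_rng(seed)
    cats = list(probs.keys())
    idx = rng.choice(len(cats), size=n, p=[probs[c] for c in cats])
    return [cats[i] for i in idx]


def generate_avpu(probs: dict[str, float], n: int, seed) -> list[str]:
    """Sample AVPU consciousness categories (A/V/P/U)."""
    unknown = set(probs) - set("AVPU")
    if unknown:
        raise ValueError(f"unknown AVPU categories {sorted(unknown)}")
    return sample_categories(probs, n, seed)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(child) for child in np.random.SeedSequence(seed).spawn(n)]


def _sample_column(spec: VitalDistributionSpec, n: int, rng) -> list:
    if spec.value_kind == "categorical":
        return sample_categories(spec.category_probs, n, rng)
    values = sample_truncated_normal(spec, n, rng)
    if spec.value_kind == "integer":
        return [int(v) for v in values]
    return [round(float(v), spec.precision) for v in values]


def generate_vitals_dataset(
    config: DatasetConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Generate the vitals dataset (one row per patient, object dtype,
    ``None`` for missing cells)."""
    config = config or load_config()
    n = config.n_patients
    # one child stream per concern, in a fixed order, so adding a column
    # never reshuffles the draws of existing ones
    rngs = _spawn(seed, len(config.vitals) + 2)
    unit_rng, missing_rng = rngs[-2], rngs[-1]

    columns: dict[str, list] = {ID_COLUMN: [f"P{i + 1:04d}" for i in range(n)]}
    for spec, rng in zip(config.vitals, rngs):
        if spec.name == "avpu":
            columns["avpu"] = generate_avpu(spec.category_probs, n, rng)
        else:
            columns[spec.name] = _sample_column(spec, n, rng)

    columns["gcs"] = [avpu_to_gcs(a) for a in columns["avpu"]]

    # per-patient temperature unit; Fahrenheit values converted then recorded
    # at the same 0.1-degree precision
    temp_spec = config.spec(TEMPERATURE_COLUMN)
    use_f = unit_rng.random(n) < config.fahrenheit_fraction
    temps, units = [], []
    for c_value, f_flag in zip(columns[TEMPERATURE_COLUMN], use_f):
        if f_flag:
            temps.append(round(celsius_to_fahrenheit(c_value), temp_spec.precision))
            units.append(FAHRENHEIT)
        else:
            temps.append(c_value)
            units.append(CELSIUS)
    columns[TEMPERATURE_COLUMN] = temps
    columns[TEMPERATURE_UNIT_COLUMN] = units

    df = pd.DataFrame({c: columns[c] for c in VITALS_COLUMNS}, dtype=object)
    return _inject_missingness(df, config.missing_rate, missing_rng)


def generate_distractor_dataset(
    config: DatasetConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Generate the distractor dataset: the vitals columns plus clinical and
    demographic features no early warning score consumes.

    The vitals portion is identical to :func:`generate_vitals_dataset` run
    with the same config and seed; distractor columns use independent seeded
    streams and the same per-cell missingness rate.
    """
    config = config or load_config()
    vitals_names = {s.name for s in config.vitals} | {"gcs", TEMPERATURE_UNIT_COLUMN, ID_COLUMN}
    clash = [s.name for s in config.distractors if s.name in vitals_names]
    if clash:
        raise ConfigurationError(f"distractor columns collide with vitals: {clash}")

    df = generate_vitals_dataset(config, seed)
    n = config.n_patients
    rngs = _spawn(seed + 1_000_003, len(config.distractors) + 1)
    missing_rng = rngs[-1]
    extra: dict[str, list] = {}
    for spec, rng in zip(config.distractors, rngs):
        extra[spec.name] = _sample_column(spec, n, rng)
    extra_df = _inject_missingness(
        pd.DataFrame(extra, dtype=object), config.missing_rate, missing_rng
    )
    return pd.concat([df, extra_df], axis=1)


def _inject_missingness(df: pd.DataFrame, rate: float, rng) -> pd.DataFrame:
    """Blank each non-identifier cell independently with probability *rate*.

    A temperature and its unit column blank together (a recorded value always
    keeps its unit tag), driven by a single coin per patient.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError(f"missing_rate {rate} outside [0, 1]")
    if rate == 0.0:
        return df
    df = df.copy()
    for col in df.columns:
        if col in (ID_COLUMN, TEMPERATURE_UNIT_COLUMN):
            continue
        mask = rng.random(len(df)) < rate
        df[col] = pd.Series(
            [None if m else v for v, m in zip(df[col].tolist(), mask)],
            index=df.index, dtype=object,
        )
        if col == TEMPERATURE_COLUMN and TEMPERATURE_UNIT_COLUMN in df.columns:
            df[TEMPERATURE_UNIT_COLUMN] = pd.Series(
                [None if m else v for v, m in zip(df[TEMPERATURE_UNIT_COLUMN].tolist(), mask)],
                index=df.index, dtype=object,
            )
    return df


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_dataset(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a dataset as UTF-8 CSV; missing cells become empty strings.

    Cell formatting is plain ``str()`` of already-rounded values, so the
    same table always produces byte-identical output.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(df.columns))
        for _, row in df.iterrows():
            writer.writerow(["" if v is None else str(v) for v in row])
    return path


def read_dataset(path: str | Path, config: DatasetConfig | None = None) -> pd.DataFrame:
    """Read a dataset CSV back into the in-memory table form.

    Column types are recovered from the generation config (integers stay
    integers, continuous values floats, categories strings); empty strings
    decode to ``None``.  A non-numeric token in a numeric column raises
    :class:`DatasetParseError` naming the offending row.
    """
    config = config or load_config()
    kinds: dict[str, str] = {}
    for s in config.vitals + config.distractors:
        kinds[s.name] = s.value_kind
    kinds["gcs"] = "integer"

    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetParseError("empty file") from None
        rows = []
        for i, raw in enumerate(reader, start=2):  # header is line 1
            if len(raw) != len(header):
                raise DatasetParseError(f"expected {len(header)} fields, got {len(raw)}", row=i)
            parsed = []
            for col, cell in zip(header, raw):
                if cell == "":
                    parsed.append(None)
                    continue
                kind = kinds.get(col)
                try:
                    if kind == "integer":
                        parsed.append(int(cell))
                    elif kind == "continuous":
                        parsed.append(float(cell))
                    else:
                        parsed.append(cell)
                except ValueError:
                    raise DatasetParseError(
                        f"non-numeric value {cell!r} in column {col!r}", row=i
                    ) from None
            rows.append(parsed)
    return pd.DataFrame(rows, columns=header, dtype=object)
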