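"""Encoding of mixed-type supply-chain monitoring records.

Raw monitoring records mix categorical fields (province, supply-chain link,
hazard type, ...) with physical measurements (contaminant content,
temperature, humidity, ...).  Models downstream need a single real-valued
feature matrix, built without train/test leakage:

* categorical columns go through a dictionary step (an ordered vocabulary
  with an index map) followed by one-hot expansion, so that any two distinct
  categories sit at the same Euclidean distance from each other;
* numeric columns are standardized to zero mean and unit variance using
  statistics computed on the *training* rows only, ``z = (x - mu_j) / s_j``
  with the population standard-deviation convention.

The fitted state lives in :class:`EncodingSchema`, which is JSON-serializable
so a trained model can be shipped together with its exact transform.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "AREAS",
    "SchemaError",
    "EncodingSchema",
    "fit_schema",
    "encode",
    "encode_labels",
    "decode_labels",
    "level_to_index",
    "index_to_level",
    "level_area",
]

# ---------------------------------------------------------------------------
# Risk levels and areas
# ---------------------------------------------------------------------------

#: The eight ordinal risk levels, lowest risk first.
LEVELS = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]

#: Grouping of levels into regulatory areas: I-II safe, III warning,
#: IV-VIII danger.
AREAS = {
    "I": "safe",
    "II": "safe",
    "III": "warning",
    "IV": "danger",
    "V": "danger",
    "VI": "danger",
    "VII": "danger",
    "VIII": "danger",
}

_LEVEL_TO_INDEX = {lv: i for i, lv in enumerate(LEVELS)}


def level_to_index(level: str) -> int:
    """Map a risk level ``"I"``..``"VIII"`` to its integer index 0..7."""
    try:
        return _LEVEL_TO_INDEX[level]
    except KeyError:
        raise ValueError(f"unknown risk level {level!r}; expected one of {LEVELS}")


def index_to_level(index: int) -> str:
    """Inverse of :func:`level_to_index`."""
    if not 0 <= int(index) < len(LEVELS):
        raise ValueError(f"risk-level index {index} out of range 0..{len(LEVELS) - 1}")
    return LEVELS[int(index)]


def level_area(level: str) -> str:
    """Regulatory area (``safe`` / ``warning`` / ``danger``) of a level."""
    if level not in AREAS:
        raise ValueError(f"unknown risk level {level!r}")
    return AREAS[level]


def encode_labels(levels) -> np.ndarray:
    """Vector of risk levels (``"I"``..``"VIII"``) -> integer indices 0..7."""
    return np.asarray([level_to_index(lv) for lv in levels], dtype=np.int64)


def decode_labels(indices):
    """Integer indices 0..7 -> list of ``(level, area)`` pairs."""
    return [(index_to_level(i), level_area(index_to_level(i))) for i in np.asarray(indices)]


# ---------------------------------------------------------------------------
# Column registry
# ---------------------------------------------------------------------------

#: Raw string-typed columns of the monitoring schema (14 of the 33 attributes).
KNOWN_CATEGORICAL = [
    "province",
    "grain_type",
    "link",
    "production_area",
    "sampling_site",
    "hazard_type",
    "risk_item",
    "content_unit",
    "production_date",
    "carcinogenicity",
    "toxicity",
    "social_attention",
    "security",
    "regulatory_accessibility",
]

#: Raw numeric columns (19 of the 33 attributes).
KNOWN_NUMERIC = [
    "content",
    "temperature",
    "humidity",
    "light",
    "oxygen",
    "co2",
    "weight",
    "expiration_months",
    "health_guidance_value",
    "ld50",
    "adi",
    "iesti",
    "event_frequency",
    "hot_search_index",
    "annual_output",
    "planting_area",
    "production_price",
    "consumption_price",
    "standard_quantity",
]

#: Columns never encoded as features.
LABEL_COLUMNS = {"risk_level"}

_MASS_UNITS = {"mg/kg": 1.0, "ug/kg": 1e-3, "μg/kg": 1e-3}
_COUNT_UNITS = {"CFU/g", "MPN/g"}

_EPOCH_YEAR, _EPOCH_MONTH = 2015, 1


class SchemaError(ValueError):
    """Raised when records cannot support fitting or applying a schema."""


def _month_index(value) -> float:
    """``"YYYY.MM"`` calendar month -> months since 2015-01 (float, NaN-safe)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value)
    try:
        year, month = s.split(".")
        return (int(year) - _EPOCH_YEAR) * 12 + (int(month) - _EPOCH_MONTH)
    except Exception:
        raise SchemaError(f"unparseable production_date {value!r}; expected 'YYYY.MM'")


def _derive_numeric(df: pd.DataFrame) -> pd.DataFrame:
    """Derived numeric columns from unit-tagged / calendar raw fields.

    * ``content`` + ``content_unit`` split into a mass concentration on a
      common mg/kg scale (μg/kg divided by 1000) and a microbial count on a
      log10(1+x) scale, each zero when the other unit family applies;
    * ``content`` / ``health_guidance_value`` — the hazard quotient of risk
      assessment (content relative to its guidance limit, both in the
      record's unit) — on a log1p scale;
    * ``production_date`` becomes a month index counted from 2015-01.
    """
    out = {}
    if "content" in df.columns and "health_guidance_value" in df.columns:
        content = pd.to_numeric(df["content"], errors="coerce").to_numpy(dtype=float)
        guide = pd.to_numeric(df["health_guidance_value"], errors="coerce").to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            quotient = np.where(guide > 0, content / guide, np.nan)
        out["hazard_quotient_log"] = np.log1p(np.clip(quotient, 0.0, None))
    if "content" in df.columns and "content_unit" in df.columns:
        content = pd.to_numeric(df["content"], errors="coerce").to_numpy(dtype=float)
        unit = df["content_unit"].astype(str).to_numpy()
        mass = np.zeros(len(df))
        count = np.zeros(len(df))
        for u, factor in _MASS_UNITS.items():
            sel = unit == u
            mass[sel] = content[sel] * factor
        for u in _COUNT_UNITS:
            sel = unit == u
            count[sel] = np.log10(1.0 + np.clip(content[sel], 0.0, None))
        out["content_mass_mgkg"] = mass
        out["content_count_log10"] = count
    elif "content" in df.columns:
        out["content_mass_mgkg"] = pd.to_numeric(df["content"], errors="coerce").to_numpy(float)
    if "production_date" in df.columns:
        out["production_month_index"] = np.asarray(
            [_month_index(v) for v in df["production_date"]], dtype=float
        )
    return pd.DataFrame(out, index=df.index)


def _split_columns(df: pd.DataFrame):
    """Classify raw columns into (categorical, numeric) in frame order.

    Registered columns use the registry; unregistered columns fall back on
    dtype (object/string -> categorical).  Columns consumed by the derived
    transforms (content, content_unit, production_date) are handled there.
    """
    consumed = set()
    if "content" in df.columns and "content_unit" in df.columns:
        consumed |= {"content", "content_unit"}
    if "production_date" in df.columns:
        consumed.add("production_date")
    categorical, numeric = [], []
    for col in df.columns:
        if col in LABEL_COLUMNS or col in consumed:
            continue
        if col in KNOWN_CATEGORICAL:
            categorical.append(col)
        elif col in KNOWN_NUMERIC:
            numeric.append(col)
        elif pd.api.types.is_numeric_dtype(df[col]):
            numeric.append(col)
        else:
            categorical.append(col)
    return categorical, numeric


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------


@dataclass
class EncodingSchema:
    """Fitted per-column transform state.

    Attributes
    ----------
    vocabularies
        Ordered (lexicographic) category vocabulary per categorical column;
        the position in the list is the one-hot bit for that category.
    numeric_mean, numeric_std
        Training mean and population standard deviation per numeric column
        (including derived columns).
    constant_columns
        Numeric columns that were constant on the training rows; they are
        encoded as all-zeros.
    """

    categorical_columns: list = field(default_factory=list)
    numeric_columns: list = field(default_factory=list)
    vocabularies: dict = field(default_factory=dict)
    numeric_mean: dict = field(default_factory=dict)
    numeric_std: dict = field(default_factory=dict)
    constant_columns: list = field(default_factory=list)
    version: int = 1

    @property
    def feature_names(self) -> list:
        names = []
        for col in self.categorical_columns:
            names.extend(f"{col}={v}" for v in self.vocabularies[col])
        names.extend(self.numeric_columns)
        return names

    @property
    def width(self) -> int:
        return sum(len(self.vocabularies[c]) for c in self.categorical_columns) + len(
            self.numeric_columns
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "categorical_columns": self.categorical_columns,
                "numeric_columns": self.numeric_columns,
                "vocabularies": self.vocabularies,
                "numeric_mean": self.numeric_mean,
                "numeric_std": self.numeric_std,
                "constant_columns": self.constant_columns,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "EncodingSchema":
        d = json.loads(text)
        return cls(
            categorical_columns=d["categorical_columns"],
            numeric_columns=d["numeric_columns"],
            vocabularies=d["vocabularies"],
            numeric_mean=d["numeric_mean"],
            numeric_std=d["numeric_std"],
            constant_columns=d["constant_columns"],
            version=d.get("version", 1),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "EncodingSchema":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def fit_schema(records: pd.DataFrame) -> EncodingSchema:
    """Fit an :class:`EncodingSchema` on training records.

    Vocabularies are the sorted distinct non-missing values of each
    categorical column; numeric statistics are training means and population
    standard deviations of each (derived) numeric column, with missing values
    excluded.  A column with no observed value raises :class:`SchemaError`;
    a constant numeric column is flagged and later encoded as zeros.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records)
    if len(records) < 2:
        raise SchemaError("need at least 2 records to fit an encoding schema")
    categorical, numeric_raw = _split_columns(records)
    derived = _derive_numeric(records)

    schema = EncodingSchema(categorical_columns=list(categorical))
    for col in categorical:
        values = records[col].dropna()
        vocab = sorted({str(v) for v in values})
        if not vocab:
            raise SchemaError(f"column {col!r} has no non-missing value")
        schema.vocabularies[col] = vocab

    numeric_frame = pd.concat(
        [records[numeric_raw].apply(pd.to_numeric, errors="coerce"), derived], axis=1
    )
    schema.numeric_columns = list(numeric_frame.columns)
    for col in schema.numeric_columns:
        x = numeric_frame[col].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise SchemaError(f"column {col!r} has no non-missing value")
        mu = float(np.mean(x))
        sd = float(np.std(x))  # population convention
        if sd <= 0.0:
            warnings.warn(
                f"numeric column {col!r} is constant on the training rows; "
                "it will be encoded as all-zeros",
                UserWarning,
                stacklevel=2,
            )
            schema.constant_columns.append(col)
            sd = 1.0
        schema.numeric_mean[col] = mu
        schema.numeric_std[col] = sd
    return schema


def encode(records: pd.DataFrame, schema: EncodingSchema) -> np.ndarray:
    """Encode records with a fitted schema into an ``n x M`` float matrix.

    One-hot blocks carry exactly one hot bit per in-vocabulary value and are
    all-zero for a value unseen at fit time.  Numeric columns are
    standardized with the schema's training statistics; missing numeric
    values are imputed with the training mean (standardizing to 0).
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records)
    n = len(records)
    blocks = []
    for col in schema.categorical_columns:
        if col not in records.columns:
            raise SchemaError(f"records lack categorical column {col!r}")
        vocab = schema.vocabularies[col]
        index = {v: i for i, v in enumerate(vocab)}
        block = np.zeros((n, len(vocab)))
        codes = records[col].map(lambda v: index.get(str(v), -1) if pd.notna(v) else -1)
        codes = codes.to_numpy(dtype=np.int64)
        rows = np.nonzero(codes >= 0)[0]
        block[rows, codes[rows]] = 1.0
        blocks.append(block)

    derived = _derive_numeric(records)
    for col in schema.numeric_columns:
        if col in derived.columns:
            x = derived[col].to_numpy(dtype=float)
        elif col in records.columns:
            x = pd.to_numeric(records[col], errors="coerce").to_numpy(dtype=float)
        else:
            raise SchemaError(f"records lack numeric column {col!r}")
        if col in schema.constant_columns:
            blocks.append(np.zeros((n, 1)))
            continue
        mu, sd = schema.numeric_mean[col], schema.numeric_std[col]
        x = np.where(np.isfinite(x), x, mu)
        blocks.append(((x - mu) / sd)[:, None])
    return np.hstack(blocks) if blocks else np.empty((n, 0))
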