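"""Synthetic grain supply-chain monitoring database.

The study system monitored grain flows across 26 provinces from 2016-2019;
that database is private, so this module generates a stand-in with the same
schema: 33 attributes (14 string-typed, 19 numeric) covering the monitored
environment (temperature, humidity, light, O2, CO2), the product (grain
type, weight, expiration, production date), the detected hazard (hazard
type, risk item, content with unit) and extended hazard/social/economic/
regulatory indicators, plus an eight-level ordinal risk label.

Ground truth is a rule-based latent risk score.  Each record gets an
exceedance grade e in 0..4 (its hazard quotient content/limit digitized at
fixed cut-offs), a storage-environment grade v in 0..2 (temperature outside
10-25 degC; relative humidity above 65%), a supply-link grade l in 0..2
(production > circulation > sale) and a dangerousness grade x in 0..2
(high/severe toxicity; IARC group 1/2A carcinogenicity).  The score is
hierarchical — the exceedance grade dominates and the other rules order
records within a grade —

    z = w1 * e + 0.9 * w1 * (w2*v/2 + w3*l/2 + w4*x/2) / (w2 + w3 + w4)
      + epsilon * log1p(quotient) + Gaussian noise,

where the small epsilon term breaks ties monotonically in the hazard
quotient.  Labels are assigned by *ranking* z and cutting at the cumulative
per-level target counts, so the generated class distribution matches the
configured counts exactly.  A label-noise rate eta then shifts a random
fraction of labels by one level.  The default per-level counts reproduce the
reference distribution I..VIII = 15566, 3752, 1288, 2117, 2575, 1726, 1386,
5760 (34,170 records).

The regulatory limit table ships plausible fixed constants per hazard; they
are configuration, not claims about any national standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .encoding import LEVELS, level_area

__all__ = ["GeneratorConfig", "generate", "split", "summarize", "HAZARD_LIMITS"]

DEFAULT_LEVEL_COUNTS = (15566, 3752, 1288, 2117, 2575, 1726, 1386, 5760)

PROVINCES = [
    "Anhui", "Beijing", "Chongqing", "Fujian", "Guangdong", "Guangxi",
    "Guizhou", "Hainan", "Hebei", "Heilongjiang", "Henan", "Hubei", "Hunan",
    "Jiangsu", "Jiangxi", "Jilin", "Liaoning", "Qinghai", "Shaanxi",
    "Shandong", "Shanghai", "Shanxi", "Sichuan", "Tianjin", "Yunnan",
    "Zhejiang",
]
GRAIN_TYPES = [
    "rice", "wheat", "corn", "roughage", "rice-processed products",
    "wheat-processed products", "else",
]
LINKS = ["production", "circulation", "sale"]
PRODUCTION_AREAS = ["city", "village"]
SAMPLING_SITES = [
    "planting bases", "warehouse", "workshop", "transportation facility",
    "farmer markets", "supermarkets", "restaurants", "hotel", "laboratories",
]

#: hazard -> (risk item, content unit, regulatory limit in that unit).
#: Plausible fixed constants; shipped as data.
HAZARD_LIMITS = {
    "AFB1": ("mycotoxins", "μg/kg", 20.0),
    "OTA": ("mycotoxins", "μg/kg", 5.0),
    "ZON": ("mycotoxins", "μg/kg", 60.0),
    "DON": ("mycotoxins", "μg/kg", 1000.0),
    "T2": ("mycotoxins", "μg/kg", 100.0),
    "fumonisin": ("mycotoxins", "μg/kg", 2000.0),
    "Al": ("heavy metals", "mg/kg", 100.0),
    "As": ("heavy metals", "mg/kg", 0.5),
    "Cd": ("heavy metals", "mg/kg", 0.1),
    "Cr": ("heavy metals", "mg/kg", 1.0),
    "Hg": ("heavy metals", "mg/kg", 0.02),
    "Pb": ("heavy metals", "mg/kg", 0.2),
    "COLI": ("microorganisms", "CFU/g", 100.0),
    "Salmonella": ("microorganisms", "MPN/g", 3.0),
    "MRSA": ("microorganisms", "CFU/g", 10.0),
    "tebuconazole": ("pesticide residues", "mg/kg", 0.05),
    "benzopyrene (BaP)": ("pesticide residues", "μg/kg", 5.0),
    "malathion": ("pesticide residues", "mg/kg", 1.0),
}

CARCINOGENICITY = ["group_1", "group_2a", "group_2b", "group_3", "not_classified"]
TOXICITY = ["low", "moderate", "high", "severe"]
TRI_LEVEL = ["low", "medium", "high"]

#: Supply-link risk grade: threats accumulate toward the front-end links.
_LINK_GRADE = {"production": 2, "circulation": 1, "sale": 0}

#: Hazard-quotient cut-offs defining the exceedance grade 0..4.
RATIO_EDGES = (0.5, 1.0, 2.0, 5.0)

#: Weight of the monotone quotient tiebreaker inside the latent score.
_TIEBREAK = 0.01

_MONTHS = [f"{y}.{m:02d}" for y in range(2015, 2020) for m in range(1, 13)][: 4 * 12 + 7]


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic database.

    ``level_counts`` are the exact per-level record counts (the reference
    distribution by default); ``noise`` is the label-noise rate eta (shifting
    that fraction of labels by one level); ``latent_noise`` scales the
    Gaussian noise on the latent score relative to its deterministic spread;
    ``weights`` are (w1, w2, w3, w4) for the exceedance / environment / link /
    dangerousness rule grades.
    """

    level_counts: tuple = DEFAULT_LEVEL_COUNTS
    seed: int = 0
    noise: float = 0.02
    latent_noise: float = 0.005
    weights: tuple = (1.0, 0.5, 0.4, 0.3)
    hazard_limits: dict = field(default_factory=lambda: dict(HAZARD_LIMITS))

    def __post_init__(self):
        self.level_counts = tuple(int(c) for c in self.level_counts)
        if len(self.level_counts) != len(LEVELS):
            raise ValueError(f"level_counts must list {len(LEVELS)} counts")
        if any(c < 0 for c in self.level_counts):
            raise ValueError("level counts must be >= 0")
        if sum(self.level_counts) == 0:
            raise ValueError("total record count is 0")
        if sum(self.level_counts) > 5_000_000:
            raise ValueError("refusing to generate more than 5e6 records")
        if not 0.0 <= self.noise < 0.5:
            raise ValueError("label-noise rate must be in [0, 0.5)")

    @property
    def n_total(self) -> int:
        return sum(self.level_counts)

    def scaled(self, n_total: int) -> "GeneratorConfig":
        """Same level proportions rescaled to ``n_total`` records.

        Largest-remainder rounding keeps the total exact.
        """
        counts = np.asarray(self.level_counts, dtype=float)
        raw = counts / counts.sum() * n_total
        floors = np.floor(raw).astype(int)
        short = n_total - floors.sum()
        order = np.argsort(-(raw - floors))
        floors[order[:short]] += 1
        return replace(self, level_counts=tuple(int(c) for c in floors))


def _rank_cut_labels(z: np.ndarray, level_counts) -> np.ndarray:
    """Assign levels by ascending latent score, cutting at cumulative counts."""
    order = np.argsort(z, kind="stable")
    labels = np.empty(len(z), dtype=np.int64)
    bounds = np.cumsum(level_counts)
    start = 0
    for level, stop in enumerate(bounds):
        labels[order[start:stop]] = level
        start = stop
    return labels


def generate(config: GeneratorConfig | None = None):
    """Generate synthetic records and labels.

    Returns ``(records, labels)``: a DataFrame with the 33-attribute schema
    and a Series of risk levels ``"I"``..``"VIII"`` aligned on the index.
    Deterministic under ``config.seed``.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_total
    w1, w2, w3, w4 = cfg.weights

    hazards = list(cfg.hazard_limits)
    hazard = rng.choice(hazards, size=n)
    item = np.asarray([cfg.hazard_limits[h][0] for h in hazard])
    unit = np.asarray([cfg.hazard_limits[h][1] for h in hazard])
    limit = np.asarray([cfg.hazard_limits[h][2] for h in hazard])

    # Contaminant content: lognormal around the regulatory limit so that a
    # realistic minority of samples exceed it.
    ratio = np.exp(rng.normal(-0.7, 1.0, size=n))
    content = limit * ratio

    link = rng.choice(LINKS, size=n, p=[0.4, 0.3, 0.3])
    records = pd.DataFrame(
        {
            "province": rng.choice(PROVINCES, size=n),
            "grain_type": rng.choice(GRAIN_TYPES, size=n),
            "link": link,
            "production_area": rng.choice(PRODUCTION_AREAS, size=n),
            "sampling_site": rng.choice(SAMPLING_SITES, size=n),
            "hazard_type": hazard,
            "risk_item": item,
            "content": np.round(content, 6),
            "content_unit": unit,
            "temperature": np.round(rng.uniform(-10, 40, size=n), 2),
            "humidity": np.round(rng.uniform(0, 100, size=n), 2),
            "light": np.round(rng.uniform(0, 1500, size=n), 1),
            "oxygen": np.round(rng.uniform(17, 25, size=n), 2),
            "co2": np.round(rng.uniform(0, 1200, size=n), 1),
            "weight": np.round(rng.uniform(0, 100, size=n), 2),
            "expiration_months": rng.integers(3, 25, size=n),
            "production_date": rng.choice(_MONTHS, size=n),
            # the hazard's health guidance value is its regulatory limit,
            # in the same unit as the content field
            "health_guidance_value": limit,
            "ld50": np.round(rng.uniform(1, 5000, size=n), 1),
            "adi": np.round(rng.uniform(1e-4, 0.5, size=n), 6),
            "iesti": np.round(rng.uniform(0.0, 1.5, size=n), 4),
            "carcinogenicity": rng.choice(CARCINOGENICITY, size=n),
            "toxicity": rng.choice(TOXICITY, size=n),
            "social_attention": rng.choice(TRI_LEVEL, size=n, p=[0.5, 0.3, 0.2]),
            "security": rng.choice(TRI_LEVEL, size=n, p=[0.2, 0.3, 0.5]),
            "event_frequency": np.round(rng.uniform(0, 50, size=n), 1),
            "hot_search_index": np.round(rng.uniform(0, 100, size=n), 1),
            "annual_output": np.round(rng.uniform(100, 4000, size=n), 1),
            "planting_area": np.round(rng.uniform(50, 3000, size=n), 1),
            "production_price": np.round(rng.uniform(2000, 6000, size=n), 0),
            "consumption_price": 0.0,  # filled below
            "regulatory_accessibility": rng.choice(TRI_LEVEL, size=n, p=[0.3, 0.4, 0.3]),
            "standard_quantity": rng.integers(1, 41, size=n),
        }
    )
    records["consumption_price"] = np.round(
        records["production_price"] * rng.uniform(1.1, 1.8, size=n), 0
    )

    # Latent risk score ----------------------------------------------------
    exceedance_grade = np.digitize(ratio, RATIO_EDGES).astype(float)  # 0..4
    env_grade = (
        ((records["temperature"] < 10) | (records["temperature"] > 25)).astype(int)
        + (records["humidity"] > 65).astype(int)
    ).to_numpy()  # 0..2
    link_grade = np.asarray([_LINK_GRADE[v] for v in link], dtype=float)  # 0..2
    danger_grade = (
        records["toxicity"].isin(["high", "severe"]).astype(int)
        + records["carcinogenicity"].isin(["group_1", "group_2a"]).astype(int)
    ).to_numpy()  # 0..2
    w_sec = w2 + w3 + w4
    secondary = (
        (w2 * env_grade / 2.0 + w3 * link_grade / 2.0 + w4 * danger_grade / 2.0) / w_sec
        if w_sec > 0
        else np.zeros(n)
    )
    z = w1 * exceedance_grade + 0.9 * w1 * secondary + _TIEBREAK * np.log1p(ratio)
    spread = float(np.std(z))
    if spread > 0 and cfg.latent_noise > 0:
        z = z + rng.normal(0.0, cfg.latent_noise * spread, size=n)

    labels_idx = _rank_cut_labels(z, cfg.level_counts)

    if cfg.noise > 0:
        n_flip = int(round(cfg.noise * n))
        flip = rng.choice(n, size=n_flip, replace=False)
        delta = rng.choice([-1, 1], size=n_flip)
        labels_idx[flip] = np.clip(labels_idx[flip] + delta, 0, len(LEVELS) - 1)

    labels = pd.Series([LEVELS[i] for i in labels_idx], name="risk_level")
    return records, labels


def split(records: pd.DataFrame, labels, train_frac: float = 0.9, seed: int = 0):
    """Stratified train/test partition.

    Returns ``(train_records, test_records, train_labels, test_labels)``,
    stratified by risk level and reproducible under the seed.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    labels = pd.Series(labels).reset_index(drop=True)
    records = records.reset_index(drop=True)
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError(
            f"class(es) {counts[counts < 2].index.tolist()} have fewer than 2 members"
        )
    tr, te = train_test_split(
        np.arange(len(labels)),
        train_size=train_frac,
        stratify=labels,
        random_state=seed,
    )
    return (
        records.iloc[tr].reset_index(drop=True),
        records.iloc[te].reset_index(drop=True),
        labels.iloc[tr].reset_index(drop=True),
        labels.iloc[te].reset_index(drop=True),
    )


def summarize(records: pd.DataFrame, labels) -> dict:
    """Distribution report over supply links.

    Returns ``level_by_link`` (level x link counts), ``danger_share_by_link``
    (share of danger-area records per link) and ``link_share_by_contaminant``
    (per risk item, the share of its records in each link; rows sum to 1).
    """
    labels = pd.Series(labels, name="risk_level").reset_index(drop=True)
    records = records.reset_index(drop=True)
    level_by_link = (
        pd.crosstab(labels, records["link"])
        .reindex(index=LEVELS, columns=LINKS, fill_value=0)
    )
    areas = labels.map(level_area)
    danger = (
        pd.crosstab(records["link"], areas)
        .reindex(index=LINKS, fill_value=0)
        .reindex(columns=["safe", "warning", "danger"], fill_value=0)
    )
    danger_share = danger["danger"] / danger.sum(axis=1)
    link_share = pd.crosstab(records["risk_item"], records["link"], normalize="index")
    link_share = link_share.reindex(columns=LINKS, fill_value=0.0)
    return {
        "level_by_link": level_by_link,
        "danger_share_by_link": danger_share,
        "link_share_by_contaminant": link_share,
    }
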