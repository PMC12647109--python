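"""Loading, cleaning, encoding and normalization of drug-review tables.

A table row carries a drug name, medical condition, a user rating on [0, 10],
a free-text side-effect description, a review count and a drug class.  The
side-effect text is scored against a term->weight severity lexicon (a weighted
mean of term weights, higher = more severe), and the three quantitative
criteria (rating, severity, review count) are min-max scaled to [0, 1] so they
enter the optimizer's weighted-sum objective on a common footing.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "EmptyTableError",
    "SeverityLexicon",
    "DrugTable",
    "DEFAULT_SCHEMA",
    "TOY_LEXICON",
    "load_table",
    "clean_tokens",
    "severity_score",
    "compute_severity",
    "normalize",
    "prepare_table",
]


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class EmptyTableError(ValueError):
    """No rows survived cleaning."""


#: canonical field -> default CSV column name (Drugs.com review-table schema)
DEFAULT_SCHEMA = {
    "drug_name": "drug_name",
    "condition": "medical_condition",
    "rating": "rating",
    "side_effects": "side_effects",
    "review_count": "no_of_reviews",
    "drug_class": "drug_classes",
}

#: toy three-tier severity lexicon used in tests and by the synthetic generator
#: (mild=1, moderate=2, severe=3); terms are lower-cased, lemmatized forms.
TOY_LEXICON: dict[str, float] = {
    # mild
    "drowsiness": 1.0,
    "dizziness": 1.0,
    "headache": 1.0,
    "nausea": 1.0,
    "itching": 1.0,
    "dryness": 1.0,
    "fatigue": 1.0,
    "rash": 1.0,
    "sweating": 1.0,
    "constipation": 1.0,
    "diarrhea": 1.0,
    "insomnia": 1.0,
    "restlessness": 1.0,
    "flushing": 1.0,
    # moderate
    "vomiting": 2.0,
    "tremor": 2.0,
    "palpitation": 2.0,
    "hypertension": 2.0,
    "fainting": 2.0,
    "swelling": 2.0,
    "fever": 2.0,
    "confusion": 2.0,
    "depression": 2.0,
    "anxiety": 2.0,
    "vertigo": 2.0,
    "hive": 2.0,
    "wheezing": 2.0,
    "bruising": 2.0,
    # severe
    "seizure": 3.0,
    "hemorrhage": 3.0,
    "infarction": 3.0,
    "arrhythmia": 3.0,
    "jaundice": 3.0,
    "hallucination": 3.0,
    "stroke": 3.0,
    "hepatotoxicity": 3.0,
    "angioedema": 3.0,
    "bradycardia": 3.0,
    "coma": 3.0,
    "syncope": 3.0,
}


@dataclass
class SeverityLexicon:
    """Term -> severity weight mapping used by :func:`severity_score`.

    Out-of-lexicon tokens contribute ``default_weight`` and are counted in the
    denominator of the weighted mean, so unknown vocabulary dilutes rather than
    inflates the score.
    """

    entries: dict[str, float]
    default_weight: float = 1.0

    def __post_init__(self) -> None:
        for term, w in self.entries.items():
            if w <= 0:
                raise ValueError(f"lexicon weight for {term!r} must be > 0, got {w}")
        if self.default_weight < 0:
            raise ValueError("default_weight must be >= 0")

    @classmethod
    def toy(cls) -> "SeverityLexicon":
        """The built-in three-tier test lexicon."""
        return cls(dict(TOY_LEXICON))

    @classmethod
    def from_tsv(cls, path: str | Path, default_weight: float = 1.0) -> "SeverityLexicon":
        """Read a two-column ``term<TAB>weight`` file; ``#`` starts a comment line."""
        entries: dict[str, float] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, weight = line.split("\t")
            entries[term.strip().lower()] = float(weight)
        return cls(entries, default_weight=default_weight)

    def weight_bounds(self) -> tuple[float, float]:
        """(min, max) attainable per-record severity, default weight included."""
        weights = list(self.entries.values()) + [self.default_weight]
        return min(weights), max(weights)


@dataclass
class DrugTable:
    """An ordered drug-review table plus derived severity and normalization state.

    Record ``i`` (0-based, ``0 <= i < D``) is row ``i`` of :attr:`df`; the row
    order is fixed at load time so selection vectors are stable identifiers.
    """

    df: pd.DataFrame
    dropped: int = 0
    norm_stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_drugs(self) -> int:
        return len(self.df)

    @property
    def is_normalized(self) -> bool:
        return "rating_norm" in self.df.columns

    def criteria_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rating_norm, severity_norm, reviews_norm) as float arrays."""
        if not self.is_normalized:
            raise ValueError("table is not normalized; call normalize() first")
        return (
            self.df["rating_norm"].to_numpy(float),
            self.df["severity_norm"].to_numpy(float),
            self.df["reviews_norm"].to_numpy(float),
        )

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def write_sidecar(self, path: str | Path) -> None:
        """JSON sidecar with normalization stats and the cleaning drop count."""
        payload = {
            "n_drugs": self.n_drugs,
            "dropped_rows": self.dropped,
            "norm_stats": {k: list(v) for k, v in self.norm_stats.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


_TOKEN_RE = re.compile(r"[a-z]+")

# Minimal suffix lemmatizer for side-effect vocabulary: plural stripping only.
# Behaviour is frozen by golden tests; it is deliberately conservative so that
# clinical terms like "dizziness" (-ss) survive unchanged.
def _lemmatize(token: str) -> str:
    if len(token) > 4 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 4 and token.endswith(("shes", "xes", "zes", "sses")):
        return token[:-2]
    if len(token) > 3 and token.endswith("s") and not token.endswith("ss"):
        return token[:-1]
    return token


def clean_tokens(text: str) -> list[str]:
    """Lower-case, strip punctuation/digits, and lemmatize a side-effect text.

    Deterministic for a fixed input; empty or non-string input yields ``[]``.
    """
    if not isinstance(text, str) or not text:
        return []
    return [_lemmatize(tok) for tok in _TOKEN_RE.findall(text.lower())]


def severity_score(tokens: list[str], lexicon: SeverityLexicon) -> float:
    """Weighted mean severity S = sum_j w_j f_j / sum_j f_j over token counts.

    ``f_j`` counts occurrences of term ``j`` among ``tokens``; out-of-lexicon
    tokens take ``lexicon.default_weight``.  Returns 0.0 for an empty list.
    """
    if not tokens:
        return 0.0
    get = lexicon.entries.get
    total = 0.0
    for tok in tokens:
        total += get(tok, lexicon.default_weight)
    return total / len(tokens)


def load_table(path: str | Path, schema_map: dict[str, str] | None = None) -> DrugTable:
    """Read a drug-review CSV into an (unnormalized) :class:`DrugTable`.

    Rows with a missing drug name, rating, or review count — or a rating outside
    [0, 10] — are dropped and counted.  Categorical condition and drug-class
    fields are label-encoded by first appearance so codes are reproducible.

    Parameters
    ----------
    path:
        CSV file with a header row (comma-delimited, UTF-8).
    schema_map:
        Overrides for :data:`DEFAULT_SCHEMA`, mapping canonical field names
        (``drug_name``, ``condition``, ``rating``, ``side_effects``,
        ``review_count``, ``drug_class``) to the file's column names.
    """
    schema = dict(DEFAULT_SCHEMA)
    if schema_map:
        unknown = set(schema_map) - set(schema)
        if unknown:
            raise SchemaError(f"unknown schema fields: {sorted(unknown)}")
        schema.update(schema_map)

    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [col for col in schema.values() if col not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s) in {path}: {missing}")

    df = pd.DataFrame(
        {
            "drug_name": raw[schema["drug_name"]],
            "condition": raw[schema["condition"]].fillna(""),
            "rating_raw": pd.to_numeric(
                raw[schema["rating"]].str.replace(",", "", regex=False), errors="coerce"
            ),
            "side_effect_text": raw[schema["side_effects"]].fillna(""),
            "review_count": pd.to_numeric(
                raw[schema["review_count"]].str.replace(",", "", regex=False),
                errors="coerce",
            ),
            "drug_class": raw[schema["drug_class"]].fillna(""),
        }
    )

    n_before = len(df)
    keep = (
        df["drug_name"].notna()
        & (df["drug_name"].str.strip() != "")
        & df["rating_raw"].notna()
        & df["rating_raw"].between(0.0, 10.0)
        & df["review_count"].notna()
        & (df["review_count"] >= 0)
    )
    df = df.loc[keep].reset_index(drop=True)
    if df.empty:
        raise EmptyTableError(f"no usable rows in {path} ({n_before} read)")
    df["review_count"] = df["review_count"].round().astype(int)

    for col, code in (("condition", "condition_code"), ("drug_class", "class_code")):
        order = {v: i for i, v in enumerate(dict.fromkeys(df[col]))}
        df[code] = df[col].map(order).astype(int)

    return DrugTable(df=df, dropped=n_before - len(df))


def compute_severity(
    table: DrugTable,
    lexicon: SeverityLexicon,
    metric: str = "severity",
) -> DrugTable:
    """Attach the per-record side-effect score column ``severity``.

    ``metric="severity"`` (default) uses the lexicon-weighted mean of
    :func:`severity_score`; ``metric="token_count"`` uses the raw token count
    of the cleaned side-effect text instead.
    """
    if metric not in ("severity", "token_count"):
        raise ValueError(f"unknown side-effect metric {metric!r}")
    token_lists = [clean_tokens(t) for t in table.df["side_effect_text"]]
    if metric == "severity":
        values = [severity_score(toks, lexicon) for toks in token_lists]
    else:
        values = [float(len(toks)) for toks in token_lists]
    table.df["severity"] = values
    return table


def _minmax(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi > lo:
        return (x - lo) / (hi - lo), lo, hi
    return np.zeros_like(x, dtype=float), lo, hi


def normalize(table: DrugTable) -> DrugTable:
    """Min-max scale rating, severity and review count onto [0, 1] in place.

    Each feature maps via (X - Xmin)/(Xmax - Xmin); a constant feature maps to
    0 for all records.  The (Xmin, Xmax) pairs are stored in ``norm_stats`` so
    scores are reproducible; re-normalizing is idempotent because scaling
    always starts from the raw columns.
    """
    if table.n_drugs < 1:
        raise EmptyTableError("cannot normalize an empty table")
    if "severity" not in table.df.columns:
        raise ValueError("severity not computed; call compute_severity() first")
    for raw_col, norm_col in (
        ("rating_raw", "rating_norm"),
        ("severity", "severity_norm"),
        ("review_count", "reviews_norm"),
    ):
        scaled, lo, hi = _minmax(table.df[raw_col].to_numpy(float))
        table.df[norm_col] = scaled
        table.norm_stats[raw_col] = (lo, hi)
    return table


def prepare_table(
    path: str | Path,
    lexicon: SeverityLexicon | None = None,
    schema_map: dict[str, str] | None = None,
    metric: str = "severity",
) -> DrugTable:
    """Full pipeline: load -> severity -> normalize."""
    lexicon = lexicon or SeverityLexicon.toy()
    return normalize(compute_severity(load_table(path, schema_map), lexicon, metric))
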