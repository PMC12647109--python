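"""Synthetic drug-review tables with known structure for testing optimizers.

The generator emulates the statistical shape of public drug-review data:
ratings bounded on [0, 10] (scaled Beta), heavily over-dispersed review
counts (negative binomial by default, log-normal optionally), and side-effect
texts composed of severity-lexicon terms so the lexicon score has a known
ground truth.  Planted instances additionally construct a subset of records
that strictly dominates every other record on all three normalized criteria
by at least ``dominance_margin``, making the planted subset the unique
optimum for any weights with alpha, gamma > 0 and beta >= 0 — a verifiable
oracle for the optimizers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from drugswarm.data import (
    DrugTable,
    SeverityLexicon,
    compute_severity,
    load_table,
    normalize,
)

__all__ = [
    "SyntheticSpec",
    "PRESETS",
    "generate_frame",
    "generate_table",
    "generate_unplanted",
    "preset_spec",
]

_CONDITIONS = [
    "pain", "acne", "hypertension", "depression", "migraine", "diabetes",
    "asthma", "allergy", "insomnia", "anxiety",
]
_CLASSES = [
    "analgesic", "antibiotic", "antidepressant", "antihistamine",
    "beta-blocker", "statin", "", "antiviral",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one synthetic table.

    Defaults model a small but realistic review table: ratings from a
    right-skewed Beta(4, 2) scaled to [0, 10] (users skew positive), review
    counts from a negative binomial with r=2, p=0.1 (mean 18, variance 180 —
    strongly over-dispersed, as real counts spanning 1 to thousands are), and
    5-ish lexicon terms per side-effect text with a mild/moderate/severe tier
    mix of 40/35/25 %.
    """

    D: int = 12
    k: int = 3
    planted_size: int | None = None  # defaults to k
    rating_a: float = 4.0
    rating_b: float = 2.0
    review_dist: str = "nbinom"  # or "lognormal"
    review_r: float = 2.0
    review_p: float = 0.1
    review_mu: float = 3.0
    review_sigma: float = 1.2
    n_side_effect_terms: float = 5.0
    severity_tiers: tuple[float, float, float] = (0.40, 0.35, 0.25)
    dominance_margin: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.k if self.planted_size is None else self.planted_size
        if not 1 <= self.k <= self.D or not 1 <= planted <= self.D:
            raise ValueError("need D >= k >= 1 and D >= planted_size >= 1")
        if self.dominance_margin <= 0:
            raise ValueError("dominance_margin must be > 0")


PRESETS = {
    "planted-small": SyntheticSpec(D=12, k=3),
    "planted-medium": SyntheticSpec(D=60, k=5),
    "unplanted": SyntheticSpec(D=200, k=5),
}


def preset_spec(name: str, seed: int = 0) -> SyntheticSpec:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed)


def _lexicon_tiers(lexicon: SeverityLexicon) -> tuple[list[str], list[str], list[str]]:
    """Split lexicon terms into (mild, moderate, severe) thirds by weight."""
    weights = sorted(set(lexicon.entries.values()))
    lo, hi = weights[0], weights[-1]
    mild = [t for t, w in lexicon.entries.items() if w == lo]
    severe = [t for t, w in lexicon.entries.items() if w == hi]
    moderate = [t for t, w in lexicon.entries.items() if lo < w < hi] or severe
    return mild, moderate, severe


def _draw_reviews(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.review_dist == "nbinom":
        return rng.negative_binomial(spec.review_r, spec.review_p, size=n)
    if spec.review_dist == "lognormal":
        return np.round(rng.lognormal(spec.review_mu, spec.review_sigma, size=n)).astype(int)
    raise ValueError(f"unknown review distribution {spec.review_dist!r}")


def _side_effect_text(
    terms_pool: tuple[list[str], list[str], list[str]],
    tier_probs: tuple[float, float, float],
    n_terms: int,
    rng: np.random.Generator,
) -> str:
    probs = np.asarray(tier_probs, dtype=float)
    probs = probs / probs.sum()
    chosen = []
    for _ in range(max(1, n_terms)):
        tier = rng.choice(3, p=probs)
        pool = terms_pool[tier]
        chosen.append(pool[rng.integers(len(pool))])
    return "; ".join(chosen)


def _background_frame(
    spec: SyntheticSpec,
    n: int,
    rng: np.random.Generator,
    lexicon: SeverityLexicon,
    rating_cap: float,
    min_tier_weight: float | None,
) -> pd.DataFrame:
    """Non-planted records.  When ``min_tier_weight`` is set (planted mode),
    each text is forced to contain at least one term of that weight or more,
    keeping background severity bounded away from the planted minimum."""
    tiers = _lexicon_tiers(lexicon)
    ratings = rating_cap * rng.beta(spec.rating_a, spec.rating_b, size=n)
    reviews = _draw_reviews(spec, n, rng)
    n_terms = rng.poisson(spec.n_side_effect_terms, size=n)
    texts = []
    for i in range(n):
        text = _side_effect_text(tiers, spec.severity_tiers, int(n_terms[i]), rng)
        if min_tier_weight is not None:
            toks = text.split("; ")
            weights = [lexicon.entries.get(t, lexicon.default_weight) for t in toks]
            # raise the record's severity floor by appending severe terms
            while float(np.mean(weights)) < min_tier_weight:
                extra = tiers[2][rng.integers(len(tiers[2]))]
                toks.append(extra)
                weights.append(lexicon.entries[extra])
            text = "; ".join(toks)
        texts.append(text)
    return pd.DataFrame(
        {
            "rating": ratings,
            "no_of_reviews": reviews,
            "side_effects": texts,
        }
    )


def generate_frame(
    spec: SyntheticSpec,
    lexicon: SeverityLexicon | None = None,
    planted: bool = True,
    max_tries: int = 20,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Build the synthetic table as a DataFrame in the input CSV schema.

    Returns (frame, planted_indices); planted_indices is None for unplanted
    tables.  Planting is construction-then-verification: draw, normalize,
    check the per-criterion margins, and retry with boosted separation if a
    margin is violated (raising after ``max_tries``).
    """
    lexicon = lexicon or SeverityLexicon.toy()
    rng = np.random.default_rng(spec.seed)
    n_planted = spec.k if spec.planted_size is None else spec.planted_size
    tiers = _lexicon_tiers(lexicon)
    w_lo, w_hi = min(lexicon.entries.values()), max(lexicon.entries.values())

    if not planted:
        frame = _background_frame(
            spec, spec.D, rng, lexicon, rating_cap=10.0, min_tier_weight=None
        )
        return _finalize_frame(frame), None

    margin = spec.dominance_margin
    rating_cap = 10.0 * (1.0 - margin) - 0.5
    # floor stays strictly below w_hi: a weighted mean can approach but never
    # reach the top weight while any mild term is present
    floor_cap = w_lo + 0.9 * (w_hi - w_lo)
    severity_floor = min(floor_cap, w_lo + margin * (w_hi - w_lo) + 0.1)
    for attempt in range(max_tries):
        bg = _background_frame(
            spec, spec.D - n_planted, rng, lexicon,
            rating_cap=max(rating_cap, 1.0), min_tier_weight=severity_floor,
        )
        # planted records: near-ceiling ratings, mild-only side effects,
        # review counts pushed past the background maximum by the margin
        p_rating = rng.uniform(9.8, 10.0, size=n_planted)
        bg_max, bg_min = int(bg["no_of_reviews"].max()), int(bg["no_of_reviews"].min())
        spread = max(1, int(0.05 * max(bg_max, 1)))
        gap = int(np.ceil(margin * (bg_max - bg_min + spread) / max(1e-9, 1 - margin))) + 1
        p_reviews = bg_max + gap + rng.integers(0, spread + 1, size=n_planted)
        p_texts = [
            "; ".join(
                tiers[0][rng.integers(len(tiers[0]))]
                for _ in range(max(1, rng.poisson(spec.n_side_effect_terms)))
            )
            for _ in range(n_planted)
        ]
        p_frame = pd.DataFrame(
            {"rating": p_rating, "no_of_reviews": p_reviews, "side_effects": p_texts}
        )
        frame = pd.concat([bg, p_frame], ignore_index=True)
        perm = rng.permutation(len(frame))
        frame = frame.iloc[perm].reset_index(drop=True)
        planted_idx = np.sort(np.nonzero(perm >= len(bg))[0])
        frame = _finalize_frame(frame)

        if _verify_margins(frame, planted_idx, lexicon, margin):
            return frame, planted_idx
        # boost separation and retry (the margin itself is part of the contract)
        rating_cap *= 0.9
        severity_floor = min(floor_cap, severity_floor + 0.2 * (w_hi - w_lo))
    raise RuntimeError(
        f"could not plant a margin-{spec.dominance_margin} optimum in {max_tries} tries"
    )


def _finalize_frame(frame: pd.DataFrame) -> pd.DataFrame:
    n = len(frame)
    out = pd.DataFrame(
        {
            "drug_name": [f"drug_{i:03d}" for i in range(n)],
            "medical_condition": [_CONDITIONS[i % len(_CONDITIONS)] for i in range(n)],
            "rating": np.round(frame["rating"].to_numpy(float), 1),
            "side_effects": frame["side_effects"].to_numpy(),
            "no_of_reviews": frame["no_of_reviews"].to_numpy(int),
            "drug_classes": [_CLASSES[i % len(_CLASSES)] for i in range(n)],
        }
    )
    return out


def _normalized_table(frame: pd.DataFrame, lexicon: SeverityLexicon) -> DrugTable:
    df = frame.copy()
    table = DrugTable(
        df=pd.DataFrame(
            {
                "drug_name": df["drug_name"],
                "condition": df["medical_condition"],
                "rating_raw": df["rating"].astype(float),
                "side_effect_text": df["side_effects"],
                "review_count": df["no_of_reviews"].astype(int),
                "drug_class": df["drug_classes"],
            }
        )
    )
    return normalize(compute_severity(table, lexicon))


def _verify_margins(
    frame: pd.DataFrame,
    planted_idx: np.ndarray,
    lexicon: SeverityLexicon,
    margin: float,
) -> bool:
    """Post-hoc check: worst planted beats best background by >= margin on
    every normalized criterion (severity reversed)."""
    table = _normalized_table(frame, lexicon)
    rating, severity, reviews = table.criteria_arrays()
    mask = np.zeros(len(frame), dtype=bool)
    mask[planted_idx] = True
    gaps = (
        rating[mask].min() - rating[~mask].max(),
        severity[~mask].min() - severity[mask].max(),
        reviews[mask].min() - reviews[~mask].max(),
    )
    return all(g >= margin for g in gaps)


def generate_table(
    spec: SyntheticSpec,
    out_csv: str | Path | None = None,
    lexicon: SeverityLexicon | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Planted-optimum table; optionally write the CSV + ground-truth JSON.

    Deterministic: the same spec (including seed) yields a byte-identical
    CSV.  The ground-truth JSON records the planted indices and drug names.
    """
    frame, planted_idx = generate_frame(spec, lexicon, planted=True)
    assert planted_idx is not None
    if out_csv is not None:
        out_csv = Path(out_csv)
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_csv, index=False)
        truth = {
            "planted_indices": planted_idx.tolist(),
            "planted_drugs": frame.loc[planted_idx, "drug_name"].tolist(),
            "k": spec.k,
            "seed": spec.seed,
        }
        out_csv.with_suffix(".truth.json").write_text(
            json.dumps(truth, indent=2), encoding="utf-8"
        )
    return frame, planted_idx


def generate_unplanted(
    spec: SyntheticSpec,
    out_csv: str | Path | None = None,
    lexicon: SeverityLexicon | None = None,
) -> pd.DataFrame:
    """Same marginals, no dominance structure (for ranking-style benchmarks)."""
    frame, _ = generate_frame(spec, lexicon, planted=False)
    if out_csv is not None:
        out_csv = Path(out_csv)
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_csv, index=False)
    return frame
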