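"""Deficit-accumulation frailty index and UCLA-3 loneliness scoring.

The frailty index (FI) of a person at one occasion is the proportion of
health deficits present among those validly measured: each raw item
(symptom, disease, functional limitation, cognitive test result) is first
mapped to a deficit score in [0, 1] (binary items to {0, 1}, ordinal items
to an equally spaced grid such as 0, 0.25, 0.5, 0.75, 1.0), and the FI is
the mean of the valid deficit scores, provided at least a minimum fraction
(default 80%) of items is valid — otherwise the FI is missing.

Loneliness (LS) is the sum of the three UCLA loneliness items, each scored
1-3, giving a total in 3..9 with higher = lonelier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ItemMap",
    "score_frailty_index",
    "score_loneliness",
    "classify",
    "map_items",
    "score_table",
    "load_item_maps",
    "save_item_maps",
    "default_item_maps",
    "FrailtyIndexScorer",
    "LonelinessScorer",
    "FI_CUTOFF",
    "LS_CUTOFF",
]

#: classification cutoffs: FI <= 0.20 counts as "not frail",
#: LS <= 5 counts as "not lonely" (cutoffs inclusive on the robust side).
FI_CUTOFF = 0.20
LS_CUTOFF = 5

DEFAULT_MIN_VALID_FRACTION = 0.8


@dataclass(frozen=True)
class ItemMap:
    """Declarative rule mapping one raw health item to a deficit in [0, 1].

    Parameters
    ----------
    item_id:
        Column name of the raw item.
    kind:
        ``"binary"``, ``"ordinal"`` or ``"continuous"``. Continuous items
        carry a two-point ``level_scores`` anchor map ``{lo: 0, hi: 1}`` and
        are linearly interpolated (clipped) between the anchors.
    level_scores:
        Mapping raw category -> deficit value in [0, 1].
    higher_is_deficit:
        Whether larger raw values indicate more deficit. Used only to
        validate monotonicity of ``level_scores``.
    """

    item_id: str
    kind: str
    level_scores: Mapping[float, float]
    higher_is_deficit: bool = True

    def __post_init__(self) -> None:
        if self.kind not in {"binary", "ordinal", "continuous"}:
            raise ValueError(f"unknown item kind {self.kind!r} for {self.item_id}")
        vals = np.asarray(list(self.level_scores.values()), dtype=float)
        if vals.size == 0:
            raise ValueError(f"empty level_scores for item {self.item_id}")
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError(f"deficit values outside [0, 1] for item {self.item_id}")
        keys = np.asarray(list(self.level_scores.keys()), dtype=float)
        order = np.argsort(keys)
        ordered = vals[order]
        diffs = np.diff(ordered)
        mono_up = np.all(diffs >= 0)
        mono_dn = np.all(diffs <= 0)
        if self.higher_is_deficit and not mono_up:
            raise ValueError(f"level_scores not monotone increasing for {self.item_id}")
        if not self.higher_is_deficit and not mono_dn:
            raise ValueError(f"level_scores not monotone decreasing for {self.item_id}")

    def apply(self, raw: np.ndarray | pd.Series) -> np.ndarray:
        """Map raw responses to deficit scores; NaN propagates."""
        raw = np.asarray(raw, dtype=float)
        out = np.full(raw.shape, np.nan)
        if self.kind == "continuous":
            keys = np.sort(np.asarray(list(self.level_scores.keys()), dtype=float))
            scores = np.asarray([self.level_scores[k] for k in keys], dtype=float)
            ok = ~np.isnan(raw)
            out[ok] = np.interp(raw[ok], keys, scores)
            return out
        for key, score in self.level_scores.items():
            out[np.isclose(raw, float(key))] = float(score)
        bad = ~np.isnan(raw) & np.isnan(out)
        if np.any(bad):
            raise ValueError(
                f"item {self.item_id}: raw value(s) {np.unique(raw[bad])} not in level_scores"
            )
        return out


def score_frailty_index(
    deficits: Sequence[float] | np.ndarray,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
) -> float:
    """Frailty index of one occasion: mean of valid deficits, or NaN.

    ``deficits`` are already-mapped values in [0, 1]; NaN marks an invalid
    item. Returns NaN when the valid fraction falls below
    ``min_valid_fraction`` (e.g. fewer than 80% of 37 items valid).
    """
    if not 0 < min_valid_fraction <= 1:
        raise ValueError("min_valid_fraction must be in (0, 1]")
    d = np.asarray(deficits, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("deficits must be a non-empty 1-d sequence")
    valid = ~np.isnan(d)
    if np.any((d[valid] < 0) | (d[valid] > 1)):
        raise ValueError("deficit values must lie in [0, 1]")
    if valid.sum() / d.size < min_valid_fraction:
        return float("nan")
    return float(d[valid].sum() / valid.sum())


def score_loneliness(items: Sequence[float]) -> float:
    """Sum of the three UCLA-3 items (each 1-3); NaN if any item missing."""
    it = np.asarray(items, dtype=float)
    if it.shape != (3,):
        raise ValueError("loneliness scale requires exactly 3 items")
    if np.any(np.isnan(it)):
        return float("nan")
    if not np.all(np.isin(it, (1.0, 2.0, 3.0))):
        raise ValueError("loneliness items must be in {1, 2, 3}")
    return float(it.sum())


def classify(
    fi: float, ls: float, fi_cutoff: float = FI_CUTOFF, ls_cutoff: float = LS_CUTOFF
) -> tuple[float, float]:
    """(frail, lonely) flags; a score at the cutoff is classified as robust.

    Missing scores yield NaN flags.
    """
    frail = float("nan") if fi is None or np.isnan(fi) else float(fi > fi_cutoff)
    lonely = float("nan") if ls is None or np.isnan(ls) else float(ls > ls_cutoff)
    return frail, lonely


def map_items(items: pd.DataFrame, item_maps: Sequence[ItemMap]) -> pd.DataFrame:
    """Apply each :class:`ItemMap` to its raw column; returns deficit columns."""
    missing = [m.item_id for m in item_maps if m.item_id not in items.columns]
    if missing:
        raise KeyError(f"item columns not found: {missing}")
    return pd.DataFrame(
        {m.item_id: m.apply(items[m.item_id].to_numpy()) for m in item_maps},
        index=items.index,
    )


def score_table(
    table: pd.DataFrame,
    item_maps: Sequence[ItemMap] | None = None,
    ls_items: Sequence[str] | None = None,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
    fi_cutoff: float = FI_CUTOFF,
    ls_cutoff: float = LS_CUTOFF,
) -> pd.DataFrame:
    """Score a long person x wave item table, appending fi/ls/frail/lonely.

    ``table`` must carry ``person_id`` and ``wave`` columns plus the raw
    item columns named in ``item_maps`` and ``ls_items``.
    """
    out = table.copy()
    if item_maps is not None:
        deficits = map_items(table, item_maps).to_numpy()
        out["fi"] = [
            score_frailty_index(row, min_valid_fraction) for row in deficits
        ]
    if ls_items is not None:
        if len(ls_items) != 3:
            raise ValueError("ls_items must name exactly 3 columns")
        raw = table[list(ls_items)].to_numpy(dtype=float)
        ls_scores = np.full(len(table), np.nan)
        complete = ~np.isnan(raw).any(axis=1)
        if np.any(complete):
            vals = raw[complete]
            if not np.all(np.isin(vals, (1.0, 2.0, 3.0))):
                raise ValueError("loneliness items must be in {1, 2, 3}")
            ls_scores[complete] = vals.sum(axis=1)
        out["ls"] = ls_scores
    if "fi" in out.columns:
        out["frail"] = np.where(out["fi"].isna(), np.nan, (out["fi"] > fi_cutoff).astype(float))
    if "ls" in out.columns:
        out["lonely"] = np.where(out["ls"].isna(), np.nan, (out["ls"] > ls_cutoff).astype(float))
    return out


# ---------------------------------------------------------------------------
# item-map configuration files


def load_item_maps(path: str) -> list[ItemMap]:
    """Read item-map configuration (YAML: one entry per item)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    entries = cfg["items"] if isinstance(cfg, dict) else cfg
    maps = []
    for e in entries:
        maps.append(
            ItemMap(
                item_id=str(e["id"]),
                kind=e.get("kind", "binary"),
                level_scores={float(k): float(v) for k, v in e["levels"].items()},
                higher_is_deficit=bool(e.get("higher_is_deficit", True)),
            )
        )
    return maps


def save_item_maps(maps: Sequence[ItemMap], path: str) -> None:
    entries = [
        {
            "id": m.item_id,
            "kind": m.kind,
            "levels": {float(k): float(v) for k, v in m.level_scores.items()},
            "higher_is_deficit": m.higher_is_deficit,
        }
        for m in maps
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"items": entries}, fh, sort_keys=False)


def default_item_maps(n_items: int = 37) -> list[ItemMap]:
    """Illustrative synthetic 37-item deficit battery.

    A stand-in configuration (age-typical item labels, mix of binary and
    5-level ordinal mappings) for demonstrations and tests; it is NOT the
    instrument of any particular study — real analyses supply their own
    item-map configuration file.
    """
    binary_labels = [
        "diabetes", "hypertension", "heart_disease", "stroke", "cancer",
        "lung_disease", "arthritis", "osteoporosis", "incontinence",
        "hearing_problem", "vision_problem", "fall_past_month",
        "hospital_past_month", "polypharmacy", "weight_loss",
        "sleep_problem", "dizziness", "chronic_pain",
    ]
    ordinal_labels = [
        "adl_walking", "adl_stairs", "adl_bathing", "adl_dressing",
        "adl_shopping", "adl_housework", "grip_weakness", "gait_slowness",
        "fatigue", "appetite_loss", "self_rated_health", "memory_complaint",
        "orientation_test", "recall_test", "fluency_test", "mood_low",
        "anxiety", "social_withdrawal", "exhaustion",
    ]
    five = {1.0: 0.0, 2.0: 0.25, 3.0: 0.5, 4.0: 0.75, 5.0: 1.0}
    maps = [ItemMap(lbl, "binary", {0.0: 0.0, 1.0: 1.0}) for lbl in binary_labels]
    maps += [ItemMap(lbl, "ordinal", dict(five)) for lbl in ordinal_labels]
    maps = maps[:n_items]
    if len(maps) < n_items:
        raise ValueError("default battery supports at most 37 items")
    return maps


# ---------------------------------------------------------------------------
# sklearn-style transformers


class FrailtyIndexScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping raw item columns to a frailty-index column.

    Stateless apart from configuration; ``fit`` only validates columns.
    """

    def __init__(
        self,
        item_maps: Sequence[ItemMap] | None = None,
        min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
    ):
        self.item_maps = item_maps
        self.min_valid_fraction = min_valid_fraction

    def fit(self, X: pd.DataFrame, y=None):
        maps = self.item_maps if self.item_maps is not None else default_item_maps()
        missing = [m.item_id for m in maps if m.item_id not in X.columns]
        if missing:
            raise KeyError(f"item columns not found: {missing}")
        self.item_maps_ = list(maps)
        self.n_features_in_ = len(self.item_maps_)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "item_maps_"):
            raise AttributeError("FrailtyIndexScorer is not fitted")
        deficits = map_items(X, self.item_maps_).to_numpy()
        fi = np.array(
            [score_frailty_index(row, self.min_valid_fraction) for row in deficits]
        )
        return fi.reshape(-1, 1)


class LonelinessScorer(BaseEstimator, TransformerMixin):
    """Transformer summing three UCLA-3 item columns into an LS column."""

    def __init__(self, ls_items: Sequence[str] = ("ls1", "ls2", "ls3")):
        self.ls_items = ls_items

    def fit(self, X: pd.DataFrame, y=None):
        if len(self.ls_items) != 3:
            raise ValueError("ls_items must name exactly 3 columns")
        missing = [c for c in self.ls_items if c not in X.columns]
        if missing:
            raise KeyError(f"loneliness item columns not found: {missing}")
        self.ls_items_ = list(self.ls_items)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "ls_items_"):
            raise AttributeError("LonelinessScorer is not fitted")
        raw = X[self.ls_items_].to_numpy(dtype=float)
        out = np.full(len(X), np.nan)
        complete = ~np.isnan(raw).any(axis=1)
        if np.any(complete):
            vals = raw[complete]
            if not np.all(np.isin(vals, (1.0, 2.0, 3.0))):
                raise ValueError("loneliness items must be in {1, 2, 3}")
            out[complete] = vals.sum(axis=1)
        return out.reshape(-1, 1)
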