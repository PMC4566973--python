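"""GO macro-category summaries of a DEG set.

The gene → macro-category map is an input (the product of an external GO
annotation/enrichment run), not something this package computes. The summary
is the count of DEGs per category and its percentage of the total DEG set,
rounded half away from zero to one decimal.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Set

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_VOCABULARY",
    "round_half_away",
    "load_category_map",
    "summarize_categories",
]

DEFAULT_VOCABULARY = (
    "transcription factors",
    "sugars",
    "secondary metabolism",
    "plant hormones",
    "cell wall",
    "antioxidant responses",
    "stresses",
)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (122/4072 -> 3.0, not 2.9)."""
    factor = 10**ndigits
    scaled = x * factor
    import math

    return math.floor(scaled + 0.5) / factor if x >= 0 else -round_half_away(-x, ndigits)


def load_category_map(
    path: str | Path,
    vocabulary: Iterable[str] = DEFAULT_VOCABULARY,
    allow_new: bool = False,
) -> dict[str, set[str]]:
    """Gene → category-set map from a two-column TSV (gene_id, category).

    Unknown category labels are rejected against the vocabulary unless
    ``allow_new``; duplicate (gene, category) rows are deduplicated with a
    warning; malformed rows raise with their line number.
    """
    vocab = set(vocabulary)
    mapping: dict[str, set[str]] = {}
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:2] == ["gene_id", "category"]:
                continue
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"malformed category-map row at line {lineno}: {line!r}")
            gene, category = parts
            if not allow_new and category not in vocab:
                raise ValueError(
                    f"unknown category {category!r} at line {lineno}; "
                    "pass allow_new=True to accept new labels"
                )
            if (gene, category) in seen:
                logger.warning("duplicate mapping (%s, %s) deduplicated", gene, category)
                continue
            seen.add((gene, category))
            mapping.setdefault(gene, set()).add(category)
    return mapping


def summarize_categories(
    deg_set: Set[str],
    category_map: Mapping[str, Set[str]],
    total: int,
    categories: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-category DEG counts and percentages of the total DEG set.

    ``total`` is the size of the DEG universe the percentages refer to (it
    may exceed the number of mapped genes). Output rows are sorted by
    descending count, then category name, so summaries are independent of
    input order.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if categories is None:
        cats: set[str] = set()
        for labels in category_map.values():
            cats |= set(labels)
        categories = sorted(cats)
    rows = []
    deg = set(deg_set)
    for cat in categories:
        count = sum(1 for g in deg if cat in category_map.get(g, ()))
        if count > total:
            raise ValueError(f"category {cat!r} count {count} exceeds total {total}")
        rows.append(
            {
                "category": cat,
                "count": count,
                "percentage": round_half_away(100.0 * count / total, 1),
            }
        )
    out = pd.DataFrame(rows, columns=["category", "count", "percentage"])
    out = out.sort_values(["count", "category"], ascending=[False, True]).reset_index(
        drop=True
    )
    out.attrs["total_degs"] = total
    return out
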