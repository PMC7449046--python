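"""Leaf-to-panicle ratio (LPR) and group comparisons.

LPR = L / P, the ratio of leaf-labeled to panicle-labeled pixels in a
canopy image.  Under the assumption that the camera sees directly reflected
sunlight, LPR is a 2-D proxy for how intercepted light is partitioned
between the source organ (leaf) and the sink organ (panicle) during grain
filling.  This module computes per-image records, grouped summaries and the
shortest-significant-ranges (SSR, Duncan-style) multiple range test used to
compare group means, reporting results as a compact letter display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

logger = logging.getLogger(__name__)


@dataclass
class LPRRecord:
    """Pixel bookkeeping of one image: L, P, LPR and grouping metadata.

    ``lpr`` is NaN when the image contains no panicle pixels (the record is
    kept so summaries can report how many images were undefined).
    """

    image_id: str
    L: int
    P: int
    lpr: float
    background_count: int
    metadata: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.lpr)


def compute_lpr(mask, image_id: str = "", metadata: dict | None = None,
                strict: bool = False) -> LPRRecord:
    """Count leaf (label 1) and panicle (label 2) pixels and form L/P."""
    labels = mask.labels if hasattr(mask, "labels") else np.asarray(mask)
    if labels.size and not np.isin(labels, (0, 1, 2)).all():
        raise ValueError("mask labels must be in {0, 1, 2}")
    counts = np.bincount(labels.ravel(), minlength=3)[:3]
    background, L, P = (int(c) for c in counts)
    if P == 0:
        if strict:
            raise ZeroDivisionError(
                f"image {image_id!r} has no panicle pixels; LPR undefined")
        lpr = float("nan")
    else:
        lpr = L / P
    return LPRRecord(image_id=image_id, L=L, P=P, lpr=lpr,
                     background_count=background,
                     metadata=dict(metadata or {}))


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({"image_id": r.image_id, "L": r.L, "P": r.P,
                     "lpr": r.lpr, "background_count": r.background_count,
                     **r.metadata})
    return pd.DataFrame(rows)


def summarize(records, group_by) -> pd.DataFrame:
    """Per-group n, mean, sd, min, max of LPR (undefined records dropped)."""
    frame = records if isinstance(records, pd.DataFrame) else \
        records_to_frame(records)
    if frame.empty:
        raise ValueError("no records to summarize")
    n_undef = int(frame["lpr"].isna().sum())
    if n_undef:
        logger.info("excluding %d records with undefined LPR", n_undef)
    defined = frame.dropna(subset=["lpr"])
    if defined.empty:
        raise ValueError("all records have undefined LPR")
    if isinstance(group_by, str):
        group_by = [group_by]
    out = (defined.groupby(list(group_by))["lpr"]
           .agg(n="count", mean="mean", sd="std", min="min", max="max")
           .reset_index())
    return out


@dataclass
class GroupComparison:
    """Result of the SSR multiple range test.

    Groups sharing a letter are not significantly different at ``alpha``;
    means are reported in descending order (the ranking the test uses).
    """

    groups: list
    means: np.ndarray
    ns: np.ndarray
    ms_error: float
    df_error: int
    alpha: float
    letters: dict
    significant_pairs: set


def _letter_display(k: int, nonsig_pairs: set) -> list:
    """Compact letters from the non-significant intervals in rank order.

    With the range-containment rule, non-significant pairs form intervals
    of consecutive ranks; each maximal interval gets one letter.
    """
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and (i, j + 1) in nonsig_pairs:
            j += 1
        intervals.append((i, j))
    maximal = [iv for iv in intervals
               if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv
                          for o in intervals)]
    letters = [""] * k
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter_idx, (lo, hi) in enumerate(maximal):
        for g in range(lo, hi + 1):
            letters[g] += alphabet[letter_idx % 26]
    return letters


def ssr_test(records, group_by: str, alpha: float = 0.05) -> GroupComparison:
    """Duncan-style shortest-significant-ranges multiple comparison.

    One-way ANOVA supplies the residual mean square and its degrees of
    freedom.  Means are ranked; for a span of ``p`` ranked means the
    shortest significant range is the studentized-range quantile at the
    protection level 1 - (1 - alpha)^(p-1), scaled by
    sqrt(MS_error / n_h) with ``n_h`` the harmonic mean group size.  A
    range is only declared significant if no enclosing range was declared
    non-significant, and the declarations are reported as a compact letter
    display.
    """
    frame = records if isinstance(records, pd.DataFrame) else \
        records_to_frame(records)
    frame = frame.dropna(subset=["lpr"])
    groups = [(g, sub["lpr"].to_numpy(float))
              for g, sub in frame.groupby(group_by)]
    if len(groups) < 2:
        raise ValueError("ssr_test needs at least 2 groups")
    for g, vals in groups:
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 defined values")
    ns = np.array([v.size for _, v in groups])
    means = np.array([v.mean() for _, v in groups])
    N = int(ns.sum())
    k = len(groups)
    df_error = N - k
    if df_error <= 0:
        raise ValueError("zero residual degrees of freedom; test undefined")
    ss_within = sum(((v - v.mean()) ** 2).sum() for _, v in groups)
    ms_error = ss_within / df_error
    order = np.argsort(-means)
    groups_sorted = [groups[i][0] for i in order]
    means_sorted = means[order]
    ns_sorted = ns[order]
    n_h = k / np.sum(1.0 / ns)
    se = np.sqrt(ms_error / n_h)

    def ssr(p: int) -> float:
        if se == 0:
            return 0.0
        protection = 1.0 - (1.0 - alpha) ** (p - 1)
        q = studentized_range.ppf(1.0 - protection, p, df_error)
        return float(q * se)

    # evaluate ranges from the widest span down; an enclosing
    # non-significant range suppresses everything inside it
    sig = {}
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(sig.get((a, b)) is False
                   for (a, b) in sig if a <= i and j <= b):
                sig[(i, j)] = False
                continue
            sig[(i, j)] = (means_sorted[i] - means_sorted[j]) > ssr(span)
    nonsig_pairs = {pair for pair, s in sig.items() if not s}
    letters_sorted = _letter_display(k, nonsig_pairs)
    letters = {g: letters_sorted[i] for i, g in enumerate(groups_sorted)}
    significant = {(groups_sorted[i], groups_sorted[j])
                   for (i, j), s in sig.items() if s}
    return GroupComparison(
        groups=groups_sorted, means=means_sorted, ns=ns_sorted,
        ms_error=float(ms_error), df_error=df_error, alpha=alpha,
        letters=letters, significant_pairs=significant)


def comparison_frame(comparison: GroupComparison) -> pd.DataFrame:
    return pd.DataFrame({
        "group": comparison.groups,
        "mean": comparison.means,
        "n": comparison.ns,
        "letters": [comparison.letters[g] for g in comparison.groups],
    })
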