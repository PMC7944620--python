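"""Cross-genotype tracking of triad bias categories.

A triad's bias category (A=B / A>B / A<B) is followed across a
three-genotype series and summarised as one of four transition classes.

Domestication series (wild -> domesticated -> extracted tetraploid,
WTW -> DTW -> ETW), "Group" labels:

    I   c1 = c2 = c3          (conserved throughout)
    II  c1 != c2, c2 = c3     (changed at domestication, then kept)
    III c1 != c2, c2 != c3    (changed at domestication, changed again)
    IV  c1 = c2, c2 != c3     (changed only in the extracted line)

Ploidy-transition series (hexaploid donor -> extracted tetraploid ->
resynthesised hexaploid, TAA10 -> ETW -> XX329), "Pattern" labels:

    I   c1 = c2 = c3          (conserved; D-genome independent)
    II  c1 != c2, c1 = c3     (reversible; strictly D-dependent)
    III c1 = c2, c2 != c3     (changed only on D reintroduction)
    IV  c1 != c2, c2 = c3     (changed on extraction, not reverted)

Triples with all three categories distinct satisfy none of the four
ploidy definitions; they are labelled III and flagged ``double_change``
so they can be counted separately.  A triad unmodified in any genotype
of the series is ``not_tracked`` and excluded from denominators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .classify import CATEGORIES, UNMODIFIED

LABELS = ("I", "II", "III", "IV")
NOT_TRACKED = "not_tracked"

SERIES_RULES = ("domestication", "ploidy")


def _check_categories(cats: tuple) -> bool:
    for c in cats:
        if c == UNMODIFIED:
            return False
        if c not in CATEGORIES:
            raise ValueError(f"unknown category {c!r}")
    return True


def track_domestication(c1: str, c2: str, c3: str) -> str:
    """Group label for a category triple along WTW -> DTW -> ETW."""
    if not _check_categories((c1, c2, c3)):
        return NOT_TRACKED
    if c1 == c2:
        return "I" if c2 == c3 else "IV"
    return "II" if c2 == c3 else "III"


def track_ploidy(c1: str, c2: str, c3: str) -> str:
    """Pattern label for a category triple along TAA10 -> ETW -> XX329."""
    if not _check_categories((c1, c2, c3)):
        return NOT_TRACKED
    if c1 == c2 == c3:
        return "I"
    if c1 == c2:          # changed only in the resynthesised hexaploid
        return "III"
    if c1 == c3:          # reverted on D reintroduction
        return "II"
    if c2 == c3:          # change persisted after D reintroduction
        return "IV"
    return "III"          # all three distinct: double change, grouped to III


class SeriesTracker(BaseEstimator):
    """Transition-class labeller over (c1, c2, c3) category triples.

    Parameters
    ----------
    series : {"domestication", "ploidy"}
        Which labelling rule to apply.
    """

    def __init__(self, series: str = "domestication"):
        self.series = series

    def fit(self, X, y=None) -> "SeriesTracker":
        if self.series not in SERIES_RULES:
            raise ValueError(f"series must be one of {SERIES_RULES}")
        X = np.asarray(X, dtype=object)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n_samples, 3) category strings")
        self.n_features_in_ = 3
        self.classes_ = np.array(list(LABELS) + [NOT_TRACKED])
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=object)
        rule = (track_domestication if self.series == "domestication"
                else track_ploidy)
        return np.array([rule(*row) for row in X], dtype=object)


def track_series(calls: pd.DataFrame, genotypes: list[str],
                 series: str) -> pd.DataFrame:
    """Build the SeriesTrack table from a BiasCall table.

    ``genotypes`` gives the three series genotypes in order.  Returns
    one row per triad x assay with the three categories, the label, and
    a double_change flag (all three categories distinct).
    """
    if len(genotypes) != 3:
        raise ValueError("a series has exactly three genotypes")
    sub = calls[calls["genotype"].isin(genotypes)]
    wide = sub.pivot_table(index=["triad_id", "assay"], columns="genotype",
                           values="category", aggfunc="first")
    missing = [g for g in genotypes if g not in wide.columns]
    if missing:
        raise ValueError(f"no calls for genotype(s) {missing}")
    wide = wide[genotypes].dropna()
    tracker = SeriesTracker(series=series).fit(wide.values)
    labels = tracker.predict(wide.values)
    out = wide.reset_index()
    out.columns = ["triad_id", "assay", "cat_1", "cat_2", "cat_3"]
    out["series"] = series
    out["label"] = labels
    out["double_change"] = (
        (out["cat_1"] != out["cat_2"]) & (out["cat_2"] != out["cat_3"])
        & (out["cat_1"] != out["cat_3"]) & (out["label"] != NOT_TRACKED)
    )
    return out


def tabulate_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    """Label counts and proportions per assay (tracked triads only)."""
    if tracks.empty:
        raise ValueError("empty track table")
    rows = []
    for assay, grp in tracks.groupby("assay"):
        tracked = grp[grp["label"] != NOT_TRACKED]
        n = len(tracked)
        counts = tracked["label"].value_counts()
        for label in LABELS:
            k = int(counts.get(label, 0))
            rows.append({"assay": assay, "label": label, "count": k,
                         "proportion": k / n if n else 0.0,
                         "n_tracked": n,
                         "n_not_tracked": int(len(grp) - n)})
    return pd.DataFrame(rows)
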