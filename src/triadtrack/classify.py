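"""Triad A/B bias classification by nearest Euclidean anchor.

Within each triad the A- and B-homoeolog TPMs are normalised to
fractions (rel_A, rel_B) = (a, b) / (a + b) and the triad is assigned
the category of the nearest anchor in that plane:

    A = B  ->  (0.5, 0.5)        A > B  ->  (1, 0)        A < B  ->  (0, 1)

Since rel_A + rel_B = 1, the category boundaries sit exactly at
rel_A = 0.25 and rel_A = 0.75.  A triad is "modified" by a marker when
either homoeolog exceeds the TPM threshold tau (default 0.5 TPM,
strict); triads below threshold carry no category.  For hexaploid
genotypes only the A and B homoeologs enter the normalisation; the D
copy is ignored by design.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import TriadTable

CATEGORIES = ("A_eq_B", "A_gt_B", "A_lt_B")
UNMODIFIED = "unmodified"

#: anchor coordinates in the (rel_A, rel_B) plane
ANCHORS = {"A_eq_B": (0.5, 0.5), "A_gt_B": (1.0, 0.0), "A_lt_B": (0.0, 1.0)}


def normalize_triad(tpm_a: float, tpm_b: float) -> tuple[float, float]:
    """Within-triad normalisation: (rel_A, rel_B) summing to one."""
    if tpm_a < 0 or tpm_b < 0:
        raise ValueError("TPM values must be non-negative")
    total = tpm_a + tpm_b
    if total <= 0:
        raise ValueError("both homoeologs zero: relative signal undefined")
    return tpm_a / total, 1.0 - tpm_a / total


def is_modified(tpm_a: float, tpm_b: float, tau: float = 0.5) -> bool:
    """True iff either homoeolog is strictly above the TPM threshold."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return tpm_a > tau or tpm_b > tau


def anchor_distances(rel_a: float, rel_b: float) -> tuple[float, float, float]:
    """Euclidean distances (d_eq, d_gt, d_lt) to the three anchors."""
    if not math.isclose(rel_a + rel_b, 1.0, abs_tol=1e-6):
        raise ValueError("rel_A + rel_B must equal 1")
    return tuple(
        math.hypot(rel_a - ax, rel_b - ay)
        for ax, ay in (ANCHORS[c] for c in CATEGORIES)
    )


def classify_bias(rel_a: float, rel_b: float,
                  tie_order: tuple = CATEGORIES) -> tuple[str, tuple]:
    """Nearest-anchor category with distances; ties resolved by order.

    The default tie order prefers the balanced call A_eq_B, then A_gt_B
    (ties arise only at rel_A exactly 0.25 or 0.75).
    """
    d = anchor_distances(rel_a, rel_b)
    by_cat = dict(zip(CATEGORIES, d))
    best = min(tie_order, key=lambda c: by_cat[c])
    return best, d


class TriadBiasClassifier(BaseEstimator, TransformerMixin):
    """Nearest-anchor bias classifier over (tpm_A, tpm_B) pairs.

    A rule-based, non-learned classifier in estimator clothing so it
    composes with sklearn pipelines: ``fit`` only validates input.

    Parameters
    ----------
    tau : float, default 0.5
        Modified-triad TPM threshold (strict ">").
    tie_order : tuple of str
        Category preference at exact boundary ties.

    Attributes
    ----------
    n_features_in_ : int
        Always 2 after fit.
    classes_ : ndarray
        The category alphabet including "unmodified".
    """

    def __init__(self, tau: float = 0.5, tie_order: tuple = CATEGORIES):
        self.tau = tau
        self.tie_order = tie_order

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): tpm_A, tpm_B")
        if (X < 0).any():
            raise ValueError("TPM values must be non-negative")
        if not np.isfinite(X).all():
            raise ValueError("TPM values must be finite")
        return X

    def fit(self, X, y=None) -> "TriadBiasClassifier":
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if sorted(self.tie_order) != sorted(CATEGORIES):
            raise ValueError("tie_order must permute the three categories")
        X = self._validate(X)
        self.n_features_in_ = 2
        self.classes_ = np.array(list(CATEGORIES) + [UNMODIFIED])
        return self

    def transform(self, X) -> np.ndarray:
        """Columns: rel_A, rel_B, d_eq, d_gt, d_lt (NaN when unmodified)."""
        X = self._validate(X)
        out = np.full((len(X), 5), np.nan)
        total = X.sum(axis=1)
        ok = total > 0
        rel_a = np.divide(X[:, 0], total, out=np.zeros(len(X)), where=ok)
        rel_b = 1.0 - rel_a
        out[ok, 0] = rel_a[ok]
        out[ok, 1] = rel_b[ok]
        for j, cat in enumerate(CATEGORIES):
            ax, ay = ANCHORS[cat]
            out[ok, 2 + j] = np.hypot(rel_a[ok] - ax, rel_b[ok] - ay)
        return out

    def predict(self, X) -> np.ndarray:
        X = self._validate(X)
        feats = self.transform(X)
        modified = (X > self.tau).any(axis=1)
        cats = np.full(len(X), UNMODIFIED, dtype=object)
        if modified.any():
            dist = feats[modified, 2:5]
            # stable argmin honouring the tie order
            order_idx = [CATEGORIES.index(c) for c in self.tie_order]
            pick = np.argmin(np.round(dist[:, order_idx], 12), axis=1)
            cats[modified] = np.array(self.tie_order, dtype=object)[pick]
        return cats


def classify_dataset(tpm: pd.DataFrame, triads: TriadTable,
                     tau: float = 0.5,
                     assays: list | None = None,
                     genotypes: list | None = None) -> pd.DataFrame:
    """One bias call per triad x genotype x assay.

    ``tpm`` has genes as rows and (genotype, assay) MultiIndex columns
    (replicates already aggregated).  Returns the BiasCall table with
    columns triad_id, genotype, assay, tpm_A, tpm_B, rel_A, rel_B,
    d_eq, d_gt, d_lt, category.
    """
    gene_a = triads.genes("A")
    gene_b = triads.genes("B")
    missing = gene_a.index[~gene_a.isin(tpm.index)]
    if len(missing) or gene_b[~gene_b.isin(tpm.index)].size:
        raise ValueError("triad homoeolog missing from the TPM matrix")
    clf = TriadBiasClassifier(tau=tau)
    frames = []
    for genotype, assay in tpm.columns:
        if assays is not None and assay not in assays:
            continue
        if genotypes is not None and genotype not in genotypes:
            continue
        a = tpm.loc[gene_a.values, (genotype, assay)].values
        b = tpm.loc[gene_b.values, (genotype, assay)].values
        X = np.column_stack([a, b])
        clf.fit(X)
        feats = clf.transform(X)
        frames.append(pd.DataFrame({
            "triad_id": gene_a.index,
            "genotype": genotype,
            "assay": assay,
            "tpm_A": a, "tpm_B": b,
            "rel_A": feats[:, 0], "rel_B": feats[:, 1],
            "d_eq": feats[:, 2], "d_gt": feats[:, 3], "d_lt": feats[:, 4],
            "category": clf.predict(X),
        }))
    return pd.concat(frames, ignore_index=True)


def summarize_calls(calls: pd.DataFrame,
                    union_genotypes: list | None = None) -> dict:
    """Category counts/percentages per genotype x assay, plus the
    union denominator: triads modified in >= 1 genotype of a named set
    (per assay)."""
    summary: dict = {"per_genotype": {}, "union_modified": {}}
    for (genotype, assay), grp in calls.groupby(["genotype", "assay"]):
        mod = grp[grp["category"] != UNMODIFIED]
        counts = mod["category"].value_counts().to_dict()
        n_mod = len(mod)
        summary["per_genotype"][f"{genotype}|{assay}"] = {
            "n_triads": len(grp),
            "n_modified": n_mod,
            "counts": {c: int(counts.get(c, 0)) for c in CATEGORIES},
            "percent": {c: (100.0 * counts.get(c, 0) / n_mod if n_mod else 0.0)
                        for c in CATEGORIES},
        }
    for assay, grp in calls.groupby("assay"):
        sub = grp
        if union_genotypes is not None:
            sub = grp[grp["genotype"].isin(union_genotypes)]
        mod_any = (sub[sub["category"] != UNMODIFIED]
                   .groupby("triad_id").size())
        n_total = sub["triad_id"].nunique()
        summary["union_modified"][assay] = {
            "n_modified_any": int(len(mod_any)),
            "n_total": int(n_total),
            "percent": 100.0 * len(mod_any) / n_total if n_total else 0.0,
        }
    return summary
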