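"""Chromosomal-zone assignment and per-zone summaries.

Wheat chromosomes partition into distal ends (R1, R3), interstitial
arms (R2a, R2b) and the proximal centromeric/pericentromeric zone (C).
Genes are assigned by the midpoint floor((start+end)/2) falling in the
half-open zone interval; summaries report per-zone gene counts,
densities per Mb, and per-label zone fractions, with an optional
two-proportion enrichment test of each label's zone share against the
background share.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import two_proportion_test

#: zone -> broad compartment used for ordering statements
COMPARTMENT = {"R1": "distal", "R3": "distal",
               "R2a": "interstitial", "R2b": "interstitial",
               "C": "proximal"}


def assign_zone(chrom: str, position: int, partition: pd.DataFrame) -> str:
    """Zone whose half-open interval [start, end) contains the position."""
    rows = partition[partition["chrom"] == chrom]
    if rows.empty:
        raise ValueError(f"chromosome {chrom!r} absent from the partition")
    hit = rows[(rows["start"] <= position) & (position < rows["end"])]
    if hit.empty:
        raise ValueError(
            f"position {chrom}:{position} outside all zone intervals")
    return hit["zone"].iloc[0]


def assign_zones(points: pd.DataFrame, partition: pd.DataFrame) -> pd.Series:
    """Vectorised zone lookup for a frame with chrom and midpoint columns."""
    out = pd.Series(index=points.index, dtype=object)
    for chrom, grp in points.groupby("chrom"):
        rows = partition[partition["chrom"] == chrom].sort_values("start")
        if rows.empty:
            raise ValueError(f"chromosome {chrom!r} absent from the partition")
        idx = np.searchsorted(rows["start"].values, grp["midpoint"].values,
                              side="right") - 1
        if (idx < 0).any():
            bad = grp.index[idx < 0][0]
            raise ValueError(f"gene {bad!r} midpoint before first zone")
        inside = grp["midpoint"].values < rows["end"].values[idx]
        if not inside.all():
            bad = grp.index[~inside][0]
            raise ValueError(f"gene {bad!r} midpoint outside all zones")
        out.loc[grp.index] = rows["zone"].values[idx]
    return out


def zone_spans_mb(partition: pd.DataFrame) -> pd.Series:
    """Total span of each zone label across chromosomes, in Mb."""
    spans = (partition["end"] - partition["start"]) / 1e6
    return spans.groupby(partition["zone"]).sum()


def zone_distribution(genes: pd.DataFrame, partition: pd.DataFrame,
                      label_col: str | None = None,
                      test_enrichment: bool = False) -> pd.DataFrame:
    """Per-zone gene counts, densities per Mb, and per-label fractions.

    ``genes`` needs chrom and midpoint columns and, optionally, a label
    column (e.g. the Group/Pattern of the triad the gene belongs to).
    With ``test_enrichment`` each (label, zone) share is tested against
    the share of all other labels pooled.
    """
    if genes.empty:
        raise ValueError("empty gene table")
    zones = assign_zones(genes, partition)
    spans = zone_spans_mb(partition)
    labels = genes[label_col] if label_col else pd.Series(
        "all", index=genes.index)
    rows = []
    total_by_zone = zones.value_counts()
    grand = len(genes)
    for label in sorted(labels.unique()):
        mask = labels == label
        n_label = int(mask.sum())
        counts = zones[mask].value_counts()
        for zone in spans.index:
            k = int(counts.get(zone, 0))
            row = {"label": label, "zone": zone, "count": k,
                   "density_per_mb": k / spans[zone],
                   "fraction_of_label": k / n_label if n_label else 0.0,
                   "n_label": n_label}
            if test_enrichment:
                k_other = int(total_by_zone.get(zone, 0)) - k
                n_other = grand - n_label
                if n_other > 0:
                    res = two_proportion_test(k, n_label, k_other, n_other)
                    row["p_value"] = res.p_value
                else:
                    row["p_value"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
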