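"""Gene-level TPM quantification, replicate aggregation, and QC statistics.

TPM (Transcripts Per Kilobase Million) for gene g with count c_g and
length L_g kilobases is 1e6 * (c_g / L_g) / sum_h (c_h / L_h); each
sample's TPM column sums to one million over the gene universe used.
The denominator universe is all genes in the supplied count table, so
library normalisation happens before any triad subsetting.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .io import SUBGENOMES, TriadTable
from .stats import TestResult, pearson_r

logger = logging.getLogger("triadtrack")

#: column MultiIndex level names for sample matrices
SAMPLE_LEVELS = ("genotype", "assay", "replicate")


def compute_tpm(counts: pd.Series, lengths: pd.Series) -> pd.Series:
    """Convert gene counts to TPM using gene lengths in bp."""
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"gene {missing[0]!r} has a count but no length")
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero total count: TPM undefined")
    kb = lengths.loc[counts.index] / 1e3
    rate = counts / kb
    return 1e6 * rate / rate.sum()


def tpm_matrix(counts_by_sample: Mapping[tuple, pd.Series],
               lengths: pd.Series) -> pd.DataFrame:
    """Build a genes x samples TPM matrix.

    Keys of ``counts_by_sample`` are (genotype, assay, replicate).
    """
    if not counts_by_sample:
        raise ValueError("no samples supplied")
    cols = {}
    for key, counts in counts_by_sample.items():
        cols[key] = compute_tpm(counts, lengths)
    mat = pd.DataFrame(cols)
    mat.columns = pd.MultiIndex.from_tuples(mat.columns, names=SAMPLE_LEVELS)
    return mat.fillna(0.0)


def aggregate_replicates(tpm: pd.DataFrame, how: str = "mean") -> pd.DataFrame:
    """Collapse replicate columns to one column per (genotype, assay).

    Default is the arithmetic mean of replicate TPMs; ``how="first"``
    keeps replicate 1 only (each-replicate-separately analyses can
    instead slice the full matrix).
    """
    if how == "mean":
        return tpm.T.groupby(level=["genotype", "assay"]).mean().T
    if how == "first":
        reps = tpm.columns.get_level_values("replicate")
        out = tpm.loc[:, reps == min(reps)]
        out.columns = out.columns.droplevel("replicate")
        return out
    raise ValueError(f"unknown aggregation {how!r}")


def replicate_correlation(tpm: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between every replicate pair within (genotype, assay)."""
    rows = []
    for (genotype, assay), sub in tpm.T.groupby(level=["genotype", "assay"]):
        sub = sub.T
        reps = list(sub.columns.get_level_values("replicate"))
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                x = sub.iloc[:, i].values
                y = sub.iloc[:, j].values
                if np.std(x) == 0 or np.std(y) == 0:
                    logger.warning(
                        "zero-variance TPM column for %s/%s: r undefined",
                        genotype, assay)
                    r = np.nan
                else:
                    r = pearson_r(x, y).statistic
                rows.append({"genotype": genotype, "assay": assay,
                             "rep_1": reps[i], "rep_2": reps[j],
                             "pearson_r": r, "n_genes": len(x)})
    return pd.DataFrame(rows)


def subgenome_share(counts: pd.Series, triads: TriadTable) -> pd.Series:
    """Per-sample proportion of triad-gene reads on the A, B, D subgenomes.

    Mirrors the read-mapping sanity check: a DD diploid sample should
    place essentially all its triad reads on D homoeologs.
    """
    totals = {}
    for sub in SUBGENOMES:
        genes = triads.genes(sub)
        totals[sub] = counts.reindex(genes).fillna(0).sum()
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("no reads on triad genes")
    return pd.Series({s: totals[s] / grand for s in SUBGENOMES}, name="share")
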