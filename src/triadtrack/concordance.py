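"""Modification-vs-expression concordance of triad transition classes.

RNA triads are classified and tracked with exactly the same machinery
as the ChIP assays (same 0.5 TPM threshold, same anchors), then the
Group/Pattern memberships of a modification assay and the expression
assay are intersected.  Each cell of the label x label contingency is
tested for enrichment over the independence expectation with the
two-proportion test: P(expr label | mod label) vs P(expr label | other
mod labels).
"""

from __future__ import annotations

import pandas as pd

from .classify import classify_dataset
from .io import TriadTable
from .stats import two_proportion_test
from .tracking import LABELS, NOT_TRACKED


def classify_expression(tpm: pd.DataFrame, triads: TriadTable,
                        tau: float = 0.5) -> pd.DataFrame:
    """Bias calls for the RNA assay, same contract as the ChIP path."""
    return classify_dataset(tpm, triads, tau=tau, assays=["RNA"])


def concordance_matrix(mod_tracks: pd.DataFrame,
                       expr_tracks: pd.DataFrame,
                       correction: bool = True,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Label x label contingency with per-cell enrichment tests.

    Both inputs are SeriesTrack tables over the same series; only
    triads tracked in both assays enter.  Per cell (m, e):
    x1/n1 = count(mod=m, expr=e) / count(mod=m) is compared with
    x2/n2 = count(mod!=m, expr=e) / count(mod!=m).
    """
    m = mod_tracks[mod_tracks["label"] != NOT_TRACKED][["triad_id", "label"]]
    e = expr_tracks[expr_tracks["label"] != NOT_TRACKED][["triad_id", "label"]]
    merged = m.merge(e, on="triad_id", suffixes=("_mod", "_expr"))
    if merged.empty:
        raise ValueError("no triads tracked in both assays")
    total = len(merged)
    rows = []
    for ml in LABELS:
        in_m = merged["label_mod"] == ml
        n1 = int(in_m.sum())
        n2 = total - n1
        for el in LABELS:
            in_e = merged["label_expr"] == el
            k = int((in_m & in_e).sum())
            expected = n1 * int(in_e.sum()) / total if total else 0.0
            row = {"mod_label": ml, "expr_label": el, "count": k,
                   "expected": expected, "n_mod": n1, "n_total": total}
            if n1 > 0 and n2 > 0:
                res = two_proportion_test(k, n1, int(in_e.sum()) - k, n2,
                                          correction=correction)
                row["p_value"] = res.p_value
                row["significant"] = res.p_value < alpha
            else:
                row["p_value"] = float("nan")
                row["significant"] = False
            rows.append(row)
    return pd.DataFrame(rows)
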