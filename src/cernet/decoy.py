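"""Decoy-gene correlation screen for candidate lncRNAs.

A tumor-only cohort has no normal samples to contrast against, so candidate
lncRNAs are selected by their correlation with two decoy genes of known,
opposite dysregulation: an upregulated oncogene-like decoy and a
downregulated tumor-suppressor-like decoy.  A lncRNA correlating positively
with the first and negatively with the second (both passing the r and p
thresholds) is oncogene-like; the mirror pattern is tumor-suppressor-like.
Opposite sign is mandatory; same-sign candidates are reported unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlate import correlate_matrix, bh_fdr
from .simulate import ExpressionMatrix

__all__ = ["CandidateLncRNA", "screen", "screen_table"]


@dataclass(frozen=True)
class CandidateLncRNA:
    id: str
    r_decoy_up: float
    p_decoy_up: float
    fdr_decoy_up: float
    r_decoy_down: float
    p_decoy_down: float
    fdr_decoy_down: float
    classification: str  # oncogene_like / tumor_suppressor_like / unclassified


def screen(
    matrix: ExpressionMatrix,
    decoy_up: str,
    decoy_down: str,
    r_min: float = 0.3,
    p_max: float = 0.01,
    method: str = "pearson",
) -> list[CandidateLncRNA]:
    """Correlate every lncRNA against both decoys and classify.

    Classification uses raw p-values (BH-FDR is reported alongside).  Output
    is sorted by ``min(|r_up|, |r_down|)`` descending, ties broken by id.
    """
    for decoy in (decoy_up, decoy_down):
        if decoy not in matrix.data.index:
            raise KeyError(f"decoy gene {decoy!r} not present in matrix")
    lnc_ids = matrix.features_of_class("lncRNA")
    if not lnc_ids:
        return []
    X = matrix.data.loc[lnc_ids].to_numpy(dtype=float)
    r_up, p_up = correlate_matrix(X, matrix.row(decoy_up), method=method)
    r_dn, p_dn = correlate_matrix(X, matrix.row(decoy_down), method=method)
    q_up, q_dn = bh_fdr(p_up), bh_fdr(p_dn)

    out = []
    for i, fid in enumerate(lnc_ids):
        passing = (abs(r_up[i]) >= r_min and abs(r_dn[i]) >= r_min
                   and p_up[i] <= p_max and p_dn[i] <= p_max)
        if passing and r_up[i] > 0 and r_dn[i] < 0:
            cls = "oncogene_like"
        elif passing and r_up[i] < 0 and r_dn[i] > 0:
            cls = "tumor_suppressor_like"
        else:
            cls = "unclassified"
        out.append(CandidateLncRNA(fid, float(r_up[i]), float(p_up[i]),
                                   float(q_up[i]), float(r_dn[i]),
                                   float(p_dn[i]), float(q_dn[i]), cls))
    out.sort(key=lambda c: (-min(abs(c.r_decoy_up), abs(c.r_decoy_down)), c.id))
    return out


def screen_table(candidates: list[CandidateLncRNA]) -> pd.DataFrame:
    """Candidate list as the TSV-ready table."""
    return pd.DataFrame(
        [(c.id, c.r_decoy_up, c.p_decoy_up, c.r_decoy_down, c.p_decoy_down,
          c.fdr_decoy_up, c.fdr_decoy_down, c.classification)
         for c in candidates],
        columns=["id", "r_up", "p_up", "r_down", "p_down",
                 "fdr_up", "fdr_down", "class"],
    )
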