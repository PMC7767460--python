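"""Sponge-triplet (ceRNA) network assembly and perturbation confirmation.

Two independent evidence branches are intersected per sponged miRNA:

* the *anticorrelation branch*: mRNAs significantly negatively correlated
  with the miRNA and significantly positively correlated with the lncRNA in
  the cohort;
* the *complementarity branch*: mRNAs whose 3'-UTR carries multiple
  predicted seed sites for the miRNA.

An accepted lncRNA-miRNA-mRNA triplet therefore satisfies all six
conditions: r(lnc, mi) < 0, r(lnc, m) > 0, r(mi, m) < 0 (all significant),
and at least ``min_sites`` sites on both the lncRNA and the UTR.  Triplets
are scored by ``|r_lnc_mi| * |r_lnc_m| * |r_mi_m|``.

``confirm_targets`` applies the perturbation criteria used after lncRNA
silencing: an mRNA is confirmed in a cell line if it shows a significant
decrease at >= 1 timepoint or a significant positive correlation with the
lncRNA; consensus requires confirmation in every cell line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correlate import correlate_matrix
from .simulate import ExpressionMatrix
from .sites import (MiRNASite, SpongedMiRNA, find_seed_sites,
                    rank_sponged_mirnas, annotate_site_energies,
                    DEFAULT_ENERGY_MODEL)

logger = logging.getLogger(__name__)

__all__ = [
    "CeRNATriplet",
    "NetworkThresholds",
    "PerturbationMeasurement",
    "PerturbationCall",
    "anticorrelation_branch",
    "complementarity_branch",
    "build_network",
    "infer_network",
    "confirm_targets",
    "edge_table",
]


@dataclass(frozen=True)
class CeRNATriplet:
    lnc_id: str
    mirna_id: str
    mrna_id: str
    r_lnc_mi: float
    p_lnc_mi: float
    r_lnc_m: float
    p_lnc_m: float
    r_mi_m: float
    p_mi_m: float
    lnc_sites: int
    utr_sites: int
    score: float

    def __post_init__(self) -> None:
        if not (self.r_lnc_mi < 0 < self.r_lnc_m and self.r_mi_m < 0):
            raise ValueError("triplet violates the correlation-sign invariant")
        if self.lnc_sites < 1 or self.utr_sites < 1:
            raise ValueError("triplet requires sites on both lncRNA and UTR")


@dataclass(frozen=True)
class NetworkThresholds:
    """Significance and evidence thresholds for triplet acceptance."""

    p_max: float = 0.05
    min_sites: int = 2
    energy_cutoff: float = -7.0
    top_k_mirnas: int = 50


def _corr_against(matrix: ExpressionMatrix, ids: Sequence[str], anchor: str):
    X = matrix.data.loc[list(ids)].to_numpy(dtype=float)
    return correlate_matrix(X, matrix.row(anchor))


def anticorrelation_branch(
    mirna_id: str,
    lnc_id: str,
    matrix: ExpressionMatrix,
    p_max: float = 0.05,
) -> set[str]:
    """mRNAs significantly anti-correlated with the miRNA AND significantly
    positively correlated with the lncRNA."""
    if mirna_id not in matrix.data.index:
        raise KeyError(f"unknown miRNA id {mirna_id!r}")
    mrna_ids = matrix.features_of_class("mRNA")
    if not mrna_ids:
        return set()
    r_mi, p_mi = _corr_against(matrix, mrna_ids, mirna_id)
    r_ln, p_ln = _corr_against(matrix, mrna_ids, lnc_id)
    keep = (r_mi < 0) & (p_mi <= p_max) & (r_ln > 0) & (p_ln <= p_max)
    return {mid for mid, k in zip(mrna_ids, keep) if k}


def complementarity_branch(
    mirna_id: str,
    mirna_seq: str,
    utr_seqs: Mapping[str, str],
    min_sites: int = 2,
) -> dict[str, list[MiRNASite]]:
    """mRNAs whose 3'-UTR carries >= ``min_sites`` predicted seed sites.

    Returns the per-mRNA site lists for the ids that pass.
    """
    out = {}
    for mrna_id, utr in utr_seqs.items():
        if utr is None:
            logger.warning("no 3'-UTR available for %s; skipped", mrna_id)
            continue
        sites = find_seed_sites(mirna_seq, utr, mirna_id, mrna_id)
        if len(sites) >= min_sites:
            out[mrna_id] = sites
    return out


def build_network(
    lnc_id: str,
    sponged: Sequence[SpongedMiRNA],
    matrix: ExpressionMatrix,
    mirna_seqs: Mapping[str, str],
    utr_seqs: Mapping[str, str],
    thresholds: NetworkThresholds = NetworkThresholds(),
) -> list[CeRNATriplet]:
    """Intersect the two evidence branches per sponged miRNA into triplets.

    ``sponged`` comes from :func:`cernet.sites.rank_sponged_mirnas` and
    carries the lncRNA-side correlation and site count for each miRNA.
    Output is sorted by score descending (ties: more total sites, then
    lexicographic ids).
    """
    mrna_ids = matrix.features_of_class("mRNA")
    triplets = []
    for sp in sponged:
        anti = anticorrelation_branch(sp.mirna_id, lnc_id, matrix,
                                      thresholds.p_max)
        comp = complementarity_branch(sp.mirna_id, mirna_seqs[sp.mirna_id],
                                      {m: utr_seqs[m] for m in mrna_ids
                                       if m in utr_seqs},
                                      thresholds.min_sites)
        shared = anti & set(comp)
        if not shared:
            continue
        r_mi, p_mi = _corr_against(matrix, mrna_ids, sp.mirna_id)
        r_ln, p_ln = _corr_against(matrix, mrna_ids, lnc_id)
        stats = {m: (r_mi[i], p_mi[i], r_ln[i], p_ln[i])
                 for i, m in enumerate(mrna_ids)}
        for m in shared:
            rmm, pmm, rlm, plm = stats[m]
            triplets.append(CeRNATriplet(
                lnc_id, sp.mirna_id, m,
                r_lnc_mi=sp.r, p_lnc_mi=sp.p,
                r_lnc_m=float(rlm), p_lnc_m=float(plm),
                r_mi_m=float(rmm), p_mi_m=float(pmm),
                lnc_sites=sp.n_sites, utr_sites=len(comp[m]),
                score=abs(sp.r * rlm * rmm),
            ))
    triplets.sort(key=lambda t: (-t.score, -(t.lnc_sites + t.utr_sites),
                                 t.mirna_id, t.mrna_id))
    return triplets


def infer_network(
    lnc_id: str,
    matrix: ExpressionMatrix,
    lnc_seq: str,
    mirna_seqs: Mapping[str, str],
    utr_seqs: Mapping[str, str],
    thresholds: NetworkThresholds = NetworkThresholds(),
    model=DEFAULT_ENERGY_MODEL,
) -> tuple[list[CeRNATriplet], list[SpongedMiRNA]]:
    """End-to-end inference for one lncRNA: site scan on the lncRNA, sponge
    ranking, then branch intersection."""
    lnc_sites = {}
    for mid, mseq in mirna_seqs.items():
        sites = find_seed_sites(mseq, lnc_seq, mid, lnc_id)
        lnc_sites[mid] = annotate_site_energies(sites, mseq, lnc_seq, model)
    sponged = rank_sponged_mirnas(
        lnc_id, list(mirna_seqs), matrix, lnc_sites,
        top_k=thresholds.top_k_mirnas, min_sites=thresholds.min_sites,
        p_max=thresholds.p_max, energy_cutoff=thresholds.energy_cutoff)
    triplets = build_network(lnc_id, sponged, matrix, mirna_seqs, utr_seqs,
                             thresholds)
    return triplets, sponged


def edge_table(triplets: Sequence[CeRNATriplet]) -> pd.DataFrame:
    """Node/edge list with signed interaction types."""
    rows = []
    for t in triplets:
        rows.append((t.lnc_id, t.mirna_id, "sponges", t.r_lnc_mi,
                     t.p_lnc_mi, t.lnc_sites))
        rows.append((t.mirna_id, t.mrna_id, "targets", t.r_mi_m,
                     t.p_mi_m, t.utr_sites))
        rows.append((t.lnc_id, t.mrna_id, "protects", t.r_lnc_m,
                     t.p_lnc_m, 0))
    df = pd.DataFrame(rows, columns=["source", "target", "interaction",
                                     "r", "p", "sites"])
    return df.drop_duplicates(ignore_index=True)


# ---------------------------------------------------------------------------
# perturbation (silencing) confirmation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerturbationMeasurement:
    """Post-silencing readout for one mRNA in one cell line.

    ``fold_changes`` maps timepoint -> (signed fold change, p-value); a
    missing timepoint simply cannot contribute evidence.
    """

    cell_line: str
    mrna_id: str
    fold_changes: Mapping[str, tuple[float, float]]
    r_vs_lnc: float
    p_r: float


@dataclass(frozen=True)
class PerturbationCall:
    mrna_id: str
    confirmed_by_line: Mapping[str, bool]
    consensus: bool
    evidence: Mapping[str, str] = field(default_factory=dict)


def confirm_targets(
    measurements: Sequence[PerturbationMeasurement],
    alpha: float = 0.05,
) -> list[PerturbationCall]:
    """Apply the target-confirmation criteria across cell lines.

    Per line: confirmed iff (significant decrease, fc < 0 with p <= alpha,
    at >= 1 timepoint) OR (significant positive correlation with the
    lncRNA).  Consensus requires confirmation in all lines present.
    """
    if not measurements:
        return []
    by_mrna: dict[str, dict[str, PerturbationMeasurement]] = {}
    lines: set[str] = set()
    for m in measurements:
        by_mrna.setdefault(m.mrna_id, {})[m.cell_line] = m
        lines.add(m.cell_line)

    calls = []
    for mrna_id in sorted(by_mrna):
        confirmed = {}
        evidence = {}
        for line in sorted(lines):
            meas = by_mrna[mrna_id].get(line)
            if meas is None:
                confirmed[line] = False
                evidence[line] = "missing"
                continue
            decrease = any(fc < 0 and p <= alpha
                           for fc, p in meas.fold_changes.values())
            pos_corr = meas.r_vs_lnc > 0 and meas.p_r <= alpha
            confirmed[line] = decrease or pos_corr
            evidence[line] = ("decrease" if decrease else "") + \
                             ("+corr" if pos_corr else "") or "none"
        calls.append(PerturbationCall(
            mrna_id, confirmed, consensus=all(confirmed.values()),
            evidence=evidence))
    return calls


def evaluate_triplets(found: Sequence[CeRNATriplet],
                      truth) -> tuple[float, float]:
    """(precision, recall) of recovered triplets against planted truth."""
    found_set = {(t.lnc_id, t.mirna_id, t.mrna_id) for t in found}
    true_set = set(truth.planted_triplets)
    tp = len(found_set & true_set)
    precision = tp / len(found_set) if found_set else 1.0
    recall = tp / len(true_set) if true_set else 1.0
    return precision, recall
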