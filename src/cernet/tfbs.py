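"""TFBS-based screening of candidate transcription-factor regulators.

Given experimentally derived TF binding-site intervals (BED, 0-based
half-open) and a gene's TSS, count sites per TF inside a promoter window
(default 1 kb upstream, 200 nt downstream, strand-aware), then rank TFs by
their expression correlation with the gene in the cohort: a significant
positive correlation marks an activator candidate, a significant negative
one a repressor candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .correlate import correlate, ZeroVarianceError
from .simulate import ExpressionMatrix

__all__ = ["TFBSRecord", "TFCandidate", "promoter_window", "read_bed",
           "tfs_in_window", "rank_tf_candidates", "screen_tfs"]


@dataclass(frozen=True)
class TFBSRecord:
    tf_name: str
    chrom: str
    start: int
    end: int
    source_track: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("TFBS interval must have start < end")


@dataclass(frozen=True)
class TFCandidate:
    tf_name: str
    n_sites_in_window: int
    r_vs_lnc: float | None
    p_vs_lnc: float | None
    direction: str  # activator_candidate / repressor_candidate / none / uncorrelatable


def promoter_window(tss: int, strand: str, upstream: int = 1000,
                    downstream: int = 200) -> tuple[int, int]:
    """Strand-aware promoter interval around a TSS, clipped at 0.

    '+' strand: [tss - upstream, tss + downstream); '-' strand the mirror.
    """
    if tss < 0:
        raise ValueError("negative TSS")
    if upstream < 0 or downstream < 0:
        raise ValueError("window extents must be non-negative")
    if strand == "+":
        lo, hi = tss - upstream, tss + downstream
    elif strand == "-":
        lo, hi = tss - downstream, tss + upstream
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return max(0, lo), max(0, hi)


def read_bed(path) -> pd.DataFrame:
    """Read a BED file of TFBS intervals (chrom, start, end, name[, track]).

    Malformed lines raise with their 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            rows.append((parts[0], start, end, parts[3],
                         parts[4] if len(parts) > 4 else ""))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "track"])


def _as_frame(bed) -> pd.DataFrame:
    if isinstance(bed, pd.DataFrame):
        return bed
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.tf_name, r.source_track) for r in bed],
        columns=["chrom", "start", "end", "name", "track"])


def tfs_in_window(bed, window: tuple[int, int], chrom: str) -> list[tuple[str, int]]:
    """Per-TF counts of sites overlapping ``window`` (half-open overlap).

    ``bed`` is a DataFrame (chrom/start/end/name) or a TFBSRecord sequence;
    output is ordered by (count desc, name).
    """
    df = _as_frame(bed)
    lo, hi = window
    hit = (df["chrom"] == chrom) & (df["start"] < hi) & (df["end"] > lo)
    counts = df.loc[hit, "name"].value_counts()
    return sorted(((tf, int(n)) for tf, n in counts.items()),
                  key=lambda t: (-t[1], t[0]))


def rank_tf_candidates(
    tf_counts: Sequence[tuple[str, int]],
    matrix: ExpressionMatrix,
    lnc_id: str,
    p_max: float = 0.05,
) -> list[TFCandidate]:
    """Correlate each TF's expression with the lncRNA and classify.

    TFs absent from the matrix are retained, flagged uncorrelatable.  Output
    sorted by r descending, uncorrelatable entries last.
    """
    lnc = matrix.row(lnc_id)
    out = []
    for tf, n_sites in tf_counts:
        if tf not in matrix.data.index:
            out.append(TFCandidate(tf, n_sites, None, None, "uncorrelatable"))
            continue
        try:
            res = correlate(matrix.row(tf), lnc, feature_a=tf, feature_b=lnc_id)
        except ZeroVarianceError:
            out.append(TFCandidate(tf, n_sites, None, None, "uncorrelatable"))
            continue
        if res.p <= p_max and res.r > 0:
            direction = "activator_candidate"
        elif res.p <= p_max and res.r < 0:
            direction = "repressor_candidate"
        else:
            direction = "none"
        out.append(TFCandidate(tf, n_sites, res.r, res.p, direction))
    out.sort(key=lambda c: (c.r_vs_lnc is None,
                            -(c.r_vs_lnc if c.r_vs_lnc is not None else 0.0),
                            c.tf_name))
    return out


def screen_tfs(
    bed,
    tss: int,
    strand: str,
    chrom: str,
    matrix: ExpressionMatrix,
    lnc_id: str,
    upstream: int = 1000,
    downstream: int = 200,
    p_max: float = 0.05,
    marks=None,
) -> list[TFCandidate]:
    """End-to-end TF screen: promoter window -> site counts -> ranking.

    When a histone-mark BED is supplied, the promoter window must overlap at
    least one mark interval, otherwise no candidates are returned.
    """
    window = promoter_window(tss, strand, upstream, downstream)
    if marks is not None:
        mdf = _as_frame(marks) if not isinstance(marks, pd.DataFrame) else marks
        lo, hi = window
        ok = ((mdf["chrom"] == chrom) & (mdf["start"] < hi)
              & (mdf["end"] > lo)).any()
        if not ok:
            return []
    counts = tfs_in_window(bed, window, chrom)
    return rank_tf_candidates(counts, matrix, lnc_id, p_max)
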