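"""Synthetic cohorts, sequences and qPCR plates with planted ground truth.

Everything downstream of this module (the decoy screen, the sponge-triplet
inference, the masking analysis, the ΔΔCt layer) is exercised on data built
here, so each generator records exactly what it planted:

* ``simulate_cohort`` draws a log2-scale expression matrix from a Gaussian
  latent-factor model.  A latent "tumor activity" variable drives two decoy
  rows of opposite sign; each planted sponge triplet shares a latent factor
  that gives the lncRNA-miRNA pair a negative and the lncRNA-mRNA pair a
  positive target correlation.  Loadings are solved so the population
  correlation equals the requested rho exactly.
* ``simulate_sequences`` writes i.i.d. uniform A/C/G/U backgrounds and
  implants seed-complementary miRNA sites at recorded, non-overlapping
  positions; optionally it also pastes the reverse complement of a UTR window
  covering a site into the lncRNA (strong flanking complementarity, used by
  the protector/masking analysis).
* ``simulate_qpcr`` emits replicate Ct tables whose generating ΔΔCt equals
  ``-log2(fold change)`` with i.i.d. normal replicate noise on the Ct scale.
* ``simulate_tfbs`` emits a BED of TF binding intervals with a known set of
  TFs planted inside a promoter window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sites import revcomp, seed_pattern, SITE_CLASSES, validate_rna

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "ExpressionMatrix",
    "QpcrDesign",
    "QpcrDataset",
    "simulate_cohort",
    "simulate_sequences",
    "simulate_qpcr",
    "simulate_tfbs",
    "random_mirnas",
]

# Correlation of each decoy row with the latent tumor-activity variable.
# Planted candidate lncRNAs load on the same variable with
# decoy_coupling / DECOY_ACTIVITY_COUPLING, so their realized correlation
# with either decoy is decoy_coupling.
DECOY_ACTIVITY_COUPLING = 0.95


class InfeasibleCorrelationError(ValueError):
    """Requested correlation structure has no valid (PSD) covariance."""


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one simulated tumor-only cohort.

    Correlations are population targets: ``rho_lnc_mi`` (lncRNA vs sponged
    miRNA, negative), ``rho_lnc_m`` (lncRNA vs protected mRNA, positive) and
    ``decoy_coupling`` (magnitude of the planted lncRNAs' correlation with
    each decoy row).  ``noise_sd`` is the residual standard deviation of
    partner features around their shared-factor prediction, in log2 units.
    """

    n_samples: int = 200
    n_lncRNA: int = 30
    n_miRNA: int = 40
    n_mRNA: int = 100
    n_triplets: int = 5
    rho_lnc_mi: float = -0.7
    rho_lnc_m: float = 0.7
    decoy_coupling: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0
    n_tsg_lnc: int = 0
    decoy_up_id: str = "MET"
    decoy_down_id: str = "BAP1"

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if min(self.n_lncRNA, self.n_miRNA, self.n_mRNA) < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_triplets > min(self.n_lncRNA, self.n_miRNA, self.n_mRNA):
            raise ValueError("n_triplets exceeds available features")
        if self.n_triplets + self.n_tsg_lnc > self.n_lncRNA:
            raise ValueError("planted lncRNAs exceed n_lncRNA")
        if not (-1.0 < self.rho_lnc_mi < 0.0 < self.rho_lnc_m < 1.0):
            raise InfeasibleCorrelationError(
                "need rho_lnc_mi in (-1, 0) and rho_lnc_m in (0, 1)")
        if not 0.0 < self.decoy_coupling < 1.0:
            raise InfeasibleCorrelationError("decoy_coupling must be in (0, 1)")
        if self.decoy_coupling > DECOY_ACTIVITY_COUPLING:
            raise InfeasibleCorrelationError(
                f"decoy_coupling > {DECOY_ACTIVITY_COUPLING} implies a lncRNA-"
                "activity loading > 1 (covariance not positive semi-definite)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """Record of everything the generators planted."""

    planted_triplets: list[tuple[str, str, str]] = field(default_factory=list)
    planted_oncogene_lncRNAs: list[str] = field(default_factory=list)
    planted_tsg_lncRNAs: list[str] = field(default_factory=list)
    # (mirna_id, sequence_id) -> list of implanted 0-based start positions
    site_positions: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    # sequence_id -> list of (start, end) lncRNA intervals pasted as
    # reverse complements of UTR windows (flanking complementarity)
    complement_regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    true_fold_changes: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["site_positions"] = {
            f"{mi}\t{seq}": pos for (mi, seq), pos in self.site_positions.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["planted_triplets"] = [tuple(t) for t in payload["planted_triplets"]]
        payload["site_positions"] = {
            tuple(k.split("\t")): v for k, v in payload["site_positions"].items()
        }
        payload["complement_regions"] = {
            k: [tuple(iv) for iv in v]
            for k, v in payload.get("complement_regions", {}).items()
        }
        return cls(**payload)


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-abundance table with feature-class labels."""

    data: pd.DataFrame            # index = feature_id, columns = sample ids
    feature_class: pd.Series      # index = feature_id -> lncRNA/miRNA/mRNA/decoy

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.feature_class.index):
            raise ValueError("feature_class index must match data index")

    def row(self, feature_id: str) -> np.ndarray:
        if feature_id not in self.data.index:
            raise KeyError(f"feature {feature_id!r} not in matrix")
        return self.data.loc[feature_id].to_numpy(dtype=float)

    def features_of_class(self, cls: str) -> list[str]:
        return list(self.feature_class.index[self.feature_class == cls])

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "feature_class", self.feature_class)
        out.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        classes = df.pop("feature_class")
        return cls(df.astype(float), classes)


def simulate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one cohort matrix plus its ground truth.

    Row layout: the two decoys, then lncRNAs, miRNAs, mRNAs.  The first
    ``n_triplets`` lncRNA/miRNA/mRNA rows form the planted triplets; the next
    ``n_tsg_lnc`` lncRNAs are tumor-suppressor-like (anti-coupled to the
    decoys, no sponge partners); everything else is independent noise.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    g = DECOY_ACTIVITY_COUPLING
    h = spec.decoy_coupling / g          # lncRNA loading on tumor activity
    r1 = -spec.rho_lnc_mi                # magnitude of lnc-miRNA correlation
    r2 = spec.rho_lnc_m

    lnc_ids = [f"LNC{i:04d}" for i in range(spec.n_lncRNA)]
    mi_ids = [f"MIR{i:04d}" for i in range(spec.n_miRNA)]
    m_ids = [f"MRNA{i:04d}" for i in range(spec.n_mRNA)]
    sample_ids = [f"S{i:03d}" for i in range(n)]

    activity = rng.standard_normal(n)

    def noisy(signal, loading):
        # standardized feature with corr(feature, signal-source) = loading
        return loading * signal + np.sqrt(1.0 - loading ** 2) * rng.standard_normal(n)

    rows: dict[str, np.ndarray] = {}
    classes: dict[str, str] = {}

    rows[spec.decoy_up_id] = noisy(activity, g)
    rows[spec.decoy_down_id] = noisy(-activity, g)
    classes[spec.decoy_up_id] = classes[spec.decoy_down_id] = "decoy"

    truth = GroundTruth()
    for t in range(spec.n_triplets):
        lnc, mi, m = lnc_ids[t], mi_ids[t], m_ids[t]
        z = noisy(activity, h)           # triplet factor rides tumor activity
        rows[lnc] = z
        rows[mi] = noisy(-z, r1)
        rows[m] = noisy(z, r2)
        truth.planted_triplets.append((lnc, mi, m))
        truth.planted_oncogene_lncRNAs.append(lnc)
    for t in range(spec.n_triplets, spec.n_triplets + spec.n_tsg_lnc):
        lnc = lnc_ids[t]
        rows[lnc] = noisy(-activity, h)
        truth.planted_tsg_lncRNAs.append(lnc)

    for fid in lnc_ids:
        classes[fid] = "lncRNA"
        rows.setdefault(fid, rng.standard_normal(n))
    for fid in mi_ids:
        classes[fid] = "miRNA"
        rows.setdefault(fid, rng.standard_normal(n))
    for fid in m_ids:
        classes[fid] = "mRNA"
        rows.setdefault(fid, rng.standard_normal(n))

    order = [spec.decoy_up_id, spec.decoy_down_id] + lnc_ids + mi_ids + m_ids
    base_mean = {"decoy": 10.0, "lncRNA": 6.0, "miRNA": 8.0, "mRNA": 9.0}
    values = np.empty((len(order), n))
    for i, fid in enumerate(order):
        values[i] = base_mean[classes[fid]] + spec.noise_sd * rows[fid]

    data = pd.DataFrame(values, index=order, columns=sample_ids)
    matrix = ExpressionMatrix(data, pd.Series(classes).reindex(order))
    return matrix, truth


def random_mirnas(ids: Sequence[str], length: int = 22,
                  seed: int | np.random.Generator = 0) -> dict[str, str]:
    """Uniform-random miRNA sequences (5'->3') for the given ids."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alphabet = np.array(list("ACGU"))
    return {mid: "".join(rng.choice(alphabet, size=length)) for mid in ids}


class ImplantOverlapError(ValueError):
    """Requested implants cannot be placed without overlapping."""


def _implant(seq: list[str], pattern: str, k: int, rng,
             lo: int, hi: int) -> list[int]:
    """Place ``k`` non-overlapping copies of ``pattern`` in seq[lo:hi).

    The region is split into ``k`` equal slots and each copy lands uniformly
    inside its slot, which guarantees non-overlap without rejection loops.
    """
    span = hi - lo
    slot = span // k if k else span
    if k and slot < len(pattern):
        raise ImplantOverlapError(
            f"cannot place {k} x {len(pattern)} nt implants in {span} nt")
    starts = []
    for s in range(k):
        a = lo + s * slot
        start = int(rng.integers(a, a + slot - len(pattern) + 1))
        seq[start:start + len(pattern)] = list(pattern)
        starts.append(start)
    return starts


def simulate_sequences(
    truth: GroundTruth,
    mirna_seqs: Mapping[str, str],
    utr_len: int = 500,
    lnc_len: int = 600,
    sites_per_pair: int = 2,
    seed: int = 0,
    site_class: str = "7mer-m8",
    lnc_ids: Sequence[str] | None = None,
    mrna_ids: Sequence[str] | None = None,
    complement_len: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Emit lncRNA and 3'-UTR FASTA-ready sequences with implanted sites.

    For each planted triplet the lncRNA and the mRNA 3'-UTR each receive
    ``sites_per_pair`` sites exactly complementary to the miRNA seed, with
    implant coordinates appended to ``truth.site_positions``.  When
    ``complement_len`` > 0, for every UTR site a window of that length
    centred on the site is copied as its reverse complement into the second
    half of the lncRNA, giving the lncRNA:UTR duplex a deep energy minimum
    over the site (the miRNA-protector configuration).

    Returns ``(lnc_seqs, utr_seqs)`` as id -> sequence dicts; background ids
    (``lnc_ids`` / ``mrna_ids`` beyond the planted ones) get pure background.
    """
    if sites_per_pair < 1:
        raise ValueError("sites_per_pair must be >= 1")
    if site_class not in SITE_CLASSES:
        raise ValueError(f"unknown site class {site_class!r}")
    for mid, s in mirna_seqs.items():
        validate_rna(s, name=mid)
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGU"))

    lnc_ids = list(lnc_ids) if lnc_ids is not None else sorted(
        {t[0] for t in truth.planted_triplets})
    mrna_ids = list(mrna_ids) if mrna_ids is not None else sorted(
        {t[2] for t in truth.planted_triplets})

    lnc_seqs = {fid: list(rng.choice(alphabet, size=lnc_len)) for fid in lnc_ids}
    utr_seqs = {fid: list(rng.choice(alphabet, size=utr_len)) for fid in mrna_ids}

    # group triplets by sequence so multiple miRNAs on one lncRNA get
    # disjoint implant blocks
    by_lnc: dict[str, list[str]] = {}
    by_utr: dict[str, list[str]] = {}
    for lnc, mi, m in truth.planted_triplets:
        by_lnc.setdefault(lnc, []).append(mi)
        by_utr.setdefault(m, []).append(mi)

    def plant(seqs, grouping, upper_half_only):
        for sid, mirnas in grouping.items():
            seq = seqs[sid]
            # lncRNAs reserve their second half for complement pastes
            usable = len(seq) // 2 if upper_half_only else len(seq)
            block = usable // len(mirnas)
            for b, mi in enumerate(mirnas):
                pattern = seed_pattern(mirna_seqs[mi], site_class)
                starts = _implant(seq, pattern, sites_per_pair, rng,
                                  b * block, (b + 1) * block)
                truth.site_positions.setdefault((mi, sid), []).extend(starts)

    plant(utr_seqs, by_utr, upper_half_only=False)
    plant(lnc_seqs, by_lnc, upper_half_only=complement_len > 0)

    if complement_len > 0:
        for lnc, mi, m in truth.planted_triplets:
            lseq, useq = lnc_seqs[lnc], utr_seqs[m]
            cursor = len(lseq) // 2 + 2
            for start in truth.site_positions[(mi, m)]:
                site_len = len(seed_pattern(mirna_seqs[mi], site_class))
                centre = start + site_len // 2
                a = max(0, centre - complement_len // 2)
                b = min(len(useq), a + complement_len)
                paste = list(revcomp("".join(useq[a:b])))
                if cursor + len(paste) > len(lseq):
                    raise ImplantOverlapError(
                        "lncRNA too short for complementarity pastes")
                lseq[cursor:cursor + len(paste)] = paste
                truth.complement_regions.setdefault(lnc, []).append(
                    (cursor, cursor + len(paste)))
                cursor += len(paste) + 3

    return ({k: "".join(v) for k, v in lnc_seqs.items()},
            {k: "".join(v) for k, v in utr_seqs.items()})


@dataclass(frozen=True)
class QpcrDesign:
    """Two-group qPCR experiment layout.

    ``n_per_group`` biological samples per group, ``replicates`` technical
    replicates per sample, optional treatment timepoints (each timepoint is
    generated with the same true fold change unless overridden).
    """

    group1: str = "tumor"
    group2: str = "normal"
    n_per_group: int = 41
    replicates: int = 3
    timepoints: tuple[str, ...] = ("0h",)

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.n_per_group < 1:
            raise ValueError("need >= 1 sample per group")


@dataclass
class QpcrDataset:
    """Replicate-level Ct table (long format).

    Columns: sample, group, timepoint, replicate, target, ct_target,
    ct_reference.
    """

    records: pd.DataFrame

    COLUMNS = ("sample", "group", "timepoint", "replicate", "target",
               "ct_target", "ct_reference")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"missing Ct table columns: {sorted(missing)}")
        cts = self.records[["ct_target", "ct_reference"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(cts)) or np.any(cts <= 0):
            raise ValueError("Ct values must be finite and positive")

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "QpcrDataset":
        return cls(pd.read_csv(path, sep="\t"))


def _fc_to_ratio(fc: float) -> float:
    """Signed fold-change convention -> expression ratio (> 0)."""
    if fc > 0:
        return float(fc)
    if fc <= -1:
        return -1.0 / fc
    raise ValueError(f"fold change must be > 0 or <= -1, got {fc}")


def simulate_qpcr(
    design: QpcrDesign,
    true_fc: Mapping[str, float],
    ct_noise_sd: float = 0.2,
    seed: int = 0,
    reference_base_ct: float = 18.0,
) -> QpcrDataset:
    """Generate Ct records whose ΔΔCt equals ``-log2(true ratio)``.

    ``true_fc`` maps target id to the group1-vs-group2 fold change, in
    either the raw-ratio (> 0) or signed (<= -1) convention.  Replicate noise
    is i.i.d. normal on the target Ct; per-sample reference-loading offsets
    are shared between target and reference wells and cancel in ΔCt.
    """
    rng = np.random.default_rng(seed)
    recs = []
    for target, fc in true_fc.items():
        ratio = _fc_to_ratio(fc)
        base_dct = float(rng.uniform(3.0, 8.0))  # baseline abundance vs reference
        for group in (design.group1, design.group2):
            shift = -np.log2(ratio) if group == design.group1 else 0.0
            for s in range(design.n_per_group):
                sample = f"{group}{s:03d}"
                loading = float(rng.normal(0.0, 0.5))
                for tp in design.timepoints:
                    for rep in range(design.replicates):
                        ct_ref = reference_base_ct + loading
                        ct_tgt = (ct_ref + base_dct + shift
                                  + float(rng.normal(0.0, ct_noise_sd)))
                        recs.append((sample, group, tp, rep, target,
                                     ct_tgt, ct_ref))
    df = pd.DataFrame(recs, columns=list(QpcrDataset.COLUMNS))
    return QpcrDataset(df)


def simulate_tfbs(
    tss: int,
    chrom: str = "chr6",
    planted_tfs: Sequence[str] = ("MITF", "KDM1A"),
    n_background_tfs: int = 20,
    sites_per_tf: int = 2,
    upstream: int = 1000,
    downstream: int = 200,
    genome_span: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """BED-ready TFBS intervals: planted TFs inside the promoter window of
    ``tss``, background TFs scattered outside it."""
    rng = np.random.default_rng(seed)
    win_lo, win_hi = max(0, tss - upstream), tss + downstream
    rows = []
    for tf in planted_tfs:
        for _ in range(sites_per_tf):
            width = int(rng.integers(8, 20))
            start = int(rng.integers(win_lo, max(win_lo + 1, win_hi - width)))
            rows.append((chrom, start, start + width, tf))
    for i in range(n_background_tfs):
        tf = f"TF{i:03d}"
        for _ in range(sites_per_tf):
            width = int(rng.integers(8, 20))
            while True:
                start = int(rng.integers(0, genome_span - width))
                if start + width <= win_lo or start >= win_hi:
                    break
            rows.append((chrom, start, start + width, tf))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
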