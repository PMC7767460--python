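"""miRNA seed-site enumeration and RNA:RNA hybridization energy.

Seed matching follows the canonical target-site classes: with the miRNA
written 5'->3', a site on the target (also 5'->3') is

* ``8mer``    — reverse complement of miRNA positions 2-8, followed by A,
* ``7mer-m8`` — reverse complement of positions 2-8,
* ``7mer-A1`` — reverse complement of positions 2-7, followed by A,
* ``6mer``    — reverse complement of positions 2-7.

Seed matching is strict Watson-Crick.  Duplex energies come from a
nearest-neighbor dynamic program over non-crossing intermolecular pairings
(Watson-Crick plus G·U wobble) with affine bulge/internal-loop penalties; it
stands in for the thermodynamic scoring of external site-prediction servers
and makes no claim to reproduce their numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .correlate import correlate_matrix

__all__ = [
    "MiRNASite",
    "EnergyModel",
    "DEFAULT_ENERGY_MODEL",
    "SITE_CLASSES",
    "revcomp",
    "validate_rna",
    "seed_pattern",
    "find_seed_sites",
    "duplex_energy",
    "annotate_site_energies",
    "SpongedMiRNA",
    "rank_sponged_mirnas",
]

RNA_ALPHABET = "ACGU"
_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}
_ENC = {b: i for i, b in enumerate(RNA_ALPHABET)}

# class name -> priority rank (lower = higher class)
SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_RANK = {c: i for i, c in enumerate(SITE_CLASSES)}

DUPLEX_WINDOW_LIMIT = 40


class InvalidAlphabetError(ValueError):
    pass


def validate_rna(seq: str, name: str = "sequence") -> None:
    bad = sorted(set(seq) - set(RNA_ALPHABET))
    if bad:
        raise InvalidAlphabetError(
            f"{name} contains non-RNA characters: {bad}")


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def seed_pattern(mirna: str, site_class: str) -> str:
    """Target-strand (5'->3') pattern matched by ``site_class``."""
    validate_rna(mirna, "miRNA")
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    if site_class == "8mer":
        return revcomp(mirna[1:8]) + "A"
    if site_class == "7mer-m8":
        return revcomp(mirna[1:8])
    if site_class == "7mer-A1":
        return revcomp(mirna[1:7]) + "A"
    if site_class == "6mer":
        return revcomp(mirna[1:7])
    raise ValueError(f"unknown site class {site_class!r}")


@dataclass
class MiRNASite:
    """One predicted site, 0-based half-open on the target sense strand."""

    mirna_id: str
    target_id: str
    start: int
    end: int
    site_class: str
    duplex_energy: float = 0.0

    def __post_init__(self) -> None:
        if self.site_class not in _RANK:
            raise ValueError(f"unknown site class {self.site_class!r}")
        expected = len(seed_pattern("A" * 22, self.site_class))
        if self.end - self.start != expected:
            raise ValueError(
                f"{self.site_class} site must span {expected} nt, "
                f"got [{self.start}, {self.end})")


def find_seed_sites(mirna: str, target: str,
                    mirna_id: str = "mirna",
                    target_id: str = "target") -> list[MiRNASite]:
    """Enumerate all seed sites of ``mirna`` on ``target``.

    Each start position is reported once under its highest matching class
    (8mer > 7mer-m8 > 7mer-A1 > 6mer), and a lower-class site whose interval
    lies entirely inside a higher-class site is suppressed, so one planted
    site yields one call.  Sites are returned sorted by start position.
    """
    validate_rna(mirna, "miRNA")
    validate_rna(target, "target")
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt")

    found: dict[int, tuple[int, int]] = {}  # start -> (rank, end)
    for cls in SITE_CLASSES:
        pattern = seed_pattern(mirna, cls)
        pos = target.find(pattern)
        while pos != -1:
            if pos not in found:  # classes scanned best-first
                found[pos] = (_RANK[cls], pos + len(pattern))
            pos = target.find(pattern, pos + 1)

    items = sorted((s, r, e) for s, (r, e) in found.items())
    kept = []
    for s, r, e in items:
        contained = any(
            r2 < r and s2 <= s and e2 >= e for s2, r2, e2 in items
            if (s2, r2, e2) != (s, r, e))
        if not contained:
            kept.append(MiRNASite(mirna_id, target_id, s, e, SITE_CLASSES[r]))
    return kept


# ---------------------------------------------------------------------------
# nearest-neighbor energy model
# ---------------------------------------------------------------------------

# Watson-Crick stack energies in kcal/mol, keyed "XY/WZ": top strand 5'-XY-3'
# paired with bottom strand 3'-WZ-5'.  Versioned package constant (v1).
_WC_STACKS = {
    "AA/UU": -0.93,
    "AU/UA": -1.10,
    "UA/AU": -1.33,
    "CU/GA": -2.08,
    "CA/GU": -2.11,
    "GU/CA": -2.24,
    "GA/CU": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26,
    "GC/CG": -3.42,
}
# simplified wobble extension: flat values by number of G·U pairs in the stack
_GU_STACK_ONE = -1.2
_GU_STACK_TWO = -0.5

_WC_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU_PAIRS = {("G", "U"), ("U", "G")}
_ALL_PAIRS = _WC_PAIRS | _GU_PAIRS


def _build_stack_table() -> dict[str, float]:
    table = {}
    for key, e in _WC_STACKS.items():
        top, bottom = key.split("/")
        table[key] = e
        # 180-degree rotation leaves the physical stack unchanged
        table[f"{bottom[1]}{bottom[0]}/{top[1]}{top[0]}"] = e
    for p1 in _ALL_PAIRS:
        for p2 in _ALL_PAIRS:
            key = f"{p1[0]}{p2[0]}/{p1[1]}{p2[1]}"
            if key in table:
                continue
            n_gu = (p1 in _GU_PAIRS) + (p2 in _GU_PAIRS)
            if n_gu:
                table[key] = _GU_STACK_ONE if n_gu == 1 else _GU_STACK_TWO
    return table


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor duplex model.

    ``nn_stack`` maps "XY/WZ" (top 5'->3' / bottom 3'->5') to kcal/mol;
    loop penalties are affine in total unpaired length; ``au_end_penalty``
    is charged once per duplex terminus closed by an A-U or G·U pair.
    ``max_loop`` caps the bulge/internal-loop extent per strand.
    """

    nn_stack: Mapping[str, float] = field(default_factory=_build_stack_table)
    loop_open: float = 3.0
    loop_extend: float = 0.4
    au_end_penalty: float = 0.45
    max_loop: int = 8

    def __post_init__(self) -> None:
        if any(v >= 0 for v in self.nn_stack.values()):
            raise ValueError("all stack energies must be negative")
        if self.loop_open < 0 or self.loop_extend < 0 or self.au_end_penalty < 0:
            raise ValueError("penalties must be non-negative")

    def stack_energy(self, x1: str, y1: str, x2: str, y2: str) -> float:
        """Energy of stacking pair (x2, y2) on pair (x1, y1); x's adjacent
        5'->3' on one strand, y's adjacent 3'->5' on the other."""
        return self.nn_stack[f"{x1}{x2}/{y1}{y2}"]

    def end_penalty(self, x: str, y: str) -> float:
        return 0.0 if (x, y) in {("C", "G"), ("G", "C")} else self.au_end_penalty


DEFAULT_ENERGY_MODEL = EnergyModel()

_BIG = 1e9


def _model_arrays(model: EnergyModel):
    """Dense numba-ready arrays: stack[a,b,c,d], pairok[a,b], endpen[a,b]."""
    stack = np.full((4, 4, 4, 4), _BIG)
    pairok = np.zeros((4, 4), dtype=np.bool_)
    endpen = np.zeros((4, 4))
    for a, b in _ALL_PAIRS:
        pairok[_ENC[a], _ENC[b]] = True
        endpen[_ENC[a], _ENC[b]] = model.end_penalty(a, b)
    for key, e in model.nn_stack.items():
        top, bottom = key.split("/")
        stack[_ENC[top[0]], _ENC[bottom[0]], _ENC[top[1]], _ENC[bottom[1]]] = e
    return stack, pairok, endpen


_MODEL_CACHE: dict[int, tuple] = {}


def _cached_arrays(model: EnergyModel):
    key = id(model)
    if key not in _MODEL_CACHE:
        _MODEL_CACHE[key] = _model_arrays(model)
    return _MODEL_CACHE[key]


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_ENC[b] for b in seq), dtype=np.int64, count=len(seq))


@njit(cache=True)
def _duplex_kernel(x, y, stack, pairok, endpen,
                   loop_open, loop_extend, max_loop):
    """Best intermolecular duplex energy between x and y (both 5'->3').

    Pairs are antiparallel and non-crossing: indices increase along x while
    decreasing along y.  Returns (energy, x_first, x_last) of the optimum;
    energy 0 with (-1, -1) when nothing beats the open state.
    """
    n, m = x.shape[0], y.shape[0]
    E = np.full((n, m), _BIG)
    S = np.full((n, m), -1, dtype=np.int64)
    best = 0.0
    bs, be = -1, -1
    for i in range(n):
        for j in range(m - 1, -1, -1):
            if not pairok[x[i], y[j]]:
                continue
            e = endpen[x[i], y[j]]  # open a fresh duplex at this pair
            s = i
            ii_lo = i - 1 - max_loop
            if ii_lo < 0:
                ii_lo = 0
            jj_hi = j + 1 + max_loop
            if jj_hi > m - 1:
                jj_hi = m - 1
            for ii in range(ii_lo, i):
                for jj in range(j + 1, jj_hi + 1):
                    prev = E[ii, jj]
                    if prev >= _BIG:
                        continue
                    gx = i - ii - 1
                    gy = jj - j - 1
                    if gx == 0 and gy == 0:
                        cost = stack[x[ii], y[jj], x[i], y[j]]
                    else:
                        cost = loop_open + loop_extend * (gx + gy)
                    cand = prev + cost
                    if cand < e:
                        e = cand
                        s = S[ii, jj]
            E[i, j] = e
            S[i, j] = s
            closed = e + endpen[x[i], y[j]]
            if closed < best:
                best = closed
                bs, be = s, i
    return best, bs, be


def duplex_energy(mirna: str, target_window: str,
                  model: EnergyModel = DEFAULT_ENERGY_MODEL) -> float:
    """Minimum free energy (kcal/mol) of the mirna:window duplex.

    Intermolecular pairs only, non-crossing, nearest-neighbor stacks with
    affine loop penalties; 0.0 when no pairing improves on the open state.
    The window may be at most 40 nt (profiles must scan windows).
    """
    validate_rna(mirna, "miRNA")
    validate_rna(target_window, "target window")
    if len(target_window) > DUPLEX_WINDOW_LIMIT:
        raise ValueError(
            f"target window longer than {DUPLEX_WINDOW_LIMIT} nt; "
            "scan windows instead")
    if not mirna or not target_window:
        return 0.0
    stack, pairok, endpen = _cached_arrays(model)
    e, _, _ = _duplex_kernel(encode(mirna), encode(target_window),
                             stack, pairok, endpen,
                             model.loop_open, model.loop_extend,
                             int(model.max_loop))
    return float(min(0.0, e))


def annotate_site_energies(sites: Sequence[MiRNASite], mirna: str,
                           target: str, model: EnergyModel = DEFAULT_ENERGY_MODEL,
                           flank: int = 12) -> list[MiRNASite]:
    """Fill ``duplex_energy`` for each site from a window of the target
    extended ``flank`` nt on both sides (3'-supplementary pairing room)."""
    out = []
    for s in sites:
        lo = max(0, s.start - flank)
        hi = min(len(target), s.end + flank)
        window = target[lo:hi]
        if len(window) > DUPLEX_WINDOW_LIMIT:
            window = window[:DUPLEX_WINDOW_LIMIT]
        e = duplex_energy(mirna, window, model)
        out.append(MiRNASite(s.mirna_id, s.target_id, s.start, s.end,
                             s.site_class, e))
    return out


@dataclass(frozen=True)
class SpongedMiRNA:
    """A miRNA retained by the sponge ranking for one lncRNA."""

    mirna_id: str
    r: float
    p: float
    n_sites: int
    mean_energy: float


def rank_sponged_mirnas(
    lnc_id: str,
    mirna_ids: Sequence[str],
    matrix,
    lnc_sites: Mapping[str, Sequence[MiRNASite]],
    top_k: int = 50,
    min_sites: int = 2,
    p_max: float = 0.05,
    energy_cutoff: float = -7.0,
) -> list[SpongedMiRNA]:
    """Rank miRNAs potentially sponged by ``lnc_id``.

    Keep miRNAs negatively and significantly correlated with the lncRNA in
    the cohort, truncate to the ``top_k`` most negative, then require at
    least ``min_sites`` predicted sites on the lncRNA (``lnc_sites``, with
    energies annotated) whose mean duplex energy is at most
    ``energy_cutoff``.  Output ordered by (site count desc, mean energy asc,
    id).
    """
    mirna_ids = list(mirna_ids)
    if not mirna_ids or top_k <= 0:
        return []
    lnc = matrix.row(lnc_id)
    X = matrix.data.loc[mirna_ids].to_numpy(dtype=float)
    r, p = correlate_matrix(X, lnc)
    order = np.argsort(r, kind="stable")
    picked = []
    for idx in order:
        if r[idx] < 0 and p[idx] <= p_max:
            picked.append(idx)
        if len(picked) == top_k:
            break
    out = []
    for idx in picked:
        mid = mirna_ids[idx]
        sites = list(lnc_sites.get(mid, ()))
        if len(sites) < min_sites:
            continue
        mean_e = float(np.mean([s.duplex_energy for s in sites]))
        if mean_e > energy_cutoff:
            continue
        out.append(SpongedMiRNA(mid, float(r[idx]), float(p[idx]),
                                len(sites), mean_e))
    out.sort(key=lambda s: (-s.n_sites, s.mean_energy, s.mirna_id))
    return out
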