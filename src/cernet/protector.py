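"""miRNA-protector analysis: lncRNA:3'-UTR energy landscapes and masking.

A lncRNA that base-pairs directly with an mRNA 3'-UTR can cover miRNA
binding sites, shielding the mRNA from miRNA-mediated repression.  This
module slides a window along the UTR, finds for each window the best duplex
any equally sized lncRNA subsequence can form with it (the hybridization DP
from :mod:`cernet.sites`), calls minimum-free-energy regions from the
resulting profile, and intersects them with predicted miRNA sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .sites import (EnergyModel, DEFAULT_ENERGY_MODEL, MiRNASite,
                    _cached_arrays, _duplex_kernel, encode, validate_rna,
                    DUPLEX_WINDOW_LIMIT, _BIG)

logger = logging.getLogger(__name__)

__all__ = ["EnergyProfile", "MaskingEvent", "energy_profile",
           "call_mfe_regions", "masking_overlap"]


@dataclass
class EnergyProfile:
    """Per-window lncRNA:UTR interaction energies.

    ``energies[k]`` is the minimum duplex energy (kcal/mol) of UTR window
    ``[starts[k], starts[k] + window)`` against any lncRNA subsequence of
    length <= window; ``lnc_partner_coords[k]`` is the 0-based half-open
    lncRNA interval achieving it (``None`` when the optimum is the open
    state).
    """

    utr_id: str
    window: int
    step: int
    starts: np.ndarray
    energies: np.ndarray
    lnc_partner_coords: list[tuple[int, int] | None]
    unit: str = "kcal/mol"


@dataclass(frozen=True)
class MaskingEvent:
    """A miRNA site overlapped by an MFE region of the lncRNA:UTR profile."""

    utr_id: str
    mfe_region: tuple[int, int]
    mirna_site: MiRNASite
    overlap_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in (0, 1]")


@njit(cache=True)
def _profile_kernel(lnc, utr, window, step, stack, pairok, endpen,
                    loop_open, loop_extend, max_loop):
    L = lnc.shape[0]
    U = utr.shape[0]
    if U <= window:
        starts = np.zeros(1, dtype=np.int64)
        widths = np.array([U], dtype=np.int64)
    else:
        n_win = (U - window) // step + 1
        starts = np.arange(n_win, dtype=np.int64) * step
        widths = np.full(n_win, window, dtype=np.int64)
    energies = np.zeros(starts.shape[0])
    coords = np.full((starts.shape[0], 2), -1, dtype=np.int64)
    n_lnc_starts = L - window + 1
    if n_lnc_starts < 1:
        n_lnc_starts = 1
    for k in range(starts.shape[0]):
        y = utr[starts[k]:starts[k] + widths[k]]
        best = 0.0
        for l in range(n_lnc_starts):
            hi = l + window
            if hi > L:
                hi = L
            e, xs, xe = _duplex_kernel(lnc[l:hi], y, stack, pairok, endpen,
                                       loop_open, loop_extend, max_loop)
            if e < best:
                best = e
                coords[k, 0] = l + xs
                coords[k, 1] = l + xe + 1
        energies[k] = best
    return starts, energies, coords


def energy_profile(
    lnc_seq: str,
    utr_seq: str,
    window: int = 25,
    step: int = 1,
    model: EnergyModel = DEFAULT_ENERGY_MODEL,
    utr_id: str = "utr",
) -> EnergyProfile:
    """Sliding-window interaction-energy profile of ``utr_seq`` vs
    ``lnc_seq``.

    For each UTR window the minimum duplex energy over all lncRNA
    subsequences of length <= ``window`` is reported (energies are monotone
    under sequence extension, so scanning length-``window`` lncRNA substrings
    realizes that minimum exactly).  A UTR shorter than the window yields a
    single whole-sequence window.
    """
    validate_rna(lnc_seq, "lncRNA")
    validate_rna(utr_seq, "3'-UTR")
    if window > DUPLEX_WINDOW_LIMIT:
        raise ValueError(f"window must be <= {DUPLEX_WINDOW_LIMIT}")
    if window < 2 or step < 1:
        raise ValueError("window must be >= 2 and step >= 1")
    stack, pairok, endpen = _cached_arrays(model)
    starts, energies, coords = _profile_kernel(
        encode(lnc_seq), encode(utr_seq), window, step, stack, pairok,
        endpen, model.loop_open, model.loop_extend, int(model.max_loop))
    partner = [None if c[0] < 0 else (int(c[0]), int(c[1])) for c in coords]
    return EnergyProfile(utr_id, window, step, starts, energies, partner)


def call_mfe_regions(profile: EnergyProfile,
                     quantile: float = 0.25) -> list[tuple[int, int]]:
    """Merge the lowest-energy windows of a profile into maximal intervals.

    Windows whose energy is <= the ``quantile``-th percentile of the profile
    (and strictly negative) are unioned when adjacent or overlapping.  A
    constant profile is degenerate and yields no regions.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    e = np.asarray(profile.energies, dtype=float)
    if e.size == 0:
        return []
    if np.ptp(e) == 0:
        logger.warning("constant energy profile for %s: no MFE regions",
                       profile.utr_id)
        return []
    thr = np.quantile(e, quantile)
    sel = (e <= thr) & (e < 0)
    regions: list[list[int]] = []
    for k in np.flatnonzero(sel):
        s = int(profile.starts[k])
        end = s + profile.window
        if regions and s <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], end)
        else:
            regions.append([s, end])
    return [(a, b) for a, b in regions]


def masking_overlap(
    regions: Sequence[tuple[int, int]],
    sites: Sequence[MiRNASite],
    min_fraction: float = 0.5,
    utr_id: str = "utr",
) -> list[MaskingEvent]:
    """Report every (MFE region, miRNA site) pair whose overlap covers at
    least ``min_fraction`` of the site (0-based half-open arithmetic)."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    events = []
    for rs, re_ in regions:
        for site in sites:
            inter = min(re_, site.end) - max(rs, site.start)
            if inter <= 0:
                continue
            frac = inter / (site.end - site.start)
            if frac >= min_fraction:
                events.append(MaskingEvent(utr_id, (rs, re_), site, frac))
    return events
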