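"""Spin-system grouping of 3D HN(CO)CACB-type peak lists.

An HN(CO)CACB list carries two peaks per residue (one for glycine) sharing
the amide (1H, 15N) root of the following residue.  Grouping proceeds in two
steps: a registration step estimates per-dimension match tolerances from the
list itself (mutual-nearest-neighbor pair distances), then DBSCAN on
tolerance-normalized (h, n) coordinates clusters peaks into spin systems.
Leftover peaks are retried with tolerances re-estimated on the leftover
subset (inflated on each pass).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .errors import InsufficientDataError
from .types import CarbonPair, Peak3D, SpinSystemGroup, ToleranceSet

TOL_FLOOR_H = 0.001
TOL_FLOOR_N = 0.01
TOL_INFLATION = 3.0
CHI2_CUTOFF = 9.0  # 3-sigma-per-dimension equivalent in normalized distance
MAX_ITERATIONS = 5
#: A competing pairing closer than this factor times the best pair distance
#: makes an oversized cluster ambiguous (coincident amide roots).
AMBIGUITY_RATIO = 2.0


def _sorted_peaks(peaks: Sequence[Peak3D]) -> list[Peak3D]:
    return sorted(peaks, key=lambda p: (p.h_shift, p.n_shift, p.c_shift))


def estimate_match_tolerances(peaks: Sequence[Peak3D]) -> ToleranceSet:
    """Derive (1H, 15N) match tolerances from mutual-nearest-neighbor pairs.

    Peaks of the same spin system are each other's nearest neighbors in the
    (h, n) plane (coordinates standardized per dimension for the search).
    The per-dimension tolerance is 3x the median intra-pair distance, floored
    at instrument-resolution scale (0.001 ppm 1H, 0.01 ppm 15N).
    """
    if len(peaks) < 4:
        raise InsufficientDataError(
            f"tolerance estimation needs >= 4 peaks, got {len(peaks)}"
        )
    peaks = _sorted_peaks(peaks)
    xy = np.array([(p.h_shift, p.n_shift) for p in peaks])
    scale = xy.std(axis=0)
    scale[scale == 0] = 1.0
    nn = NearestNeighbors(n_neighbors=2).fit(xy / scale)
    _, idx = nn.kneighbors(xy / scale)
    nearest = idx[:, 1]
    mutual = [(i, j) for i, j in enumerate(nearest) if nearest[j] == i and i < j]
    if not mutual:
        return ToleranceSet(TOL_FLOOR_H, TOL_FLOOR_N)
    dh = np.array([abs(xy[i, 0] - xy[j, 0]) for i, j in mutual])
    dn = np.array([abs(xy[i, 1] - xy[j, 1]) for i, j in mutual])
    return ToleranceSet(
        tol_h=max(float(np.median(dh)) * TOL_INFLATION, TOL_FLOOR_H),
        tol_n=max(float(np.median(dn)) * TOL_INFLATION, TOL_FLOOR_N),
    )


def _resolve_oversized(
    members: list[int], coords: np.ndarray, cutoff: float
) -> tuple[list[list[int]], list[int], list[int]]:
    """Split a >2-peak cluster into pairs; returns (pairs, leftover, ambiguous).

    Repeatedly extracts the closest pair in normalized coordinates.  If a
    third peak offers a competing pairing within AMBIGUITY_RATIO times the
    best pair distance, the pairing cannot be trusted (coincident roots) and
    the involved peaks are flagged ambiguous instead.
    """
    pairs: list[list[int]] = []
    ambiguous: list[int] = []
    members = list(members)
    while len(members) >= 2:
        pts = coords[members]
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        best = d[i, j]
        if best > cutoff:
            break
        rivals = [
            k
            for k in range(len(members))
            if k not in (i, j) and min(d[i, k], d[j, k]) < AMBIGUITY_RATIO * best
        ]
        chosen = [members[i], members[j]]
        if rivals:
            ambiguous.extend(chosen + [members[k] for k in rivals])
            drop = set(chosen) | {members[k] for k in rivals}
        else:
            pairs.append(chosen)
            drop = set(chosen)
        members = [m for m in members if m not in drop]
    return pairs, members, ambiguous


def group_into_spin_systems(
    peaks: Sequence[Peak3D],
    tolerances: ToleranceSet,
    chi2_cutoff: float = CHI2_CUTOFF,
) -> tuple[list[SpinSystemGroup], list[Peak3D], list[Peak3D]]:
    """Cluster peaks into spin systems by their shared amide root.

    DBSCAN runs on ((h - h')/tol_h, (n - n')/tol_n) coordinates with the
    squared normalized distance cutoff ``chi2_cutoff`` as the neighborhood
    relation and minimum cluster size 1, so isolated peaks survive as
    glycine-candidate singletons.  Clusters larger than two are resolved by
    closest-pair extraction; unresolvable members are flagged ambiguous.

    Returns (groups, ungrouped peaks, ambiguous peaks).
    """
    peaks = _sorted_peaks(peaks)
    if not peaks:
        return [], [], []
    coords = np.array(
        [(p.h_shift / tolerances.tol_h, p.n_shift / tolerances.tol_n) for p in peaks]
    )
    labels = DBSCAN(eps=float(np.sqrt(chi2_cutoff)), min_samples=1).fit_predict(coords)
    groups: list[SpinSystemGroup] = []
    ungrouped: list[Peak3D] = []
    ambiguous: list[Peak3D] = []
    for lab in np.unique(labels):
        members = list(np.flatnonzero(labels == lab))
        if len(members) <= 2:
            groups.append(SpinSystemGroup(peaks=[peaks[m] for m in members]))
            continue
        pairs, leftover, ambig = _resolve_oversized(
            members, coords, cutoff=float(np.sqrt(chi2_cutoff))
        )
        groups.extend(SpinSystemGroup(peaks=[peaks[a], peaks[b]]) for a, b in pairs)
        ungrouped.extend(peaks[m] for m in leftover)
        ambiguous.extend(peaks[m] for m in ambig)
    return groups, ungrouped, ambiguous


def iterative_grouping(
    peaks: Sequence[Peak3D],
    chi2_cutoff: float = CHI2_CUTOFF,
    max_iterations: int = MAX_ITERATIONS,
) -> list[SpinSystemGroup]:
    """Group with tolerance re-estimation on leftovers until convergence.

    Each pass estimates tolerances on the not-yet-grouped subset (doubled
    when the subset is too small to register) and regroups it.  Peaks still
    unresolved after ``max_iterations`` passes, and peaks flagged ambiguous,
    are returned as ambiguous singleton groups rather than dropped.
    """
    if len(peaks) < 4:
        raise InsufficientDataError(
            f"iterative grouping needs >= 4 peaks, got {len(peaks)}"
        )
    remaining = _sorted_peaks(peaks)
    all_groups: list[SpinSystemGroup] = []
    ambiguous_peaks: list[Peak3D] = []
    tol = estimate_match_tolerances(remaining)
    for _ in range(max_iterations):
        groups, leftover, ambig = group_into_spin_systems(remaining, tol, chi2_cutoff)
        all_groups.extend(groups)
        ambiguous_peaks.extend(ambig)
        if not leftover:
            remaining = []
            break
        remaining = leftover
        if len(remaining) >= 4:
            tol = estimate_match_tolerances(remaining)
        else:
            tol = ToleranceSet(tol.tol_h * 2, tol.tol_n * 2)
    for p in remaining + ambiguous_peaks:
        all_groups.append(SpinSystemGroup(peaks=[p], ambiguous=True))
    return all_groups


def spin_systems_to_pairs(
    groups: Sequence[SpinSystemGroup],
) -> tuple[list[CarbonPair], list[str]]:
    """Carbon pairs from 2-peak groups; singletons and ambiguous groups skipped.

    Returns the pairs and a log of exclusion reasons (one line per skipped
    group).
    """
    pairs: list[CarbonPair] = []
    log: list[str] = []
    for g in groups:
        root = f"(h={g.root_h:.3f}, n={g.root_n:.2f})"
        if g.ambiguous:
            log.append(f"excluded ambiguous group at {root}")
            continue
        if len(g.peaks) == 1:
            log.append(f"excluded singleton (glycine candidate) at {root}")
            continue
        c1, c2 = g.carbon_shifts
        pairs.append(CarbonPair(shift_a=c1, shift_b=c2, ordered=False))
    return pairs, log
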