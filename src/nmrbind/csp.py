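"""Weighted chemical-shift perturbations, peak tracking and CSP profiles.

In the fast-exchange regime each amide peak moves continuously from its
free position toward its bound position as ligand is added, and the
observed displacement is the population-weighted average of the two
states.  The per-residue readout is the weighted CSP

    Δδ = sqrt( Δδ(1H)^2 + w · Δδ(15N)^2 ),   w = 1/4 by default,

which down-weights the nitrogen dimension by its larger intrinsic shift
range.  The 1/4 coefficient follows the convention used for amide
titrations; other conventions exist (e.g. (Δδ_N/5)^2), so the weight is
exposed as a parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _segments
from ._util import NmrbindWarning, parse_residue_label
from .io import PeakList, SequenceRecord, TitrationSeries

__all__ = [
    "weighted_csp", "peak_distance", "track_peaks", "PeakMatching",
    "ShiftTrajectory", "build_trajectories", "CSPProfile", "csp_profile",
    "call_binding_segments", "DEFAULT_N_WEIGHT", "DEFAULT_TRACK_CUTOFF",
]

DEFAULT_N_WEIGHT = 0.25
DEFAULT_TRACK_CUTOFF = 0.15  # weighted ppm, between adjacent points


def weighted_csp(delta_H_change, delta_N_change,
                 n_weight: float = DEFAULT_N_WEIGHT):
    """Weighted 1H/15N chemical-shift perturbation in ppm.

    Accepts scalars or arrays; the result is a norm on
    ``(Δδ_H, sqrt(w)·Δδ_N)`` and therefore non-negative, symmetric under
    sign flips, and obeys the triangle inequality.
    """
    dH = np.asarray(delta_H_change, dtype=float)
    dN = np.asarray(delta_N_change, dtype=float)
    if not (np.all(np.isfinite(dH)) and np.all(np.isfinite(dN))):
        raise ValueError("non-finite chemical-shift change")
    out = np.sqrt(dH ** 2 + n_weight * dN ** 2)
    return float(out) if out.ndim == 0 else out


def peak_distance(a, b, n_weight: float = DEFAULT_N_WEIGHT) -> float:
    """Distance between two peaks in the weighted ppm metric."""
    return weighted_csp(a.delta_H - b.delta_H, a.delta_N - b.delta_N,
                        n_weight=n_weight)


@dataclass
class PeakMatching:
    """Result of matching peaks between two adjacent titration points."""

    pairs: list[tuple[int, int, float]]  # (ref index, target index, distance)
    unmatched_reference: list[int]
    unmatched_target: list[int]

    def target_for(self, ref_index: int) -> int | None:
        for i, j, _ in self.pairs:
            if i == ref_index:
                return j
        return None

    def as_dict(self) -> dict[int, int]:
        return {i: j for i, j, _ in self.pairs}


def track_peaks(reference: PeakList, target: PeakList,
                cutoff: float = DEFAULT_TRACK_CUTOFF,
                n_weight: float = DEFAULT_N_WEIGHT) -> PeakMatching:
    """Match peaks of ``reference`` to ``target`` between adjacent points.

    Matching is greedy nearest-neighbour in the weighted ppm metric,
    processed in increasing-distance order; pairs farther apart than
    ``cutoff`` stay unmatched.  When both lists assign the same residue
    label, that pair is matched first regardless of geometry.  Tracking is
    only meaningful between *adjacent* titration points, where
    fast-exchange peak movement is small.
    """
    if len(reference) == 0 or len(target) == 0:
        raise ValueError("cannot track empty peak lists")
    pairs: list[tuple[int, int, float]] = []
    used_ref: set[int] = set()
    used_tgt: set[int] = set()

    tgt_by_label = {p.residue_label: j for j, p in enumerate(target)
                    if p.is_assigned}
    for i, p in enumerate(reference):
        if p.is_assigned and p.residue_label in tgt_by_label:
            j = tgt_by_label[p.residue_label]
            pairs.append((i, j, peak_distance(p, target.peaks[j], n_weight)))
            used_ref.add(i)
            used_tgt.add(j)

    candidates = sorted(
        (peak_distance(p, q, n_weight), i, j)
        for i, p in enumerate(reference) if i not in used_ref
        for j, q in enumerate(target) if j not in used_tgt
    )
    for d, i, j in candidates:
        if d > cutoff:
            break
        if i in used_ref or j in used_tgt:
            continue
        pairs.append((i, j, d))
        used_ref.add(i)
        used_tgt.add(j)

    pairs.sort()
    return PeakMatching(
        pairs=pairs,
        unmatched_reference=[i for i in range(len(reference))
                             if i not in used_ref],
        unmatched_target=[j for j in range(len(target))
                          if j not in used_tgt],
    )


@dataclass
class ShiftTrajectory:
    """Per-residue shift changes along the titration, relative to apo."""

    residue_label: str
    ligand_total: np.ndarray     # molar, one entry per reached point
    delta_H_change: np.ndarray   # ppm
    delta_N_change: np.ndarray   # ppm
    csp: np.ndarray              # weighted ppm
    truncated: bool = False

    def __post_init__(self):
        self.ligand_total = np.asarray(self.ligand_total, dtype=float)
        self.delta_H_change = np.asarray(self.delta_H_change, dtype=float)
        self.delta_N_change = np.asarray(self.delta_N_change, dtype=float)
        self.csp = np.asarray(self.csp, dtype=float)
        if self.csp[0] != 0.0:
            raise ValueError("first (apo) point must have csp == 0")
        if np.any(self.csp < 0):
            raise ValueError("csp must be non-negative")

    def __len__(self) -> int:
        return len(self.csp)

    @property
    def residue_number(self) -> int:
        return parse_residue_label(self.residue_label)[1]


def build_trajectories(series: TitrationSeries,
                       cutoff: float = DEFAULT_TRACK_CUTOFF,
                       n_weight: float = DEFAULT_N_WEIGHT
                       ) -> dict[str, ShiftTrajectory]:
    """Chain peak tracking across the titration into per-residue trajectories.

    One trajectory is emitted per assigned apo residue.  A residue whose
    peak cannot be followed at some point yields a truncated trajectory
    and a warning; shifts are always reported relative to the apo point.
    """
    apo = series.points[0].peaklist
    if not apo.assigned:
        raise ValueError("apo point has no assigned peaks")

    matchings = [
        track_peaks(series.points[k].peaklist, series.points[k + 1].peaklist,
                    cutoff=cutoff, n_weight=n_weight)
        for k in range(len(series) - 1)
    ]

    trajectories: dict[str, ShiftTrajectory] = {}
    for label, apo_peak in apo.assigned.items():
        index = next(i for i, p in enumerate(apo) if p is apo_peak)
        lig = [series.points[0].ligand_total]
        dH, dN = [0.0], [0.0]
        truncated = False
        for k, matching in enumerate(matchings):
            nxt = matching.target_for(index)
            if nxt is None:
                warnings.warn(
                    f"trajectory {label} truncated at point {k + 1} "
                    "(peak unmatched)", NmrbindWarning)
                truncated = True
                break
            peak = series.points[k + 1].peaklist.peaks[nxt]
            lig.append(series.points[k + 1].ligand_total)
            dH.append(peak.delta_H - apo_peak.delta_H)
            dN.append(peak.delta_N - apo_peak.delta_N)
            index = nxt
        csp = weighted_csp(np.array(dH), np.array(dN), n_weight=n_weight)
        csp = np.atleast_1d(csp)
        trajectories[label] = ShiftTrajectory(
            residue_label=label, ligand_total=np.array(lig),
            delta_H_change=np.array(dH), delta_N_change=np.array(dN),
            csp=csp, truncated=truncated)
    return trajectories


@dataclass
class CSPProfile:
    """Per-residue weighted CSP at one named titration point."""

    values: dict[str, float]             # residue label -> csp (ppm)
    point_index: int
    sequence: SequenceRecord | None = None

    def __post_init__(self):
        if not self.values:
            raise ValueError("empty CSP profile")
        if any(v < 0 for v in self.values.values()):
            raise ValueError("csp values must be non-negative")
        ordered = sorted(self.values,
                         key=lambda lab: parse_residue_label(lab)[1])
        self.values = {lab: self.values[lab] for lab in ordered}

    def positions(self) -> dict[int, float]:
        return {parse_residue_label(lab)[1]: v
                for lab, v in self.values.items()}

    def __len__(self) -> int:
        return len(self.values)


def csp_profile(trajectories: dict[str, ShiftTrajectory],
                point_index: int = -1,
                sequence: SequenceRecord | None = None) -> CSPProfile:
    """Collect per-residue CSP at one titration point (default: final).

    Trajectories truncated before the requested point are excluded with a
    warning.  Prolines never appear (no backbone amide peak), and
    unassigned peaks never produce trajectories.
    """
    n_points = max(len(t) for t in trajectories.values())
    index = point_index if point_index >= 0 else n_points + point_index
    values = {}
    for label, traj in trajectories.items():
        if len(traj) <= index:
            warnings.warn(f"residue {label} missing from CSP profile "
                          f"(trajectory truncated before point {index})",
                          NmrbindWarning)
            continue
        values[label] = float(traj.csp[index])
    return CSPProfile(values=values, point_index=index, sequence=sequence)


def call_binding_segments(profile: CSPProfile,
                          threshold_rule: str = "mean_plus_sd",
                          min_run: int = 3,
                          absolute: float | None = None
                          ) -> list[tuple[int, int]]:
    """Call contiguous binding segments from a CSP profile.

    Returns closed residue intervals (sequence numbering) where at least
    ``min_run`` residues exceed the threshold; single measured
    non-exceeding residues and any stretch of unmeasured residues
    (prolines, unassigned) are bridged.
    """
    threshold = _segments.threshold_value(profile.values.values(),
                                         threshold_rule, absolute)
    return _segments.call_segments(profile.positions(), threshold,
                                   min_run=min_run, max_gap=1,
                                   max_exceptions=None)


def profile_to_frame(profile: CSPProfile, threshold_rule: str = "mean_plus_sd",
                     absolute: float | None = None):
    """CSP profile as a DataFrame (residue, position, csp_ppm, exceeds)."""
    import pandas as pd

    threshold = _segments.threshold_value(profile.values.values(),
                                         threshold_rule, absolute)
    rows = [(lab, parse_residue_label(lab)[1], v, v > threshold)
            for lab, v in profile.values.items()]
    return pd.DataFrame(rows, columns=["residue", "position", "csp_ppm",
                                       "exceeds_threshold"])
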