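"""Run-calling engine shared by the CSP and ΔR2 segment callers.

A "segment" is a maximal run of residues whose per-residue statistic
(weighted CSP, or ΔR2) exceeds a threshold.  Two kinds of interruption
are tolerated inside a run:

* residues absent from the profile entirely (prolines have no backbone
  amide; unassigned residues carry no evidence) are bridged regardless of
  how many occur consecutively — e.g. a Pro-Pro-Pro triple must not split
  a binding region;
* measured residues that fail the threshold ("interior exceptions") are
  bridged only in gaps of at most ``max_gap`` consecutive measured
  residues, and optionally capped at ``max_exceptions`` per run.

Runs are reported as closed ``[first, last]`` intervals in the protein's
own sequence numbering, anchored on exceeding residues.
"""

from __future__ import annotations

import numpy as np

THRESHOLD_RULES = ("mean_plus_sd", "mean", "absolute")


def threshold_value(values, rule: str = "mean_plus_sd",
                    absolute: float | None = None) -> float:
    """Threshold for segment calling from a profile's values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty profile")
    if rule == "mean_plus_sd":
        return float(arr.mean() + arr.std())
    if rule == "mean":
        return float(arr.mean())
    if rule == "absolute":
        if absolute is None:
            raise ValueError("rule 'absolute' requires an explicit value")
        return float(absolute)
    raise ValueError(f"unknown threshold rule {rule!r}; "
                     f"choose from {THRESHOLD_RULES}")


def call_segments(profile: dict[int, float], threshold: float,
                  min_run: int = 3, max_gap: int = 1,
                  max_exceptions: int | None = None) -> list[tuple[int, int]]:
    """Call closed intervals of positions exceeding ``threshold``.

    ``profile`` maps sequence position -> statistic; positions not present
    are treated as unmeasured (bridgeable).  ``min_run`` is the minimum
    number of *exceeding* residues a reported run must contain.
    """
    if not profile:
        raise ValueError("empty profile")
    exceeding = sorted(p for p, v in profile.items() if v > threshold)
    if not exceeding:
        return []
    measured = set(profile)

    segments: list[tuple[int, int]] = []
    run_start = run_end = exceeding[0]
    run_count = 1
    run_exceptions = 0
    for pos in exceeding[1:]:
        gap_measured = [q for q in range(run_end + 1, pos) if q in measured]
        # measured failures inside the gap must be few and consecutive-short
        longest = 0
        streak = 0
        for q in range(run_end + 1, pos):
            streak = streak + 1 if q in measured else 0
            longest = max(longest, streak)
        bridgeable = longest <= max_gap
        if bridgeable and max_exceptions is not None:
            bridgeable = run_exceptions + len(gap_measured) <= max_exceptions
        if bridgeable:
            run_exceptions += len(gap_measured)
            run_end = pos
            run_count += 1
        else:
            if run_count >= min_run:
                segments.append((run_start, run_end))
            run_start = run_end = pos
            run_count = 1
            run_exceptions = 0
    if run_count >= min_run:
        segments.append((run_start, run_end))
    return segments


def write_segments_bed(segments, path, name: str = "segment") -> None:
    """Write segments as 3-column BED-like text.

    Coordinates are 1-based closed intervals in the protein's sequence
    numbering (not genomic BED half-open convention); documented here and
    in the output header.
    """
    lines = ["# name start end (1-based closed, sequence numbering)"]
    for start, end in segments:
        lines.append(f"{name}\t{start}\t{end}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
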