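"""End-to-end orchestration: titration -> CSP -> segments -> K_D fits.

The single entry point :func:`analyze_titration` chains peak tracking,
CSP profiling, binding-segment calling and per-residue depletion-model
fits, and returns a plain-dict manifest suitable for JSON serialization;
:func:`analyze_relaxation` does the same for the ΔR2 route.  The CLI and
the numbered analysis drivers are thin wrappers over these two.
"""

from __future__ import annotations

import numpy as np

from . import __version__
from .binding import fit_binding, global_fit
from .csp import (DEFAULT_N_WEIGHT, DEFAULT_TRACK_CUTOFF, build_trajectories,
                  call_binding_segments, csp_profile)
from .io import TitrationSeries
from .relaxation import (call_dynamic_segments, delta_r2_profile, fit_decay,
                         rate_summary)

__all__ = ["analyze_titration", "analyze_relaxation"]


def analyze_titration(series: TitrationSeries,
                      threshold_rule: str = "mean_plus_sd",
                      min_run: int = 3,
                      absolute: float | None = None,
                      fit_residues=None,
                      fix_n: float | None = None,
                      track_cutoff: float = DEFAULT_TRACK_CUTOFF,
                      n_weight: float = DEFAULT_N_WEIGHT,
                      do_global_fit: bool = False,
                      point_index: int = -1) -> dict:
    """Run the full CSP/binding pipeline on a titration series.

    ``fit_residues`` selects which residues get per-residue K_D fits;
    by default every residue inside a called binding segment is fit.
    Returns a manifest dict with the profile, segments and fit results.
    """
    trajectories = build_trajectories(series, cutoff=track_cutoff,
                                      n_weight=n_weight)
    profile = csp_profile(trajectories, point_index=point_index)
    segments = call_binding_segments(profile, threshold_rule=threshold_rule,
                                     min_run=min_run, absolute=absolute)

    if fit_residues is None:
        fit_residues = [lab for lab in profile.values
                        if any(a <= int(lab[1:]) <= b for a, b in segments)]
    fits = {}
    for label in fit_residues:
        traj = trajectories.get(label)
        if traj is None or traj.truncated:
            continue
        fits[label] = fit_binding(traj, series.receptor_total, fix_n=fix_n)

    manifest = {
        "nmrbind_version": __version__,
        "n_points": len(series),
        "receptor_total_M": series.receptor_total,
        "molar_ratios": list(series.molar_ratios),
        "n_weight": n_weight,
        "track_cutoff_ppm": track_cutoff,
        "threshold_rule": threshold_rule,
        "min_run": min_run,
        "csp_profile": dict(profile.values),
        "segments": [list(s) for s in segments],
        "fits": {
            lab: {"kd_uM": fit.kd_uM, "kd_err_uM": fit.kd_err * 1e6,
                  "n": fit.n, "n_err": fit.n_err,
                  "delta_max_ppm": fit.delta_max,
                  "delta_max_err_ppm": fit.delta_max_err,
                  "converged": fit.converged, "n_fixed": fit.n_fixed}
            for lab, fit in fits.items()
        },
    }
    if fits:
        kds = [f.kd_uM for f in fits.values() if f.converged]
        if kds:
            manifest["median_kd_uM"] = float(np.median(kds))
    if do_global_fit and len(fits) >= 2:
        shared = global_fit({lab: trajectories[lab] for lab in fits},
                            series.receptor_total, fix_n=fix_n)
        manifest["global_fit"] = {
            "kd_uM": shared.kd * 1e6, "kd_err_uM": shared.kd_err * 1e6,
            "n": shared.n, "redchi": shared.redchi,
            "converged": shared.converged,
        }
    manifest["_objects"] = {"trajectories": trajectories,
                            "profile": profile, "fits": fits}
    return manifest


def analyze_relaxation(free_series, bound_series,
                       threshold_rule: str = "mean_plus_sd",
                       min_run: int = 3,
                       absolute: float | None = None,
                       max_exceptions: int = 2) -> dict:
    """Fit free/bound decay series, build the ΔR2 profile, call segments."""
    free_fits = [fit_decay(s) for s in free_series]
    bound_fits = [fit_decay(s) for s in bound_series]
    profile = delta_r2_profile(free_fits, bound_fits)
    segments = call_dynamic_segments(profile, threshold_rule=threshold_rule,
                                     min_run=min_run, absolute=absolute,
                                     max_exceptions=max_exceptions)
    return {
        "nmrbind_version": __version__,
        "free_summary": rate_summary(free_fits),
        "bound_summary": rate_summary(bound_fits),
        "segments": [list(s) for s in segments],
        "_objects": {"free_fits": free_fits, "bound_fits": bound_fits,
                     "delta_r2": profile},
    }
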