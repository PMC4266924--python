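"""15N relaxation rates, heteronuclear NOE ratios and ΔR2 binding segments.

R1 and R2 are extracted from mono-exponential decays of cross-peak
intensity over a delay series, I(t) = A·exp(-R·t); the steady-state
1H->15N NOE is the ratio of peak heights with and without proton
saturation.  For a disordered peptide, elevated transverse relaxation
(ΔR2 = R2_bound - R2_free) flags residues slowed or exchange-broadened
by complex formation, and is used here as an independent binding-segment
readout alongside the CSP profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import _segments
from ._util import NmrbindWarning, parse_residue_label

__all__ = [
    "R1_DELAYS", "CPMG_DELAYS", "RelaxationSeries", "RelaxationResult",
    "NOERecord", "fit_decay", "het_noe", "delta_r2_profile",
    "call_dynamic_segments", "rate_summary", "read_relaxation_csv",
]

#: Longitudinal (R1) relaxation delay schedule, seconds.
R1_DELAYS = (0.0016, 0.050, 0.100, 0.200, 0.300, 0.400, 0.800, 1.000, 1.200)
#: CPMG transverse (R2) total relaxation delay schedule, seconds.
CPMG_DELAYS = (0.064, 0.128, 0.160, 0.192, 0.224, 0.250)

_RATE_CLIP = (1e-3, 1e3)  # s^-1, clip window for the initial-guess rate


@dataclass
class RelaxationSeries:
    """Intensity-vs-delay series for one residue and one experiment."""

    residue_label: str
    delays: np.ndarray       # seconds
    intensities: np.ndarray  # arbitrary units
    experiment: str          # 'R1' | 'R2'

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.experiment not in ("R1", "R2"):
            raise ValueError("experiment must be 'R1' or 'R2'")
        if len(self.delays) != len(self.intensities):
            raise ValueError("delays and intensities differ in length")
        if len(np.unique(self.delays)) < 3:
            raise ValueError("need >= 3 distinct delays")
        if np.any(self.delays < 0):
            raise ValueError("delays must be >= 0")


@dataclass
class RelaxationResult:
    """Fitted mono-exponential decay rate for one residue."""

    residue_label: str
    rate: float        # s^-1
    rate_error: float  # s^-1
    amplitude: float
    converged: bool
    experiment: str = ""


@dataclass
class NOERecord:
    """Steady-state heteronuclear NOE ratio with propagated uncertainty."""

    residue_label: str
    I_sat: float
    I_unsat: float
    sigma_sat: float
    sigma_unsat: float
    noe: float
    noe_error: float


def fit_decay(series: RelaxationSeries,
              fit_offset: bool = False) -> RelaxationResult:
    """Least-squares fit of I(t) = A·exp(-R·t) (2 parameters).

    The initial rate guess is ln(I_first/I_last)/(t_last - t_first),
    clipped to [1e-3, 1e3] s^-1.  ``fit_offset=True`` adds a constant
    baseline term — off by default, matching plain exponential fitting of
    peak heights.  The rate error is the asymptotic standard error from
    the fit covariance.
    """
    t, I = series.delays, series.intensities
    if np.sum(I <= 0) > len(I) / 2:
        raise ValueError(
            f"{series.residue_label}: more than half of the intensities are "
            "non-positive; decay not fittable")
    span = t[-1] - t[0]
    ratio = I[0] / I[-1] if I[-1] > 0 and I[0] > 0 else None
    r0 = np.log(ratio) / span if (ratio and ratio > 0 and span > 0) else 1.0
    r0 = float(np.clip(r0, *_RATE_CLIP))
    a0 = float(max(I.max(), 1e-12))

    if fit_offset:
        def model(t, A, R, c):
            return A * np.exp(-R * t) + c
        p0 = (a0, r0, 0.0)
        bounds = ([0.0, 0.0, -np.inf], [np.inf, _RATE_CLIP[1], np.inf])
    else:
        def model(t, A, R):
            return A * np.exp(-R * t)
        p0 = (a0, r0)
        bounds = ([0.0, 0.0], [np.inf, _RATE_CLIP[1]])

    try:
        popt, pcov = curve_fit(model, t, I, p0=p0, bounds=bounds,
                               maxfev=10000, xtol=1e-14, ftol=1e-14,
                               gtol=1e-14)
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        return RelaxationResult(series.residue_label, float("nan"),
                                float("nan"), float("nan"), False,
                                series.experiment)
    perr = np.sqrt(np.diag(pcov))
    rate_error = float(perr[1]) if np.isfinite(perr[1]) else float("inf")
    return RelaxationResult(
        residue_label=series.residue_label,
        rate=float(popt[1]), rate_error=rate_error,
        amplitude=float(popt[0]), converged=converged,
        experiment=series.experiment)


def het_noe(I_sat: float, I_unsat: float, sigma_sat: float = 0.0,
            sigma_unsat: float = 0.0,
            residue_label: str = "") -> NOERecord:
    """NOE = I_sat / I_unsat with first-order error propagation.

    noe_error = |noe| * sqrt((σ_sat/I_sat)^2 + (σ_unsat/I_unsat)^2); the
    spectral noise levels σ are supplied by the user (one per spectrum).
    Negative NOEs are the signature of sub-nanosecond backbone motion in
    disordered chains.
    """
    if sigma_sat < 0 or sigma_unsat < 0:
        raise ValueError("noise estimates must be >= 0")
    if I_unsat == 0:
        raise ValueError("I_unsat must be nonzero")
    noe = I_sat / I_unsat
    if I_sat == 0:
        err = sigma_sat / abs(I_unsat)
    else:
        err = abs(noe) * np.sqrt((sigma_sat / I_sat) ** 2
                                 + (sigma_unsat / I_unsat) ** 2)
    return NOERecord(residue_label=residue_label, I_sat=I_sat,
                     I_unsat=I_unsat, sigma_sat=sigma_sat,
                     sigma_unsat=sigma_unsat, noe=noe,
                     noe_error=float(err))


def delta_r2_profile(free, bound) -> pd.DataFrame:
    """ΔR2 = R2_bound - R2_free per residue, with combined errors.

    ``free`` and ``bound`` are collections of :class:`RelaxationResult`.
    Residues present in only one set are omitted with a warning; the
    error is the quadrature sum of the two fit errors.
    """
    free_by = {r.residue_label: r for r in free}
    bound_by = {r.residue_label: r for r in bound}
    shared = sorted(set(free_by) & set(bound_by),
                    key=lambda lab: parse_residue_label(lab)[1])
    only = sorted((set(free_by) | set(bound_by)) - set(shared))
    if not shared:
        raise ValueError("free and bound rate sets share no residues")
    if only:
        warnings.warn(f"residues only in one set omitted from dR2: {only}",
                      NmrbindWarning)
    rows = []
    for lab in shared:
        f, b = free_by[lab], bound_by[lab]
        rows.append((lab, parse_residue_label(lab)[1],
                     b.rate - f.rate,
                     float(np.hypot(f.rate_error, b.rate_error))))
    return pd.DataFrame(rows, columns=["residue", "position",
                                       "delta_r2", "error"])


def call_dynamic_segments(delta_profile: pd.DataFrame,
                          threshold_rule: str = "mean_plus_sd",
                          min_run: int = 3,
                          absolute: float | None = None,
                          max_exceptions: int = 2) -> list[tuple[int, int]]:
    """Call binding segments from a ΔR2 profile.

    Same contract as the CSP segment caller, but a run tolerates up to
    ``max_exceptions`` interior measured residues below threshold (single
    residues within a binding region can stay fast, e.g. through local
    motion, without splitting the region).
    """
    values = dict(zip(delta_profile["position"].astype(int),
                      delta_profile["delta_r2"].astype(float)))
    threshold = _segments.threshold_value(values.values(),
                                         threshold_rule, absolute)
    return _segments.call_segments(values, threshold, min_run=min_run,
                                   max_gap=1, max_exceptions=max_exceptions)


def rate_summary(results) -> dict[str, float]:
    """Min/max/mean of fitted rates over converged fits only."""
    rates = [r.rate for r in results if r.converged]
    if not rates:
        raise ValueError("no converged fits to summarise")
    return {"n": len(rates), "min": float(np.min(rates)),
            "max": float(np.max(rates)), "mean": float(np.mean(rates))}


def read_relaxation_csv(path, experiment: str) -> list[RelaxationSeries]:
    """Read per-residue decay series from CSV.

    Long format has columns (residue, delay_s, intensity); wide format
    has a ``residue`` column plus one numeric column per delay (header =
    delay in seconds).
    """
    df = pd.read_csv(path)
    if "residue" not in df.columns:
        raise ValueError(f"{path}: missing 'residue' column")
    out = []
    if {"delay_s", "intensity"} <= set(df.columns):
        for label, grp in df.groupby("residue", sort=False):
            out.append(RelaxationSeries(
                residue_label=str(label),
                delays=grp["delay_s"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                experiment=experiment))
    else:
        delay_cols = [c for c in df.columns if c != "residue"]
        try:
            delays = np.array([float(c) for c in delay_cols])
        except ValueError:
            raise ValueError(
                f"{path}: wide-format delay columns must be numeric "
                "(delay in seconds)") from None
        for _, row in df.iterrows():
            out.append(RelaxationSeries(
                residue_label=str(row["residue"]), delays=delays,
                intensities=row[delay_cols].to_numpy(float),
                experiment=experiment))
    if not out:
        raise ValueError(f"{path}: no decay series")
    return out
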