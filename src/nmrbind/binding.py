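"""Two-state ligand-depletion binding model and per-residue K_D fitting.

The titrations analysed here are done with the receptor peptide at
0.8 mM, far above a micromolar K_D, so the free-ligand approximation is
invalid and the full mass-action ("ligand depletion") solution is used.
With F the total ligand (titrant) concentration, P the total receptor
concentration and n binding sites per receptor, the fraction of sites
occupied is the physical root of the binding quadratic:

    f = [ F + nP + K_D - sqrt((F + nP + K_D)^2 - 4·F·nP) ] / (2·nP)

In fast exchange the observed weighted CSP of a residue is
``Δδ_obs = Δδ_max · f``, so per-residue saturation curves are fit
directly in CSP space with parameters (K_D, n, Δδ_max).  Fitting in CSP
space rather than pre-normalised saturation space avoids distorting the
error structure by dividing by a noisy endpoint; the fractional-
saturation view is available via :func:`saturation_from_trajectory`.

A caveat inherited from the experimental design: when K_D << P the curve
approaches the stoichiometric limit and K_D is poorly conditioned — fits
in that regime carry a tight-binding warning (the K_D values are then
order-of-magnitude estimates, as the original measurement itself was).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from ._util import NmrbindWarning
from .csp import ShiftTrajectory

__all__ = [
    "fraction_bound", "BindingFitResult", "fit_binding",
    "GlobalFitResult", "global_fit", "saturation_from_trajectory",
    "KD_MULTISTART", "TIGHT_BINDING_FACTOR",
]

#: K_D multistart grid (molar): 0.1, 1, 10, 100 μM.
KD_MULTISTART = (1e-7, 1e-6, 1e-5, 1e-4)
#: warn when fitted K_D < receptor_total / TIGHT_BINDING_FACTOR
TIGHT_BINDING_FACTOR = 50.0

_KD_BOUNDS = (1e-12, 1.0)      # molar, (0, 1 M]
_N_BOUNDS = (1e-6, 4.0)        # (0, 4]
_DMAX_BOUNDS = (1e-9, 10.0)    # ppm, (0, 10]
_LSQ_TOL = dict(xtol=1e-14, ftol=1e-14, gtol=1e-14)


def fraction_bound(ligand_total, receptor_total, n: float = 1.0,
                   kd: float = 0.0):
    """Fractional saturation under the ligand-depletion binding quadratic.

    Vectorised over ``ligand_total``.  Computed in the numerically stable
    ``2F / (b + sqrt(b^2 - 4·F·nP))`` form (equivalent to the textbook
    root but immune to cancellation when K_D is small); the K_D = 0 limit
    is the exact stoichiometric result ``min(F, nP)/nP``.
    """
    F = np.asarray(ligand_total, dtype=float)
    P = float(receptor_total)
    if P <= 0:
        raise ValueError("receptor_total must be > 0")
    if n <= 0:
        raise ValueError("stoichiometry n must be > 0")
    if kd < 0:
        raise ValueError("K_D must be >= 0")
    if np.any(F < 0):
        raise ValueError("ligand_total must be >= 0")
    nP = n * P
    if kd == 0:
        out = np.minimum(F, nP) / nP
    else:
        b = F + nP + kd
        disc = np.maximum(b * b - 4.0 * F * nP, 0.0)
        out = np.clip(2.0 * F / (b + np.sqrt(disc)), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _stderrs_and_covar(result, n_data: int):
    """Asymptotic parameter errors from the least-squares Jacobian."""
    n_par = len(result.x)
    dof = max(n_data - n_par, 1)
    s_sq = 2.0 * result.cost / dof
    try:
        covar = np.linalg.inv(result.jac.T @ result.jac) * s_sq
        errs = np.sqrt(np.maximum(np.diag(covar), 0.0))
    except np.linalg.LinAlgError:
        covar = None
        errs = np.full(n_par, np.nan)
    return errs, covar


@dataclass
class BindingFitResult:
    """Per-residue fit of the depletion isotherm to a CSP trajectory."""

    residue_label: str
    kd: float                 # molar
    n: float                  # sites per receptor
    delta_max: float          # ppm, CSP amplitude at full saturation
    kd_err: float
    n_err: float
    delta_max_err: float
    covar: np.ndarray | None
    converged: bool
    residuals: np.ndarray     # ppm, one per non-apo point
    n_fixed: bool
    chisqr: float

    @property
    def kd_uM(self) -> float:
        """Dissociation constant in μM (reporting unit)."""
        return self.kd * 1e6


def _check_trajectory(traj: ShiftTrajectory, min_points: int) -> None:
    n_data = len(traj) - 1  # non-apo points
    if n_data < min_points:
        raise ValueError(
            f"insufficient titration points for {traj.residue_label}: "
            f"{n_data} non-apo points, need >= {min_points}")
    if np.max(traj.csp) <= 0:
        raise ValueError(
            f"residue {traj.residue_label} shows no perturbation "
            "(flat trajectory)")


def fit_binding(traj: ShiftTrajectory, receptor_total: float,
                fix_n: float | None = None,
                kd_starts=KD_MULTISTART) -> BindingFitResult:
    """Nonlinear least-squares fit of ``csp = Δδ_max · f(F; n, K_D)``.

    Needs at least 4 non-apo points with n free, 3 with n fixed.  The fit
    is restarted from each K_D in ``kd_starts`` (0.1–100 μM by default)
    and the lowest-cost solution kept, because the depletion isotherm has
    shallow, flat-bottomed cost surfaces in the tight-binding regime.
    Parameters are bounded (K_D ≤ 1 M, n ≤ 4, Δδ_max ≤ 10 ppm); standard
    errors are the asymptotic ones from the converged fit's covariance.
    """
    _check_trajectory(traj, 3 if fix_n is not None else 4)
    F = traj.ligand_total[1:]
    y = traj.csp[1:]
    P = float(receptor_total)
    dmax0 = max(float(np.max(y)), 1e-3)
    free_n = fix_n is None

    if free_n:
        def residual(x):
            return x[2] * fraction_bound(F, P, n=x[1], kd=x[0]) - y
        lo = (_KD_BOUNDS[0], _N_BOUNDS[0], _DMAX_BOUNDS[0])
        hi = (_KD_BOUNDS[1], _N_BOUNDS[1], _DMAX_BOUNDS[1])

        def start(kd0):
            return (kd0, 1.0, dmax0)
    else:
        def residual(x):
            return x[1] * fraction_bound(F, P, n=fix_n, kd=x[0]) - y
        lo = (_KD_BOUNDS[0], _DMAX_BOUNDS[0])
        hi = (_KD_BOUNDS[1], _DMAX_BOUNDS[1])

        def start(kd0):
            return (kd0, dmax0)

    best = None
    for kd0 in kd_starts:
        result = least_squares(residual, start(kd0), bounds=(lo, hi),
                               **_LSQ_TOL)
        if best is None or result.cost < best.cost:
            best = result

    errs, covar = _stderrs_and_covar(best, len(y))
    if free_n:
        kd, n, dmax = best.x
        kd_err, n_err, dmax_err = errs
    else:
        kd, dmax = best.x
        n = float(fix_n)
        kd_err, dmax_err = errs
        n_err = 0.0

    if kd < P / TIGHT_BINDING_FACTOR:
        warnings.warn(
            f"{traj.residue_label}: fitted K_D ({kd * 1e6:.2g} uM) is far "
            f"below the receptor concentration ({P * 1e3:.2g} mM); the fit "
            "is in the tight-binding regime and K_D is an estimate only",
            NmrbindWarning)
    return BindingFitResult(
        residue_label=traj.residue_label,
        kd=float(kd), n=float(n), delta_max=float(dmax),
        kd_err=float(kd_err), n_err=float(n_err),
        delta_max_err=float(dmax_err),
        covar=covar, converged=bool(best.success),
        residuals=np.asarray(best.fun, dtype=float),
        n_fixed=not free_n,
        chisqr=float(2.0 * best.cost),
    )


@dataclass
class GlobalFitResult:
    """Shared-(K_D, n) fit across residues with per-residue amplitudes."""

    kd: float
    n: float
    kd_err: float
    n_err: float
    delta_max: dict[str, float]
    converged: bool
    chisqr: float
    redchi: float
    n_fixed: bool


def global_fit(trajectories, receptor_total: float,
               fix_n: float | None = None,
               kd_starts=KD_MULTISTART) -> GlobalFitResult:
    """Fit one K_D and one n across residues, amplitudes free per residue.

    With a single trajectory this reduces to :func:`fit_binding` (same
    residuals, same multistart).  Residual diagnostics (``redchi``)
    exceed the noise floor when residues genuinely carry different
    affinities — a check worth making before trusting a shared K_D.
    """
    trajs = list(trajectories.values()) \
        if isinstance(trajectories, dict) else list(trajectories)
    if not trajs:
        raise ValueError("no trajectories to fit")
    for traj in trajs:
        _check_trajectory(traj, 3 if fix_n is not None else 4)
    P = float(receptor_total)
    free_n = fix_n is None
    n_shared = 2 if free_n else 1  # kd (+ n)
    Fs = [t.ligand_total[1:] for t in trajs]
    ys = [t.csp[1:] for t in trajs]
    n_data = sum(len(y) for y in ys)

    def residual(x):
        kd = x[0]
        n = x[1] if free_n else fix_n
        amps = x[n_shared:]
        return np.concatenate([
            amps[i] * fraction_bound(Fs[i], P, n=n, kd=kd) - ys[i]
            for i in range(len(trajs))])

    lo = [_KD_BOUNDS[0]] + ([_N_BOUNDS[0]] if free_n else []) \
        + [_DMAX_BOUNDS[0]] * len(trajs)
    hi = [_KD_BOUNDS[1]] + ([_N_BOUNDS[1]] if free_n else []) \
        + [_DMAX_BOUNDS[1]] * len(trajs)
    amps0 = [max(float(np.max(y)), 1e-3) for y in ys]

    best = None
    for kd0 in kd_starts:
        x0 = [kd0] + ([1.0] if free_n else []) + amps0
        result = least_squares(residual, x0, bounds=(lo, hi), **_LSQ_TOL)
        if best is None or result.cost < best.cost:
            best = result

    errs, _ = _stderrs_and_covar(best, n_data)
    dof = max(n_data - len(best.x), 1)
    return GlobalFitResult(
        kd=float(best.x[0]),
        n=float(best.x[1]) if free_n else float(fix_n),
        kd_err=float(errs[0]),
        n_err=float(errs[1]) if free_n else 0.0,
        delta_max={t.residue_label: float(a)
                   for t, a in zip(trajs, best.x[n_shared:])},
        converged=bool(best.success),
        chisqr=float(2.0 * best.cost),
        redchi=float(2.0 * best.cost / dof),
        n_fixed=not free_n,
    )


def saturation_from_trajectory(traj: ShiftTrajectory,
                               normalization: str = "fitted_amplitude",
                               receptor_total: float | None = None,
                               fit: BindingFitResult | None = None):
    """Convert a CSP trajectory to a fractional-saturation series.

    ``final_point`` divides by the endpoint CSP (the last point is then
    exactly 1); ``fitted_amplitude`` (default) divides by the fitted
    Δδ_max, in which case the endpoint saturation stays below 1 by
    exactly the unbound fraction at the final ligand concentration.
    Returns ``(ligand_total, saturation)`` arrays including the apo point.
    """
    if len(traj) - 1 < 3:
        raise ValueError("need at least 3 non-apo points")
    if traj.csp[-1] <= 0:
        raise ValueError(
            f"residue {traj.residue_label} shows no perturbation")
    if normalization == "final_point":
        scale = traj.csp[-1]
    elif normalization == "fitted_amplitude":
        if fit is None:
            if receptor_total is None:
                raise ValueError("fitted_amplitude normalization needs a fit "
                                 "or receptor_total")
            fit = fit_binding(traj, receptor_total)
        scale = fit.delta_max
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return traj.ligand_total.copy(), traj.csp / scale
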