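"""Levenberg-Marquardt estimation of SSIS parameters from injection heats.

The observable is the vector of per-injection heats (J, dilution-corrected);
the model is the displaced-volume-corrected SSIS forward prediction.  The
sum of squared residuals is minimized over (N, ln Kb, dH) — the logarithm
enforces Kb > 0 and conditions the problem.  Standard errors come from the
residual-variance-scaled inverse Gauss-Newton Hessian, i.e. the usual
asymptotic (linearized) covariance.

A low Wiseman c-value (c = Kb * N * [M]0 below ~1) produces a shallow
isotherm with no inflection in the measured range; the fit then becomes
ill-conditioned and the binding parameters are only weakly identified.  The
fitter warns (it never silently fails) when it detects this regime, the
failure mode seen experimentally when increasing ionic strength suppresses
the measured enthalpy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .binding import BindingParameters, ThermoSummary, thermo_summary
from .preprocessing import InjectionHeats
from .titration import InjectionSchedule, cell_trajectory, normalize_heats, predicted_heats

__all__ = ["FitResult", "FitDiagnosticWarning", "initial_guess", "fit_ssis", "fit_report"]


class FitDiagnosticWarning(UserWarning):
    """An identifiability or convergence concern that does not abort the fit."""


@dataclass
class FitResult:
    """Outcome of an SSIS fit.

    ``standard_errors`` and ``covariance`` are on the natural scale
    (N, Kb, dH); ``c_value`` is the Wiseman parameter Kb*N*[M]0 at the
    fitted optimum; ``derived`` holds the dG/dH/-TdS decomposition.
    """

    params: BindingParameters
    standard_errors: dict[str, float]
    covariance: np.ndarray | None
    ssr: float
    n_points_used: int
    converged: bool
    n_iterations: int
    c_value: float
    derived: ThermoSummary
    warnings: list[str] = field(default_factory=list)
    low_confidence: bool = False


def initial_guess(
    heats: InjectionHeats,
    schedule: InjectionSchedule,
    macroion_conc: float | None = None,
) -> BindingParameters:
    """Heuristic starting point for the SSIS fit.

    dH0 is the mean of the first three normalized heats divided by an
    assumed initial bound fraction of 0.8 (early injections bind most of the
    delivered titrant); N0 is the molar ratio at which the normalized heat
    first falls to half its initial value (linear interpolation, floor 1.0;
    if the isotherm never crosses half-height, the largest measured molar
    ratio is used); Kb0 = 1e3 M^-1.
    """
    if len(heats) < 5:
        raise ValueError(f"need at least 5 injections for an initial guess, got {len(heats)}")
    x0 = macroion_conc if macroion_conc is not None else schedule.cell_macroion_conc
    norm = normalize_heats(heats.heat, schedule)  # kJ/mol
    traj = cell_trajectory(
        schedule if macroion_conc is None else _with_macroion(schedule, macroion_conc)
    )
    ratio = traj["molar_ratio"].to_numpy()

    h0 = float(np.mean(norm[:3]))
    if h0 == 0.0 or not np.isfinite(h0):
        raise ValueError("initial heats are zero; cannot form an enthalpy guess")
    dh0 = h0 / 0.8

    half = 0.5 * h0
    n0 = None
    # first crossing of half the initial amplitude, in the direction of decay
    sign = 1.0 if h0 > 0 else -1.0
    below = sign * norm < sign * half
    idx = np.flatnonzero(below)
    if idx.size:
        j = idx[0]
        if j == 0:
            n0 = ratio[0]
        else:
            f = (half - norm[j - 1]) / (norm[j] - norm[j - 1])
            n0 = ratio[j - 1] + f * (ratio[j] - ratio[j - 1])
    if n0 is None:  # never reaches half-height: far from saturation
        warnings.warn(
            "isotherm does not decay to half its initial amplitude; "
            "using the final molar ratio as the site-count guess",
            FitDiagnosticWarning,
            stacklevel=2,
        )
        n0 = ratio[-1]
    return BindingParameters(n_sites=max(float(n0), 1.0), binding_constant=1e3, enthalpy=dh0)


def _with_macroion(schedule: InjectionSchedule, conc: float) -> InjectionSchedule:
    return InjectionSchedule(
        cell_volume=schedule.cell_volume,
        syringe_conc=schedule.syringe_conc,
        cell_macroion_conc=conc,
        injection_volumes=schedule.injection_volumes,
        spacing=schedule.spacing,
        temperature=schedule.temperature,
        cell_titrant_conc=schedule.cell_titrant_conc,
        initial_delay=schedule.initial_delay,
    )


def _residuals(p: lmfit.Parameters, schedule: InjectionSchedule,
               measured: np.ndarray, weights: np.ndarray | None) -> np.ndarray:
    bp = BindingParameters(
        n_sites=p["n_sites"].value,
        binding_constant=np.exp(p["log_kb"].value),
        enthalpy=p["enthalpy"].value,
    )
    resid = measured - predicted_heats(bp, schedule)
    return resid if weights is None else resid * weights


def fit_ssis(
    heats: InjectionHeats,
    schedule: InjectionSchedule,
    macroion_conc: float | None = None,
    init: BindingParameters | None = None,
    discard_first: bool = False,
    weight_by_sigma: bool = False,
) -> FitResult:
    """Fit the SSIS model to measured injection heats.

    Minimizes sum_i (q_i - dQ'_i(N, Kb, dH))^2 by Levenberg-Marquardt over
    (N, ln Kb, dH).  ``discard_first`` drops the first injection (backlash
    convention); ``weight_by_sigma`` uses 1/sigma_i weights when sigmas are
    present.  Non-convergence is reported on the result, never raised; if
    the initial start stalls, three log-spaced Kb restarts are tried and the
    best accepted.
    """
    if macroion_conc is not None:
        schedule = _with_macroion(schedule, macroion_conc)
    x0 = schedule.cell_macroion_conc

    # the full trajectory is always propagated; discarding the first
    # injection only masks its residual, it does not rewrite the history
    measured = heats.heat.copy()
    n_used = measured.size - (1 if discard_first else 0)
    if n_used < 4:
        raise ValueError(f"need at least 4 usable points, got {n_used}")

    weights = None
    if weight_by_sigma and heats.sigma is not None and np.all(heats.sigma > 0):
        weights = 1.0 / heats.sigma
    mask = np.ones(measured.size, dtype=bool)
    if discard_first:
        mask[0] = False

    if init is None:
        try:
            init = initial_guess(heats, schedule)
        except ValueError:
            init = BindingParameters(n_sites=5.0, binding_constant=1e3, enthalpy=1.0)

    diag_warnings: list[str] = []

    def run(kb0: float) -> lmfit.minimizer.MinimizerResult:
        p = lmfit.Parameters()
        p.add("n_sites", value=init.n_sites, min=1e-6)
        p.add("log_kb", value=np.log(kb0), min=np.log(1e-3), max=np.log(1e12))
        p.add("enthalpy", value=init.enthalpy)

        def fn(pars):
            r = _residuals(pars, schedule, measured, weights)
            return r[mask]

        return lmfit.minimize(fn, p, method="leastsq", xtol=1e-12, ftol=1e-12,
                              max_nfev=500 * 4)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lmfit chatter on flat directions
        result = run(init.binding_constant)
        if not result.success:
            candidates = [result]
            for kb0 in (1e2, 1e4, 1e6):
                try:
                    candidates.append(run(kb0))
                except Exception:
                    continue
            ok = [r for r in candidates if r.success]
            pool = ok if ok else candidates
            result = min(pool, key=lambda r: float(np.sum(np.asarray(r.residual) ** 2)))

    pvals = result.params
    n_fit = float(pvals["n_sites"].value)
    kb_fit = float(np.exp(pvals["log_kb"].value))
    dh_fit = float(pvals["enthalpy"].value)
    bp = BindingParameters(n_sites=n_fit, binding_constant=kb_fit, enthalpy=dh_fit)
    ssr = float(np.sum(np.asarray(result.residual) ** 2))

    # covariance on (N, ln Kb, dH) -> (N, Kb, dH) via jacobian diag(1, Kb, 1)
    cov = None
    stderr = {"n_sites": np.nan, "binding_constant": np.nan, "enthalpy": np.nan}
    if getattr(result, "covar", None) is not None:
        jac = np.diag([1.0, kb_fit, 1.0])
        cov = jac @ result.covar @ jac.T
        d = np.diag(cov)
        if np.all(d >= 0):
            se = np.sqrt(d)
            stderr = {
                "n_sites": float(se[0]),
                "binding_constant": float(se[1]),
                "enthalpy": float(se[2]),
            }
    else:
        diag_warnings.append(
            "singular Gauss-Newton Hessian: standard errors unavailable"
        )

    c_value = kb_fit * n_fit * x0
    if c_value < 0.5:
        diag_warnings.append(
            f"Wiseman c-value {c_value:.3g} < 0.5: shallow isotherm, "
            "binding parameters weakly identified"
        )
    if not _has_inflection(bp, schedule):
        diag_warnings.append(
            "model isotherm has no inflection within the measured molar-ratio "
            "range; site count and binding constant may be degenerate"
        )
    rel_err = [
        stderr["n_sites"] / n_fit if np.isfinite(stderr["n_sites"]) else np.inf,
        stderr["binding_constant"] / kb_fit
        if np.isfinite(stderr["binding_constant"])
        else np.inf,
        stderr["enthalpy"] / abs(dh_fit) if dh_fit and np.isfinite(stderr["enthalpy"]) else np.inf,
    ]
    low_confidence = bool(max(rel_err) > 0.5 or c_value < 0.5)
    if low_confidence:
        diag_warnings.append(
            "low-confidence fit: relative standard errors exceed 50% or c < 0.5"
        )
    if not result.success:
        diag_warnings.append(f"optimizer did not converge: {result.message}")

    for msg in diag_warnings:
        warnings.warn(msg, FitDiagnosticWarning, stacklevel=2)

    return FitResult(
        params=bp,
        standard_errors=stderr,
        covariance=cov,
        ssr=ssr,
        n_points_used=n_used,
        converged=bool(result.success),
        n_iterations=int(result.nfev),
        c_value=float(c_value),
        derived=thermo_summary(bp, schedule.temperature),
        warnings=diag_warnings,
        low_confidence=low_confidence,
    )


def _has_inflection(params: BindingParameters, schedule: InjectionSchedule) -> bool:
    """Does the normalized model isotherm change curvature within range?"""
    norm = normalize_heats(predicted_heats(params, schedule), schedule)
    d2 = np.diff(norm, n=2)
    signs = np.sign(d2[np.abs(d2) > 1e-12 * max(np.max(np.abs(norm)), 1e-300)])
    return bool(signs.size >= 2 and np.any(np.diff(signs) != 0))


def fit_report(result: FitResult, temperature: float = 303.15) -> dict[str, float]:
    """Summarize a converged fit in the conventional reporting units.

    Returns N (sites, = bound ions per macroion at saturation), dH (kJ/mol),
    Kb in units of 1e3 M^-1, and dG = -RT ln Kb (kJ/mol) with its
    uncertainty propagated as R*T*sigma_Kb/Kb; each parameter is paired with
    its standard error.  Refuses an unconverged result.
    """
    if not result.converged:
        raise ValueError("fit did not converge; no report (inspect FitResult.warnings)")
    from .binding import GAS_CONSTANT, gibbs_free_energy

    p = result.params
    dg = gibbs_free_energy(p.binding_constant, temperature)
    se_kb = result.standard_errors["binding_constant"]
    dg_err = (
        GAS_CONSTANT * temperature * se_kb / p.binding_constant / 1e3
        if np.isfinite(se_kb)
        else np.nan
    )
    return {
        "N_b": p.n_sites,
        "N_b_err": result.standard_errors["n_sites"],
        "dH_kJ_mol": p.enthalpy,
        "dH_err_kJ_mol": result.standard_errors["enthalpy"],
        "Kb_1e3_M": p.binding_constant / 1e3,
        "Kb_err_1e3_M": se_kb / 1e3 if np.isfinite(se_kb) else np.nan,
        "dG_kJ_mol": dg,
        "dG_err_kJ_mol": dg_err,
        "c_value": result.c_value,
        "ssr": result.ssr,
    }
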