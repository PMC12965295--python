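"""Global analysis of femtosecond transient-absorption surfaces.

Fits the parallel model — a sum of independent exponential decays convolved
with a Gaussian instrument response function (IRF) — to a ΔA(delay,
wavelength) surface and returns the decay-associated difference spectra
(DADS): the wavelength-dependent amplitude of each kinetic component.

The fit uses variable projection: the nonlinear parameters (lifetimes τ_i,
time zero t0, IRF width σ) are optimized by trust-region least squares while
the DADS, which enter linearly, are solved exactly by per-wavelength
ordinary least squares at every iterate.  Lifetimes are optimized in
log-space (they span four decades, sub-picosecond relaxation to
nanosecond-lived uncoupled antenna) with bounds [1e-3, 1e5] ps.

The IRF-convolved exponential has the closed form

    f(t) = 1/2 · exp(σ²/(2τ²) − (t−t0)/τ) · erfc(σ/(√2 τ) − (t−t0)/(√2 σ))

which is evaluated through scaled erfcx to avoid overflow at early delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erfc, erfcx

from .errors import ConditioningError, ParameterError

LOG_TAU_BOUNDS = (np.log(1e-3), np.log(1e5))  # ps


@dataclass
class TASurface:
    """ΔA(delay, wavelength) matrix with axes and IRF metadata.

    delays in ps (strictly increasing), wavelengths in nm, dA in ΔOD with
    shape (n_delays, n_wavelengths).
    """

    delays: np.ndarray
    wavelengths: np.ndarray
    dA: np.ndarray
    irf_sigma: float = 0.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.dA = np.asarray(self.dA, dtype=float)
        if self.dA.shape != (self.delays.size, self.wavelengths.size):
            raise ValueError("dA shape inconsistent with axes")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")

    @classmethod
    def from_text(cls, path: str | Path, **meta) -> "TASurface":
        """Read a delimited matrix: first row wavelengths (nm), first column delays (ps)."""
        raw = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls(delays=raw.index.to_numpy(float),
                   wavelengths=raw.columns.to_numpy(float),
                   dA=raw.to_numpy(float), **meta)

    def to_text(self, path: str | Path, sep: str = "\t") -> None:
        df = pd.DataFrame(self.dA, index=self.delays, columns=self.wavelengths)
        df.index.name = "delay_ps"
        df.to_csv(path, sep=sep)


@dataclass
class DADSResult:
    """Parallel-model fit: ascending lifetimes and their associated spectra."""

    lifetimes: np.ndarray           # ps, ascending
    dads: np.ndarray                # (n_components, n_wavelengths), ΔOD
    fit_rss: float
    n_components: int
    wavelengths: np.ndarray = field(default_factory=lambda: np.array([]))
    t0: float = 0.0
    irf_sigma: float = 0.0
    success: bool = True
    flags: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"tau_{t:.6g}_ps": self.dads[i]
                for i, t in enumerate(self.lifetimes)}
        return pd.DataFrame({"wavelength_nm": self.wavelengths, **cols})


def irf_decay(t: np.ndarray | float, tau: float, t0: float = 0.0,
              sigma: float = 0.0) -> np.ndarray | float:
    """Exponential decay convolved with a Gaussian IRF (unit amplitude).

    For σ = 0 the step-gated exponential exp(−(t−t0)/τ)·1[t ≥ t0].
    """
    if tau <= 0:
        raise ParameterError("tau must be positive")
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    t = np.asarray(t, dtype=float)
    u = t - t0
    if sigma == 0.0:
        out = np.where(u >= 0, np.exp(-np.clip(u, 0, None) / tau), 0.0)
        return out if out.shape else float(out)
    b = sigma / (np.sqrt(2.0) * tau) - u / (np.sqrt(2.0) * sigma)
    # For b > 0 use erfcx: 1/2 erfc(b) e^a = 1/2 erfcx(b) e^(a-b²),
    # and a − b² = −u²/(2σ²) exactly, which never overflows.
    a = sigma**2 / (2.0 * tau**2) - u / tau
    with np.errstate(over="ignore"):
        direct = 0.5 * np.exp(a) * erfc(b)
    stable = 0.5 * erfcx(np.maximum(b, 0.0)) * np.exp(-(u**2) / (2.0 * sigma**2))
    out = np.where(b > 0, stable, direct)
    return out if out.shape else float(out)


def _component_basis(delays: np.ndarray, lifetimes: np.ndarray, t0: float,
                     sigma: float) -> np.ndarray:
    """(n_delays, n_components) matrix of IRF-convolved decays."""
    return np.column_stack(
        [irf_decay(delays, float(tau), t0, sigma) for tau in lifetimes])


def dads_linear_solve(surface: TASurface, lifetimes: np.ndarray | list[float],
                      t0: float | None = None, sigma: float | None = None
                      ) -> tuple[np.ndarray, float]:
    """Exact DADS given lifetimes: per-wavelength OLS against the decay basis.

    Returns (dads of shape (n_components, n_wavelengths), residual sum of
    squares).  Duplicate lifetimes make the basis rank-deficient and raise.
    """
    lifetimes = np.asarray(lifetimes, dtype=float)
    if lifetimes.size >= surface.delays.size:
        raise ValueError("need fewer components than delay points")
    t0 = surface.t0 if t0 is None else t0
    sigma = surface.irf_sigma if sigma is None else sigma
    B = _component_basis(surface.delays, lifetimes, t0, sigma)
    # rank check: duplicate (or numerically indistinct) lifetimes
    s = np.linalg.svd(B, compute_uv=False)
    if s[0] <= 0 or s[-1] / s[0] < 1e-12:
        raise ConditioningError(
            f"decay basis is rank-deficient for lifetimes {lifetimes}")
    amps, _, _, _ = np.linalg.lstsq(B, surface.dA, rcond=None)
    rss = float(np.sum((surface.dA - B @ amps) ** 2))
    return amps, rss


def fit_parallel_model(surface: TASurface, n_components: int,
                       tau_init: np.ndarray | list[float],
                       fit_t0: bool = True, fit_sigma: bool = True,
                       log_tau_bounds: tuple[float, float] = LOG_TAU_BOUNDS,
                       max_nfev: int = 2000) -> DADSResult:
    """Variable-projection fit of the parallel (sum-of-exponential) model.

    Outer nonlinear least squares over {log τ_i, t0, σ}; inner exact linear
    solve for the DADS.  Deterministic given the surface and the starting
    values.  Lifetimes are returned sorted ascending with their spectra
    reordered to match; components pushed to a bound or carrying a
    near-zero spectrum are flagged as redundant.
    """
    tau_init = np.asarray(tau_init, dtype=float)
    if tau_init.size != n_components:
        raise ParameterError("tau_init length must equal n_components")
    if np.any(tau_init <= 0):
        raise ParameterError("initial lifetimes must be positive")

    sigma0 = max(surface.irf_sigma, 1e-4)
    theta0 = list(np.log(tau_init))
    lo = [log_tau_bounds[0]] * n_components
    hi = [log_tau_bounds[1]] * n_components
    if fit_t0:
        theta0.append(surface.t0)
        span = surface.delays[-1] - surface.delays[0]
        lo.append(surface.t0 - 0.1 * span)
        hi.append(surface.t0 + 0.1 * span)
    if fit_sigma:
        theta0.append(np.log(sigma0))
        lo.append(np.log(1e-5))
        hi.append(np.log(1e3))

    def unpack(theta):
        taus = np.exp(theta[:n_components])
        k = n_components
        t0 = theta[k] if fit_t0 else surface.t0
        if fit_t0:
            k += 1
        sigma = np.exp(theta[k]) if fit_sigma else surface.irf_sigma
        return taus, t0, sigma

    def residuals(theta):
        taus, t0, sigma = unpack(theta)
        B = _component_basis(surface.delays, taus, t0, sigma)
        amps, _, _, _ = np.linalg.lstsq(B, surface.dA, rcond=None)
        return (surface.dA - B @ amps).ravel()

    sol = least_squares(residuals, theta0, bounds=(lo, hi),
                        method="trf", max_nfev=max_nfev)
    taus, t0, sigma = unpack(sol.x)
    order = np.argsort(taus)
    taus = taus[order]
    fitted = TASurface(delays=surface.delays, wavelengths=surface.wavelengths,
                       dA=surface.dA, irf_sigma=sigma, t0=t0)
    dads, rss = dads_linear_solve(fitted, taus, t0, sigma)

    flags: list[str] = []
    norms = np.linalg.norm(dads, axis=1)
    scale = norms.max() if norms.size else 0.0
    for i, tau in enumerate(taus):
        at_bound = (abs(np.log(tau) - log_tau_bounds[0]) < 1e-6
                    or abs(np.log(tau) - log_tau_bounds[1]) < 1e-6)
        if at_bound:
            flags.append(f"component {i}: tau at bound ({tau:.4g} ps)")
        if scale > 0 and norms[i] < 1e-6 * scale:
            flags.append(f"component {i}: near-zero DADS norm (redundant)")
    if not sol.success:
        flags.append(f"optimizer: {sol.message}")

    return DADSResult(lifetimes=taus, dads=dads, fit_rss=rss,
                      n_components=n_components,
                      wavelengths=surface.wavelengths, t0=t0, irf_sigma=sigma,
                      success=sol.success, flags=flags)


def trapping_efficiency(tau_trap: float, tau_intrinsic: float) -> float:
    """Photochemical trapping yield 1 − τ_trap/τ_intrinsic.

    τ_trap is the dominant antenna→trap transfer component; τ_intrinsic the
    excited-state lifetime in the absence of trapping (user-supplied).
    """
    if not 0 < tau_trap < tau_intrinsic:
        raise ParameterError("need 0 < tau_trap < tau_intrinsic")
    return 1.0 - tau_trap / tau_intrinsic


def dispersion_correct(surface: TASurface, coefficients: list[float]
                       ) -> TASurface:
    """Chirp correction: shift each wavelength's time axis by polynomial t0(λ).

    ``coefficients`` are ascending-power polynomial coefficients in λ (nm)
    giving the per-wavelength group delay (ps).  The corrected column is
    re-interpolated onto the common delay grid (linear, edges held).  Orders
    above 5 are rejected as an overfitting guard.
    """
    coeffs = np.asarray(coefficients, dtype=float)
    if coeffs.size > 6:
        raise ParameterError("chirp polynomial order > 5 rejected")
    shifts = np.polyval(coeffs[::-1], surface.wavelengths)
    dA = np.empty_like(surface.dA)
    for j, s in enumerate(shifts):
        dA[:, j] = np.interp(surface.delays, surface.delays - s,
                             surface.dA[:, j])
    return TASurface(delays=surface.delays.copy(),
                     wavelengths=surface.wavelengths.copy(), dA=dA,
                     irf_sigma=surface.irf_sigma, t0=surface.t0)


def fit_report(result: DADSResult) -> str:
    """Plain-text fit summary block."""
    lines = ["# parallel-model global fit",
             f"n_components\t{result.n_components}",
             f"rss\t{result.fit_rss:.6e}",
             f"t0_ps\t{result.t0:.6g}",
             f"irf_sigma_ps\t{result.irf_sigma:.6g}",
             "lifetimes_ps\t" + "\t".join(f"{t:.6g}" for t in result.lifetimes)]
    for flag in result.flags:
        lines.append(f"flag\t{flag}")
    return "\n".join(lines)
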