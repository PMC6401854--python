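"""Circular-dichroism analysis of pH-dependent polymer structuring.

The chiroptical signature of PAAC self-structuring is followed by
normalizing raw ellipticity (mdeg) to the molar concentration of repeat
units, differencing each spectrum against a pH-3 reference at a fixed
wavelength, and fitting the resulting differential-molar-ellipticity
versus pH series with a four-parameter logistic whose inflection marks
the structuring transition.  Because the band amplitude tracks amine
deprotonation, that inflection coincides with the amine
half-ionization point, pH = pKa2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import (
    AnalysisError,
    ConfigurationError,
    DomainError,
    FitError,
    InsufficientDataError,
)

__all__ = [
    "CDSpectrum",
    "PeakSummary",
    "repeat_unit_concentration",
    "to_molar_ellipticity",
    "differential_series",
    "find_peaks",
    "SigmoidTransitionModel",
    "SigmoidFitResults",
    "fit_sigmoid",
]


@dataclass
class CDSpectrum:
    """One CD scan at a given pH.

    ``ellipticity`` is in mdeg when ``normalized`` is False and in
    mdeg M^-1 cm^-1 (molar ellipticity per repeat unit) when True.
    ``path_length`` is in cm, ``mass_conc`` in mg/mL,
    ``repeat_unit_conc`` in mol/L.
    """

    wavelengths: np.ndarray
    ellipticity: np.ndarray
    ph: float
    path_length: float = 1.0
    mass_conc: float | None = None
    repeat_unit_conc: float | None = None
    temperature: float | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.wavelengths.shape != self.ellipticity.shape:
            raise DomainError("wavelengths and ellipticity must match in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise DomainError("wavelengths must be sorted strictly ascending")
        if np.any(self.wavelengths <= 0):
            raise DomainError("wavelengths must be positive")
        if not self.path_length > 0:
            raise DomainError("path_length must be positive")

    def theta_at(self, wavelength: float) -> float:
        """Ellipticity interpolated at one wavelength (linear)."""
        lam = self.wavelengths
        if not lam[0] <= wavelength <= lam[-1]:
            raise DomainError(
                f"wavelength {wavelength} nm outside data range "
                f"[{lam[0]}, {lam[-1]}]"
            )
        return float(np.interp(wavelength, lam, self.ellipticity))


def repeat_unit_concentration(mass_conc: float, repeat_unit_mass: float) -> float:
    """Molar concentration of repeat units, mol/L.

    ``mass_conc`` in mg/mL (numerically equal to g/L) divided by the
    repeat-unit molar mass in g/mol.
    """
    if mass_conc <= 0 or repeat_unit_mass <= 0:
        raise DomainError("mass concentration and repeat-unit mass must be positive")
    return mass_conc / repeat_unit_mass


def to_molar_ellipticity(spec: CDSpectrum) -> CDSpectrum:
    """Normalize a raw spectrum to molar ellipticity per repeat unit.

    theta(lambda) = raw_mdeg(lambda) / (repeat_unit_conc * path_length),
    in mdeg M^-1 cm^-1.  The input spectrum is left untouched.
    """
    if spec.normalized:
        return spec
    if spec.repeat_unit_conc is None or spec.repeat_unit_conc <= 0:
        raise ConfigurationError(
            "repeat_unit_conc must be set (mol/L) before normalization"
        )
    theta = spec.ellipticity / (spec.repeat_unit_conc * spec.path_length)
    return replace(spec, ellipticity=theta, normalized=True)


def differential_series(
    spectra: Iterable[CDSpectrum],
    ref_ph: float = 3.0,
    wavelength: float | str = "peak",
    ref_tol: float = 0.2,
    window: tuple[float, float] = (200.0, 280.0),
) -> pd.DataFrame:
    """Differential molar ellipticity versus pH against a low-pH reference.

    For every normalized spectrum, Delta-theta(pH) = theta_pH(lambda*) -
    theta_ref(lambda*).  ``wavelength`` fixes lambda* explicitly (e.g. the
    printed band maximum of the polymer) or, with ``"peak"``, uses each
    spectrum's own positive-band maximum within ``window`` and evaluates
    the reference at that same wavelength.

    Returns a DataFrame with columns ``ph``, ``delta_theta`` and
    ``wavelength_nm``, sorted by pH, the reference row included (zero by
    construction).

    Raises
    ------
    AnalysisError
        If no spectrum lies within ``ref_tol`` of ``ref_ph``.
    ConfigurationError
        If any spectrum has not been normalized.
    """
    specs = sorted(spectra, key=lambda s: s.ph)
    if not specs:
        raise InsufficientDataError("no spectra supplied")
    for s in specs:
        if not s.normalized:
            raise ConfigurationError(
                f"spectrum at pH {s.ph} is not normalized; call "
                "to_molar_ellipticity first"
            )
    dist = [abs(s.ph - ref_ph) for s in specs]
    i_ref = int(np.argmin(dist))
    if dist[i_ref] > ref_tol:
        raise AnalysisError(
            f"no reference spectrum within {ref_tol} pH of pH {ref_ph}"
        )
    ref = specs[i_ref]
    rows = []
    for s in specs:
        if isinstance(wavelength, str):
            if wavelength != "peak":
                raise DomainError(f"unknown wavelength mode {wavelength!r}")
            pk = find_peaks(s, window=window)
            lam = pk.lambda_max
        else:
            lam = float(wavelength)
        rows.append(
            {
                "ph": s.ph,
                "delta_theta": s.theta_at(lam) - ref.theta_at(lam),
                "wavelength_nm": lam,
            }
        )
    return pd.DataFrame(rows)


class PeakSummary(NamedTuple):
    """Positive/negative band extremes of one spectrum within a window."""

    lambda_max: float
    theta_max: float
    lambda_min: float
    theta_min: float
    min_below_max: bool
    degenerate: bool


def find_peaks(
    spec: CDSpectrum, window: tuple[float, float] = (200.0, 280.0)
) -> PeakSummary:
    """Global ellipticity maximum and minimum within a wavelength window.

    Also reports whether the negative extreme sits at lower wavelength
    than the positive one (the arrangement characteristic of the PAAC
    couplet) and flags spectra that are flat within the window.
    """
    lo, hi = window
    lam = spec.wavelengths
    if lo < lam[0] or hi > lam[-1]:
        raise DomainError(
            f"window [{lo}, {hi}] nm outside data range [{lam[0]}, {lam[-1]}]"
        )
    mask = (lam >= lo) & (lam <= hi)
    lam_w = lam[mask]
    th_w = spec.ellipticity[mask]
    i_max = int(np.argmax(th_w))
    i_min = int(np.argmin(th_w))
    degenerate = bool(np.ptp(th_w) < 1e-12 * max(1.0, np.abs(th_w).max()))
    return PeakSummary(
        lambda_max=float(lam_w[i_max]),
        theta_max=float(th_w[i_max]),
        lambda_min=float(lam_w[i_min]),
        theta_min=float(th_w[i_min]),
        min_below_max=bool(lam_w[i_min] < lam_w[i_max]),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Sigmoid (four-parameter logistic) transition fit
# ---------------------------------------------------------------------------

def _logistic4(ph, lower, upper, ph50, slope):
    return lower + (upper - lower) / (1.0 + 10.0 ** (slope * (ph50 - ph)))


class SigmoidTransitionModel:
    """Four-parameter logistic fit of Delta-theta versus pH.

    Model: ``y(pH) = L + (U - L) / (1 + 10**(m (pH50 - pH)))`` with lower
    plateau L, upper plateau U, inflection pH50 and steepness m.  The
    base-10 form mirrors the amine deprotonation isotherm, so for a signal
    proportional to the deprotonated fraction the fitted pH50 equals the
    amine pKa2 exactly in the noise-free limit (with m = 1/beta2).

    Initialization takes L and U from the 5th/95th percentiles of the
    data, pH50 from the pH of the mid-amplitude crossing, and tries
    steepness starts m in {0.5, 1, 2}; the best converged start (lowest
    residual sum of squares) wins.
    """

    min_points = 8
    slope_starts = (0.5, 1.0, 2.0)

    def __init__(self, ph, delta_theta):
        self.ph = np.asarray(ph, dtype=float)
        self.delta_theta = np.asarray(delta_theta, dtype=float)
        if self.ph.shape != self.delta_theta.shape or self.ph.ndim != 1:
            raise DomainError("ph and delta_theta must be 1-D of equal length")
        if self.ph.size < self.min_points:
            raise InsufficientDataError(
                f"need at least {self.min_points} points, got {self.ph.size}"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SigmoidTransitionModel":
        """Build from a ``differential_series`` output frame."""
        return cls(df["ph"].to_numpy(), df["delta_theta"].to_numpy())

    def fit(self) -> "SigmoidFitResults":
        ph, y = self.ph, self.delta_theta
        order = np.argsort(ph)
        ph, y = ph[order], y[order]
        lo0, hi0 = np.percentile(y, [5.0, 95.0])
        amplitude = hi0 - lo0
        scale = max(np.abs(y).max(), 1.0)
        if amplitude < 1e-9 * scale:
            raise FitError("zero-amplitude series: no transition to fit")
        mid = 0.5 * (lo0 + hi0)
        # pH of the mid-amplitude crossing as pH50 start
        above = y >= mid
        cross = np.nonzero(above[1:] != above[:-1])[0]
        ph50_0 = float(ph[cross[0]]) if cross.size else float(np.median(ph))

        best = None
        diagnostics = []
        for m0 in self.slope_starts:
            try:
                popt, pcov = optimize.curve_fit(
                    _logistic4,
                    ph,
                    y,
                    p0=[lo0, hi0, ph50_0, m0],
                    maxfev=20000,
                )
            except RuntimeError as err:
                diagnostics.append(f"start m={m0}: {err}")
                continue
            rss = float(np.sum((y - _logistic4(ph, *popt)) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt, pcov)
        if best is None:
            raise FitError(
                "sigmoid fit failed to converge from all starts: "
                + "; ".join(diagnostics)
            )
        rss, popt, pcov = best
        lower, upper, ph50, slope = (float(p) for p in popt)
        if slope < 0:  # canonical orientation: positive slope, swap plateaus
            lower, upper, slope = upper, lower, -slope
        return SigmoidFitResults(
            lower_plateau=lower,
            upper_plateau=upper,
            inflection_ph=ph50,
            slope=slope,
            covariance=np.asarray(pcov, dtype=float),
            rss=rss,
            n_points=int(ph.size),
            ph=ph,
            delta_theta=y,
        )


@dataclass
class SigmoidFitResults:
    """Fitted transition parameters and diagnostics."""

    lower_plateau: float
    upper_plateau: float
    inflection_ph: float
    slope: float
    covariance: np.ndarray
    rss: float
    n_points: int
    ph: np.ndarray
    delta_theta: np.ndarray

    @property
    def amplitude(self) -> float:
        return self.upper_plateau - self.lower_plateau

    def predict(self, ph) -> np.ndarray:
        return _logistic4(
            np.asarray(ph, dtype=float),
            self.lower_plateau,
            self.upper_plateau,
            self.inflection_ph,
            self.slope,
        )

    def plateau_intervals(self, frac: float = 0.05):
        """pH ranges where the model stays within ``frac`` of each plateau.

        Returns ((ph_min, ph_lower_end), (ph_upper_start, ph_max)) on the
        fitted data range, or None for a plateau not reached within it.
        """
        ph = np.linspace(self.ph.min(), self.ph.max(), 801)
        y = self.predict(ph)
        amp = abs(self.amplitude)
        near_lo = np.abs(y - self.lower_plateau) < frac * amp
        near_hi = np.abs(y - self.upper_plateau) < frac * amp
        lo = (float(ph[0]), float(ph[near_lo][-1])) if near_lo.any() else None
        hi = (float(ph[near_hi][0]), float(ph[-1])) if near_hi.any() else None
        return lo, hi

    def summary(self) -> str:
        se = np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))
        lo, hi = self.plateau_intervals()
        lines = [
            "Sigmoid transition fit (4-parameter logistic in pH)",
            "---------------------------------------------------",
            f"lower plateau    : {self.lower_plateau:10.1f} +/- {se[0]:.1f}  mdeg/M/cm",
            f"upper plateau    : {self.upper_plateau:10.1f} +/- {se[1]:.1f}  mdeg/M/cm",
            f"inflection pH    : {self.inflection_ph:10.3f} +/- {se[2]:.3f}",
            f"slope m          : {self.slope:10.3f} +/- {se[3]:.3f}  per pH",
            f"RSS              : {self.rss:10.3g}   (n = {self.n_points})",
            f"lower plateau pH : {lo}",
            f"upper plateau pH : {hi}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Quick-look overlay of data and fitted logistic."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ph, self.delta_theta, "o", label="data")
        grid = np.linspace(self.ph.min(), self.ph.max(), 400)
        ax.plot(grid, self.predict(grid), "-", label="fit")
        ax.axvline(self.inflection_ph, ls="--", c="gray")
        ax.set_xlabel("pH")
        ax.set_ylabel(r"$\Delta\theta$ (mdeg M$^{-1}$ cm$^{-1}$)")
        ax.legend()
        return ax


def fit_sigmoid(ph, delta_theta=None) -> SigmoidFitResults:
    """Fit the transition sigmoid to (pH, Delta-theta) data.

    Accepts either two arrays or a DataFrame with ``ph`` and
    ``delta_theta`` columns.
    """
    if delta_theta is None and isinstance(ph, pd.DataFrame):
        return SigmoidTransitionModel.from_dataframe(ph).fit()
    return SigmoidTransitionModel(ph, delta_theta).fit()
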