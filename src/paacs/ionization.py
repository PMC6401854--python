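"""Acid-base analysis of amphoteric polyelectrolytes.

Polyamidoamino acids (PAACs) carry one carboxyl and one tertiary amine per
repeat unit and are therefore amphoteric polyelectrolytes.  Because the
ionizable groups of neighbouring repeat units interact, their effective
("apparent") dissociation constants drift with the degree of dissociation
``alpha``.  This module implements the standard polyelectrolyte treatment:

* the Henderson-Hasselbalch relation ``pH = pKa - log10((1 - alpha)/alpha)``,
  inverted point-by-point to obtain the apparent pKa at each alpha;
* its Katchalsky-Spitnik modification
  ``pH = pKa - beta * log10((1 - alpha)/alpha)``, whose exponent ``beta``
  absorbs nearest-neighbour electrostatic coupling along the chain
  (``beta = 1`` recovers the ideal single-site law);
* extraction of per-group dissociation-degree series from a potentiometric
  titration curve, with a free-H+/OH- mass-balance correction so that the
  titrant actually delivered to the polymer is counted;
* the pH speciation of the four repeat-unit microstates (cationic,
  zwitterionic, uncharged, anionic) under the site-independence assumption,
  and the isoelectric point where the mean net charge per repeat unit
  crosses zero.

Conventions
-----------
Both groups are described on the acid-dissociation scale: ``alpha`` is the
fraction of carboxyls present as COO- and, for the amine, the fraction of
ammonium centres already deprotonated (NH+ -> N).  With this convention a
single pair of equations covers both buffering regions and the
half-neutralization point of either group satisfies ``pH = pKa`` exactly,
for any ``beta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

from .exceptions import AnalysisError, DomainError, InsufficientDataError

__all__ = [
    "ACID",
    "BASE",
    "IonizableGroup",
    "PolymerSpec",
    "TitrationCurve",
    "AlphaSeries",
    "SpeciationProfile",
    "MICROSTATES",
    "apparent_pka",
    "KatchalskySpitnikModel",
    "KatchalskySpitnikResults",
    "fit_katchalsky_spitnik",
    "compute_alpha",
    "half_neutralization_ph",
    "speciation",
    "isoelectric_point",
]

KW = 1.0e-14  # ionic product of water at 25 degC; activities taken as concentrations

ACID = "carboxyl-acid"
BASE = "amine-base"


@dataclass(frozen=True)
class IonizableGroup:
    """One titratable site of the repeat unit.

    Parameters
    ----------
    kind : {"carboxyl-acid", "amine-base"}
        Chemical role of the group.
    pka : float
        Apparent pKa at half-neutralization (pH units, in (0, 14)).
    beta : float, default 1.0
        Katchalsky-Spitnik cooperativity exponent (> 0).  Values above 1
        broaden the titration, values below 1 sharpen it.
    """

    kind: str
    pka: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in (ACID, BASE):
            raise DomainError(f"unknown group kind {self.kind!r}")
        if not 0.0 < self.pka < 14.0:
            raise DomainError(f"pka must lie in (0, 14), got {self.pka}")
        if not self.beta > 0.0:
            raise DomainError(f"beta must be positive, got {self.beta}")

    def fraction_deprotonated(self, ph):
        """Fraction of the group in its deprotonated form at ``ph``.

        Follows the Katchalsky-Spitnik isotherm
        ``alpha(pH) = 1 / (1 + 10**((pKa - pH)/beta))``; equals 0.5 at
        ``pH = pKa`` for any ``beta``.
        """
        ph = np.asarray(ph, dtype=float)
        return 1.0 / (1.0 + 10.0 ** ((self.pka - ph) / self.beta))

    def fraction_protonated(self, ph):
        """Complement of :meth:`fraction_deprotonated`."""
        return 1.0 - self.fraction_deprotonated(ph)


@dataclass(frozen=True)
class PolymerSpec:
    """Amphoteric polymer description: one acid and one base per repeat unit."""

    name: str
    repeat_unit_mass: float  # g/mol
    acid_group: IonizableGroup
    base_group: IonizableGroup

    def __post_init__(self) -> None:
        if not self.repeat_unit_mass > 0.0:
            raise DomainError("repeat_unit_mass must be positive")
        if self.acid_group.kind != ACID or self.base_group.kind != BASE:
            raise DomainError("acid_group/base_group kinds are swapped or invalid")
        if self.acid_group.pka > self.base_group.pka:
            raise DomainError("acid pKa must not exceed base pKa")


@dataclass
class TitrationCurve:
    """A potentiometric titration: added titrant volume versus measured pH.

    ``volumes`` are in mL (monotone non-decreasing), ``titrant_conc`` in
    mol/L, ``titrant_sign`` +1 for base (NaOH) and -1 for acid (HCl),
    ``n_repeat_units`` the moles of titratable repeat units in the vessel,
    ``volume0`` the initial sample volume in mL and
    ``n_strong_acid_excess`` the moles of strong acid added during the
    pre-adjustment of pH (may be None when unknown; it is not needed by
    the analysis, which anchors alpha at the equivalence points).
    """

    volumes: np.ndarray
    ph: np.ndarray
    titrant_conc: float
    titrant_sign: int = 1
    n_repeat_units: float = 0.0
    volume0: float = 0.0
    n_strong_acid_excess: float | None = None

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        if self.volumes.shape != self.ph.shape or self.volumes.ndim != 1:
            raise DomainError("volumes and ph must be 1-D arrays of equal length")
        if np.any(np.diff(self.volumes) < 0):
            raise DomainError("volumes must be monotone non-decreasing")
        if np.any((self.ph <= 0) | (self.ph >= 14)):
            raise DomainError("pH readings must lie in (0, 14)")
        if self.titrant_sign not in (-1, 1):
            raise DomainError("titrant_sign must be +1 (base) or -1 (acid)")

    def __len__(self) -> int:
        return self.volumes.size


@dataclass
class AlphaSeries:
    """Matched (alpha, pH) values for one ionizable group."""

    alpha: np.ndarray
    ph: np.ndarray
    group: str  # ACID or BASE

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        if self.alpha.shape != self.ph.shape:
            raise DomainError("alpha and ph must have equal length")

    def __len__(self) -> int:
        return self.alpha.size


def apparent_pka(alpha, ph):
    """Apparent pKa from one (alpha, pH) reading via Henderson-Hasselbalch.

    Inverts ``pH = pKa - log10((1 - alpha)/alpha)`` for pKa, i.e. returns
    ``pH + log10((1 - alpha)/alpha)``.  At ``alpha = 0.5`` the log term
    vanishes and the apparent pKa equals the pH (half-neutralization).

    Raises
    ------
    DomainError
        If any alpha lies outside the open interval (0, 1).
    """
    alpha = np.asarray(alpha, dtype=float)
    ph = np.asarray(ph, dtype=float)
    if np.any((alpha <= 0.0) | (alpha >= 1.0)):
        raise DomainError("alpha must lie strictly inside (0, 1)")
    out = ph + np.log10((1.0 - alpha) / alpha)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Katchalsky-Spitnik regression
# ---------------------------------------------------------------------------

class KatchalskySpitnikModel:
    """Linearized fit of the modified Henderson-Hasselbalch equation.

    Plotting pH against ``x = log10((1 - alpha)/alpha)`` makes the modified
    equation a straight line with slope ``-beta`` and intercept ``pKa``.
    Points are restricted to an ``alpha_window`` (default [0.2, 0.8])
    because the linearization degenerates at the extremes of ionization,
    where the log transform amplifies endpoint noise.

    Parameters
    ----------
    series : AlphaSeries
        Dissociation-degree series for one group.
    alpha_window : (float, float)
        Closed alpha interval retained for the regression.
    """

    min_points = 5

    def __init__(self, series: AlphaSeries, alpha_window=(0.2, 0.8)):
        lo, hi = float(alpha_window[0]), float(alpha_window[1])
        if not 0.0 < lo < hi < 1.0:
            raise DomainError("alpha_window must satisfy 0 < lo < hi < 1")
        self.series = series
        self.alpha_window = (lo, hi)

    def fit(self) -> "KatchalskySpitnikResults":
        a, ph = self.series.alpha, self.series.ph
        lo, hi = self.alpha_window
        mask = (a >= lo) & (a <= hi) & np.isfinite(ph)
        if int(mask.sum()) < self.min_points:
            raise InsufficientDataError(
                f"only {int(mask.sum())} points with alpha in "
                f"[{lo}, {hi}]; need at least {self.min_points}"
            )
        x = np.log10((1.0 - a[mask]) / a[mask])
        res = stats.linregress(x, ph[mask])
        return KatchalskySpitnikResults(
            pka=float(res.intercept),
            beta=float(-res.slope),
            pka_stderr=float(res.intercept_stderr),
            beta_stderr=float(res.stderr),
            r_squared=float(res.rvalue**2),
            n_points=int(mask.sum()),
            alpha_window=self.alpha_window,
            group=self.series.group,
        )


@dataclass(frozen=True)
class KatchalskySpitnikResults:
    """Estimates and diagnostics of a Katchalsky-Spitnik regression."""

    pka: float
    beta: float
    pka_stderr: float
    beta_stderr: float
    r_squared: float
    n_points: int
    alpha_window: tuple
    group: str

    def summary(self) -> str:
        lines = [
            "Katchalsky-Spitnik fit",
            "----------------------",
            f"group            : {self.group}",
            f"pKa (apparent)   : {self.pka:8.3f} +/- {self.pka_stderr:.3f}",
            f"beta             : {self.beta:8.3f} +/- {self.beta_stderr:.3f}",
            f"R^2              : {self.r_squared:8.5f}",
            f"points used      : {self.n_points} "
            f"(alpha in [{self.alpha_window[0]}, {self.alpha_window[1]}])",
        ]
        return "\n".join(lines)


def fit_katchalsky_spitnik(series: AlphaSeries, alpha_window=(0.2, 0.8)):
    """Convenience wrapper: build the model and return its fitted results."""
    return KatchalskySpitnikModel(series, alpha_window=alpha_window).fit()


# ---------------------------------------------------------------------------
# Titration-curve reduction
# ---------------------------------------------------------------------------

def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y.astype(float), pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + y.size]
    return out


def _net_base_to_polymer(curve: TitrationCurve) -> np.ndarray:
    """Moles of titrant delivered to the polymer, relative to the first point.

    Subtracts the change in free-proton/hydroxide content of the (diluting)
    solution from the cumulative titrant charge, so that strong-acid
    neutralization at low pH and free-base accumulation at high pH do not
    masquerade as polymer ionization.
    """
    h = 10.0 ** (-curve.ph)
    oh = KW / h
    vt_l = (curve.volume0 + curve.volumes) / 1000.0
    n_titrant = curve.titrant_sign * curve.titrant_conc * curve.volumes / 1000.0
    free = (h - oh) * vt_l
    return n_titrant + (free - free[0])


def find_equivalence_points(
    curve: TitrationCurve, n_points: int = 2, smooth_window: int = 5
):
    """Indices of equivalence points from maxima of dpH/dV.

    The pH trace is smoothed with a centred moving average and
    differentiated with centred differences (non-uniform spacing handled
    by ``numpy.gradient``).  Local maxima are ranked by derivative height
    and selected greedily subject to a minimum volume separation of a
    quarter of one stoichiometric region width, so the two buffering
    regions of an amphoteric polymer yield exactly two well-separated
    jumps.

    Returns sorted indices into ``curve.volumes``.

    Raises
    ------
    AnalysisError
        If fewer than ``n_points`` acceptable maxima exist.
    """
    v = curve.volumes
    if v.size < 2 * smooth_window:
        raise AnalysisError("titration curve too short for equivalence detection")
    sign = 1.0 if curve.titrant_sign > 0 else -1.0
    ph_s = _moving_average(curve.ph, smooth_window)
    # guard against zero spacing in the derivative
    v_safe = v + np.arange(v.size) * 1e-12
    deriv = sign * np.gradient(ph_s, v_safe)
    # tiny floor rejects numerically flat curves while keeping the weaker
    # second (amine-region) jump, which OH- buffering can flatten
    peaks, props = signal.find_peaks(deriv, height=1e-6)
    if peaks.size == 0:
        raise AnalysisError("no equivalence point found (flat derivative)")
    # minimum separation: a quarter of one stoichiometric region, when known
    if curve.n_repeat_units > 0:
        min_sep = 0.25 * curve.n_repeat_units / curve.titrant_conc * 1000.0
    else:
        min_sep = 0.02 * (v[-1] - v[0])
    order = np.argsort(props["peak_heights"])[::-1]
    chosen: list[int] = []
    for idx in peaks[order]:
        if all(abs(v[idx] - v[j]) > min_sep for j in chosen):
            chosen.append(int(idx))
        if len(chosen) == n_points:
            break
    if len(chosen) < n_points:
        region = "carboxyl" if len(chosen) == 0 else "amine"
        raise AnalysisError(
            f"could not locate the {region}-region equivalence point "
            f"({len(chosen)}/{n_points} found)"
        )
    return sorted(chosen)


def compute_alpha(
    curve: TitrationCurve,
    spec: PolymerSpec,
    eps: float = 0.01,
    smooth_window: int = 5,
):
    """Reduce a titration curve to per-group dissociation-degree series.

    The two equivalence volumes are located from the first-derivative
    maxima of pH(V).  In a forward base titration the first buffering
    region (before the first equivalence) is the carboxyl deprotonation
    and the second region the ammonium deprotonation; a backward acid
    titration is handled by reversing the roles.  Within each region the
    dissociation degree is the free-ion-corrected moles of titrant past
    the region boundary divided by the moles of repeat units, clamped to
    ``(eps, 1 - eps)`` before any log transform.

    The equivalence points split the curve into buffering segments; each
    group is matched to the segment whose pH range contains its pKa (so
    the assignment is independent of titration direction and of an extra
    jump where the strong-acid/base pre-adjustment is consumed), and its
    alpha values are anchored at a detected equivalence boundary, where
    the group is known to be fully protonated or fully deprotonated.

    Returns
    -------
    (AlphaSeries, AlphaSeries)
        Carboxyl series first, amine series second.  Both empty (with a
        warning) when the curve contains no polymer.
    """
    if curve.n_repeat_units <= 0.0:
        warnings.warn(
            "titration curve declares zero repeat units: no buffering region",
            stacklevel=2,
        )
        empty = np.empty(0)
        return (
            AlphaSeries(empty.copy(), empty.copy(), ACID),
            AlphaSeries(empty.copy(), empty.copy(), BASE),
        )
    eq_indices = find_equivalence_points(curve, 2, smooth_window)
    n_poly = _net_base_to_polymer(curve)
    n_ru = curve.n_repeat_units
    lo, hi = eps, 1.0 - eps
    forward = curve.titrant_sign > 0

    bounds = [0] + list(eq_indices) + [len(curve) - 1]
    segments = [
        (bounds[k], bounds[k + 1])
        for k in range(len(bounds) - 1)
        if bounds[k + 1] - bounds[k] > 1
    ]
    detected = set(eq_indices)
    out = {}
    for kind, pka in (
        (ACID, spec.acid_group.pka),
        (BASE, spec.base_group.pka),
    ):
        matches = []
        for i, j in segments:
            seg_ph = curve.ph[i : j + 1]
            if seg_ph.min() < pka < seg_ph.max():
                matches.append((abs(np.median(seg_ph) - pka), (i, j)))
        if not matches:
            raise AnalysisError(
                f"no buffering segment brackets the {kind} pKa {pka:.2f}"
            )
        _, (i, j) = min(matches)
        # at the low-pH-side equivalence the group is fully protonated
        # (alpha = 0), at the high-pH side fully deprotonated (alpha = 1)
        high_ph_idx, low_ph_idx = (j, i) if forward else (i, j)
        if low_ph_idx in detected:
            anchor, anchor_alpha = low_ph_idx, 0.0
        elif high_ph_idx in detected:
            anchor, anchor_alpha = high_ph_idx, 1.0
        else:
            raise AnalysisError(
                f"{kind} segment has no detected equivalence boundary"
            )
        idx = np.arange(i, j + 1)
        idx = idx[~np.isin(idx, list(detected))]
        alpha = np.clip(
            anchor_alpha + (n_poly[idx] - n_poly[anchor]) / n_ru, lo, hi
        )
        out[kind] = AlphaSeries(alpha, curve.ph[idx], kind)
    return out[ACID], out[BASE]


def half_neutralization_ph(series: AlphaSeries) -> float:
    """pH at alpha = 0.5, by interpolation; equals the apparent pKa.

    Raises
    ------
    AnalysisError
        If the series does not bracket alpha = 0.5.
    """
    if len(series) < 2:
        raise AnalysisError("series too short for half-neutralization")
    order = np.argsort(series.alpha)
    a = series.alpha[order]
    ph = series.ph[order]
    if not (a[0] < 0.5 < a[-1]):
        raise AnalysisError("series does not bracket alpha = 0.5")
    return float(np.interp(0.5, a, ph))


# ---------------------------------------------------------------------------
# Speciation
# ---------------------------------------------------------------------------

MICROSTATES = ("cationic", "zwitterionic", "uncharged", "anionic")


@dataclass
class SpeciationProfile:
    """Microstate fractions of the repeat unit on a pH grid.

    ``fractions`` has one row per grid point and one column per microstate
    in the order ``MICROSTATES`` = (cationic COOH/NH+, zwitterionic
    COO-/NH+, uncharged COOH/NH, anionic COO-/NH); rows sum to one.
    ``net_charge`` is the mean charge per repeat unit,
    ``f(NH+) - f(COO-)``.
    """

    ph_grid: np.ndarray
    fractions: np.ndarray
    net_charge: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        data = {"pH": self.ph_grid}
        for j, name in enumerate(
            ("f_cation", "f_zwitterion", "f_neutral", "f_anion")
        ):
            data[name] = self.fractions[:, j]
        data["net_charge"] = self.net_charge
        return pd.DataFrame(data)

    def net_neutral_fraction(self) -> np.ndarray:
        """Zwitterionic plus uncharged fraction (the lumped 'neutral' state)."""
        return self.fractions[:, 1] + self.fractions[:, 2]

    def plot(self, ax=None):
        """Quick-look speciation diagram (fractions and net charge vs pH)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for j, name in enumerate(MICROSTATES):
            ax.plot(self.ph_grid, self.fractions[:, j], label=name)
        ax.plot(self.ph_grid, self.net_charge, "k--", label="net charge")
        ax.set_xlabel("pH")
        ax.set_ylabel("fraction / charge per repeat unit")
        ax.legend(fontsize="small")
        return ax


def speciation(spec: PolymerSpec, ph_grid=None) -> SpeciationProfile:
    """Microstate distribution versus pH from the pKa/beta pairs.

    Site independence is assumed: the joint microstate probabilities are
    products of the two single-site isotherms (the beta exponents already
    absorb nearest-neighbour coupling within each group).  With
    pKa1 << pKa2 the uncharged microstate is negligible but is carried
    explicitly so the four fractions normalize exactly.
    """
    if ph_grid is None:
        ph_grid = np.arange(0.0, 14.0 + 1e-9, 0.05)
    ph_grid = np.asarray(ph_grid, dtype=float)
    f_a = spec.acid_group.fraction_deprotonated(ph_grid)   # COO-
    f_b = spec.base_group.fraction_protonated(ph_grid)     # NH+
    fractions = np.column_stack(
        [
            (1.0 - f_a) * f_b,        # cationic COOH / NH+
            f_a * f_b,                # zwitterionic COO- / NH+
            (1.0 - f_a) * (1.0 - f_b),  # uncharged COOH / NH
            f_a * (1.0 - f_b),        # anionic COO- / NH
        ]
    )
    return SpeciationProfile(ph_grid, fractions, f_b - f_a)


def isoelectric_point(spec: PolymerSpec) -> float:
    """pH at which the mean net charge per repeat unit vanishes.

    Found by bisection of ``net_charge(pH)`` on (0, 14) to 1e-6 pH.

    Raises
    ------
    AnalysisError
        If the net charge does not change sign on the interval.
    """

    def net(ph: float) -> float:
        return float(
            spec.base_group.fraction_protonated(ph)
            - spec.acid_group.fraction_deprotonated(ph)
        )

    lo, hi = 1e-9, 14.0 - 1e-9
    if net(lo) * net(hi) > 0:
        raise AnalysisError("net charge does not change sign on (0, 14)")
    return float(optimize.bisect(net, lo, hi, xtol=1e-7))
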