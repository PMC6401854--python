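"""Synthetic instrument data with the statistical structure the analysis assumes.

Three generators stand in for the raw measurements:

* :func:`simulate_titration` — a forward/backward potentiometric titration
  of an amphoteric polymer.  For each pH on a grid the added titrant
  volume is obtained in closed form from the electroneutrality condition
  ``[Na+] + [H+] + c_RU f(NH+) = [Cl-] + [OH-] + c_RU f(COO-)``
  (dilution included, Kw = 1e-14, activity coefficients unity, the inert
  NaCl background cancelling).  Gaussian noise is applied to the pH
  readings only, so the volume axis stays monotone as in a real burette
  programme.
* :func:`simulate_cd_series` — a pH series of CD spectra: a positive
  Gaussian band whose amplitude is proportional to the amine
  deprotonation fraction of the polymer, plus a negative band at lower
  wavelength that blue-shifts linearly below pH 5, converted back to raw
  millidegrees for the configured concentration and path length.
* :func:`make_coil` — a randomly coiled oligomer built by re-torsioning
  the idealized extended chain with a 70/30 mixture of transoid
  (near +/-180 deg) and turn (|phi| in 60-120 deg) dihedrals under
  hard-sphere overlap rejection.

Every generator is deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chainmetrics import (
    PAAC_TEMPLATE,
    Conformer,
    RepeatTemplate,
    chain_from_torsions,
)
from .cdspec import CDSpectrum, repeat_unit_concentration
from .exceptions import AnalysisError, DomainError
from .ionization import KW, PolymerSpec, TitrationCurve

__all__ = [
    "TitrationProtocol",
    "simulate_titration",
    "CDSeriesParams",
    "simulate_cd_series",
    "simulate_differential_series",
    "make_coil",
]


@dataclass(frozen=True)
class TitrationProtocol:
    """Conditions of a simulated potentiometric titration.

    Defaults mirror the standard bench protocol for these polymers:
    0.05 M repeat units, 0.1 M NaOH titrant, forward run from the
    pre-acidified start near pH 1.7 up to strongly basic pH.
    ``strong_acid_excess`` (mol) is the HCl used for the pre-adjustment;
    when None it is chosen so the curve starts exactly at ``ph_start``.
    """

    sample_conc: float = 0.05     # mol repeat units / L
    volume0: float = 20.0         # mL
    titrant_conc: float = 0.1     # mol/L
    titrant_sign: int = 1         # +1 NaOH forward, -1 HCl backward
    strong_acid_excess: float | None = None  # mol
    ph_start: float = 1.7
    ph_end: float = 11.8
    ph_step: float = 0.05
    ph_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_conc < 0 or self.titrant_conc <= 0 or self.volume0 <= 0:
            raise DomainError("concentrations and volumes must be positive")
        if self.titrant_sign == 1 and not self.ph_start < self.ph_end:
            raise DomainError("forward runs need ph_start < ph_end")
        if self.titrant_sign == -1 and not self.ph_start > self.ph_end:
            raise DomainError("backward runs need ph_start > ph_end")
        if self.ph_step <= 0:
            raise DomainError("ph_step must be positive")


def _net_proton_excess(ph):
    h = 10.0 ** (-np.asarray(ph, dtype=float))
    return h - KW / h


def simulate_titration(
    spec: PolymerSpec | None, protocol: TitrationProtocol
) -> TitrationCurve:
    """Forward-model a titration curve from the speciation isotherms.

    Solving the electroneutrality balance for the added volume at each pH
    gives (for a forward NaOH run; the backward HCl run is symmetric)

        V = (n_acid + n_RU (f_COO- - f_NH+) - d(pH) V0) / (C_t + d(pH)),

    with d(pH) = [H+] - [OH-].  ``spec`` may be None for a polymer-free
    strong-acid/strong-base blank.

    Raises
    ------
    AnalysisError
        If part of the requested pH range is unreachable (negative or
        non-monotone volumes).
    """
    s = protocol.titrant_sign
    n_grid = int(round(abs(protocol.ph_end - protocol.ph_start) / protocol.ph_step)) + 1
    ph_grid = protocol.ph_start + s * protocol.ph_step * np.arange(n_grid)
    v0_l = protocol.volume0 / 1000.0
    n_ru = protocol.sample_conc * v0_l

    def f_acid(ph):
        return spec.acid_group.fraction_deprotonated(ph) if spec else 0.0

    def f_base(ph):
        return spec.base_group.fraction_protonated(ph) if spec else 0.0

    d0 = _net_proton_excess(protocol.ph_start)
    if protocol.strong_acid_excess is None:
        # choose the pre-adjustment HCl so that V = 0 at ph_start
        n_acid = d0 * v0_l + n_ru * (
            f_base(protocol.ph_start) - f_acid(protocol.ph_start)
        )
    else:
        n_acid = protocol.strong_acid_excess

    d = _net_proton_excess(ph_grid)
    rhs = n_acid + n_ru * (f_acid(ph_grid) - f_base(ph_grid)) - d * v0_l
    denom = protocol.titrant_conc + s * d
    if np.any(denom <= 0):
        raise AnalysisError("requested pH range unreachable with this titrant")
    v_l = s * rhs / denom  # volume of titrant, L (positive for both signs)
    v_ml = v_l * 1000.0
    if protocol.strong_acid_excess is None:
        v_ml = v_ml - v_ml[0]  # the pre-adjustment was chosen to start at zero
    if np.any(np.diff(v_ml) < -1e-9) or np.any(v_ml < -1e-9):
        raise AnalysisError("titration volumes not monotone: unreachable pH range")
    v_ml = np.maximum.accumulate(np.maximum(v_ml, 0.0))

    ph_out = ph_grid.astype(float)
    if protocol.ph_noise_sd > 0:
        rng = np.random.default_rng(protocol.seed)
        ph_out = ph_out + rng.normal(0.0, protocol.ph_noise_sd, ph_out.size)
        ph_out = np.clip(ph_out, 1e-3, 14.0 - 1e-3)

    return TitrationCurve(
        volumes=v_ml,
        ph=ph_out,
        titrant_conc=protocol.titrant_conc,
        titrant_sign=s,
        n_repeat_units=n_ru,
        volume0=protocol.volume0,
        n_strong_acid_excess=n_acid,
    )


@dataclass(frozen=True)
class CDSeriesParams:
    """Parameters of a synthetic pH series of CD spectra.

    Band tuples are (center nm, sigma nm, amplitude mdeg M^-1 cm^-1);
    the negative band additionally carries the blue-shift (nm) it reaches
    at pH 3.  ``noise_sd`` is the Gaussian noise, as a fraction of the
    positive-band amplitude, added to the molar ellipticity at every
    wavelength.  The structuring amplitude is coupled to the amine
    deprotonation fraction of the polymer.
    """

    ph_values: tuple = tuple(np.arange(3.0, 11.0 + 1e-9, 0.25))
    pos_band: tuple = (228.0, 8.0, 5000.0)
    neg_band: tuple = (210.0, 9.0, 4000.0, 6.0)
    wavelength_range: tuple = (200.0, 300.0)
    wavelength_step: float = 0.5
    mass_conc: float = 0.5       # mg/mL
    path_length: float = 1.0     # cm
    noise_sd: float = 0.0        # fraction of positive amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        for c in (self.pos_band[0], self.neg_band[0]):
            if not 195.0 <= c <= 300.0:
                raise DomainError("band centers must lie within 195-300 nm")
        if self.pos_band[1] <= 0 or self.neg_band[1] <= 0:
            raise DomainError("band widths must be positive")


def _gaussian(lam, center, width):
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def simulate_cd_series(
    spec: PolymerSpec, params: CDSeriesParams
) -> list[CDSpectrum]:
    """Generate raw (mdeg) CD spectra over the configured pH values.

    Molar ellipticity model:
    ``theta(lam, pH) = A (1 - f_NH+(pH)) G(lam; c+, w+) - B G(lam; c-(pH), w-)``
    with the negative-band center moving linearly from its base value at
    pH >= 5 to ``base - blue_shift`` at pH 3.  Gaussian noise (sd =
    ``noise_sd * A``) is added to theta, then each spectrum is converted
    back to raw millidegrees for the configured mass concentration.
    """
    lam = np.arange(
        params.wavelength_range[0],
        params.wavelength_range[1] + 1e-9,
        params.wavelength_step,
    )
    c_pos, w_pos, a_pos = params.pos_band
    c_neg, w_neg, a_neg, shift = params.neg_band
    conc = repeat_unit_concentration(params.mass_conc, spec.repeat_unit_mass)
    rng = np.random.default_rng(params.seed)
    out = []
    for ph in params.ph_values:
        deprot = float(spec.base_group.fraction_deprotonated(ph))
        center_neg = c_neg - shift * min(max((5.0 - ph) / 2.0, 0.0), 1.0)
        theta = a_pos * deprot * _gaussian(lam, c_pos, w_pos)
        theta = theta - a_neg * _gaussian(lam, center_neg, w_neg)
        if params.noise_sd > 0:
            theta = theta + rng.normal(0.0, params.noise_sd * a_pos, lam.size)
        raw = theta * conc * params.path_length
        out.append(
            CDSpectrum(
                wavelengths=lam.copy(),
                ellipticity=raw,
                ph=float(ph),
                path_length=params.path_length,
                mass_conc=params.mass_conc,
                repeat_unit_conc=conc,
                normalized=False,
            )
        )
    return out


def simulate_differential_series(
    spec: PolymerSpec,
    ph_values=None,
    amplitude: float = 1000.0,
    noise_sd: float = 0.02,
    seed: int = 0,
):
    """Differential molar ellipticity series coupled to amine deprotonation.

    Shortcut generator for the reduced observable itself:
    ``Delta-theta(pH) = amplitude * (1 - f_NH+(pH)) + noise``, with
    Gaussian noise of sd ``noise_sd * amplitude``.  This is the pH 3
    reference already subtracted (the deprotonated fraction is ~0 there
    for these polymers).  Returns ``(ph, delta_theta)`` arrays.
    """
    if ph_values is None:
        ph_values = np.arange(3.0, 11.0 + 1e-9, 0.2)
    ph = np.asarray(ph_values, dtype=float)
    rng = np.random.default_rng(seed)
    dtheta = amplitude * spec.base_group.fraction_deprotonated(ph)
    if noise_sd > 0:
        dtheta = dtheta + rng.normal(0.0, noise_sd * amplitude, ph.size)
    return ph, dtheta


def make_coil(
    template: RepeatTemplate = PAAC_TEMPLATE,
    n_units: int = 10,
    seed: int = 0,
    transoid_prob: float = 0.7,
    transoid_sd: float = 8.0,
    clash_cutoff: float = 2.2,
    max_restarts: int = 200,
    side_chain: bool = True,
) -> Conformer:
    """Randomly coiled chain with a prescribed transoid/turn torsion mixture.

    Each backbone torsion is drawn transoid (normal around +/-180 deg, sd
    ``transoid_sd``) with probability ``transoid_prob``, otherwise a turn
    (|phi| uniform in 60-120 deg, random sign).  The chain is grown
    atom-by-atom; a placement whose distance to any atom at least four
    backbone positions back falls below ``clash_cutoff`` (Angstrom) is
    redrawn, and the whole chain restarts when a position exhausts its
    redraws.  Deterministic for a given seed.

    Raises
    ------
    AnalysisError
        If no clash-free chain is found within ``max_restarts``.
    """
    import math

    from .chainmetrics import _place_atom  # shared placement kernel

    rng = np.random.default_rng(seed)
    p = len(template.elements)
    n_bb = n_units * p

    def draw_torsion() -> float:
        if rng.random() < transoid_prob:
            ang = rng.normal(180.0, transoid_sd) * (1 if rng.random() < 0.5 else -1)
        else:
            ang = rng.uniform(60.0, 120.0) * (1 if rng.random() < 0.5 else -1)
        # wrap to (-180, 180]
        ang = (ang + 180.0) % 360.0 - 180.0
        return 180.0 if ang == -180.0 else ang

    lengths = [template.bond_lengths[i % p] for i in range(n_bb)]
    angles = [template.bond_angles[i % p] for i in range(n_bb)]
    for _ in range(max_restarts):
        xyz = np.zeros((n_bb, 3))
        xyz[1] = (lengths[1], 0.0, 0.0)
        th = math.radians(angles[2])
        xyz[2] = xyz[1] + lengths[2] * np.array([-math.cos(th), math.sin(th), 0.0])
        torsions = np.empty(n_bb - 3)
        failed = False
        for i in range(3, n_bb):
            placed = False
            for _attempt in range(50):
                phi = draw_torsion()
                pos = _place_atom(
                    xyz[i - 3], xyz[i - 2], xyz[i - 1],
                    lengths[i], angles[i], phi,
                )
                prior = xyz[: max(i - 3, 0)]
                if prior.size:
                    d2 = np.sum((prior - pos) ** 2, axis=1)
                    if d2.min() < clash_cutoff**2:
                        continue
                xyz[i] = pos
                torsions[i - 3] = phi
                placed = True
                break
            if not placed:
                failed = True
                break
        if not failed:
            return chain_from_torsions(torsions, template, n_units, side_chain)
    raise AnalysisError(
        f"could not grow a clash-free coil in {max_restarts} restarts"
    )
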