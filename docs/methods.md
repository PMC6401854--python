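# Methods

This note records the models implemented in `paacs`, the assumptions
behind them, the defaults of the synthetic-data generators, and the
numerical choices that were genuinely open.

## Ionization model

Both repeat-unit groups are treated on the acid-dissociation scale: α is
the fraction of carboxyls present as COO⁻ and, for the amine, the
fraction of ammonium centres already deprotonated.  Each group follows
the Katchalsky–Spitnik isotherm

    α(pH) = 1 / (1 + 10^((pKa − pH)/β)),

which is the closed-form inverse of the modified Henderson–Hasselbalch
equation pH = pKa − β·log₁₀[(1−α)/α].  The exponent β (dimensionless,
β > 0) is an empirical lump for nearest-neighbour coupling along the
chain: β > 1 broadens the titration, β < 1 sharpens it, and at α = 0.5
the pH equals the apparent pKa for any β.  No activity-coefficient or
ionic-strength corrections are applied (measurements are taken in a
0.1 M NaCl swamping background; Kw is fixed at 1.0e−14, 25 °C).

**Speciation** assumes site independence: microstate probabilities are
products of the two single-site isotherms, the β values having already
absorbed intra-group coupling.  All four microstates are carried —
including the uncharged COOH/NH state, which is negligible whenever
pKa₁ ≪ pKa₂ but is required for exact normalization — and reporting can
lump {zwitterionic + uncharged} as net-neutral, matching the
three-state picture usual for these polymers.  The isoelectric point is
the bisection root (tolerance 1e−7 pH) of the net charge
f(NH⁺) − f(COO⁻) on (0, 14).

**Titration reduction.**  Equivalence points are taken as maxima of
dpH/dV after a 5-point moving average, using centred differences on the
non-uniform volume grid, with a 1e−6 pH/mL floor so flat curves are
rejected rather than mis-segmented.  The two highest maxima separated
by at least a quarter of one stoichiometric region width are kept.  The
curve segments they delimit are then matched to groups by pH content —
a group's segment is the one whose pH range brackets its pKa — which
makes the assignment independent of titration direction and of the
extra jump where the strong-acid/base pre-adjustment is consumed.
Within a segment, α is anchored at a detected equivalence boundary
(α = 0 at the low-pH side, α = 1 at the high-pH side) and advanced by
the titrant actually delivered to the polymer: cumulative titrant
charge minus the change in free-H⁺/OH⁻ content of the diluting
solution.  Without that correction the α scale is biased by ≈0.1 at
pH ≈ 2.3 under the bench conditions (0.05 M repeat units), enough to
shift the carboxyl half-neutralization point by ~0.2 pH.  α values are
clamped to (0.01, 0.99) before any log transform; the β regression uses
only α ∈ [0.2, 0.8] by default because the linearization degenerates at
the extremes (both limits configurable).

## CD transition model

Raw ellipticity in mdeg is normalized per repeat unit,
θ = raw/(c·l) in mdeg M⁻¹ cm⁻¹ with c the repeat-unit molarity (mass
concentration over repeat-unit molar mass) and l the path length in cm.
The differential series Δθ(pH) is evaluated at a fixed wavelength —
by default the polymer's positive-band maximum (228/234/231 nm for the
Ala/Val/Leu polymer) — against the spectrum closest to pH 3 (accepted
within ±0.2 pH, reflecting experimental pH-adjustment scatter).

The transition is fitted with a four-parameter logistic in pH,

    Δθ(pH) = L + (U − L) / (1 + 10^{m (pH₅₀ − pH)}),

chosen because it corresponds exactly to the amine isotherm: for a
signal proportional to the deprotonated fraction, pH₅₀ = pKa₂ and
m = 1/β₂ analytically.  Whether the original curves were fitted or read
graphically is not documented; fitting is this package's choice.
Initialization takes L, U from the 5th/95th percentiles, pH₅₀ from the
mid-amplitude crossing, and multi-starts the steepness at
m ∈ {0.5, 1, 2}, keeping the converged start with the lowest residual
sum of squares.  Fits are reported in a canonical orientation (m > 0);
plateau intervals are quoted as the pH ranges where the model stays
within 5% of the amplitude of each plateau, since no criterion for the
plateau extents is standard.  Constant series raise a zero-amplitude
error instead of returning a degenerate fit.

## Chain descriptors

Coordinates are in Å; outputs in nm, nm², Debye and degrees.  Radius of
gyration is mass-weighted by default (standard atomic weights); SASA
uses Shrake–Rupley sampling with a deterministic golden-spiral point set
(960 points by default; the 960 → 3840 change is below 0.5% on the
bundled fixtures) and a 0.14 nm probe, with exact duplicate atoms
collapsed first; van der Waals radii are the Bondi set.  Dipole moments
need user-supplied partial charges (1 e·Å = 4.80320 D); for non-neutral
systems the value is origin-dependent, so the origin convention
(absolute-charge-weighted centre by default) is always reported with the
value.  Torsions are signed dihedrals of four consecutive backbone
atoms in (−180°, 180°]; collinear triples yield NaN rather than an
error.  The transoid threshold is |φ| ≥ 150°, splitting the reported
transoid (±180°-peaked) population from the ±60–120° turn range.

The idealized builder places the ten-backbone-atom PAAC repeat
(N–C–C–C(O)–N–C–N–C(O)–C–C) by natural-extension (NeRF) geometry with
standard bond lengths (C–C 1.53 Å, C–N 1.47 Å, amide C–N 1.33 Å) and
angles (109.5° sp³, 120° trigonal), all torsions 180° for the elongated
chain.  Side pendants are single pseudo-atoms (mass 74 amu, radius
2.5 Å, a CH(R)COOH lump) on the tertiary amine nitrogen: backbone
descriptors dominate the analysis, and full side-chain geometry is out
of scope.  Ten backbone atoms give n−3 = 7 internal torsions per
isolated repeat.

## Synthetic generators

The generators encode the bench study conditions and are deterministic
per seed.

*Titration*: 0.05 M repeat units in 20 mL, 0.1 M NaOH forward from
pH 1.7 (pre-acidified with strong acid) to pH 11.8 on a 0.05-pH grid;
backward HCl runs are symmetric.  The added volume at each pH solves
the electroneutrality balance in closed form (dilution included),
V = s·[n_acid + n_RU(f_COO⁻ − f_NH⁺) − d·V₀]/(C_t + s·d) with
d = [H⁺] − [OH⁻] and s the titrant sign.  Gaussian noise (default
σ = 0.02 pH) is applied to the pH readings only, so volumes remain
monotone as in a real burette programme.

*CD series*: θ(λ, pH) is a positive Gaussian band whose amplitude is
proportional to the amine deprotonated fraction, minus a negative band
at lower wavelength whose centre blue-shifts linearly below pH 5
(reaching the configured shift at pH 3), converted to raw mdeg for
0.5 mg/mL and a 1 cm cell.  Band centres use the observed positive-band
maxima (228/234/231 nm); widths (8/9 nm), amplitudes (≈5000–7000
mdeg M⁻¹ cm⁻¹), the negative-band centres (≈210 nm) and the 6 nm blue
shift are plausibility fixtures — the real band shapes are not
tabulated anywhere, so these are not measured values.  The default pH
grid is 3–11 in steps of 0.25 (CD series) and 0–14 in steps of 0.05
(speciation tables), matching the resolution at which such figures are
drawn.  Coupling the amplitude to amine deprotonation (rather than net
charge) reflects the observation that the amine protonation degree is
the main factor governing structuring.

*Coils*: backbone torsions are drawn from a 70/30 mixture of transoid
(normal around ±180°, σ = 8°) and turn (|φ| uniform in 60–120°) angles,
mimicking the reported torsion distribution of compact states, and the
chain is grown with hard-sphere rejection (2.2 Å cutoff between atoms
four or more backbone positions apart, 50 redraws per position, then a
full restart).  The rejection slightly reshuffles which draws survive,
so the realized transoid fraction is checked on outputs (0.7 ± 0.1 over
seed ensembles) rather than assumed.

**What the generators do not emulate**: electrode drift and junction
potentials, CO₂ uptake at basic pH, spectral baseline drift and
wavelength-dependent noise, polymer polydispersity, and any real
conformational energetics (coils are geometric, not Boltzmann-weighted).
Passing round-trip tests therefore demonstrates the correctness and
stability of the analysis chain under the assumed noise model, not the
accuracy of the physical model for any particular instrument record.

## Fixture parameters of the three polymers

The amine pKa₂ values of the built-in parameter sets (8.1, 6.8, 7.3 for
the Ala/Val/Leu polymer) are anchored at the observed chiroptical
transition pH, which coincides with amine half-ionization.  The
carboxyl pKa₁ values (2.3–2.5) and all β values (0.90 for the carboxyl,
1.30–1.35 for the amine) are synthetic fixtures chosen in the range
typical of weak amphoteric polyelectrolytes, with β₁ < 1 and β₂ > 1
reproducing the observed directions of the apparent-pKa drifts (the
carboxyl's falls with ionization, the amine's rises).  They are
simulation defaults, not measured constants.

## Known limitations

- The Katchalsky–Spitnik exponent is an empirical lump; no multi-site
  partition-function or Ising treatment is attempted.
- Speciation assumes inter-group independence; real carboxyl–ammonium
  pairing would correlate the sites beyond what β captures.
- Equivalence detection needs visibly separated buffering regions; it
  will refuse (with a named region) rather than guess on curves where a
  group's jump is absent from the scanned pH window.
- MD-grade size descriptors (force-field Rg/SASA/dipole values) are not
  desk-reproducible; the geometric coil ensemble supports ordering and
  magnitude checks only.
- Dipole moments of non-neutral structures are origin-dependent by
  physics; the package reports the convention rather than hiding it.
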