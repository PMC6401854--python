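# paacs

Acid–base, chiroptical and conformational analysis of **polyamidoamino
acids (PAACs)** — amphoteric polymers obtained by Michael polyaddition of
an α-amino acid (alanine, valine, leucine) with
N,N′-methylenebisacrylamide, whose repeat unit carries one carboxyl and
one tertiary amine.  The package is aimed at polymer physical chemists
who want a reproducible, scriptable version of the desk-scale analysis
chain for such polymers: potentiometric titration reduction, pH
speciation, circular-dichroism (CD) transition analysis, and
conformational descriptors of oligomer structures.  A seeded
synthetic-data generator emulates each measurement so the whole pipeline
can be exercised and validated without instrument data.

## The models

**Titration.**  For a polyelectrolyte the apparent dissociation constant
drifts with the degree of dissociation α.  Each reading is inverted
through the Henderson–Hasselbalch relation

    pH = pKa − log10[(1 − α)/α]

and the α-dependence is summarized by the Katchalsky–Spitnik
modification

    pH = pKa − β · log10[(1 − α)/α]

whose exponent β absorbs interactions between neighbouring ionizable
groups (β = 1 recovers the ideal single-site law).  Plotting pH against
x = log10[(1 − α)/α] makes this a straight line with slope −β and
intercept pKa.  α itself is extracted from the titration curve by
locating equivalence points from dpH/dV maxima and counting the
free-H⁺/OH⁻-corrected titrant delivered to the polymer.

**Speciation.**  With (pKa₁, β₁) for the carboxyl and (pKa₂, β₂) for the
amine, the repeat unit distributes over four microstates — cationic
(COOH/NH⁺), zwitterionic (COO⁻/NH⁺), uncharged (COOH/NH) and anionic
(COO⁻/NH) — as products of the two single-site isotherms; the net charge
per repeat unit is f(NH⁺) − f(COO⁻) and its root is the isoelectric
point.

**CD transition.**  Raw ellipticity (mdeg) is normalized to molar
ellipticity per repeat unit, θ = raw/(c·l); the differential series
Δθ(pH) = θ_pH(λ*) − θ_pH3(λ*) against the pH-3 reference is fitted with
a four-parameter logistic in pH.  Because the structuring amplitude
tracks amine deprotonation, the fitted inflection coincides with amine
half-ionization: pH₅₀ = pKa₂ (and slope m = 1/β₂) in the noise-free
limit.

**Chain descriptors.**  End-to-end distance, radius of gyration,
Shrake–Rupley solvent-accessible surface area (0.14 nm probe), overall
dipole moment and backbone torsion statistics (transoid fraction,
|φ| ≥ 150°), computed on PDB/XYZ structures or on the built-in
idealized all-trans chain and seeded random coils of the
ten-backbone-atom repeat.

## Worked example

```python
from paacs import (M_L_VAL, TitrationProtocol, simulate_titration,
                   compute_alpha, fit_katchalsky_spitnik)

curve = simulate_titration(M_L_VAL, TitrationProtocol(ph_noise_sd=0.02, seed=1))
acid, base = compute_alpha(curve, M_L_VAL)
print(fit_katchalsky_spitnik(base).summary())
```

```
Katchalsky-Spitnik fit
----------------------
group            : amine-base
pKa (apparent)   :    6.817 +/- 0.003
beta             :    1.296 +/- 0.009
R^2              :  0.99867
points used      : 32 (alpha in [0.2, 0.8])
```

The simulated bench titration (0.05 M repeat units, 0.1 M NaOH, 0.02 pH
noise) is reduced back to the generating amine parameters (pKa₂ = 6.8,
β₂ = 1.3) to within the noise.  The matching CD analysis on a synthetic
spectral series of the same polymer gives

```
Sigmoid transition fit (4-parameter logistic in pH)
---------------------------------------------------
lower plateau    :       94.9 +/- 75.1  mdeg/M/cm
upper plateau    :     6960.6 +/- 68.7  mdeg/M/cm
inflection pH    :      6.807 +/- 0.035
slope m          :      0.800 +/- 0.046  per pH
```

i.e. the chiroptical transition sits at the amine half-ionization point,
the central result the pipeline is built to quantify.  The same chain is
available from the shell:

```bash
paac run --seed 1 --out demo_run          # synth -> titrate -> speciate -> cd -> chain
paac speciate --out demo_spec             # just the speciation table
```

Each run writes tidy CSV tables (α series, speciation, differential
series, torsions), JSON fit reports and a `summary.json` carrying the
headline numbers, the configuration hash and the seed.

## Layout

- `paacs.ionization` — titration reduction, Katchalsky–Spitnik model,
  speciation, isoelectric point
- `paacs.cdspec` — CD normalization, differential series, peak finding,
  sigmoid transition model
- `paacs.chainmetrics` — conformational descriptors and the idealized
  chain builder
- `paacs.synth` — seeded generators for titration curves, CD series and
  coiled conformers
- `paacs.pipeline` / `paacs.cli` — YAML-configured runs and the `paac`
  command
- `docs/methods.md` — modelling assumptions, parameter choices and
  limitations
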