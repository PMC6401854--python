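"""End-to-end pipeline: configuration, stage execution and run reports.

A single YAML configuration (or a :class:`RunConfig` built in code)
drives any subset of the stages

``synth``    generate synthetic titration/CD/conformer inputs,
``titrate``  reduce the titration curve to alpha series, apparent pKa
             and Katchalsky-Spitnik beta per group,
``speciate`` tabulate the repeat-unit microstate fractions versus pH,
``cd``       normalize CD spectra, build the differential series and fit
             the structuring sigmoid,
``chain``    build/load conformers and compute their descriptors,

in dependency order.  Every run writes per-stage CSV/JSON outputs plus a
``summary.json`` carrying the headline numbers (pKa1, pKa2, beta values,
sigmoid inflection and its distance from pKa2, chain descriptors), the
configuration hash, package versions and the seed, so reruns are
reproducible and comparable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, cdspec, chainmetrics, io, ionization, synth
from .exceptions import ConfigurationError, PaacsError
from .ionization import ACID, BASE, IonizableGroup, PolymerSpec
from .polymers import BUILTIN_POLYMERS, CD_BANDS

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("synth", "titrate", "speciate", "cd", "chain")


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    ``polymer`` is either the name of a built-in parameter set or a
    mapping with ``name``, ``repeat_unit_mass``, ``pka1``, ``beta1``,
    ``pka2``, ``beta2``.  File inputs (``titration_csv``,
    ``cd_manifest``, ``structures``) are only needed when the matching
    stage runs on measured rather than synthetic data.
    """

    polymer: str | dict = "M-l-Ala"
    seed: int = 0
    outdir: str = "paacs_run"
    # analysis options
    alpha_window: tuple = (0.2, 0.8)
    sigmoid_wavelength: float | str | None = None  # None -> band center / peak
    sasa_probe_nm: float = 0.14
    sasa_points: int = 960
    transoid_threshold: float = 150.0
    ph_grid_step: float = 0.05
    # synthetic-data conditions
    titration: dict = field(default_factory=dict)
    cd_series: dict = field(default_factory=dict)
    n_units: int = 10
    n_coils: int = 3
    # measured inputs (optional)
    titration_csv: str | None = None
    titration_meta: dict = field(default_factory=dict)
    cd_manifest: str | None = None
    structures: list = field(default_factory=list)
    backbone: list | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(cfg) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    def polymer_spec(self) -> PolymerSpec:
        if isinstance(self.polymer, str):
            try:
                return BUILTIN_POLYMERS[self.polymer]
            except KeyError:
                raise ConfigurationError(
                    f"unknown polymer {self.polymer!r}; built-ins: "
                    f"{sorted(BUILTIN_POLYMERS)}"
                )
        p = dict(self.polymer)
        return PolymerSpec(
            name=p.get("name", "custom"),
            repeat_unit_mass=float(p["repeat_unit_mass"]),
            acid_group=IonizableGroup(ACID, float(p["pka1"]), float(p.get("beta1", 1.0))),
            base_group=IonizableGroup(BASE, float(p["pka2"]), float(p.get("beta2", 1.0))),
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig, stages) -> dict:
    """Execute the requested stages and return the run report.

    Stages run in the canonical order regardless of how they are listed.
    A stage failure is recorded in the report (and re-raised at the end
    as :class:`PaacsError`) but does not destroy the outputs of earlier
    stages.

    Raises
    ------
    ConfigurationError
        For an empty or unknown stage list.
    """
    stages = list(stages)
    if not stages:
        raise ConfigurationError("empty stage list: nothing to run")
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.polymer_spec()
    report: dict = {
        "polymer": spec.name,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "versions": {"paacs": __version__, "numpy": np.__version__},
        "stages": {},
    }
    summary: dict = {}
    state: dict = {}
    errors: list[str] = []

    for stage in ordered:
        try:
            runner = _RUNNERS[stage]
            report["stages"][stage] = runner(config, spec, state, summary, outdir)
        except PaacsError as err:
            errors.append(f"{stage}: {err}")
            report["stages"][stage] = {"error": str(err)}

    if "pka2_fit" in summary and "inflection_ph" in summary:
        summary["abs_inflection_minus_pka2"] = abs(
            summary["inflection_ph"] - summary["pka2_fit"]
        )
    report["summary"] = summary
    (outdir / "summary.json").write_text(
        json.dumps(report, indent=2, default=_json_default, sort_keys=True)
    )
    if errors:
        raise PaacsError("stage failures: " + "; ".join(errors))
    return report


# --------------------------------------------------------------------------
# stage runners (each returns a small manifest of what it wrote)
# --------------------------------------------------------------------------

def _stage_synth(config, spec, state, summary, outdir):
    protocol = synth.TitrationProtocol(
        ph_noise_sd=config.titration.get("ph_noise_sd", 0.02),
        seed=config.seed,
        **{
            k: v
            for k, v in config.titration.items()
            if k not in ("ph_noise_sd", "seed")
        },
    )
    curve = synth.simulate_titration(spec, protocol)
    io.write_titration_csv(curve, outdir / "titration.csv")
    state["curve"] = curve

    bands = CD_BANDS.get(spec.name)
    cd_kwargs = dict(config.cd_series)
    if bands is not None:
        cd_kwargs.setdefault(
            "pos_band", (bands.pos_center, bands.pos_width, bands.pos_amplitude)
        )
        cd_kwargs.setdefault(
            "neg_band",
            (bands.neg_center, bands.neg_width, bands.neg_amplitude, bands.blue_shift),
        )
    cd_kwargs.setdefault("noise_sd", 0.02)
    params = synth.CDSeriesParams(seed=config.seed + 1, **cd_kwargs)
    spectra = synth.simulate_cd_series(spec, params)
    io.write_cd_manifest(spectra, outdir / "cd")
    state["spectra"] = spectra

    extended = chainmetrics.build_extended_chain(n_units=config.n_units)
    io.write_xyz(extended, outdir / "extended.xyz", comment="all-trans chain")
    coils = [
        synth.make_coil(n_units=config.n_units, seed=config.seed + 10 + i)
        for i in range(config.n_coils)
    ]
    for i, coil in enumerate(coils):
        io.write_xyz(coil, outdir / f"coil_{i}.xyz", comment=f"coil seed {config.seed + 10 + i}")
    state["extended"] = extended
    state["coils"] = coils
    return {
        "titration_points": len(curve),
        "cd_spectra": len(spectra),
        "conformers": 1 + len(coils),
    }


def _stage_titrate(config, spec, state, summary, outdir):
    curve = state.get("curve")
    if curve is None:
        if config.titration_csv is None:
            raise ConfigurationError(
                "titrate stage needs the synth stage or a titration_csv input"
            )
        curve = io.read_titration_csv(config.titration_csv, **config.titration_meta)
    acid_series, base_series = ionization.compute_alpha(curve, spec)
    rows = []
    results = {}
    for series in (acid_series, base_series):
        label = "pka1" if series.group == ACID else "pka2"
        fit = ionization.fit_katchalsky_spitnik(series, config.alpha_window)
        half = ionization.half_neutralization_ph(series)
        results[series.group] = fit
        summary[f"{label}_half_neutralization"] = half
        summary[f"{label}_fit"] = fit.pka
        summary[f"beta{label[-1]}_fit"] = fit.beta
        mask = (series.alpha > 0.01) & (series.alpha < 0.99)
        for a, ph in zip(series.alpha[mask], series.ph[mask]):
            rows.append(
                {
                    "group": series.group,
                    "alpha": a,
                    "pH": ph,
                    "pKa_apparent": ionization.apparent_pka(a, ph),
                }
            )
    import pandas as pd

    pd.DataFrame(rows).to_csv(outdir / "alpha_series.csv", index=False)
    return {
        "alpha_points": len(rows),
        "carboxyl": results[ACID].summary(),
        "amine": results[BASE].summary(),
    }


def _stage_speciate(config, spec, state, summary, outdir):
    grid = np.arange(0.0, 14.0 + 1e-9, config.ph_grid_step)
    profile = ionization.speciation(spec, grid)
    profile.to_dataframe().to_csv(outdir / "speciation.csv", index=False)
    pi = ionization.isoelectric_point(spec)
    summary["isoelectric_point"] = pi
    state["profile"] = profile
    return {"grid_points": grid.size, "isoelectric_point": pi}


def _stage_cd(config, spec, state, summary, outdir):
    spectra = state.get("spectra")
    if spectra is None:
        if config.cd_manifest is None:
            raise ConfigurationError(
                "cd stage needs the synth stage or a cd_manifest input"
            )
        spectra = io.read_cd_manifest(config.cd_manifest)
    normalized = [cdspec.to_molar_ellipticity(s) for s in spectra]
    wavelength = config.sigmoid_wavelength
    if wavelength is None:
        bands = CD_BANDS.get(spec.name)
        wavelength = bands.pos_center if bands is not None else "peak"
    series = cdspec.differential_series(normalized, wavelength=wavelength)
    series.to_csv(outdir / "differential_series.csv", index=False)
    fit = cdspec.fit_sigmoid(series)
    summary["inflection_ph"] = fit.inflection_ph
    summary["pka2_fit"] = summary.get("pka2_fit", spec.base_group.pka)
    (outdir / "sigmoid_fit.json").write_text(
        json.dumps(
            {
                "lower_plateau": fit.lower_plateau,
                "upper_plateau": fit.upper_plateau,
                "inflection_ph": fit.inflection_ph,
                "slope": fit.slope,
                "rss": fit.rss,
                "n_points": fit.n_points,
                "plateau_intervals": fit.plateau_intervals(),
            },
            indent=2,
            default=_json_default,
        )
    )
    return {"spectra": len(normalized), "fit": fit.summary()}


def _stage_chain(config, spec, state, summary, outdir):
    conformers: dict[str, chainmetrics.Conformer] = {}
    if state.get("extended") is not None:
        conformers["extended"] = state["extended"]
        for i, coil in enumerate(state.get("coils", [])):
            conformers[f"coil_{i}"] = coil
    for entry in config.structures:
        path = entry["file"] if isinstance(entry, dict) else entry
        backbone = (
            entry.get("backbone", config.backbone)
            if isinstance(entry, dict)
            else config.backbone
        )
        conformers[Path(path).stem] = io.read_conformer(path, backbone=backbone)
    if not conformers:
        raise ConfigurationError(
            "chain stage needs the synth stage or structure inputs"
        )
    descriptors = {}
    torsion_rows = []
    for name, conf in conformers.items():
        ds = chainmetrics.describe(
            conf,
            probe_radius=config.sasa_probe_nm,
            n_sphere_points=config.sasa_points,
            transoid_threshold=config.transoid_threshold,
        )
        descriptors[name] = ds.to_dict()
        for j, angle in enumerate(ds.torsions):
            torsion_rows.append({"conformer": name, "index": j, "torsion_deg": angle})
    import pandas as pd

    pd.DataFrame(torsion_rows).to_csv(outdir / "torsions.csv", index=False)
    (outdir / "descriptors.json").write_text(
        json.dumps(descriptors, indent=2, default=_json_default, sort_keys=True)
    )
    summary["descriptors"] = descriptors
    return {"conformers": sorted(conformers)}


_RUNNERS = {
    "synth": _stage_synth,
    "titrate": _stage_titrate,
    "speciate": _stage_speciate,
    "cd": _stage_cd,
    "chain": _stage_chain,
}
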