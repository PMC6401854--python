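"""Readers and writers for the plain-text formats used by the pipeline.

Titration curves travel as two-column CSV (``volume_mL,pH``) with the
sample/titrant bookkeeping in a YAML sidecar or passed explicitly; CD
spectra as two-column CSV (``wavelength_nm,ellipticity_mdeg``), one file
per pH, listed in a YAML manifest; structures as PDB (via Biopython) or
extended XYZ with an optional per-atom partial-charge column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cdspec import CDSpectrum, repeat_unit_concentration
from .chainmetrics import Conformer
from .exceptions import ConfigurationError, DomainError
from .ionization import TitrationCurve

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_cd_spectrum",
    "write_cd_spectrum",
    "read_cd_manifest",
    "write_cd_manifest",
    "read_conformer",
    "read_xyz",
    "write_xyz",
    "read_pdb",
]


def read_titration_csv(path, **metadata) -> TitrationCurve:
    """Load a ``volume_mL,pH`` CSV; metadata become TitrationCurve fields."""
    df = pd.read_csv(path)
    missing = {"volume_mL", "pH"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    return TitrationCurve(
        volumes=df["volume_mL"].to_numpy(),
        ph=df["pH"].to_numpy(),
        **metadata,
    )


def write_titration_csv(curve: TitrationCurve, path) -> None:
    pd.DataFrame({"volume_mL": curve.volumes, "pH": curve.ph}).to_csv(
        path, index=False
    )


def read_cd_spectrum(path, ph: float, **metadata) -> CDSpectrum:
    """Load one two-column spectrum (``wavelength_nm,ellipticity_mdeg``).

    Accepts CSV with a header or plain whitespace/comma-separated
    two-column text without one.
    """
    try:
        df = pd.read_csv(path)
        if not {"wavelength_nm", "ellipticity_mdeg"} <= set(df.columns):
            raise ValueError
        lam = df["wavelength_nm"].to_numpy()
        theta = df["ellipticity_mdeg"].to_numpy()
    except ValueError:
        arr = np.loadtxt(path, delimiter=None, comments="#", ndmin=2)
        if arr.shape[1] < 2:
            raise ConfigurationError(f"{path}: expected two columns")
        lam, theta = arr[:, 0], arr[:, 1]
    return CDSpectrum(wavelengths=lam, ellipticity=theta, ph=ph, **metadata)


def write_cd_spectrum(spec: CDSpectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths, "ellipticity_mdeg": spec.ellipticity}
    ).to_csv(path, index=False)


def read_cd_manifest(path) -> list[CDSpectrum]:
    """Load a YAML manifest describing a pH series of spectra.

    Expected layout::

        path_length_cm: 1.0
        mass_conc_mg_ml: 0.5
        repeat_unit_mass: 243.26     # or repeat_unit_conc_M directly
        spectra:
          - {file: ph3.csv, ph: 3.0}
          - {file: ph4.csv, ph: 4.0, temperature_C: 25.0}

    File paths are resolved relative to the manifest.
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict) or "spectra" not in cfg:
        raise ConfigurationError(f"{path}: manifest must define 'spectra'")
    path_length = float(cfg.get("path_length_cm", 1.0))
    mass_conc = cfg.get("mass_conc_mg_ml")
    conc = cfg.get("repeat_unit_conc_M")
    if conc is None and mass_conc is not None and "repeat_unit_mass" in cfg:
        conc = repeat_unit_concentration(
            float(mass_conc), float(cfg["repeat_unit_mass"])
        )
    spectra = []
    for entry in cfg["spectra"]:
        spectra.append(
            read_cd_spectrum(
                path.parent / entry["file"],
                ph=float(entry["ph"]),
                path_length=path_length,
                mass_conc=None if mass_conc is None else float(mass_conc),
                repeat_unit_conc=None if conc is None else float(conc),
                temperature=entry.get("temperature_C"),
            )
        )
    return spectra


def write_cd_manifest(spectra, directory, **extra) -> Path:
    """Write per-pH spectrum CSVs plus a YAML manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(spectra):
        name = f"cd_{i:02d}_ph{s.ph:.2f}.csv"
        write_cd_spectrum(s, directory / name)
        entries.append({"file": name, "ph": float(s.ph)})
    first = spectra[0]
    manifest = {
        "path_length_cm": float(first.path_length),
        "spectra": entries,
    }
    if first.mass_conc is not None:
        manifest["mass_conc_mg_ml"] = float(first.mass_conc)
    if first.repeat_unit_conc is not None:
        manifest["repeat_unit_conc_M"] = float(first.repeat_unit_conc)
    manifest.update(extra)
    out = directory / "manifest.yaml"
    out.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def read_xyz(path) -> Conformer:
    """Read (extended) XYZ: ``element x y z [charge]`` per atom line."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise ConfigurationError(f"{path}: truncated XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ConfigurationError(f"{path}: first line must hold the atom count")
    body = lines[2 : 2 + n]
    if len(body) < n:
        raise ConfigurationError(f"{path}: expected {n} atom lines")
    elements, xyz, charges = [], [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise ConfigurationError(f"{path}: bad atom line {ln!r}")
        elements.append(parts[0])
        xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        charges.append(float(parts[4]) if len(parts) > 4 else np.nan)
    charges = np.asarray(charges)
    return Conformer(
        elements=np.array(elements, dtype=object),
        coords=np.asarray(xyz),
        charges=None if np.isnan(charges).any() else charges,
    )


def write_xyz(conf: Conformer, path, comment: str = "") -> None:
    """Write extended XYZ, including the charge column when present."""
    with open(path, "w") as fh:
        fh.write(f"{conf.n_atoms}\n{comment}\n")
        for i in range(conf.n_atoms):
            x, y, z = conf.coords[i]
            line = f"{conf.elements[i]:2s} {x:12.6f} {y:12.6f} {z:12.6f}"
            if conf.charges is not None:
                line += f" {conf.charges[i]:10.5f}"
            fh.write(line + "\n")


def read_pdb(path, backbone_atom_names=None) -> Conformer:
    """Read ATOM/HETATM records of a PDB file via Biopython.

    ``backbone_atom_names``: ordered main-chain selection — atoms whose
    name is in the list are flagged as backbone, in file order.
    Occupancy and altlocs are ignored (first model only).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("conf", str(path))
    model = next(structure.get_models())
    elements, xyz, names = [], [], []
    for atom in model.get_atoms():
        el = (atom.element or atom.get_name()[0]).strip().capitalize()
        elements.append(el)
        xyz.append(atom.coord.astype(float))
        names.append(atom.get_name().strip())
    backbone = np.empty(0, dtype=int)
    if backbone_atom_names:
        wanted = set(backbone_atom_names)
        backbone = np.array([i for i, nm in enumerate(names) if nm in wanted])
    return Conformer(
        elements=np.array(elements, dtype=object),
        coords=np.asarray(xyz),
        backbone=backbone,
    )


def read_conformer(path, backbone=None) -> Conformer:
    """Dispatch on extension: ``.pdb`` -> PDB, otherwise extended XYZ.

    ``backbone`` is a list of atom names (PDB) or indices (any format).
    """
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        names = backbone if backbone and isinstance(backbone[0], str) else None
        conf = read_pdb(path, backbone_atom_names=names)
        if backbone and not isinstance(backbone[0], str):
            conf.backbone = np.asarray(backbone, dtype=int)
        return conf
    conf = read_xyz(path)
    if backbone:
        if isinstance(backbone[0], str):
            raise DomainError("XYZ backbone selection must use atom indices")
        conf.backbone = np.asarray(backbone, dtype=int)
    return conf
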