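"""Conformational descriptors of PAAC oligomer structures.

Computes the size and shape quantities used to characterize single-chain
compaction — end-to-end distance, radius of gyration, solvent-accessible
surface area (Shrake-Rupley sphere sampling), overall dipole moment and
backbone torsion statistics — plus an idealized all-trans builder for the
ten-backbone-atom PAAC repeat unit (N-C-C-C(O)-N-C-N-C(O)-C-C).

Coordinates are stored in Angstrom; reported lengths are nm, areas nm^2,
dipoles Debye, torsions degrees in (-180, 180].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import AnalysisError, DomainError

__all__ = [
    "BONDI_RADII",
    "ATOM_MASSES",
    "Conformer",
    "DescriptorSet",
    "end_to_end",
    "radius_of_gyration",
    "DipoleResult",
    "dipole_moment",
    "sasa",
    "backbone_torsions",
    "transoid_fraction",
    "RepeatTemplate",
    "PAAC_TEMPLATE",
    "build_extended_chain",
    "chain_from_torsions",
    "describe",
]

# Bondi van der Waals radii, Angstrom
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}
_DEFAULT_RADIUS = 1.70

ATOM_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "Cl": 35.45, "Br": 79.904, "I": 126.904,
}
_DEFAULT_MASS = 12.011

E_ANGSTROM_TO_DEBYE = 4.80320  # 1 e*Angstrom in Debye


@dataclass
class Conformer:
    """A molecular structure: elements, coordinates and per-atom attributes.

    ``coords`` in Angstrom, ``charges`` in elementary charges (optional),
    ``radii`` in Angstrom (Bondi defaults by element), ``masses`` in amu
    (standard atomic weights by element), ``backbone`` an ordered index
    list of the main-chain atoms.
    """

    elements: np.ndarray
    coords: np.ndarray
    charges: np.ndarray | None = None
    radii: np.ndarray | None = None
    masses: np.ndarray | None = None
    backbone: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.elements.size
        if self.coords.shape != (n, 3):
            raise DomainError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise DomainError("coordinates must be finite")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (n,):
                raise DomainError("charges must have one value per atom")
        if self.radii is None:
            self.radii = np.array(
                [BONDI_RADII.get(e, _DEFAULT_RADIUS) for e in self.elements]
            )
        else:
            self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.shape != (n,) or np.any(self.radii <= 0):
            raise DomainError("radii must be positive, one per atom")
        if self.masses is None:
            self.masses = np.array(
                [ATOM_MASSES.get(e, _DEFAULT_MASS) for e in self.elements]
            )
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (n,):
            raise DomainError("masses must have one value per atom")
        self.backbone = np.asarray(self.backbone, dtype=int)
        if self.backbone.size and (
            self.backbone.min() < 0 or self.backbone.max() >= n
        ):
            raise DomainError("backbone indices out of range")

    @property
    def n_atoms(self) -> int:
        return self.elements.size

    def backbone_coords(self) -> np.ndarray:
        if self.backbone.size < 2:
            raise AnalysisError("conformer has no usable backbone ordering")
        return self.coords[self.backbone]

    def transformed(self, rotation=None, translation=None) -> "Conformer":
        """Copy with coordinates rigidly rotated and/or translated."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return Conformer(
            self.elements.copy(), xyz,
            None if self.charges is None else self.charges.copy(),
            self.radii.copy(), self.masses.copy(), self.backbone.copy(),
        )


def end_to_end(conf: Conformer) -> float:
    """Distance between the first and last backbone atoms, nm."""
    bb = conf.backbone_coords()
    return float(np.linalg.norm(bb[-1] - bb[0])) / 10.0


def radius_of_gyration(conf: Conformer, mass_weighted: bool = True) -> float:
    """Radius of gyration sqrt(sum m_i |r_i - r_cm|^2 / sum m_i), nm."""
    if conf.n_atoms < 2:
        raise DomainError("need at least two atoms")
    w = conf.masses if mass_weighted else np.ones(conf.n_atoms)
    com = np.average(conf.coords, axis=0, weights=w)
    sq = np.sum((conf.coords - com) ** 2, axis=1)
    return math.sqrt(float(np.average(sq, weights=w))) / 10.0


class DipoleResult(NamedTuple):
    debye: float
    origin: str
    net_charge: float


def dipole_moment(conf: Conformer, origin: str = "center_of_charge") -> DipoleResult:
    """Magnitude of the molecular dipole, Debye.

    ``|sum q_i (r_i - r_0)|`` with r_0 the chosen origin.  For a net-neutral
    system the value is origin-independent; for charged systems it is not,
    so the origin convention is returned with the value.  The charge
    center uses absolute-charge weights (falling back to the centroid if
    all charges vanish).
    """
    if conf.charges is None:
        raise DomainError("dipole moment requires per-atom charges")
    q = conf.charges
    if origin == "center_of_mass":
        r0 = np.average(conf.coords, axis=0, weights=conf.masses)
    elif origin == "center_of_charge":
        w = np.abs(q)
        if w.sum() > 0:
            r0 = np.average(conf.coords, axis=0, weights=w)
        else:
            r0 = conf.coords.mean(axis=0)
    else:
        raise DomainError(f"unknown dipole origin {origin!r}")
    mu = np.sum(q[:, None] * (conf.coords - r0), axis=0)
    return DipoleResult(
        debye=float(np.linalg.norm(mu)) * E_ANGSTROM_TO_DEBYE,
        origin=origin,
        net_charge=float(q.sum()),
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    conf: Conformer,
    probe_radius: float = 0.14,
    n_sphere_points: int = 960,
) -> float:
    """Solvent-accessible surface area by Shrake-Rupley sampling, nm^2.

    Each atom is expanded by the probe radius (``probe_radius`` in nm,
    default 0.14, roughly a water molecule) and sampled with a
    deterministic golden-spiral point set; the accessible fraction of
    each expanded sphere contributes ``f * 4 pi (r_i + p)^2``.  Exact
    duplicate atoms (same position and radius) are collapsed first so
    they neither double-count nor spuriously bury one another.
    """
    if probe_radius < 0:
        raise DomainError("probe_radius must be non-negative")
    probe = probe_radius * 10.0  # nm -> Angstrom
    xyz, rad = conf.coords, conf.radii
    # collapse exact duplicates
    key = np.round(np.column_stack([xyz, rad]), 6)
    _, keep = np.unique(key, axis=0, return_index=True)
    keep.sort()
    xyz, rad = xyz[keep], rad[keep]
    n = len(keep)
    ext = rad + probe
    pts = _fibonacci_sphere(n_sphere_points)
    tree = cKDTree(xyz)
    area = 0.0
    max_ext = ext.max()
    for i in range(n):
        neighbours = tree.query_ball_point(xyz[i], ext[i] + max_ext)
        neighbours = [j for j in neighbours if j != i]
        sample = xyz[i] + ext[i] * pts
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((sample - xyz[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
            if not accessible.any():
                break
        frac = accessible.mean()
        area += frac * 4.0 * math.pi * ext[i] ** 2
    return area / 100.0  # Angstrom^2 -> nm^2


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral of four points, degrees in (-180, 180]; NaN if collinear."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        return float("nan")
    b2u = b2 / np.linalg.norm(b2)
    m1 = np.cross(n1, b2u)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def backbone_torsions(conf: Conformer) -> np.ndarray:
    """Dihedral angle of every four consecutive backbone atoms, degrees.

    Collinear triples yield NaN (undefined torsion) rather than an error.
    """
    bb = conf.backbone_coords()
    if bb.shape[0] < 4:
        raise AnalysisError("backbone needs at least 4 atoms for torsions")
    return np.array(
        [_dihedral(bb[i], bb[i + 1], bb[i + 2], bb[i + 3])
         for i in range(bb.shape[0] - 3)]
    )


def transoid_fraction(torsions, threshold: float = 150.0) -> float:
    """Share of defined torsions with |angle| >= threshold (degrees)."""
    t = np.asarray(torsions, dtype=float)
    ok = np.isfinite(t)
    if not ok.any():
        raise AnalysisError("no defined torsions")
    return float(np.mean(np.abs(t[ok]) >= threshold))


# ---------------------------------------------------------------------------
# Idealized chain building (internal coordinates, NeRF placement)
# ---------------------------------------------------------------------------

TETRAHEDRAL = 109.5
TRIGONAL = 120.0


@dataclass(frozen=True)
class RepeatTemplate:
    """Internal-coordinate template of one backbone repeat.

    ``elements[i]`` is the i-th backbone atom of the repeat;
    ``bond_lengths[i]`` the bond from the previous backbone atom (the
    last atom of the preceding repeat for i = 0), Angstrom;
    ``bond_angles[i]`` the angle at that previous atom, degrees.
    Side pendants are attached as one pseudo-atom per repeat on the atom
    at ``side_attach`` (the tertiary amine nitrogen for PAACs).
    """

    elements: tuple
    bond_lengths: tuple
    bond_angles: tuple
    side_attach: int = 0
    side_bond: float = 1.53
    side_angle: float = TETRAHEDRAL
    side_element: str = "C"
    side_mass: float = 74.0     # CH(R)COOH pendant lump, amu
    side_radius: float = 2.5    # pseudo-atom envelope, Angstrom

    def __post_init__(self) -> None:
        k = len(self.elements)
        if len(self.bond_lengths) != k or len(self.bond_angles) != k:
            raise DomainError("template arrays must have equal length")
        if k < 2:
            raise DomainError("template needs at least two backbone atoms")


# PAAC main chain: tert-amine N, two ethylene C, amide C(O)-N,
# aminal methylene C, amide N-C(O), two ethylene C  (10 atoms/repeat)
PAAC_TEMPLATE = RepeatTemplate(
    elements=("N", "C", "C", "C", "N", "C", "N", "C", "C", "C"),
    bond_lengths=(1.47, 1.47, 1.53, 1.53, 1.33, 1.47, 1.47, 1.33, 1.53, 1.53),
    bond_angles=(
        TETRAHEDRAL,  # at preceding sp3 C
        TETRAHEDRAL,  # at amine N
        TETRAHEDRAL,
        TETRAHEDRAL,
        TRIGONAL,     # at carbonyl C
        TRIGONAL,     # at amide N
        TETRAHEDRAL,  # at methylene C
        TRIGONAL,     # at amide N
        TRIGONAL,     # at carbonyl C
        TETRAHEDRAL,
    ),
)


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Natural-extension (NeRF) placement of the next atom from three."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    # z-component sign chosen so the placed dihedral matches the signed
    # (IUPAC) convention used by the torsion measurement
    d2 = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(phi),
            -bond * math.sin(theta) * math.sin(phi),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        # degenerate (collinear) support: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d2


def chain_from_torsions(
    torsions,
    template: RepeatTemplate = PAAC_TEMPLATE,
    n_units: int = 10,
    side_chain: bool = True,
) -> Conformer:
    """Build a chain with prescribed backbone torsions.

    ``torsions`` supplies the dihedral for every backbone atom placed
    after the first three, i.e. ``n_units * len(template) - 3`` values in
    degrees.  Bond lengths and angles come from the template; repeat k
    contributes atoms ``[k*P, (k+1)*P)`` of the backbone (P atoms per
    repeat).
    """
    if n_units < 1:
        raise DomainError("n_units must be >= 1")
    p = len(template.elements)
    n_bb = n_units * p
    torsions = np.asarray(torsions, dtype=float)
    if torsions.shape != (n_bb - 3,):
        raise DomainError(
            f"expected {n_bb - 3} torsions for {n_units} repeat units, "
            f"got {torsions.shape}"
        )
    elements = [template.elements[i % p] for i in range(n_bb)]
    lengths = [template.bond_lengths[i % p] for i in range(n_bb)]
    angles = [template.bond_angles[i % p] for i in range(n_bb)]

    xyz = np.zeros((n_bb, 3))
    xyz[0] = (0.0, 0.0, 0.0)
    xyz[1] = (lengths[1], 0.0, 0.0)
    th = math.radians(angles[2])
    xyz[2] = xyz[1] + lengths[2] * np.array([-math.cos(th), math.sin(th), 0.0])
    for i in range(3, n_bb):
        xyz[i] = _place_atom(
            xyz[i - 3], xyz[i - 2], xyz[i - 1],
            lengths[i], angles[i], torsions[i - 3],
        )

    all_elements = list(elements)
    all_xyz = [xyz]
    masses = [ATOM_MASSES.get(e, _DEFAULT_MASS) for e in elements]
    radii = [BONDI_RADII.get(e, _DEFAULT_RADIUS) for e in elements]
    if side_chain:
        side_xyz = []
        for k in range(n_units):
            i0 = k * p + template.side_attach
            # support atoms: the two following backbone atoms (always exist)
            pos = _place_atom(
                xyz[i0 + 2], xyz[i0 + 1], xyz[i0],
                template.side_bond, template.side_angle, 60.0,
            )
            side_xyz.append(pos)
            all_elements.append(template.side_element)
            masses.append(template.side_mass)
            radii.append(template.side_radius)
        all_xyz.append(np.array(side_xyz))
    coords = np.vstack(all_xyz)
    return Conformer(
        elements=np.array(all_elements, dtype=object),
        coords=coords,
        radii=np.array(radii),
        masses=np.array(masses),
        backbone=np.arange(n_bb),
    )


def build_extended_chain(
    template: RepeatTemplate = PAAC_TEMPLATE,
    n_units: int = 10,
    side_chain: bool = True,
) -> Conformer:
    """Fully elongated (all-trans, every torsion 180 deg) PAAC chain."""
    p = len(template.elements)
    torsions = np.full(n_units * p - 3, 180.0)
    return chain_from_torsions(torsions, template, n_units, side_chain)


@dataclass(frozen=True)
class DescriptorSet:
    """Bundle of the standard conformational descriptors of one structure."""

    end_to_end: float            # nm
    rg: float                    # nm
    sasa: float                  # nm^2
    dipole: DipoleResult | None  # Debye, None without charges
    torsions: np.ndarray         # degrees
    transoid_fraction: float

    def to_dict(self) -> dict:
        out = {
            "end_to_end_nm": self.end_to_end,
            "rg_nm": self.rg,
            "sasa_nm2": self.sasa,
            "transoid_fraction": self.transoid_fraction,
            "n_torsions": int(self.torsions.size),
        }
        if self.dipole is not None:
            out["dipole_debye"] = self.dipole.debye
            out["dipole_origin"] = self.dipole.origin
            out["net_charge_e"] = self.dipole.net_charge
        return out


def describe(
    conf: Conformer,
    probe_radius: float = 0.14,
    n_sphere_points: int = 960,
    transoid_threshold: float = 150.0,
) -> DescriptorSet:
    """Compute the full descriptor set of one conformer."""
    torsions = backbone_torsions(conf)
    return DescriptorSet(
        end_to_end=end_to_end(conf),
        rg=radius_of_gyration(conf),
        sasa=sasa(conf, probe_radius, n_sphere_points),
        dipole=None if conf.charges is None else dipole_moment(conf),
        torsions=torsions,
        transoid_fraction=transoid_fraction(torsions, transoid_threshold),
    )
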