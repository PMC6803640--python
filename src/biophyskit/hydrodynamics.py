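"""Structure- and measurement-derived hydrodynamic quantities.

Structure side: radius of gyration and Shrake-Rupley solvent-accessible
surface area (SASA) split into hydrophobic (C, S atoms) and hydrophilic
(everything else) contributions.  Measurement side: the Stokes-Einstein
relation, second-order cumulant analysis of DLS correlograms, and
size-exclusion chromatography (SEC) calibration of apparent molecular
weight from elution volume.

Internally all coordinates and radii are in angstroms; reported lengths
are nanometres and areas square nanometres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .errors import FitFailureError, InsufficientDataError, PreconditionError

__all__ = [
    "StructureModel",
    "SasaResult",
    "SecCalibration",
    "CumulantFit",
    "VDW_RADII",
    "ATOMIC_MASSES",
    "BOLTZMANN",
    "WATER_VISCOSITY_37C",
    "classify_polarity",
    "radius_of_gyration",
    "sasa",
    "stokes_einstein_diameter",
    "diffusion_from_diameter",
    "scattering_vector",
    "dls_cumulant_diameter",
    "sec_calibrate",
    "mw_from_elution",
]

BOLTZMANN = 1.380649e-23  # J/K
#: Dynamic viscosity of water at 37 degC (Pa*s), the DLS bath temperature.
WATER_VISCOSITY_37C = 6.913e-4

#: van der Waals radii (angstrom), Bondi (1964) with Rowland & Taylor H.
VDW_RADII = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

#: Standard atomic weights (u) for mass-weighted geometry.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45,
}
DEFAULT_ATOMIC_MASS = 12.011

#: Apolar elements for the hydrophobic/hydrophilic SASA partition.
HYDROPHOBIC_ELEMENTS = frozenset({"C", "S"})


def classify_polarity(element: str) -> str:
    """'hydrophobic' for carbon and sulfur, 'hydrophilic' otherwise."""
    return "hydrophobic" if element.upper() in HYDROPHOBIC_ELEMENTS else "hydrophilic"


@dataclass
class StructureModel:
    """A set of atoms with everything the surface/shape metrics need.

    coords : (n, 3) angstrom; radii : (n,) vdW radii, angstrom;
    masses : (n,) u; elements, residue names/indices, and a per-atom
    ``hydrophobic`` mask derived from the element.
    """

    coords: np.ndarray
    radii: np.ndarray
    masses: np.ndarray
    elements: np.ndarray
    residue_names: np.ndarray
    residue_indices: np.ndarray
    hydrophobic: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        if n < 1:
            raise PreconditionError("a structure needs at least one atom")
        self.radii = np.asarray(self.radii, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        for name in ("radii", "masses", "elements", "residue_names",
                     "residue_indices", "hydrophobic"):
            if len(getattr(self, name)) != n:
                raise PreconditionError(f"{name} length does not match coords")
        if np.any(self.radii <= 0):
            raise PreconditionError("all vdW radii must be > 0")
        if not np.all(np.isfinite(self.coords)):
            raise PreconditionError("coordinates must be finite")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_arrays(cls, coords, elements, residue_names=None,
                    residue_indices=None, radii=None, masses=None,
                    label: str = "") -> "StructureModel":
        """Build a structure from coordinates and element symbols; radii,
        masses and polarity are filled from the bundled element tables
        unless given explicitly."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = coords.shape[0]
        elements = np.asarray([str(e).upper() for e in elements])
        if radii is None:
            radii = np.array([VDW_RADII.get(e, DEFAULT_VDW_RADIUS) for e in elements])
        if masses is None:
            masses = np.array([ATOMIC_MASSES.get(e, DEFAULT_ATOMIC_MASS) for e in elements])
        if residue_names is None:
            residue_names = np.array(["UNK"] * n)
        if residue_indices is None:
            residue_indices = np.arange(1, n + 1)
        hydrophobic = np.array([e in HYDROPHOBIC_ELEMENTS for e in elements])
        return cls(coords=coords, radii=np.asarray(radii, dtype=float),
                   masses=np.asarray(masses, dtype=float), elements=elements,
                   residue_names=np.asarray(residue_names),
                   residue_indices=np.asarray(residue_indices),
                   hydrophobic=hydrophobic, label=label)

    @classmethod
    def from_pdb(cls, path, include_hetero: bool = False,
                 include_hydrogens: bool = False) -> "StructureModel":
        """Read the first model of a PDB file (Bio.PDB parser).

        Waters, ions and other heteroatoms are excluded by default;
        hydrogens are excluded by default (united-atom convention for
        structures deposited without them).
        """
        from Bio.PDB import PDBParser

        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("s", str(path))
        model = next(structure.get_models())
        coords, elements, resnames, resids = [], [], [], []
        for chain in model:
            for residue in chain:
                het = residue.id[0].strip()
                if het and not include_hetero:
                    continue
                for atom in residue:
                    elem = (atom.element or atom.get_name()[0]).upper()
                    if elem == "H" and not include_hydrogens:
                        continue
                    coords.append(atom.get_coord())
                    elements.append(elem)
                    resnames.append(residue.get_resname())
                    resids.append(residue.id[1])
        if not coords:
            raise PreconditionError(f"no atoms read from {path}")
        return cls.from_arrays(np.array(coords), elements, np.array(resnames),
                               np.array(resids), label=str(path))


def radius_of_gyration(structure: StructureModel, weighting: str = "mass") -> float:
    """Radius of gyration in nm.

    Rg = sqrt( sum_i w_i |r_i - r_cm|^2 / sum_i w_i ) with w_i the atomic
    mass (default) or 1 (uniform), and r_cm the w-weighted centroid.
    """
    if weighting not in ("mass", "uniform"):
        raise PreconditionError(f"unknown weighting {weighting!r}")
    if len(structure) == 1:
        warnings.warn("radius of gyration of a single atom is 0", stacklevel=2)
        return 0.0
    w = structure.masses if weighting == "mass" else np.ones(len(structure))
    com = np.average(structure.coords, axis=0, weights=w)
    sq = np.sum((structure.coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=w))) / 10.0  # A -> nm


@dataclass
class SasaResult:
    """Per-atom and class-resolved solvent-accessible surface areas.

    ``per_atom`` is in square angstroms; the three totals are in nm^2 and
    satisfy hydrophobic + hydrophilic == total exactly (they are sums over
    the same per-atom vector).
    """

    per_atom: np.ndarray  # A^2
    hydrophobic_nm2: float
    hydrophilic_nm2: float
    probe_radius: float
    n_sphere_points: int

    @property
    def total_nm2(self) -> float:
        return self.hydrophobic_nm2 + self.hydrophilic_nm2


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden-spiral
    lattice, as in the classic Shrake-Rupley implementations)."""
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(structure: StructureModel, probe_radius: float = 1.4,
         n_sphere_points: int = 960) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom is expanded by the probe radius and sampled with a
    golden-spiral point lattice; a point is accessible if it lies outside
    every neighbouring expanded sphere.  Area_i = 4*pi*(r_i+p)^2 *
    (accessible fraction).  Coincident duplicate atoms simply bury each
    other (zero marginal area) — not an error.
    """
    if probe_radius <= 0:
        raise PreconditionError("probe radius must be > 0")
    if n_sphere_points < 100:
        raise PreconditionError("need >= 100 sphere points")
    n = len(structure)
    expanded = structure.radii + probe_radius
    pts = _sphere_points(n_sphere_points)
    tree = cKDTree(structure.coords)
    max_reach = 2.0 * expanded.max()
    pairs = tree.query_pairs(max_reach, output_type="ndarray")
    neighbours: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        d = np.linalg.norm(structure.coords[i] - structure.coords[j])
        if d < expanded[i] + expanded[j]:
            neighbours[i].append(j)
            neighbours[j].append(i)

    per_atom = np.empty(n)
    for i in range(n):
        sphere = structure.coords[i] + expanded[i] * pts
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours[i]:
            if not exposed.any():
                break
            # exactly coincident equal-size duplicates would bury each other
            # completely; the lower index keeps the shared surface so the
            # duplicate contributes zero marginal area
            coincident = (structure.coords[i] == structure.coords[j]).all()
            if coincident and expanded[j] == expanded[i] and j > i:
                continue
            d2 = np.sum((sphere - structure.coords[j]) ** 2, axis=1)
            # tolerance keeps points exactly on a burying sphere (coincident
            # duplicates) classified as buried despite rounding
            exposed &= d2 >= expanded[j] ** 2 * (1.0 + 1e-12)
        frac = exposed.sum() / n_sphere_points
        per_atom[i] = 4.0 * math.pi * expanded[i] ** 2 * frac

    hpho = float(per_atom[structure.hydrophobic].sum()) / 100.0  # A^2 -> nm^2
    hphi = float(per_atom[~structure.hydrophobic].sum()) / 100.0
    return SasaResult(per_atom=per_atom, hydrophobic_nm2=hpho,
                      hydrophilic_nm2=hphi, probe_radius=probe_radius,
                      n_sphere_points=n_sphere_points)


def stokes_einstein_diameter(diffusion_coefficient: float, temperature: float,
                             viscosity: float) -> float:
    """Hydrodynamic diameter d = kB*T / (3*pi*eta*D), returned in nm.

    diffusion_coefficient in m^2/s, temperature in K, viscosity in Pa*s.
    """
    if min(diffusion_coefficient, temperature, viscosity) <= 0:
        raise PreconditionError("D, T and eta must all be > 0")
    d_m = BOLTZMANN * temperature / (3.0 * math.pi * viscosity * diffusion_coefficient)
    return d_m * 1e9


def diffusion_from_diameter(diameter_nm: float, temperature: float,
                            viscosity: float) -> float:
    """Inverse of :func:`stokes_einstein_diameter` (m^2/s)."""
    if min(diameter_nm, temperature, viscosity) <= 0:
        raise PreconditionError("d, T and eta must all be > 0")
    return BOLTZMANN * temperature / (3.0 * math.pi * viscosity * diameter_nm * 1e-9)


def scattering_vector(wavelength_m: float = 633e-9, refractive_index: float = 1.330,
                      angle_deg: float = 173.0) -> float:
    """Magnitude of the scattering vector q = 4*pi*n*sin(theta/2)/lambda
    (1/m).  Defaults are the 633 nm backscatter (173 degrees) geometry of
    a Zetasizer Nano-S in aqueous buffer."""
    return 4.0 * math.pi * refractive_index * math.sin(math.radians(angle_deg) / 2.0) / wavelength_m


@dataclass
class CumulantFit:
    """Second-order cumulant reduction of a DLS correlogram."""

    diameter_nm: float
    pdi: float
    gamma: float  # mean decay rate, 1/s
    mu2: float  # second cumulant, 1/s^2
    diffusion_coefficient: float  # m^2/s
    intercept: float  # fitted B of g2-1 at tau=0


def dls_cumulant_diameter(lag_times, g2_minus_1, temperature: float = 310.15,
                          viscosity: float = WATER_VISCOSITY_37C,
                          q: float | None = None) -> CumulantFit:
    """Method-of-cumulants DLS analysis.

    Fits ln(g2-1) = ln B - 2*Gamma*tau + mu2*tau^2 by weighted least
    squares (weights g2-1, countering the log-transform's amplification of
    tail noise), converts Gamma to a diffusion coefficient D = Gamma/q^2
    and then to a hydrodynamic diameter via Stokes-Einstein; the
    polydispersity index is PDI = mu2/Gamma^2.

    Raises :class:`FitFailureError` for non-decaying correlograms.
    """
    tau = np.asarray(lag_times, dtype=float)
    y = np.asarray(g2_minus_1, dtype=float)
    if tau.size < 10:
        raise PreconditionError("cumulant fit needs >= 10 lag times")
    if np.any(y <= 0):
        raise PreconditionError("g2-1 must be positive over the fitted range")
    if q is None:
        q = scattering_vector()
    lny = np.log(y)
    # weighted quadratic fit in tau
    coeffs = np.polynomial.polynomial.polyfit(tau, lny, 2, w=y)
    lnb, c1, c2 = coeffs
    gamma = -c1 / 2.0
    mu2 = c2
    # a real correlogram decays appreciably over its lag window; numerically
    # flat data yields gamma ~ 0 (either sign) and must be rejected
    if gamma <= 0 or gamma * (tau.max() - tau.min()) < 1e-6:
        raise FitFailureError("correlogram does not decay: mean decay rate <= 0")
    diffusion = gamma / q**2
    diameter = stokes_einstein_diameter(diffusion, temperature, viscosity)
    return CumulantFit(diameter_nm=diameter, pdi=float(mu2 / gamma**2),
                       gamma=float(gamma), mu2=float(mu2),
                       diffusion_coefficient=float(diffusion),
                       intercept=float(np.exp(lnb)))


@dataclass
class SecCalibration:
    """SEC calibration line log10(MW/kDa) = slope*V + intercept."""

    slope: float
    intercept: float
    r_squared: float
    v_min: float
    v_max: float

    def __post_init__(self):
        if self.slope >= 0:
            warnings.warn(
                "SEC calibration slope is non-negative; larger species "
                "should elute earlier", stacklevel=2)


def sec_calibrate(standards) -> SecCalibration:
    """Least-squares SEC calibration from (MW_kDa, elution_volume) pairs."""
    arr = np.asarray(list(standards), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InsufficientDataError("need >= 3 (MW, elution volume) standards")
    mw, vol = arr[:, 0], arr[:, 1]
    if np.unique(vol).size < 3:
        raise InsufficientDataError("standards must have >= 3 distinct volumes")
    if np.any(mw <= 0):
        raise PreconditionError("standard MWs must be > 0")
    fit = stats.linregress(vol, np.log10(mw))
    return SecCalibration(slope=float(fit.slope), intercept=float(fit.intercept),
                          r_squared=float(fit.rvalue**2),
                          v_min=float(vol.min()), v_max=float(vol.max()))


def mw_from_elution(cal: SecCalibration, elution_volume: float) -> float:
    """Apparent MW (kDa) at an elution volume: 10^(slope*V + intercept).

    Volumes outside the calibrated range are allowed but flagged with a
    warning (extrapolation)."""
    if not (cal.v_min <= elution_volume <= cal.v_max):
        warnings.warn(
            f"elution volume {elution_volume:g} outside calibrated range "
            f"[{cal.v_min:g}, {cal.v_max:g}]: extrapolating", stacklevel=2)
    return float(10.0 ** (cal.slope * elution_volume + cal.intercept))
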