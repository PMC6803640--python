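"""Ground-truth-bearing synthetic inputs for every analysis in the package.

Each generator is deterministic given a seed and returns the generated
data together with a ``ground_truth`` record carrying everything needed
to score downstream recovery (parameters, seed, noise level) without
re-reading the generator's internals.

Defaults mirror the CIB2 / alpha7B-peptide study conditions: two-fold
dilution series from 30 uM, 120 s / 200 s injection cycles at 1 s
sampling, Rmax = 500 RU, additive Gaussian noise of 1 RU, and the
published Mg2+-only kinetic constants as the generating truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import PreconditionError
from .flexibility import Trajectory
from .hydrodynamics import StructureModel
from .ms_utils import PeakList, neutral_to_mz
from .spr_kinetics import (
    InjectionProtocol,
    RateConstants,
    Sensorgram,
    simulate_series,
)

__all__ = [
    "NoiseSpec",
    "SyntheticSensorgramSet",
    "SyntheticIsotherm",
    "make_series",
    "noisy_sensorgrams",
    "noisy_isotherm",
    "synthetic_peaks",
    "toy_structure",
    "two_point_structure",
    "bead_sphere_structure",
    "dumbbell_structure",
    "fluctuation_trajectory",
    "monodisperse_correlogram",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive homoscedastic Gaussian noise, optional linear drift.

    sigma in the data's response units (RU for sensorgrams); drift in
    RU/s.  The seed fixes the entire random stream.
    """

    sigma: float = 1.0
    drift: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise PreconditionError("noise sigma must be >= 0")


def make_series(c_max: float, dilution_factor: float = 2.0, n_steps: int = 8) -> np.ndarray:
    """Descending geometric concentration series (molar).

    The default 8-step two-fold series from 30 uM spans 30 uM down to
    0.234 uM, i.e. the sub-uM-to-tens-of-uM window typical of weak
    peptide-protein interactions.
    """
    if c_max <= 0:
        raise PreconditionError("c_max must be > 0")
    if dilution_factor <= 1:
        raise PreconditionError("dilution factor must be > 1")
    if n_steps < 2:
        raise PreconditionError("need >= 2 steps")
    return c_max / dilution_factor ** np.arange(n_steps)


@dataclass
class SyntheticSensorgramSet:
    """Noisy sensorgrams plus the generating ground truth."""

    sensorgrams: list
    ground_truth: dict = field(default_factory=dict)


def noisy_sensorgrams(
    k: RateConstants,
    rmax: float = 500.0,
    concentrations=None,
    protocol: InjectionProtocol | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> SyntheticSensorgramSet:
    """Simulate a concentration series and add seeded Gaussian noise.

    With ``noise.sigma == 0`` and no drift the traces are bit-identical to
    the simulator output.  Species trajectories are dropped from the noisy
    traces (an instrument only reports the response).
    """
    if concentrations is None:
        concentrations = make_series(30e-6)
    if protocol is None:
        protocol = InjectionProtocol(analyte_concentration=0.0)
    clean = simulate_series(k, rmax, concentrations, protocol)
    rng = np.random.default_rng(noise.seed)
    noisy = []
    for s in clean:
        r = s.response
        if noise.sigma > 0:
            r = r + rng.normal(0.0, noise.sigma, r.shape)
        if noise.drift != 0.0:
            r = r + noise.drift * s.time
        noisy.append(Sensorgram(time=s.time.copy(), response=r,
                                protocol=s.protocol, species=None))
    truth = {
        "ka1": k.ka1, "ka2": k.ka2, "kd1": k.kd1, "kd2": k.kd2,
        "rmax": rmax,
        "concentrations_molar": list(np.asarray(concentrations, dtype=float)),
        "noise": asdict(noise),
        "protocol": asdict(protocol),
    }
    return SyntheticSensorgramSet(sensorgrams=noisy, ground_truth=truth)


@dataclass
class SyntheticIsotherm:
    """(concentration, equilibrium response) table plus ground truth."""

    concentrations: np.ndarray  # M, replicates concatenated
    responses: np.ndarray  # RU
    ground_truth: dict = field(default_factory=dict)

    def pairs(self):
        return np.column_stack([self.concentrations, self.responses])


def noisy_isotherm(
    kd: float,
    rmax_eq: float,
    concentrations=None,
    n_replicates: int = 4,
    relative_sigma: float = 0.02,
    seed: int = 0,
) -> SyntheticIsotherm:
    """Equilibrium-response table from a saturation hyperbola.

    Defaults emulate a steady-state avidity titration of a weak
    interaction: 4 replicate series of 7 two-fold dilutions from 1 mM
    (bracketing a ~0.2 mM KD), with multiplicative 2% Gaussian noise.
    """
    if kd <= 0 or rmax_eq <= 0:
        raise PreconditionError("kd and rmax_eq must be > 0")
    if concentrations is None:
        concentrations = make_series(1e-3, 2.0, 7)
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    all_c = np.tile(c, n_replicates)
    r_true = rmax_eq * all_c / (all_c + kd)
    r = r_true * (1.0 + rng.normal(0.0, relative_sigma, all_c.shape))
    truth = {
        "kd_molar": kd, "rmax_eq": rmax_eq, "relative_sigma": relative_sigma,
        "n_replicates": n_replicates, "seed": seed,
        "concentrations_molar": list(c),
    }
    return SyntheticIsotherm(concentrations=all_c, responses=np.clip(r, 0.0, None),
                             ground_truth=truth)


def synthetic_peaks(
    neutral_mass: float,
    charges=range(8, 11),
    intensities=None,
    mz_decimals: int | None = None,
) -> PeakList:
    """ESI charge-state peak series of one neutral species.

    m/z_i = (M + z_i * m_proton)/z_i, optionally rounded to
    ``mz_decimals`` (0 emulates integer-printed peak lists).  With no
    rounding, :func:`~biophyskit.ms_utils.deconvolute_charge_series`
    recovers M exactly.
    """
    if neutral_mass <= 0:
        raise PreconditionError("neutral mass must be > 0")
    charges = np.asarray(list(charges), dtype=int)
    if charges.size < 1 or np.any(charges < 1):
        raise PreconditionError("charges must be positive integers")
    mz = np.array([neutral_to_mz(neutral_mass, int(z)) for z in charges])
    if mz_decimals is not None:
        mz = np.round(mz, mz_decimals)
    if intensities is None:
        intensities = np.ones_like(mz)
    return PeakList(mz=mz, intensity=np.asarray(intensities, dtype=float))


def two_point_structure(separation_nm: float = 2.0, mass: float = 12.011) -> StructureModel:
    """Two equal point masses a fixed distance apart: Rg = separation/2."""
    d_a = separation_nm * 10.0
    coords = np.array([[-d_a / 2, 0, 0], [d_a / 2, 0, 0]])
    return StructureModel.from_arrays(coords, ["C", "C"],
                                      masses=np.array([mass, mass]),
                                      label="two-point")


def bead_sphere_structure(radius_nm: float = 2.0, n_beads: int = 10000,
                          seed: int = 0) -> StructureModel:
    """Beads filling a solid sphere uniformly: Rg -> sqrt(3/5)*R.

    Beads are given a tiny vdW radius so the fixture is usable (if slow)
    with the surface algorithms too.
    """
    if radius_nm <= 0 or n_beads < 2:
        raise PreconditionError("need radius > 0 and >= 2 beads")
    rng = np.random.default_rng(seed)
    # uniform in the ball via radius ~ U^(1/3) times a random direction
    u = rng.uniform(0.0, 1.0, n_beads) ** (1.0 / 3.0)
    v = rng.normal(size=(n_beads, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    coords = (radius_nm * 10.0) * u[:, None] * v
    return StructureModel.from_arrays(
        coords, ["C"] * n_beads,
        radii=np.full(n_beads, 0.1), masses=np.ones(n_beads),
        label="bead-sphere")


def dumbbell_structure(radius1: float = 1.9, radius2: float = 1.9,
                       separation: float = 100.0) -> StructureModel:
    """Two spherical atoms (angstrom units) on the x axis.

    At separations beyond contact the SASA is exactly additive, which
    makes this the reference fixture for surface-algorithm checks.
    """
    coords = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    return StructureModel.from_arrays(
        coords, ["C", "N"], radii=np.array([radius1, radius2]),
        label="dumbbell")


def toy_structure(kind: str, **params) -> StructureModel:
    """Dispatch to the named toy-structure generator
    ('two-point', 'bead-sphere' or 'dumbbell')."""
    makers = {
        "two-point": two_point_structure,
        "bead-sphere": bead_sphere_structure,
        "dumbbell": dumbbell_structure,
    }
    if kind not in makers:
        raise PreconditionError(f"unknown toy structure kind {kind!r}")
    return makers[kind](**params)


def fluctuation_trajectory(
    n_residues: int = 20,
    n_frames: int = 1000,
    sigma_nm=0.1,
    rigid_motion: bool = False,
    seed: int = 0,
) -> tuple[Trajectory, dict]:
    """C-alpha trace whose residues fluctuate isotropically about a helix-
    like reference curve.

    Each coordinate of residue i gets N(0, sigma_i^2) displacements, so
    the expected RMSF is sigma_i * sqrt(3).  With ``rigid_motion`` every
    frame is additionally rotated/translated by a random rigid transform,
    which per-frame superposition in the RMSF step must remove.

    Returns the trajectory and its ground-truth record.
    """
    if n_residues < 3 or n_frames < 2:
        raise PreconditionError("need >= 3 residues and >= 2 frames")
    sigma = np.broadcast_to(np.asarray(sigma_nm, dtype=float), (n_residues,)).copy()
    if np.any(sigma < 0):
        raise PreconditionError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_residues)
    ref = np.column_stack([  # open helical curve, ~3.8 A spacing
        5.0 * np.cos(t * 0.6), 5.0 * np.sin(t * 0.6), 1.5 * t])
    sigma_a = sigma * 10.0
    disp = rng.normal(0.0, 1.0, (n_frames, n_residues, 3)) * sigma_a[None, :, None]
    coords = ref[None, :, :] + disp
    if rigid_motion:
        for f in range(n_frames):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            coords[f] = coords[f] @ rot.T + rng.uniform(-20, 20, 3)
    traj = Trajectory(coords=coords,
                      atom_names=np.array(["CA"] * n_residues),
                      residue_indices=np.arange(1, n_residues + 1))
    truth = {"sigma_nm": list(sigma), "expected_rmsf_nm": list(sigma * np.sqrt(3.0)),
             "n_frames": n_frames, "rigid_motion": rigid_motion, "seed": seed,
             "reference_coords": ref.tolist()}
    return traj, truth


def monodisperse_correlogram(
    diameter_nm: float,
    lag_times=None,
    temperature: float = 310.15,
    viscosity: float = 6.913e-4,
    q: float | None = None,
    intercept: float = 0.9,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Noise-free DLS correlogram g2-1 = B*exp(-2*Gamma*tau) of a single
    species, for exercising the cumulant reduction.

    Returns (lag_times, g2_minus_1, ground_truth).
    """
    from .hydrodynamics import diffusion_from_diameter, scattering_vector

    if q is None:
        q = scattering_vector()
    d_coeff = diffusion_from_diameter(diameter_nm, temperature, viscosity)
    gamma = d_coeff * q**2
    if lag_times is None:
        lag_times = np.geomspace(1e-7, 2.0 / gamma, 60)
    tau = np.asarray(lag_times, dtype=float)
    g2m1 = intercept * np.exp(-2.0 * gamma * tau)
    truth = {"diameter_nm": diameter_nm, "gamma": gamma,
             "diffusion_m2_s": d_coeff, "q": q, "intercept": intercept}
    return tau, g2m1, truth
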