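"""Native-MS charge-series deconvolution and cross-link mass arithmetic.

Electrospray of an intact protein produces a series of peaks at
consecutive charges z, related to the neutral average mass M by

    m/z = (M + z * m_proton) / z        (positive mode)

Deconvolution searches consecutive charge assignments for the one that
makes the per-peak neutral masses most self-consistent.  The cross-link
arithmetic covers amine-reactive DSBU: a fully reacted bridge adds 196.1 u
to the target mass, a one-side-reacted (hydrolysed) linker additionally
carries a water.

All masses are average (not monoisotopic) masses — intact-protein
measurements at the 20 kDa scale resolve the isotope envelope centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSequenceError, NoConsistentSeriesError, PreconditionError

__all__ = [
    "PROTON_MASS",
    "WATER_AVG",
    "DSBU_BRIDGE",
    "AVERAGE_RESIDUE_MASS",
    "PeakList",
    "DeconvolutionResult",
    "MassLadder",
    "mz_to_neutral",
    "neutral_to_mz",
    "deconvolute_charge_series",
    "peptide_average_mass",
    "adduct_masses",
    "complex_mass",
]

PROTON_MASS = 1.00728  # u, positive-mode charge carrier
WATER_AVG = 18.0153  # u
#: Mass added per fully reacted DSBU bridge (u).
DSBU_BRIDGE = 196.1
ACETYL_DELTA = 42.0367  # N-terminal acetylation
AMIDE_DELTA = -0.9847  # C-terminal amidation (OH -> NH2)

#: Average residue masses (u) of the 20 standard amino acids
#: (monomer minus water), IUPAC standard atomic weights.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}


@dataclass
class PeakList:
    """(m/z, intensity) records, kept sorted by ascending m/z."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.atleast_1d(np.asarray(self.mz, dtype=float))
        self.intensity = np.atleast_1d(np.asarray(self.intensity, dtype=float))
        if self.mz.shape != self.intensity.shape:
            raise PreconditionError("mz and intensity must have equal length")
        if np.any(self.mz <= 0):
            raise PreconditionError("m/z values must be > 0")
        if np.any(self.intensity < 0):
            raise PreconditionError("intensities must be >= 0")
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return self.mz.size

    @classmethod
    def from_pairs(cls, pairs) -> "PeakList":
        arr = np.asarray(list(pairs), dtype=float).reshape(-1, 2)
        return cls(mz=arr[:, 0], intensity=arr[:, 1])


def mz_to_neutral(mz: float, charge: int) -> float:
    """Neutral mass from one peak with known charge: z*(m/z - m_proton)."""
    if charge < 1:
        raise PreconditionError("charge must be >= 1")
    return charge * (mz - PROTON_MASS)


def neutral_to_mz(neutral_mass: float, charge: int) -> float:
    """Expected peak position of a neutral mass at a given charge."""
    if charge < 1:
        raise PreconditionError("charge must be >= 1")
    return (neutral_mass + charge * PROTON_MASS) / charge


@dataclass
class DeconvolutionResult:
    """Outcome of a consecutive-charge deconvolution.

    ``neutral_mass`` is the intensity-weighted mean of the per-peak masses
    z_i*(m/z_i - m_proton); ``dispersion`` is their (unweighted) standard
    deviation, a consistency figure for the charge assignment.
    """

    neutral_mass: float
    charges: np.ndarray  # aligned with the ascending-m/z peak list
    per_peak_mass: np.ndarray
    dispersion: float

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=int)
        self.per_peak_mass = np.asarray(self.per_peak_mass, dtype=float)


def deconvolute_charge_series(
    peaks: PeakList,
    z_min: int = 1,
    z_max: int = 50,
    dispersion_threshold: float = 2e-3,
) -> DeconvolutionResult:
    """Assign consecutive charges to a peak series and deconvolve the mass.

    Every window of consecutive charges inside [z_min, z_max] is tried
    (highest charge on the lowest-m/z peak); the assignment minimising the
    standard deviation of the per-peak neutral masses wins, with ties
    broken by higher summed intensity.  If the best dispersion exceeds
    ``dispersion_threshold`` (fractional, default 0.2% of the mass) no
    consistent series exists and :class:`NoConsistentSeriesError` is
    raised.
    """
    if len(peaks) < 2:
        raise PreconditionError(
            "deconvolution needs >= 2 peaks; use mz_to_neutral for one peak")
    if not (1 <= z_min < z_max <= 50):
        raise PreconditionError("require 1 <= z_min < z_max <= 50")
    n = len(peaks)
    if z_max - z_min + 1 < n:
        raise PreconditionError("charge window narrower than the peak list")

    best = None
    for z_top in range(z_min + n - 1, z_max + 1):
        charges = np.arange(z_top, z_top - n, -1)  # descending with m/z
        masses = charges * (peaks.mz - PROTON_MASS)
        disp = float(np.std(masses))
        key = (disp, -float(peaks.intensity.sum()))
        if best is None or key < best[0]:
            best = (key, charges, masses, disp)

    _, charges, masses, disp = best
    weights = peaks.intensity if peaks.intensity.sum() > 0 else np.ones(n)
    mass = float(np.average(masses, weights=weights))
    if disp > dispersion_threshold * mass:
        raise NoConsistentSeriesError(
            f"best charge assignment has dispersion {disp:.1f} Da "
            f"({disp / mass:.2%} of {mass:.0f} Da), above the "
            f"{dispersion_threshold:.2%} threshold")
    return DeconvolutionResult(neutral_mass=mass, charges=charges,
                               per_peak_mass=masses, dispersion=disp)


def peptide_average_mass(sequence: str, n_term_mod: str = "free",
                         c_term_mod: str = "free") -> float:
    """Average mass (u) of a peptide from its one-letter sequence.

    Mass = sum of residue masses + water, plus +42.037 for an N-terminal
    acetyl and -0.985 for a C-terminal amide.
    """
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    try:
        total = sum(AVERAGE_RESIDUE_MASS[aa] for aa in sequence.upper())
    except KeyError as exc:
        raise InvalidSequenceError(f"unknown residue letter {exc.args[0]!r}") from exc
    total += WATER_AVG
    if n_term_mod == "acetyl":
        total += ACETYL_DELTA
    elif n_term_mod != "free":
        raise PreconditionError(f"unknown N-terminal modification {n_term_mod!r}")
    if c_term_mod == "amide":
        total += AMIDE_DELTA
    elif c_term_mod != "free":
        raise PreconditionError(f"unknown C-terminal modification {c_term_mod!r}")
    return total


@dataclass
class MassLadder:
    """Masses of a base species carrying 0..n_max cross-linker adducts."""

    base_label: str
    species: str  # "bridged" or "hydrolyzed"
    entries: list = field(default_factory=list)  # (n_adducts, mass_da)

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for _, m in self.entries])


def adduct_masses(base_mass: float, n_max: int, bridge_mass: float = DSBU_BRIDGE,
                  hydrolyzed: bool = False, label: str = "") -> MassLadder:
    """Mass ladder of a species decorated with 0..n_max linker adducts.

    Fully reacted ("bridged") linkers add ``bridge_mass`` each; one-side-
    reacted linkers are hydrolysed on the free end and add an extra water.
    """
    if base_mass <= 0:
        raise PreconditionError("base mass must be > 0")
    if n_max < 0:
        raise PreconditionError("n_max must be >= 0")
    step = bridge_mass + (WATER_AVG if hydrolyzed else 0.0)
    entries = [(n, base_mass + n * step) for n in range(n_max + 1)]
    return MassLadder(base_label=label,
                      species="hydrolyzed" if hydrolyzed else "bridged",
                      entries=entries)


def complex_mass(protein_mass: float, peptide_mass: float, n_crosslinkers: int = 1,
                 bridge_mass: float = DSBU_BRIDGE) -> float:
    """Average mass of a cross-linked protein/peptide complex:
    protein + peptide + n * bridge."""
    if protein_mass <= 0 or peptide_mass <= 0:
        raise PreconditionError("masses must be > 0")
    if n_crosslinkers < 0:
        raise PreconditionError("n_crosslinkers must be >= 0")
    return protein_mass + peptide_mass + n_crosslinkers * bridge_mass
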