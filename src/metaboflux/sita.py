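"""Stable-isotope tracer analysis of mass-isotopolog spectra.

Raw M+0..M+n intensities measured after a [U-13C]-glucose pulse mix the
tracer signal with mass shifts caused by naturally occurring 13C (and by
incomplete tracer enrichment). This module removes that background by
correction-matrix deconvolution: column j of the matrix is the measured
mass-shift distribution of a species carrying j tracer-derived carbons
(each 13C with probability ``tracer_purity``) and n - j non-tracer carbons
(each 13C with probability ``p13_natural``). The corrected mass-isotopolog
distribution (MID) is recovered by nonnegative least squares and
renormalized to sum to one, which suppresses the small negative artifacts a
direct matrix inversion produces on noisy spectra.

On corrected MIDs the module computes labeled/unlabeled pool abundances
(the M+0 fraction vs the rest, protein-normalized) and the pyruvate-entry
surrogate ratios: citrate M+2 / pyruvate M+3 for pyruvate dehydrogenase
(PDH) and citrate M+3 / pyruvate M+3 for pyruvate carboxylase (PC).

Only carbon isotopes are corrected; derivatization (H/N/O/Si) correction is
out of scope and inputs are assumed to be carbon-backbone spectra.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import nnls

from ._core import Undefined

#: Natural 13C abundance used by default (fraction of carbon atoms).
P13_NATURAL = 0.0107
#: Default isotopic enrichment of the tracer carbons.
TRACER_PURITY = 0.99


@dataclass(frozen=True)
class IsotopologSpectrum:
    """Raw M+0..M+n intensities of one metabolite in one sample."""

    metabolite: str
    n_carbons: int
    intensities: np.ndarray
    protein_ug: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if len(arr) != self.n_carbons + 1:
            raise ValueError(
                f"{self.metabolite}: expected {self.n_carbons + 1} intensities, got {len(arr)}"
            )
        if np.any(arr < 0):
            raise ValueError(f"{self.metabolite}: intensities must be >= 0")
        if not np.any(arr > 0):
            raise ValueError(f"{self.metabolite}: all-zero spectrum")

    @property
    def total(self) -> float:
        return float(self.intensities.sum())


@dataclass(frozen=True)
class MIDProfile:
    """Corrected fractional mass-isotopolog distribution of one metabolite."""

    metabolite: str
    fractions: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", arr)
        if np.any(arr < -1e-12):
            raise ValueError(f"{self.metabolite}: MID fractions must be >= 0")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.metabolite}: MID fractions must sum to 1 (got {arr.sum()})")

    @property
    def n_carbons(self) -> int:
        return len(self.fractions) - 1

    def fraction(self, mass_shift: int) -> float:
        return float(self.fractions[mass_shift])


@dataclass(frozen=True)
class AbundanceSummary:
    metabolite: str
    labeled_c13: float
    unlabeled_c12: float


def correction_matrix(
    n_carbons: int,
    p13_natural: float = P13_NATURAL,
    tracer_purity: float = TRACER_PURITY,
) -> np.ndarray:
    """(n+1) x (n+1) matrix mapping a true MID to the measured spectrum.

    Column j is the mass-shift distribution of a species with j
    tracer-labeled carbons and n - j natural-abundance carbons. For a
    carbon-only correction the shift cannot exceed n, so every column sums
    to exactly 1.
    """
    if not 0 <= p13_natural < 0.5:
        raise ValueError(f"p13_natural must be in [0, 0.5), got {p13_natural}")
    if not 0 < tracer_purity <= 1:
        raise ValueError(f"tracer_purity must be in (0, 1], got {tracer_purity}")
    n = int(n_carbons)
    C = np.zeros((n + 1, n + 1))
    shifts = np.arange(n + 1)
    for j in range(n + 1):
        tracer = stats.binom.pmf(shifts[: j + 1], j, tracer_purity)
        natural = stats.binom.pmf(shifts[: n - j + 1], n - j, p13_natural)
        C[:, j] = np.convolve(tracer, natural)
    return C


def correct_natural_abundance(
    spectrum: IsotopologSpectrum,
    p13_natural: float = P13_NATURAL,
    tracer_purity: float = TRACER_PURITY,
) -> MIDProfile:
    """Deconvolve a raw spectrum into its tracer-labeled MID (NNLS + renorm)."""
    C = correction_matrix(spectrum.n_carbons, p13_natural, tracer_purity)
    x, _ = nnls(C, spectrum.intensities)
    total = x.sum()
    if total <= 0:
        raise ValueError(f"{spectrum.metabolite}: correction produced an all-zero MID")
    return MIDProfile(spectrum.metabolite, x / total)


def labeled_abundance(
    spectrum: IsotopologSpectrum,
    mid: MIDProfile,
    total_pool: float | None = None,
) -> AbundanceSummary:
    """Split a metabolite pool into unlabeled (M+0) and labeled (rest) parts.

    Both are normalized to the sample's protein content. ``total_pool``
    defaults to the spectrum's total intensity.
    """
    if spectrum.protein_ug <= 0:
        raise ValueError(f"{spectrum.metabolite}: protein_ug must be > 0")
    pool = spectrum.total if total_pool is None else float(total_pool)
    m0 = mid.fraction(0)
    return AbundanceSummary(
        metabolite=spectrum.metabolite,
        labeled_c13=pool * (1.0 - m0) / spectrum.protein_ug,
        unlabeled_c12=pool * m0 / spectrum.protein_ug,
    )


def _surrogate(citrate: MIDProfile, pyruvate: MIDProfile, citrate_shift: int) -> float:
    if citrate.n_carbons < citrate_shift or pyruvate.n_carbons < 3:
        raise ValueError("citrate needs >= M+3 and pyruvate M+3 isotopologs")
    denom = pyruvate.fraction(3)
    if denom <= 0:
        return Undefined("surrogate_zero_pyruvate_m3")
    return citrate.fraction(citrate_shift) / denom


def pdh_surrogate(citrate: MIDProfile, pyruvate: MIDProfile) -> float:
    """Citrate M+2 / pyruvate M+3 — surrogate for PDH activity."""
    return _surrogate(citrate, pyruvate, 2)


def pc_surrogate(citrate: MIDProfile, pyruvate: MIDProfile) -> float:
    """Citrate M+3 / pyruvate M+3 — surrogate for PC activity."""
    return _surrogate(citrate, pyruvate, 3)
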