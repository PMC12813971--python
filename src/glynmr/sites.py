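"""Labeled sites, experimental conditions, and crosspeak observations."""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from . import constants

__all__ = [
    "SiteClass",
    "VectorKind",
    "FieldConditions",
    "LabeledSite",
    "Observation",
    "pcs_sigma",
    "PCS_ERR_FRACTION",
    "PCS_ERR_FLOOR",
]

#: experimental PCS uncertainty model: 15% with a 0.03 ppm floor (~linewidth)
PCS_ERR_FRACTION = 0.15
PCS_ERR_FLOOR = 0.03


def pcs_sigma(pcs_ppm: float, reported: float | None = None) -> float:
    """PCS uncertainty from the observation record.

    A recorded error stands, clamped from below by the 0.03 ppm floor
    (~linewidth); when no error is recorded the 15% / 0.03 ppm model
    supplies it."""
    if reported is not None and np.isfinite(reported):
        return max(float(reported), PCS_ERR_FLOOR)
    return max(PCS_ERR_FRACTION * abs(pcs_ppm), PCS_ERR_FLOOR)


class SiteClass(str, Enum):
    protein_methyl = "protein_methyl"
    first_C1 = "first_C1"
    second_C1 = "second_C1"
    acetyl = "acetyl"


class VectorKind(str, Enum):
    ch_bond = "ch_bond"
    methyl_axis = "methyl_axis"


@dataclass(frozen=True)
class FieldConditions:
    """Spectrometer and sample conditions entering the RDC prefactor.

    Defaults correspond to a 900 MHz instrument at 25 C with a 1.095 A
    effective C-H bond length.
    """

    b0: float = constants.b0_from_proton_frequency()
    temperature: float = constants.T_DEFAULT
    gamma_h: float = constants.GAMMA_H
    gamma_c: float = constants.GAMMA_C
    rch: float = constants.RCH_DEFAULT
    h: float = constants.H_PLANCK
    kb: float = constants.KB_SI
    #: methyl-axis projection factor; (3cos^2(110.5deg)-1)/2 by default,
    #: -1/3 is the common rough alternative
    methyl_factor: float = constants.methyl_projection_factor()

    def __post_init__(self):
        for name in ("b0", "temperature", "gamma_h", "gamma_c", "rch", "h", "kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"FieldConditions.{name} must be strictly positive")

    @property
    def rdc_prefactor(self) -> float:
        """K in Hz per 1e-32 m^3 of susceptibility anisotropy."""
        num = self.h * self.b0**2 * self.gamma_c * self.gamma_h
        den = (
            240.0
            * math.pi**3
            * self.kb
            * self.temperature
            * (self.rch * constants.ANGSTROM) ** 3
        )
        return num / den * constants.CHI_UNIT


@dataclass(frozen=True)
class LabeledSite:
    """One 13C-labeled position: coordinates plus the interaction vector.

    ``vector`` is the C->H bond direction for anomeric C1-H1 pairs
    (``ch_bond``) or the three-fold symmetry axis for methyl groups
    (``methyl_axis``); it must be a unit vector.
    """

    id: str
    site_class: SiteClass
    position: np.ndarray
    vector: np.ndarray
    vector_kind: VectorKind
    glyco_site: Optional[str] = None
    #: for acetyls: 1 = first GlcNAc, 2 = second GlcNAc
    glcnac_index: Optional[int] = None

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        vec = np.asarray(self.vector, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"site {self.id}: position must be finite 3-vector")
        if vec.shape != (3,):
            raise ValueError(f"site {self.id}: vector must be a 3-vector")
        n = np.linalg.norm(vec)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"site {self.id}: vector must be unit length (|v|={n})")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "vector", vec)
        object.__setattr__(self, "site_class", SiteClass(self.site_class))
        object.__setattr__(self, "vector_kind", VectorKind(self.vector_kind))


@dataclass(frozen=True)
class Observation:
    """One crosspeak's (PCS, RDC) pair with uncertainties.

    Either value may be missing (None); the PCS sigma respects the
    15% / 0.03 ppm floor.  ``site_id`` is filled for protein observations
    whose assignment is known.
    """

    id: str
    site_class: SiteClass
    lanthanide: str
    pcs_ppm: Optional[float] = None
    pcs_err: Optional[float] = None
    rdc_hz: Optional[float] = None
    rdc_err: Optional[float] = None
    site_id: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "site_class", SiteClass(self.site_class))
        if self.pcs_ppm is not None:
            object.__setattr__(
                self, "pcs_err", pcs_sigma(self.pcs_ppm, self.pcs_err)
            )
        if self.rdc_hz is not None:
            if self.rdc_err is None or not self.rdc_err > 0:
                raise ValueError(f"observation {self.id}: rdc_err must be > 0")
        if self.pcs_ppm is None and self.rdc_hz is None:
            raise ValueError(f"observation {self.id}: no observable present")

    @property
    def has_pcs(self) -> bool:
        return self.pcs_ppm is not None

    @property
    def has_rdc(self) -> bool:
        return self.rdc_hz is not None
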