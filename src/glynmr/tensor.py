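"""Traceless symmetric magnetic-susceptibility tensors.

A lanthanide's anisotropic susceptibility is a traceless symmetric rank-2
tensor, fully determined by five independent Cartesian components.  The
component order used everywhere in this package is

    c5 = (chi_xx, chi_yy, chi_xy, chi_xz, chi_yz),   chi_zz = -(chi_xx + chi_yy)

in units of 1e-32 m^3.  The principal decomposition orders eigenvalues by
increasing magnitude into (chi_x, chi_y, chi_z) so that
|chi_z| >= |chi_y| >= |chi_x|, and reports

    dchi_ax = 3/2 chi_z,        dchi_rh = chi_x - chi_y.

Under this convention dchi_rh/dchi_ax lies in [0, 2/3].
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = ["SusceptibilityTensor", "tensor_from_c5", "c5_from_matrix"]

#: relative tolerance below which two principal values count as degenerate
AXIAL_TOL = 1e-9


def c5_from_matrix(m: np.ndarray) -> np.ndarray:
    """Extract the five independent components from a traceless symmetric
    3x3 matrix.  Raises if the matrix is not (numerically) traceless
    symmetric."""
    m = np.asarray(m, dtype=float)
    scale = max(np.abs(m).max(), 1.0)
    if not np.allclose(m, m.T, atol=1e-9 * scale):
        raise ValueError("susceptibility matrix must be symmetric")
    if abs(np.trace(m)) > 1e-9 * scale:
        raise ValueError("susceptibility matrix must be traceless")
    return np.array([m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2]])


def _matrix_from_c5(c5: np.ndarray) -> np.ndarray:
    xx, yy, xy, xz, yz = c5
    return np.array(
        [
            [xx, xy, xz],
            [xy, yy, yz],
            [xz, yz, -(xx + yy)],
        ]
    )


@dataclass(frozen=True)
class SusceptibilityTensor:
    """Five-component traceless symmetric susceptibility tensor.

    Attributes
    ----------
    c5 : ndarray, shape (5,)
        (chi_xx, chi_yy, chi_xy, chi_xz, chi_yz) in 1e-32 m^3.
    lanthanide_label : str
        Free-text ion tag, e.g. "Tb", "Tm", "Lu".
    """

    c5: np.ndarray
    lanthanide_label: str = ""

    def __post_init__(self):
        c5 = np.asarray(self.c5, dtype=float)
        if c5.shape != (5,) or not np.all(np.isfinite(c5)):
            raise ValueError("c5 must be five finite numbers")
        object.__setattr__(self, "c5", c5)

    @property
    def matrix(self) -> np.ndarray:
        """Full 3x3 matrix, 1e-32 m^3; symmetric, exactly traceless."""
        return _matrix_from_c5(self.c5)

    # -- principal decomposition -------------------------------------------

    @cached_property
    def _decomposition(self):
        m = self.matrix
        vals, vecs = np.linalg.eigh(m)
        # order by |value| ascending -> (x, y, z); ties by signed value
        order = np.lexsort((vals, np.abs(vals)))
        vals = vals[order]
        vecs = vecs[:, order]
        # sign-fix: largest-magnitude component of each eigenvector positive
        for k in range(3):
            j = int(np.argmax(np.abs(vecs[:, k])))
            if vecs[j, k] < 0:
                vecs[:, k] = -vecs[:, k]
        # enforce right-handedness by flipping the x eigenvector
        if np.linalg.det(vecs) < 0:
            vecs[:, 0] = -vecs[:, 0]
        return vals, vecs

    @property
    def principal_values(self) -> np.ndarray:
        """(chi_x, chi_y, chi_z) ordered by increasing magnitude."""
        return self._decomposition[0]

    @property
    def rotation(self) -> np.ndarray:
        """Right-handed rotation matrix whose columns are the principal
        axes (x, y, z); r_principal = rotation.T @ r_lab."""
        return self._decomposition[1]

    @property
    def dchi_ax(self) -> float:
        """Axial anisotropy, 3/2 chi_z, 1e-32 m^3."""
        return 1.5 * float(self.principal_values[2])

    @property
    def dchi_rh(self) -> float:
        """Rhombic anisotropy, chi_x - chi_y, 1e-32 m^3."""
        vx, vy, _ = self.principal_values
        return float(vx - vy)

    @property
    def axially_symmetric(self) -> bool:
        """True when chi_x and chi_y are degenerate within tolerance."""
        vx, vy, vz = self.principal_values
        scale = max(abs(vz), 1e-300)
        return abs(vx - vy) <= AXIAL_TOL * scale

    # -- algebra -----------------------------------------------------------

    def rotated(self, rot: np.ndarray) -> "SusceptibilityTensor":
        """Tensor expressed after the rigid rotation ``rot`` (3x3, proper
        orthogonal) of the lab frame: chi' = R chi R^T."""
        rot = np.asarray(rot, dtype=float)
        m = rot @ self.matrix @ rot.T
        # symmetrize against round-off before extracting components
        m = 0.5 * (m + m.T)
        m -= np.eye(3) * np.trace(m) / 3.0
        return SusceptibilityTensor(c5_from_matrix(m), self.lanthanide_label)

    def __neg__(self) -> "SusceptibilityTensor":
        return SusceptibilityTensor(-self.c5, self.lanthanide_label)


def tensor_from_c5(c5, lanthanide_label: str = "") -> SusceptibilityTensor:
    """Build a :class:`SusceptibilityTensor` from its five Cartesian
    components (chi_xx, chi_yy, chi_xy, chi_xz, chi_yz), 1e-32 m^3."""
    return SusceptibilityTensor(np.asarray(c5, dtype=float), lanthanide_label)
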