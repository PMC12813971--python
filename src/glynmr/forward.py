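"""Forward models: susceptibility tensor + geometry -> PCS (ppm), RDC (Hz).

Both observables share one angular factor evaluated in the tensor's
principal frame,

    A(theta, phi) = dchi_ax (3 cos^2 theta - 1) + 3/2 dchi_rh sin^2 theta cos 2phi,

with (theta, phi) the polar angles of the lanthanide->site vector (PCS) or
of the bond / methyl-axis vector (RDC).  The PCS decays as 1/R^3 from the
ion; the RDC is distance-independent because alignment is field-induced and
molecule-wide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import PCS_PREFACTOR
from .sites import FieldConditions, LabeledSite, VectorKind
from .tensor import SusceptibilityTensor

__all__ = [
    "pcs_predict",
    "rdc_predict",
    "PcsField",
    "pcs_field",
    "isosurface_radius",
    "CONTACT_CUTOFF",
]

#: below this lanthanide-nucleus distance (A) the point-dipole picture is
#: unreliable (contact and ligand-field effects); a warning is issued
CONTACT_CUTOFF = 5.0


def _angular_factor(tensor: SusceptibilityTensor, v: np.ndarray) -> np.ndarray:
    """A(theta, phi) for lab-frame direction(s) ``v`` (…, 3), not
    necessarily normalized — only the direction is used."""
    rot = tensor.rotation
    vp = np.asarray(v, dtype=float) @ rot  # rows rotated into principal frame
    r2 = np.einsum("...i,...i->...", vp, vp)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos2_th = vp[..., 2] ** 2 / r2
        sin2_th = 1.0 - cos2_th
        # cos 2phi = (x^2 - y^2) / (x^2 + y^2); 0 when the xy-projection vanishes
        xy2 = vp[..., 0] ** 2 + vp[..., 1] ** 2
        cos_2phi = np.where(xy2 > 0, (vp[..., 0] ** 2 - vp[..., 1] ** 2) / np.where(xy2 > 0, xy2, 1.0), 0.0)
    return tensor.dchi_ax * (3.0 * cos2_th - 1.0) + 1.5 * tensor.dchi_rh * sin2_th * cos_2phi


def pcs_predict(
    tensor: SusceptibilityTensor,
    lanthanide_pos: np.ndarray,
    site: LabeledSite,
) -> float:
    """Pseudocontact shift (ppm) of a labeled site.

    delta = A(theta, phi) / (12 pi R^3) with (R, theta, phi) the spherical
    coordinates of the site in the tensor principal frame centred on the
    lanthanide; coordinates in Angstrom, tensor in 1e-32 m^3.
    """
    r = np.asarray(site.position, dtype=float) - np.asarray(lanthanide_pos, dtype=float)
    dist = float(np.linalg.norm(r))
    if dist == 0.0:
        raise ValueError("site coincides with the lanthanide position")
    if dist < CONTACT_CUTOFF:
        warnings.warn(
            f"site {site.id} is {dist:.2f} A from the ion; point-dipole "
            "approximation unreliable below "
            f"{CONTACT_CUTOFF} A",
            stacklevel=2,
        )
    return float(PCS_PREFACTOR * _angular_factor(tensor, r) / dist**3)


def rdc_predict(
    tensor: SusceptibilityTensor,
    site: LabeledSite,
    cond: FieldConditions | None = None,
) -> float:
    """Field-induced residual dipolar coupling (Hz) for the site's C-H bond
    or methyl symmetry axis.

    D = -K * A(theta, phi) with K the field/temperature prefactor; for a
    methyl axis the result is additionally scaled by the three-fold
    projection factor (3 cos^2 beta_CH - 1)/2.
    """
    cond = cond or FieldConditions()
    vec = np.asarray(site.vector, dtype=float)
    if abs(np.linalg.norm(vec) - 1.0) > 1e-9:
        raise ValueError(f"site {site.id}: vector must be a unit vector")
    d = -cond.rdc_prefactor * float(_angular_factor(tensor, vec))
    kind = VectorKind(site.vector_kind)
    if kind is VectorKind.methyl_axis:
        d *= cond.methyl_factor
    elif kind is not VectorKind.ch_bond:  # pragma: no cover - enum guards
        raise ValueError(f"unrecognized vector_kind {site.vector_kind!r}")
    return d


@dataclass(frozen=True)
class PcsField:
    """Scalar PCS field (ppm) on a regular 3-D lattice around the ion."""

    origin: np.ndarray          # lanthanide position, A
    grid_origin: np.ndarray     # lattice corner, A
    spacing: float              # A
    values: np.ndarray          # (nx, ny, nz) ppm

    def axes(self):
        """Coordinate axes (x, y, z) of the lattice in Angstrom."""
        return tuple(
            self.grid_origin[i] + self.spacing * np.arange(self.values.shape[i])
            for i in range(3)
        )


def pcs_field(
    tensor: SusceptibilityTensor,
    lanthanide_pos: np.ndarray,
    extent: float = 60.0,
    spacing: float = 2.0,
) -> PcsField:
    """Evaluate the PCS on a cube of half-width ``extent`` (A) centred on
    the lanthanide, for isosurface rendering.

    Lattice points closer to the ion than the grid spacing are set to NaN
    (the 1/R^3 singularity cannot be represented); a warning notes how many.
    """
    origin = np.asarray(lanthanide_pos, dtype=float)
    ax = np.arange(-extent, extent + spacing / 2, spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    rel = np.stack([gx, gy, gz], axis=-1)
    dist = np.linalg.norm(rel, axis=-1)
    bracket = _angular_factor(tensor, rel)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = PCS_PREFACTOR * bracket / dist**3
    near = dist < max(spacing, 1e-6)
    if near.any():
        warnings.warn(
            f"{int(near.sum())} lattice point(s) within one spacing of the "
            "ion masked as NaN; refine the grid for near-field work",
            stacklevel=2,
        )
        vals = np.where(near, np.nan, vals)
    return PcsField(origin=origin, grid_origin=origin - extent, spacing=spacing, values=vals)


def isosurface_radius(
    tensor: SusceptibilityTensor,
    isovalue: float,
    theta: float,
    phi: float,
) -> float | None:
    """Radius (A) at which the PCS equals ``isovalue`` (ppm) along the
    principal-frame direction (theta, phi); None when the angular factor
    and the isovalue have opposite signs (the surface does not cross that
    ray).

    Closed form: R = [A(theta, phi) * prefactor / isovalue]^(1/3).
    """
    if isovalue == 0:
        raise ValueError("isovalue must be nonzero")
    a = tensor.dchi_ax * (3.0 * np.cos(theta) ** 2 - 1.0) + 1.5 * tensor.dchi_rh * np.sin(
        theta
    ) ** 2 * np.cos(2.0 * phi)
    ratio = PCS_PREFACTOR * a / isovalue
    if ratio <= 0:
        return None
    return float(ratio ** (1.0 / 3.0))
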