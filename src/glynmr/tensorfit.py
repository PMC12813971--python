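"""Weighted linear least-squares determination of the susceptibility tensor
from protein-site PCS and RDC observations, with iterative outlier
exclusion.

Both observables are linear in the five tensor components, so a single
weighted linear solve recovers the tensor; no initial guess is needed.
Rows are whitened by 1/sigma so PCS (ppm) and RDC (Hz) contribute on a
common dimensionless scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import PCS_PREFACTOR
from .sites import FieldConditions, LabeledSite, Observation, SiteClass, VectorKind
from .tensor import SusceptibilityTensor

__all__ = [
    "FitResult",
    "fit_tensor",
    "fit_with_exclusion",
    "bootstrap_tensor",
    "vector_order_parameters",
    "flag_mobile_sites",
]

MIN_OBSERVATIONS = 5


def _pcs_row(rel: np.ndarray) -> np.ndarray:
    """Design-matrix row mapping c5 -> PCS (ppm) for a site at lab-frame
    offset ``rel`` (A) from the ion.

    From delta = prefactor * 3 r^T chi r / R^5 with chi_zz = -(chi_xx+chi_yy):
    coefficients on (chi_xx, chi_yy, chi_xy, chi_xz, chi_yz).
    """
    x, y, z = rel
    r2 = x * x + y * y + z * z
    scale = 3.0 * PCS_PREFACTOR / r2**2.5
    return scale * np.array(
        [x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z]
    )


def _rdc_row(vec: np.ndarray, kind: VectorKind, cond: FieldConditions) -> np.ndarray:
    """Design-matrix row mapping c5 -> RDC (Hz) for unit bond/axis vector."""
    x, y, z = vec
    scale = -3.0 * cond.rdc_prefactor
    if VectorKind(kind) is VectorKind.methyl_axis:
        scale *= cond.methyl_factor
    return scale * np.array(
        [x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z]
    )


@dataclass
class FitResult:
    """Outcome of a tensor fit.

    ``residuals`` holds (predicted - observed) in native units for every
    input observation row — including excluded ones, which are evaluated at
    the final solution but carry no weight.
    """

    tensor: SusceptibilityTensor
    residuals: dict            # row id -> residual (native units)
    sigmas: dict               # row id -> sigma used
    quality: dict              # per-type weighted RMS and Q-factor
    excluded: list = field(default_factory=list)  # (row id, reason) in order
    n_used: int = 0

    @property
    def excluded_ids(self) -> list:
        return [e[0] for e in self.excluded]


def _build_rows(sites_by_id, obs, lanthanide_pos, cond):
    """Expand observations into scalar rows: (row_id, obs_id, type, A-row,
    value, sigma).  A crosspeak with both PCS and RDC produces two rows."""
    rows = []
    ln = np.asarray(lanthanide_pos, dtype=float)
    for o in obs:
        if o.site_id is None or o.site_id not in sites_by_id:
            raise ValueError(f"observation {o.id} is not mapped to a known site")
        site = sites_by_id[o.site_id]
        rel = np.asarray(site.position, dtype=float) - ln
        if o.has_pcs:
            rows.append((f"{o.id}:pcs", o.id, "pcs", _pcs_row(rel), o.pcs_ppm, o.pcs_err))
        if o.has_rdc:
            rows.append(
                (
                    f"{o.id}:rdc",
                    o.id,
                    "rdc",
                    _rdc_row(site.vector, site.vector_kind, cond),
                    o.rdc_hz,
                    o.rdc_err,
                )
            )
    return rows


def _solve(rows):
    a = np.array([r[3] for r in rows])
    y = np.array([r[4] for r in rows])
    w = 1.0 / np.array([r[5] for r in rows])
    aw = a * w[:, None]
    yw = y * w
    # column scaling guards conditioning; exactly linear problem otherwise
    col = np.linalg.norm(aw, axis=0)
    col[col == 0] = 1.0
    sol, _, rank, _ = np.linalg.lstsq(aw / col, yw, rcond=None)
    if rank < 5:
        _, _, vt = np.linalg.svd(aw / col)
        null = vt[-1] * col  # un-scale back to c5 space direction
        raise ValueError(
            "rank-deficient design matrix (collinear geometry); "
            f"null direction in c5 space ~ {np.round(null / np.linalg.norm(null), 3)}"
        )
    return sol / col


def fit_tensor(
    sites: Sequence[LabeledSite],
    obs: Sequence[Observation],
    lanthanide_pos,
    cond: FieldConditions | None = None,
    lanthanide_label: str = "",
) -> FitResult:
    """Weighted linear least-squares fit of the five tensor components.

    Requires at least five scalar observations (PCS rows + RDC rows); a
    PCS-only fit is allowed.  Weights are 1/sigma^2 with the PCS error
    floor already applied by :class:`Observation`.
    """
    cond = cond or FieldConditions()
    sites_by_id = {s.id: s for s in sites}
    rows = _build_rows(sites_by_id, obs, lanthanide_pos, cond)
    if len(rows) < MIN_OBSERVATIONS:
        raise ValueError(
            f"need at least {MIN_OBSERVATIONS} scalar observations, got {len(rows)}"
        )
    c5 = _solve(rows)
    tensor = SusceptibilityTensor(c5, lanthanide_label)
    return _result(tensor, rows, excluded=[])


def _result(tensor, rows, excluded, all_rows=None):
    """Assemble a FitResult; residuals are reported for every row in
    ``all_rows`` (defaults to the fitted rows)."""
    report_rows = all_rows if all_rows is not None else rows
    residuals, sigmas = {}, {}
    per_type = {"pcs": ([], []), "rdc": ([], [])}
    used_ids = {r[0] for r in rows}
    for rid, _oid, typ, arow, yval, sig in report_rows:
        pred = float(arow @ tensor.c5)
        residuals[rid] = pred - yval
        sigmas[rid] = sig
        if rid in used_ids:
            per_type[typ][0].append(pred)
            per_type[typ][1].append(yval)
    quality = {}
    for typ, (pred, yval) in per_type.items():
        if not yval:
            continue
        pred = np.array(pred)
        yval = np.array(yval)
        rms = float(np.sqrt(np.mean((pred - yval) ** 2)))
        denom = float(np.sqrt(np.sum(yval**2)))
        quality[typ] = {
            "rms": rms,
            "q_factor": float(np.sqrt(np.sum((pred - yval) ** 2)) / denom)
            if denom > 0
            else float("nan"),
            "n": int(len(yval)),
        }
    return FitResult(
        tensor=tensor,
        residuals=residuals,
        sigmas=sigmas,
        quality=quality,
        excluded=list(excluded),
        n_used=len(rows),
    )


def fit_with_exclusion(
    sites: Sequence[LabeledSite],
    obs: Sequence[Observation],
    lanthanide_pos,
    cond: FieldConditions | None = None,
    k_sigma: float = 3.0,
    motional_blacklist: Sequence[str] = (),
    min_keep: int = MIN_OBSERVATIONS,
    lanthanide_label: str = "",
) -> FitResult:
    """Tensor fit with motional blacklisting and iterative outlier rejection.

    Observations at blacklisted sites are removed up front (reason
    "motional_blacklist").  The fit then iterates: solve, find the single
    worst row whose studentized residual |r| / (sigma * sqrt(1 - h))
    exceeds k_sigma (h the row's leverage — without this correction a
    gross error at a high-leverage site drags the fit toward itself and
    hides below threshold), drop it, refit — until no row exceeds the
    threshold or dropping would leave fewer than ``min_keep`` rows
    (flagged by a final "stopped_at_min_count" entry).
    """
    if not k_sigma > 0:
        raise ValueError("k_sigma must be > 0")
    cond = cond or FieldConditions()
    sites_by_id = {s.id: s for s in sites}
    all_rows = _build_rows(sites_by_id, obs, lanthanide_pos, cond)
    blacklist = set(motional_blacklist)
    excluded = []
    rows = []
    for r in all_rows:
        oid = r[1]
        site_id = next(o.site_id for o in obs if o.id == oid)
        if site_id in blacklist:
            excluded.append((r[0], "motional_blacklist"))
        else:
            rows.append(r)
    while True:
        if len(rows) < MIN_OBSERVATIONS:
            raise ValueError(
                f"only {len(rows)} usable observations remain (< {MIN_OBSERVATIONS})"
            )
        c5 = _solve(rows)
        aw = np.array([r[3] / r[5] for r in rows])
        q = np.linalg.qr(aw, mode="reduced")[0]
        leverage = np.minimum(np.sum(q**2, axis=1), 1.0 - 1e-12)
        z = np.array(
            [abs(r[3] @ c5 - r[4]) / r[5] for r in rows]
        ) / np.sqrt(1.0 - leverage)
        worst = int(np.argmax(z))
        if z[worst] <= k_sigma:
            break
        if len(rows) - 1 < min_keep:
            excluded.append((rows[worst][0], "stopped_at_min_count"))
            break
        excluded.append((rows[worst][0], f"outlier_{z[worst]:.2f}_sigma"))
        rows.pop(worst)
    tensor = SusceptibilityTensor(c5, lanthanide_label)
    return _result(tensor, rows, excluded, all_rows=all_rows)


def bootstrap_tensor(
    sites,
    obs,
    lanthanide_pos,
    cond: FieldConditions | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Case-resampling bootstrap of the fit; returns (n_boot,) samples of
    dchi_ax for interval construction."""
    rng = np.random.default_rng(seed)
    obs = list(obs)
    out = np.empty(n_boot)
    n = len(obs)
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            try:
                fit = fit_tensor(sites, [obs[i] for i in idx], lanthanide_pos, cond)
            except ValueError:
                continue  # degenerate resample; redraw
            out[b] = fit.tensor.dchi_ax
            break
        else:  # pragma: no cover
            raise RuntimeError("bootstrap could not find a full-rank resample")
    return out


def vector_order_parameters(vectors: np.ndarray) -> np.ndarray:
    """Generalized order parameters S^2 for per-frame unit vectors.

    ``vectors``: (n_frames, n_sites, 3).  S^2 = (3 tr<bb^T>^2 - 1)/2, the
    plateau of the vector autocorrelation; 1 = rigid, 0 = isotropic.
    """
    v = np.asarray(vectors, dtype=float)
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    outer = np.einsum("fsi,fsj->sij", v, v) / v.shape[0]
    tr2 = np.einsum("sij,sji->s", outer, outer)
    return (3.0 * tr2 - 1.0) / 2.0


def flag_mobile_sites(
    site_ids: Sequence[str], vectors: np.ndarray, s2_threshold: float = 0.8
) -> list[str]:
    """Site ids whose bond-vector order parameter falls below the
    threshold — candidates for the motional blacklist (internal motion
    averages their RDCs)."""
    s2 = vector_order_parameters(vectors)
    return [sid for sid, v in zip(site_ids, s2) if v < s2_threshold]
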