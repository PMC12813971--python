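"""Conformer screening against assigned glycan PCS/RDC observations.

For every glycosylation site, each candidate representative structure is
scored against the site's assigned crosspeaks with the weighted chi^2

    chi^2 = sum_obs [ (d_pcs/sigma_pcs)^2 + (d_rdc/sigma_rdc)^2 ]

and per-observable accept flags (|residual| <= tolerance * sigma, default
2 sigma).  Two-structure 50:50 averages over candidate pairs are screened
the same way; a probability-weighted average over the full ensemble is
deliberately not offered — the sparse data cannot support extra weight
variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assign import Conformer, TOLERANCE_MULT_DEFAULT, average_predictions
from .forward import pcs_predict, rdc_predict
from .sites import FieldConditions, Observation
from .tensor import SusceptibilityTensor

__all__ = [
    "SiteScreen",
    "ScreenReport",
    "screen_single",
    "screen_pairs",
    "motional_restriction_summary",
]

#: a site counts as motionally restricted when this fraction of its
#: observations is matched by at most two structures
RESTRICTED_FRACTION_DEFAULT = 0.75


def _conformer_prediction(conf: Conformer, slot, tensor, lanthanide_pos, cond):
    site = conf.labeled(slot)
    if site is None:
        return (np.nan, np.nan)
    return (
        pcs_predict(tensor, lanthanide_pos, site),
        rdc_predict(tensor, site, cond),
    )


def _score(obs_slots, pred_by_slot, tolerance_mult):
    """chi^2, accept flags and residual records of one candidate (single
    structure or averaged pair) against a site's observations."""
    chi2 = 0.0
    accepts = []
    rows = []
    for o, slot in obs_slots:
        pcs_p, rdc_p = pred_by_slot[slot]
        row = {"obs_id": o.id, "slot": slot}
        ok_parts = []
        if o.has_pcs and np.isfinite(pcs_p):
            d = pcs_p - o.pcs_ppm
            chi2 += (d / o.pcs_err) ** 2
            row["pcs_resid"] = d
            row["pcs_accept"] = bool(abs(d) <= tolerance_mult * o.pcs_err)
            ok_parts.append(row["pcs_accept"])
        if o.has_rdc and np.isfinite(rdc_p):
            d = rdc_p - o.rdc_hz
            chi2 += (d / o.rdc_err) ** 2
            row["rdc_resid"] = d
            row["rdc_accept"] = bool(abs(d) <= tolerance_mult * o.rdc_err)
            ok_parts.append(row["rdc_accept"])
        accepts.extend(ok_parts)
        rows.append(row)
    frac = float(np.mean(accepts)) if accepts else np.nan
    return float(chi2), frac, rows


@dataclass
class SiteScreen:
    """Screening outcome for one glycosylation site."""

    glyco_site: str
    candidates: pd.DataFrame          # ordered by descending cluster probability
    per_obs: dict                     # conformer id -> residual records
    best_single: Optional[str] = None
    best_single_chi2: float = np.nan
    best_pair: Optional[tuple] = None  # (id_a, id_b, weight)
    best_pair_chi2: float = np.nan
    improving_pairs: list = field(default_factory=list)
    restriction_index: float = np.nan  # accept fraction of the best model


@dataclass
class ScreenReport:
    lanthanide: str
    sites: dict  # glyco_site -> SiteScreen


def _site_candidates(conformers, glyco_site, top_k):
    cands = [c for c in conformers if c.glyco_site == glyco_site]
    # reproducible order: descending cluster probability, id as tie-break
    cands.sort(key=lambda c: (-(c.probability if c.probability is not None else -np.inf), c.id))
    if top_k is not None:
        cands = cands[:top_k]
    return cands


def screen_single(
    conformers: Sequence[Conformer],
    tensor: SusceptibilityTensor,
    lanthanide_pos,
    site_obs: dict,
    cond: FieldConditions | None = None,
    tolerance_mult: float = TOLERANCE_MULT_DEFAULT,
    top_k: Optional[int] = None,
) -> ScreenReport:
    """Score every candidate structure site-by-site.

    ``site_obs``: {glyco_site: [(Observation, slot), ...]} — the staged
    output of the assignment step.  ``top_k`` restricts candidates to the
    k most probable clusters (the analysis convention is 4).
    """
    cond = cond or FieldConditions()
    report = ScreenReport(lanthanide=tensor.lanthanide_label, sites={})
    all_sites = sorted({c.glyco_site for c in conformers})
    for g in all_sites:
        obs_slots = site_obs.get(g, [])
        if not obs_slots:
            warnings.warn(f"site {g}: no assigned observations; skipped", stacklevel=2)
            continue
        cands = _site_candidates(conformers, g, top_k)
        rows, per_obs = [], {}
        for c in cands:
            preds = {
                slot: _conformer_prediction(c, slot, tensor, lanthanide_pos, cond)
                for _, slot in obs_slots
            }
            chi2, frac, rec = _score(obs_slots, preds, tolerance_mult)
            rows.append(
                {
                    "conformer": c.id,
                    "probability": c.probability,
                    "chi2": chi2,
                    "accept_fraction": frac,
                }
            )
            per_obs[c.id] = rec
        df = pd.DataFrame(rows)
        best = df.loc[df.chi2.idxmin()]
        ss = SiteScreen(
            glyco_site=g,
            candidates=df,
            per_obs=per_obs,
            best_single=str(best.conformer),
            best_single_chi2=float(best.chi2),
        )
        ss.restriction_index = float(best.accept_fraction)
        report.sites[g] = ss
    return report


def screen_pairs(
    conformers: Sequence[Conformer],
    tensor: SusceptibilityTensor,
    lanthanide_pos,
    site_obs: dict,
    cond: FieldConditions | None = None,
    tolerance_mult: float = TOLERANCE_MULT_DEFAULT,
    top_k: Optional[int] = None,
    weight_grid: Sequence[float] = (0.5,),
) -> ScreenReport:
    """Screen two-structure weighted averages for every candidate pair.

    The default weight grid holds only 0.5 (the 50:50 average); pairs that
    strictly reduce chi^2 against the best single structure are listed in
    ``improving_pairs``.  The report's best model is whichever of best
    single / best pair has the lower chi^2.
    """
    cond = cond or FieldConditions()
    report = screen_single(
        conformers, tensor, lanthanide_pos, site_obs, cond, tolerance_mult, top_k
    )
    for g, ss in report.sites.items():
        cands = _site_candidates(conformers, g, top_k)
        if len(cands) < 2:
            continue
        obs_slots = site_obs[g]
        slot_list = [slot for _, slot in obs_slots]
        pred_cache = {
            c.id: {
                slot: _conformer_prediction(c, slot, tensor, lanthanide_pos, cond)
                for slot in slot_list
            }
            for c in cands
        }
        best_pair, best_chi2, best_frac = None, np.inf, np.nan
        improving = []
        for i in range(len(cands) - 1):
            for j in range(i + 1, len(cands)):
                a, b = cands[i].id, cands[j].id
                for w in weight_grid:
                    preds = {
                        slot: average_predictions(
                            pred_cache[a][slot], pred_cache[b][slot], w
                        )
                        for slot in slot_list
                    }
                    chi2, frac, _ = _score(obs_slots, preds, tolerance_mult)
                    if chi2 < best_chi2:
                        best_pair, best_chi2, best_frac = (a, b, float(w)), chi2, frac
                    if chi2 < ss.best_single_chi2:
                        improving.append({"pair": (a, b), "weight": float(w), "chi2": chi2})
        ss.best_pair = best_pair
        ss.best_pair_chi2 = float(best_chi2)
        ss.improving_pairs = improving
        if np.isfinite(best_chi2) and best_chi2 < ss.best_single_chi2:
            ss.restriction_index = float(best_frac)
    return report


def motional_restriction_summary(
    reports: Sequence[ScreenReport],
    site_obs_by_lanthanide: dict,
    restricted_fraction: float = RESTRICTED_FRACTION_DEFAULT,
) -> pd.DataFrame:
    """Per-site summary across lanthanides: the largest experimental |RDC|,
    the best-model accept fraction, and a "restricted" flag set when at
    least ``restricted_fraction`` of the site's observations are matched by
    one structure or a two-structure average.

    Small experimental RDCs with poor single/pair coverage indicate
    extensive motional averaging (uniform bond sampling drives RDCs to 0);
    large RDCs matched by one or two structures indicate a restricted,
    surface-contacting glycan.
    """
    sites = sorted(
        {g for r in reports for g in r.sites}
        | {g for m in site_obs_by_lanthanide.values() for g in m}
    )
    rows = []
    for g in sites:
        max_rdc = np.nan
        best_frac = np.nan
        for rep in reports:
            obs_slots = site_obs_by_lanthanide.get(rep.lanthanide, {}).get(g, [])
            rdcs = [abs(o.rdc_hz) for o, _ in obs_slots if o.has_rdc]
            if rdcs:
                m = max(rdcs)
                max_rdc = m if np.isnan(max_rdc) else max(max_rdc, m)
            if g in rep.sites:
                f = rep.sites[g].restriction_index
                if np.isfinite(f):
                    best_frac = f if np.isnan(best_frac) else max(best_frac, f)
        rows.append(
            {
                "glyco_site": g,
                "max_abs_rdc_hz": max_rdc,
                "best_accept_fraction": best_frac,
                "restricted": bool(best_frac >= restricted_fraction)
                if np.isfinite(best_frac)
                else None,
            }
        )
    return pd.DataFrame(rows)
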