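"""Class-constrained assignment of glycan crosspeaks to glycosylation
sites.

Each 2-D crosspeak carries a (PCS, RDC) pair that must be assigned jointly.
Chemical shifts fix the chemical class — first-GlcNAc C1, second-GlcNAc C1,
or acetyl methyl — but not the glycosylation site.  Multiplicities: one
first_C1 and one second_C1 per site, two acetyls per site (the acetyl's
GlcNAc identity is itself decided by the optimization and emitted from the
matched geometry).

Because the classes do not compete for slots, the global minimum-cost
assignment decouples into three independent rectangular linear assignment
problems, solved exactly with ``scipy.optimize.linear_sum_assignment``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .forward import pcs_predict, rdc_predict
from .sites import FieldConditions, LabeledSite, Observation, SiteClass
from .tensor import SusceptibilityTensor

__all__ = [
    "Conformer",
    "predict_table",
    "assign",
    "average_predictions",
    "AssignmentResult",
    "TOLERANCE_MULT_DEFAULT",
]

#: "acceptable match" = within 2 x experimental error
TOLERANCE_MULT_DEFAULT = 2.0

#: cost assigned to a pairing with no comparable observable
_INFEASIBLE = 1.0e9


@dataclass(frozen=True)
class Conformer:
    """One representative glycan structure at one glycosylation site."""

    id: str
    glyco_site: str
    sites: tuple
    probability: Optional[float] = None

    def labeled(self, slot: str) -> Optional[LabeledSite]:
        """Labeled site filling ``slot`` in {first_C1, second_C1,
        acetyl_1, acetyl_2}; None when the atom is missing."""
        for s in self.sites:
            if slot == "first_C1" and s.site_class is SiteClass.first_C1:
                return s
            if slot == "second_C1" and s.site_class is SiteClass.second_C1:
                return s
            if (
                slot in ("acetyl_1", "acetyl_2")
                and s.site_class is SiteClass.acetyl
                and s.glcnac_index == int(slot[-1])
            ):
                return s
        return None


SLOTS = ("first_C1", "second_C1", "acetyl_1", "acetyl_2")
_SLOT_CLASS = {
    "first_C1": SiteClass.first_C1,
    "second_C1": SiteClass.second_C1,
    "acetyl_1": SiteClass.acetyl,
    "acetyl_2": SiteClass.acetyl,
}


def predict_table(
    conformers: Sequence[Conformer],
    tensor: SusceptibilityTensor,
    lanthanide_pos,
    cond: FieldConditions | None = None,
) -> pd.DataFrame:
    """Predicted (PCS, RDC) for every (site, conformer, slot).

    Rows are ordered by glycosylation site, then descending cluster
    probability, then slot; conformers missing a labeled atom get NaN
    ("ND") entries for that slot.
    """
    cond = cond or FieldConditions()
    rows = []
    for c in conformers:
        for slot in SLOTS:
            site = c.labeled(slot)
            rows.append(
                {
                    "glyco_site": c.glyco_site,
                    "conformer": c.id,
                    "probability": np.nan if c.probability is None else c.probability,
                    "slot": slot,
                    "site_class": _SLOT_CLASS[slot].value,
                    "pcs_ppm": np.nan if site is None else pcs_predict(tensor, lanthanide_pos, site),
                    "rdc_hz": np.nan if site is None else rdc_predict(tensor, site, cond),
                }
            )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["glyco_site", "probability", "conformer", "slot"],
        ascending=[True, False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return df


def _pair_cost(o: Observation, pred: pd.DataFrame):
    """min over candidate conformers of the weighted squared residual of
    observation ``o`` against the slot predictions in ``pred`` (rows of one
    (site, slot)); returns (cost, best conformer id)."""
    best = (_INFEASIBLE, None)
    for _, row in pred.iterrows():
        cost, n_terms = 0.0, 0
        if o.has_pcs and np.isfinite(row.pcs_ppm):
            cost += ((row.pcs_ppm - o.pcs_ppm) / o.pcs_err) ** 2
            n_terms += 1
        if o.has_rdc and np.isfinite(row.rdc_hz):
            cost += ((row.rdc_hz - o.rdc_hz) / o.rdc_err) ** 2
            n_terms += 1
        if n_terms and cost < best[0]:
            best = (cost, row.conformer)
    return best


@dataclass
class AssignmentResult:
    """Optimal crosspeak-to-site mapping.

    ``mapping``: observation id -> (glyco_site, conformer id, slot).
    ``records``: per-observation residuals and accept flags at the chosen
    pairing.  ``total_cost``: sum of weighted squared residuals.
    """

    mapping: dict
    records: pd.DataFrame
    total_cost: float


def assign(
    obs: Sequence[Observation],
    predictions: pd.DataFrame,
    tolerance_mult: float = TOLERANCE_MULT_DEFAULT,
) -> AssignmentResult:
    """Minimum-cost class-constrained assignment of crosspeaks to sites.

    For each pairing the best-matching candidate conformer of the site is
    used.  Fewer observations than slots leaves sites unfilled; more is an
    error.  Observations are id-sorted first so the outcome is
    deterministic (ties resolved by the solver on that fixed ordering).
    """
    obs = sorted(obs, key=lambda o: o.id)
    sites_all = sorted(predictions["glyco_site"].unique())
    mapping = {}
    records = []
    total = 0.0
    for cls in (SiteClass.first_C1, SiteClass.second_C1, SiteClass.acetyl):
        cls_obs = [o for o in obs if o.site_class is cls]
        if not cls_obs:
            continue
        if cls is SiteClass.acetyl:
            slots = [(g, s) for g in sites_all for s in ("acetyl_1", "acetyl_2")]
        else:
            slots = [(g, cls.value) for g in sites_all]
        if len(cls_obs) > len(slots):
            raise ValueError(
                f"{len(cls_obs)} {cls.value} observations but only "
                f"{len(slots)} slots — infeasible multiplicities"
            )
        cost = np.full((len(cls_obs), len(slots)), _INFEASIBLE)
        best_conf = {}
        for j, (g, slot) in enumerate(slots):
            pred = predictions[
                (predictions.glyco_site == g) & (predictions.slot == slot)
            ]
            for i, o in enumerate(cls_obs):
                c, conf = _pair_cost(o, pred)
                cost[i, j] = c
                best_conf[(i, j)] = conf
        ri, ci = linear_sum_assignment(cost)
        for i, j in zip(ri, ci):
            g, slot = slots[j]
            conf = best_conf[(i, j)]
            o = cls_obs[i]
            mapping[o.id] = (g, conf, slot)
            total += cost[i, j]
            pred = predictions[
                (predictions.glyco_site == g)
                & (predictions.slot == slot)
                & (predictions.conformer == conf)
            ].iloc[0]
            d_pcs = (pred.pcs_ppm - o.pcs_ppm) if o.has_pcs else np.nan
            d_rdc = (pred.rdc_hz - o.rdc_hz) if o.has_rdc else np.nan
            records.append(
                {
                    "obs_id": o.id,
                    "glyco_site": g,
                    "conformer": conf,
                    "slot": slot,
                    "pcs_resid": d_pcs,
                    "rdc_resid": d_rdc,
                    "pcs_accept": bool(abs(d_pcs) <= tolerance_mult * o.pcs_err)
                    if o.has_pcs and np.isfinite(d_pcs)
                    else None,
                    "rdc_accept": bool(abs(d_rdc) <= tolerance_mult * o.rdc_err)
                    if o.has_rdc and np.isfinite(d_rdc)
                    else None,
                    "cost": cost[i, j],
                }
            )
    return AssignmentResult(
        mapping=mapping,
        records=pd.DataFrame(records),
        total_cost=float(total),
    )


def average_predictions(pred_a, pred_b, weight: float):
    """Convex combination ``weight * a + (1 - weight) * b`` of two
    (PCS, RDC) prediction pairs.

    At the degenerate weights 1 and 0 the corresponding input is returned
    unchanged; otherwise a missing member on either side propagates as
    missing (NaN).
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must be within [0, 1]")
    if weight == 1.0:
        return tuple(pred_a)
    if weight == 0.0:
        return tuple(pred_b)

    def comb(a, b):
        if a is None or b is None:
            return np.nan
        a, b = float(a), float(b)
        if not (np.isfinite(a) and np.isfinite(b)):
            return np.nan
        return weight * a + (1.0 - weight) * b

    return tuple(comb(a, b) for a, b in zip(pred_a, pred_b))
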