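"""Synthetic scenarios with known ground truth for every pipeline stage.

The generator emulates the data shapes of a lanthanide-tagged, sparsely
13C-labeled glycoprotein study: a rigid pseudo-protein carrying ~20 labeled
methyl sites 10-40 A from the ion, three N-glycosylation sites each with
two GlcNAc residues (anomeric C1-H1 vector + acetyl methyl axis per
residue), two lanthanide-like susceptibility tensors of opposite sign and
~60% magnitude ratio, the 15% / 0.03 ppm PCS noise model with ~1.6 Hz RDC
noise, and boosted pseudo-trajectories whose cluster populations are
recoverable exactly (in expectation) by cumulant reweighting.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .assign import Conformer
from .cluster import FrameSeries
from .constants import KB_KCAL_MOL, PCS_PREFACTOR
from .forward import pcs_predict, rdc_predict
from .sites import (
    FieldConditions,
    LabeledSite,
    Observation,
    SiteClass,
    VectorKind,
)
from .tensor import SusceptibilityTensor, c5_from_matrix

__all__ = [
    "make_tensor",
    "default_tensors",
    "make_geometry",
    "make_observables",
    "make_boosted_frames",
    "SyntheticScenario",
    "default_scenario",
    "TB_LIKE_DCHI_AX",
    "TM_LIKE_DCHI_AX",
    "RDC_SIGMA_DEFAULT",
]

# Axial anisotropies (1e-32 m^3) calibrated so that the on-axis PCS at
# 40 A is -0.13 ppm (Tb-like) and +0.08 ppm (Tm-like): opposite signs,
# magnitude ratio 1.63.
TB_LIKE_DCHI_AX = -0.13 * 40.0**3 / (2.0 * PCS_PREFACTOR)
TM_LIKE_DCHI_AX = +0.08 * 40.0**3 / (2.0 * PCS_PREFACTOR)

#: default glycan/protein RDC uncertainty, Hz
RDC_SIGMA_DEFAULT = 1.6

#: default per-lanthanide protein data counts (n_pcs, n_rdc)
PROTEIN_COUNTS_DEFAULT = {"Tm": (20, 11), "Tb": (14, 7)}


def make_tensor(
    dchi_ax: float,
    rhombicity: float,
    seed: int = 0,
    lanthanide_label: str = "",
) -> SusceptibilityTensor:
    """Tensor with requested axial anisotropy and rhombicity ratio
    (|dchi_rh/dchi_ax| = rhombicity, in [0, 2/3]) in a random principal
    frame drawn from the seed."""
    if not abs(rhombicity) <= 2.0 / 3.0:
        raise ValueError("rhombicity must satisfy |rh| <= 2/3")
    chi_z = 2.0 / 3.0 * dchi_ax
    dchi_rh = rhombicity * dchi_ax
    chi_x = (-chi_z + dchi_rh) / 2.0
    chi_y = (-chi_z - dchi_rh) / 2.0
    rng = np.random.default_rng(seed)
    q = Rotation.random(rng=rng).as_matrix()
    m = q @ np.diag([chi_x, chi_y, chi_z]) @ q.T
    m = 0.5 * (m + m.T)
    m -= np.eye(3) * np.trace(m) / 3.0
    return SusceptibilityTensor(c5_from_matrix(m), lanthanide_label)


def default_tensors(seed: int = 0) -> dict:
    """The Tb-like / Tm-like ground-truth pair: opposite signs, ~1.6
    magnitude ratio, slightly different rhombicities."""
    return {
        "Tb": make_tensor(TB_LIKE_DCHI_AX, 0.30, seed=seed * 2 + 11, lanthanide_label="Tb"),
        "Tm": make_tensor(TM_LIKE_DCHI_AX, 0.25, seed=seed * 2 + 12, lanthanide_label="Tm"),
    }


def _random_unit(rng, n=None):
    v = rng.normal(size=(3,) if n is None else (n, 3))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


GLYCO_SLOT_SPECS = (
    ("first_C1", SiteClass.first_C1, VectorKind.ch_bond, None),
    ("second_C1", SiteClass.second_C1, VectorKind.ch_bond, None),
    ("acetyl_1", SiteClass.acetyl, VectorKind.methyl_axis, 1),
    ("acetyl_2", SiteClass.acetyl, VectorKind.methyl_axis, 2),
)


def _conformer_rmsd(a: Conformer, b: Conformer) -> float:
    pa = np.stack([a.labeled(s).position for s, *_ in GLYCO_SLOT_SPECS])
    pb = np.stack([b.labeled(s).position for s, *_ in GLYCO_SLOT_SPECS])
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def make_geometry(
    n_protein_sites: int = 20,
    n_glyco_sites: int = 3,
    conformers_per_site: int = 4,
    seed: int = 0,
    rmsd_floor: float = 2.0,
):
    """Pseudo-protein geometry around a lanthanide at the origin.

    Protein methyl sites are scattered 10-40 A from the ion with random
    methyl axes.  The first glycosylation site sits closest to the ion
    (~12 A, giving it the largest-magnitude PCS per class); the others sit
    farther out.  Each site gets ``conformers_per_site`` candidate
    conformers built by rigidly reorienting and jittering a local
    two-GlcNAc arrangement; a minimum pairwise RMSD between conformers is
    enforced by resampling.

    Returns (protein_sites, conformer library dict, lanthanide position).
    """
    if min(n_protein_sites, n_glyco_sites, conformers_per_site) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    lanthanide_pos = np.zeros(3)
    protein_sites = [
        LabeledSite(
            id=f"P{i + 1:02d}",
            site_class=SiteClass.protein_methyl,
            position=_random_unit(rng) * rng.uniform(10.0, 40.0),
            vector=_random_unit(rng),
            vector_kind=VectorKind.methyl_axis,
        )
        for i in range(n_protein_sites)
    ]
    # local arrangement of the four labeled glycan positions (A), roughly a
    # two-residue sugar: C1 atoms ~5 A apart, acetyl carbons offset sideways
    template = np.array(
        [
            [0.0, 0.0, 0.0],    # first_C1
            [4.8, 1.0, 0.6],    # second_C1
            [1.5, -2.6, 1.2],   # acetyl_1
            [6.2, -1.8, -0.9],  # acetyl_2
        ]
    )
    radii = 12.0 + 7.0 * np.arange(n_glyco_sites)  # 12, 19, 26, ... A
    library = {}
    for gi in range(n_glyco_sites):
        gname = f"NG{gi + 1}"
        base_dir = _random_unit(rng)
        base = base_dir * radii[gi]
        confs: list[Conformer] = []
        attempts = 0
        while len(confs) < conformers_per_site:
            attempts += 1
            if attempts > 500:
                raise RuntimeError("could not satisfy conformer diversity floor")
            rot = Rotation.random(rng=rng).as_matrix()
            shift = base + rng.normal(scale=2.0, size=3)
            pos = template @ rot.T + shift
            sites = tuple(
                LabeledSite(
                    id=f"{gname}/c{len(confs) + 1}/{slot}",
                    site_class=cls,
                    position=pos[k],
                    vector=_random_unit(rng),
                    vector_kind=kind,
                    glyco_site=gname,
                    glcnac_index=idx,
                )
                for k, (slot, cls, kind, idx) in enumerate(GLYCO_SLOT_SPECS)
            )
            cand = Conformer(
                id=f"{gname}-c{len(confs) + 1}", glyco_site=gname, sites=sites
            )
            if all(_conformer_rmsd(cand, c) >= rmsd_floor for c in confs):
                confs.append(cand)
        # descending synthetic cluster probabilities, normalized
        probs = rng.dirichlet(np.full(conformers_per_site, 2.0))
        probs = np.sort(probs)[::-1]
        library[gname] = [
            Conformer(id=c.id, glyco_site=c.glyco_site, sites=c.sites, probability=float(p))
            for c, p in zip(confs, probs)
        ]
    return protein_sites, library, lanthanide_pos


def _noisy_pcs(rng, true, noise_scale):
    sd = max(0.15 * abs(true), 0.03) * noise_scale
    return true + rng.normal(scale=sd) if sd > 0 else true


def make_observables(
    tensors: dict,
    protein_sites: Sequence[LabeledSite],
    library: dict,
    lanthanide_pos,
    mixture_weights: dict | None = None,
    cond: FieldConditions | None = None,
    protein_counts: dict | None = None,
    glycan_nd_pcs: int = 1,
    glycan_nd_rdc: int = 4,
    rdc_sigma: float = RDC_SIGMA_DEFAULT,
    noise_scale: float = 1.0,
    seed: int = 0,
):
    """Noisy observations for every lanthanide.

    Glycan observables are mixture-weighted averages of the per-conformer
    predictions (``mixture_weights``: {site: weight vector}, default
    weight 1 on the most probable conformer), with the 15%/0.03 ppm PCS
    noise model and Gaussian RDC noise; ``glycan_nd_*`` crosspeak values
    per lanthanide are masked ND to mimic paramagnetic data loss.

    Returns {lanthanide: {"protein": [...], "glycan": [...],
    "truth": {obs id: (site, slot)}}}.
    """
    cond = cond or FieldConditions()
    protein_counts = protein_counts or PROTEIN_COUNTS_DEFAULT
    rng = np.random.default_rng(seed)
    out = {}
    for lab, tensor in tensors.items():
        n_pcs, n_rdc = protein_counts.get(lab, (len(protein_sites), len(protein_sites) // 2))
        pcs_sites = list(rng.choice(len(protein_sites), size=min(n_pcs, len(protein_sites)), replace=False))
        rdc_sites = set(rng.choice(pcs_sites, size=min(n_rdc, len(pcs_sites)), replace=False).tolist())
        protein_obs = []
        for i in pcs_sites:
            s = protein_sites[i]
            pcs = pcs_predict(tensor, lanthanide_pos, s)
            rdc = rdc_predict(tensor, s, cond) if i in rdc_sites else None
            protein_obs.append(
                Observation(
                    id=f"{lab}-{s.id}",
                    site_class=SiteClass.protein_methyl,
                    lanthanide=lab,
                    pcs_ppm=_noisy_pcs(rng, pcs, noise_scale),
                    rdc_hz=None
                    if rdc is None
                    else rdc + rng.normal(scale=rdc_sigma * noise_scale),
                    rdc_err=None if rdc is None else rdc_sigma,
                    site_id=s.id,
                )
            )
        glycan_obs, truth = [], {}
        k = 0
        rows = []
        for gname, confs in library.items():
            w = None if mixture_weights is None else np.asarray(mixture_weights[gname], float)
            if w is None:
                w = np.zeros(len(confs))
                w[0] = 1.0
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"mixture weights for {gname} must sum to 1")
            for slot, cls, _kind, _idx in GLYCO_SLOT_SPECS:
                pcs = sum(
                    wi * pcs_predict(tensor, lanthanide_pos, c.labeled(slot))
                    for wi, c in zip(w, confs)
                    if wi > 0
                )
                rdc = sum(
                    wi * rdc_predict(tensor, c.labeled(slot), cond)
                    for wi, c in zip(w, confs)
                    if wi > 0
                )
                rows.append((gname, slot, cls, pcs, rdc))
        # ND masking: drop PCSs / RDCs from randomly chosen crosspeaks;
        # disjoint draws keep every crosspeak observable at least once
        nd_pcs = set(rng.choice(len(rows), size=min(glycan_nd_pcs, len(rows)), replace=False).tolist())
        rest = [i for i in range(len(rows)) if i not in nd_pcs]
        nd_rdc = set(rng.choice(rest, size=min(glycan_nd_rdc, len(rest)), replace=False).tolist())
        for idx, (gname, slot, cls, pcs, rdc) in enumerate(rows):
            if idx in nd_pcs and idx in nd_rdc:
                continue
            k += 1
            oid = f"{lab}-g{k:02d}"
            glycan_obs.append(
                Observation(
                    id=oid,
                    site_class=cls,
                    lanthanide=lab,
                    pcs_ppm=None if idx in nd_pcs else _noisy_pcs(rng, pcs, noise_scale),
                    rdc_hz=None
                    if idx in nd_rdc
                    else rdc + rng.normal(scale=rdc_sigma * noise_scale),
                    rdc_err=None if idx in nd_rdc else rdc_sigma,
                    site_id=None,
                )
            )
            truth[oid] = (gname, slot)
        out[lab] = {"protein": protein_obs, "glycan": glycan_obs, "truth": truth}
    return out


def make_boosted_frames(
    centers: np.ndarray,
    populations: Sequence[float],
    n_frames: int,
    seed: int = 0,
    boost_mean: float | Sequence[float] = 45.0,
    boost_sd: float | Sequence[float] = 8.0,
    coord_sd: float = 0.25,
    temperature: float = 300.0,
    energy_offset: float = -5000.0,
):
    """Boosted pseudo-trajectory around planted cluster centres.

    Biased occupancies are constructed analytically as
    p_biased ~ p_target / <exp(beta DV)>  with the Gaussian closed form
    <exp(beta DV)> = exp(beta mu + beta^2 sd^2 / 2), so exact second-order
    cumulant reweighting recovers ``populations`` in expectation.  Boost
    draws are clipped at 0 (negligible for mean >> sd).  Returns
    (FrameSeries, true labels); frames are shuffled.
    """
    centers = np.asarray(centers, dtype=float)
    k = len(centers)
    p_t = np.asarray(populations, dtype=float)
    if abs(p_t.sum() - 1.0) > 1e-9:
        raise ValueError("populations must sum to 1")
    mu = np.broadcast_to(np.asarray(boost_mean, float), (k,))
    sd = np.broadcast_to(np.asarray(boost_sd, float), (k,))
    beta = 1.0 / (KB_KCAL_MOL * temperature)
    log_factor = beta * mu + 0.5 * beta**2 * sd**2
    log_biased = np.log(p_t) - log_factor
    p_biased = np.exp(log_biased - np.max(log_biased))
    p_biased /= p_biased.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_frames, p_biased)
    coords, boosts, labels = [], [], []
    for c in range(k):
        n = counts[c]
        if n == 0:
            continue
        coords.append(centers[c] + rng.normal(scale=coord_sd, size=(n,) + centers[c].shape))
        boosts.append(np.clip(rng.normal(mu[c], sd[c], size=n), 0.0, None))
        labels.append(np.full(n, c))
    coords = np.concatenate(coords)
    boosts = np.concatenate(boosts)
    labels = np.concatenate(labels)
    energy = energy_offset + rng.normal(scale=3.0, size=len(labels))
    perm = rng.permutation(len(labels))
    series = FrameSeries(
        coords=coords[perm],
        energy=energy[perm],
        boost=boosts[perm],
        indices=np.arange(len(labels)),
    )
    return series, labels[perm]


# ---------------------------------------------------------------------------


@dataclass
class SyntheticScenario:
    """Fully reproducible synthetic study: geometry, tensors, weights and
    noise settings, sufficient to score every recovery test."""

    seed: int
    tensors: dict
    protein_sites: list
    library: dict
    lanthanide_pos: np.ndarray
    mixture_weights: dict
    rdc_sigma: float = RDC_SIGMA_DEFAULT
    protein_counts: dict = field(default_factory=lambda: dict(PROTEIN_COUNTS_DEFAULT))

    def observables(self, noise_scale: float = 1.0, seed: Optional[int] = None):
        return make_observables(
            self.tensors,
            self.protein_sites,
            self.library,
            self.lanthanide_pos,
            mixture_weights=self.mixture_weights,
            protein_counts=self.protein_counts,
            rdc_sigma=self.rdc_sigma,
            noise_scale=noise_scale,
            seed=self.seed if seed is None else seed,
        )

    # -- JSON round trip ----------------------------------------------------

    def to_json(self) -> str:
        def site_d(s: LabeledSite):
            return {
                "id": s.id,
                "site_class": s.site_class.value,
                "position": s.position.tolist(),
                "vector": s.vector.tolist(),
                "vector_kind": s.vector_kind.value,
                "glyco_site": s.glyco_site,
                "glcnac_index": s.glcnac_index,
            }

        return json.dumps(
            {
                "seed": self.seed,
                "tensors": {
                    lab: {"c5": t.c5.tolist(), "label": t.lanthanide_label}
                    for lab, t in self.tensors.items()
                },
                "protein_sites": [site_d(s) for s in self.protein_sites],
                "library": {
                    g: [
                        {
                            "id": c.id,
                            "glyco_site": c.glyco_site,
                            "probability": c.probability,
                            "sites": [site_d(s) for s in c.sites],
                        }
                        for c in confs
                    ]
                    for g, confs in self.library.items()
                },
                "lanthanide_pos": np.asarray(self.lanthanide_pos).tolist(),
                "mixture_weights": {
                    g: np.asarray(w, float).tolist() for g, w in self.mixture_weights.items()
                },
                "rdc_sigma": self.rdc_sigma,
                "protein_counts": {k: list(v) for k, v in self.protein_counts.items()},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticScenario":
        d = json.loads(text)

        def site_o(sd):
            return LabeledSite(
                id=sd["id"],
                site_class=SiteClass(sd["site_class"]),
                position=np.array(sd["position"]),
                vector=np.array(sd["vector"]),
                vector_kind=VectorKind(sd["vector_kind"]),
                glyco_site=sd["glyco_site"],
                glcnac_index=sd["glcnac_index"],
            )

        return cls(
            seed=d["seed"],
            tensors={
                lab: SusceptibilityTensor(np.array(td["c5"]), td["label"])
                for lab, td in d["tensors"].items()
            },
            protein_sites=[site_o(sd) for sd in d["protein_sites"]],
            library={
                g: [
                    Conformer(
                        id=cd["id"],
                        glyco_site=cd["glyco_site"],
                        probability=cd["probability"],
                        sites=tuple(site_o(sd) for sd in cd["sites"]),
                    )
                    for cd in confs
                ]
                for g, confs in d["library"].items()
            },
            lanthanide_pos=np.array(d["lanthanide_pos"]),
            mixture_weights={g: np.array(w) for g, w in d["mixture_weights"].items()},
            rdc_sigma=d["rdc_sigma"],
            protein_counts={k: tuple(v) for k, v in d["protein_counts"].items()},
        )


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """The default study conditions: 3 glyco sites x 4 conformers, 20
    protein PCS + 11 RDC (Tm-like) and 14 + 7 (Tb-like), single-conformer
    ground truth (weight 1 on the most probable conformer per site)."""
    protein_sites, library, ln = make_geometry(
        n_protein_sites=20, n_glyco_sites=3, conformers_per_site=4, seed=seed
    )
    weights = {
        g: np.eye(len(confs))[0] for g, confs in library.items()
    }
    return SyntheticScenario(
        seed=seed,
        tensors=default_tensors(seed),
        protein_sites=protein_sites,
        library=library,
        lanthanide_pos=ln,
        mixture_weights=weights,
    )
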