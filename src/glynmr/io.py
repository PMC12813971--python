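"""Readers, writers and pipeline configuration.

File dialects: CSV is comma-separated, dot-decimal, UTF-8, with "ND" for
missing values (matching the convention of paramagnetic NMR data tables);
coordinates are Angstrom with PDB 1-based residue numbering; tensors are
JSON with components in 1e-32 m^3.  Every file written through this module
embeds the hash of the configuration that produced it (a ``# config_hash:``
comment in CSV/DX, a ``"config_hash"`` key in JSON).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

from .cluster import ClusterSet, FrameSeries
from .forward import PcsField
from .sites import LabeledSite, Observation, SiteClass, VectorKind
from .tensor import SusceptibilityTensor

__all__ = [
    "PipelineConfig",
    "load_config",
    "config_hash",
    "read_observations_csv",
    "write_observations_csv",
    "read_tensor_json",
    "write_tensor_json",
    "read_sites_json",
    "write_sites_json",
    "read_structure",
    "write_representative_pdb",
    "write_frames_pdb",
    "frame_series_from_pdb",
    "read_energies_csv",
    "write_energies_csv",
    "write_cluster_labels_csv",
    "write_cluster_summary_json",
    "write_dx",
    "MISSING",
]

MISSING = "ND"


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected on load."""

    seed: int = 0
    # field conditions
    proton_frequency_hz: float = 900.0e6
    temperature_k: float = 298.15
    rch_angstrom: float = 1.095
    methyl_factor: Optional[float] = None  # None -> (3cos^2(110.5deg)-1)/2
    # paths
    structure: Optional[str] = None
    frames: Optional[str] = None
    energies: Optional[str] = None
    observations: Optional[str] = None
    tensor: Optional[str] = None
    # selection spec (see read_structure)
    selection: dict = field(default_factory=dict)
    # clustering
    stride: int = 10
    min_cluster_size: int = 500
    cutoff_start: float = 0.5
    cutoff_stop: float = 4.0
    cutoff_step: float = 0.05
    md_temperature_k: float = 300.0
    # fitting
    k_sigma: float = 3.0
    motional_blacklist: list = field(default_factory=list)
    # screening
    tolerance_mult: float = 2.0
    top_k_clusters: int = 4
    weight_grid: list = field(default_factory=lambda: [0.5])

    def field_conditions(self):
        from . import constants
        from .sites import FieldConditions

        kwargs = dict(
            b0=constants.b0_from_proton_frequency(self.proton_frequency_hz),
            temperature=self.temperature_k,
            rch=self.rch_angstrom,
        )
        if self.methyl_factor is not None:
            kwargs["methyl_factor"] = self.methyl_factor
        return FieldConditions(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML/JSON pipeline config."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path}: top level must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"config {path}: unknown keys {sorted(unknown)}; known keys are {sorted(known)}"
        )
    cfg = PipelineConfig(**data)
    if cfg.stride < 1:
        raise ValueError("config: stride must be >= 1")
    if cfg.min_cluster_size < 1:
        raise ValueError("config: min_cluster_size must be >= 1")
    if cfg.k_sigma <= 0:
        raise ValueError("config: k_sigma must be > 0")
    if not cfg.tolerance_mult > 0:
        raise ValueError("config: tolerance_mult must be > 0")
    return cfg


def config_hash(cfg) -> str:
    """Short deterministic hash of a config (dataclass or mapping)."""
    d = asdict(cfg) if hasattr(cfg, "__dataclass_fields__") else dict(cfg)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _hash_header(cfg) -> str:
    return f"# config_hash: {config_hash(cfg) if cfg is not None else 'none'}\n"


# ---------------------------------------------------------------------------
# observations CSV

_OBS_COLS = [
    "id",
    "site_id",
    "class",
    "lanthanide",
    "pcs_ppm",
    "pcs_err",
    "rdc_hz",
    "rdc_err",
    "use",
]


def write_observations_csv(path, obs: Sequence[Observation], cfg=None) -> None:
    rows = []
    for o in obs:
        rows.append(
            {
                "id": o.id,
                "site_id": o.site_id or MISSING,
                "class": o.site_class.value,
                "lanthanide": o.lanthanide,
                "pcs_ppm": o.pcs_ppm if o.has_pcs else MISSING,
                "pcs_err": o.pcs_err if o.has_pcs else MISSING,
                "rdc_hz": o.rdc_hz if o.has_rdc else MISSING,
                "rdc_err": o.rdc_err if o.has_rdc else MISSING,
                "use": 1,
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_hash_header(cfg))
        pd.DataFrame(rows, columns=_OBS_COLS).to_csv(fh, index=False)


def read_observations_csv(path) -> list[Observation]:
    """Read a crosspeak table; "ND" marks missing values, and the PCS error
    floor (15% / 0.03 ppm) is applied at read time."""
    df = pd.read_csv(path, comment="#", na_values=[MISSING], encoding="utf-8")
    missing = set(_OBS_COLS) - {"use"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "use" in df.columns:
        df = df[df["use"].fillna(1).astype(int) == 1]
    obs = []
    for _, r in df.iterrows():
        has_pcs = pd.notna(r.pcs_ppm)
        has_rdc = pd.notna(r.rdc_hz)
        obs.append(
            Observation(
                id=str(r["id"]),
                site_class=SiteClass(r["class"]),
                lanthanide=str(r["lanthanide"]),
                pcs_ppm=float(r.pcs_ppm) if has_pcs else None,
                pcs_err=float(r.pcs_err) if has_pcs and pd.notna(r.pcs_err) else None,
                rdc_hz=float(r.rdc_hz) if has_rdc else None,
                rdc_err=float(r.rdc_err) if has_rdc else None,
                site_id=None if pd.isna(r.site_id) else str(r.site_id),
            )
        )
    return obs


# ---------------------------------------------------------------------------
# tensors and sites (JSON)


def write_tensor_json(path, tensor: SusceptibilityTensor, lanthanide_pos, cfg=None) -> None:
    payload = {
        "lanthanide_label": tensor.lanthanide_label,
        "c5_1e-32_m3": tensor.c5.tolist(),
        "lanthanide_position_A": np.asarray(lanthanide_pos, float).tolist(),
        "dchi_ax_1e-32_m3": tensor.dchi_ax,
        "dchi_rh_1e-32_m3": tensor.dchi_rh,
        "config_hash": config_hash(cfg) if cfg is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_tensor_json(path):
    d = json.loads(Path(path).read_text())
    tensor = SusceptibilityTensor(np.array(d["c5_1e-32_m3"]), d.get("lanthanide_label", ""))
    pos = np.array(d["lanthanide_position_A"])
    return tensor, pos


def _site_dict(s: LabeledSite) -> dict:
    return {
        "id": s.id,
        "site_class": s.site_class.value,
        "position": s.position.tolist(),
        "vector": s.vector.tolist(),
        "vector_kind": s.vector_kind.value,
        "glyco_site": s.glyco_site,
        "glcnac_index": s.glcnac_index,
    }


def _site_from_dict(d) -> LabeledSite:
    return LabeledSite(
        id=d["id"],
        site_class=SiteClass(d["site_class"]),
        position=np.array(d["position"]),
        vector=np.array(d["vector"]),
        vector_kind=VectorKind(d["vector_kind"]),
        glyco_site=d.get("glyco_site"),
        glcnac_index=d.get("glcnac_index"),
    )


def write_sites_json(path, sites: Sequence[LabeledSite], lanthanide_pos=None, cfg=None) -> None:
    payload = {
        "lanthanide_position_A": None
        if lanthanide_pos is None
        else np.asarray(lanthanide_pos, float).tolist(),
        "sites": [_site_dict(s) for s in sites],
        "config_hash": config_hash(cfg) if cfg is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_sites_json(path):
    d = json.loads(Path(path).read_text())
    sites = [_site_from_dict(sd) for sd in d["sites"]]
    pos = d.get("lanthanide_position_A")
    return sites, (None if pos is None else np.array(pos))


# ---------------------------------------------------------------------------
# structures (PDB via gemmi)

#: default atom-selection spec for structures
DEFAULT_SELECTION = {
    # residue names recognized as the bound lanthanide
    "lanthanide_resnames": ["TB", "TM", "LU", "YB", "DY", "LN"],
    # N-glycan residue name and atom roles
    "glycan_resnames": ["NAG"],
    "anomeric": ["C1", "H1"],
    "acetyl": ["C7", "C8"],  # carbonyl carbon -> methyl carbon axis
    "ring_atoms": ["C1", "C2", "C4", "C5"],
    # protein methyl sites: resname -> [(methyl carbon, axis parent), ...]
    "protein_methyls": {
        "ALA": [["CB", "CA"]],
        "VAL": [["CG1", "CB"], ["CG2", "CB"]],
    },
    # glyco_sites: {label: [[chain, seqid first GlcNAc], [chain, seqid second]]}
    "glyco_sites": {},
    # attachment residues for clustering selections: {label: [[chain, seqid], ...]}
    "attachment_residues": {},
}


def _merged_selection(selection: dict | None) -> dict:
    spec = {k: v for k, v in DEFAULT_SELECTION.items()}
    if selection:
        unknown = set(selection) - set(spec)
        if unknown:
            raise ValueError(f"selection: unknown keys {sorted(unknown)}")
        spec.update(selection)
    return spec


def _find_residue(model, chain_name, seqid):
    chain = model.find_chain(str(chain_name))
    if chain is None:
        raise ValueError(
            f"chain {chain_name!r} not found; available: "
            f"{[c.name for c in model]}"
        )
    for res in chain:
        if res.seqid.num == int(seqid):
            return res
    raise ValueError(
        f"residue {seqid} not found in chain {chain_name}; available seqids: "
        f"{[r.seqid.num for r in chain]}"
    )


def _atom_pos(res, name):
    a = res.find_atom(name, "*")
    return None if a is None else np.array([a.pos.x, a.pos.y, a.pos.z])


def _unit(v):
    return v / np.linalg.norm(v)


def _anomeric_vector(res, c1_name, h1_name, rid):
    c1 = _atom_pos(res, c1_name)
    if c1 is None:
        raise ValueError(f"{rid}: anomeric carbon {c1_name} missing")
    h1 = _atom_pos(res, h1_name)
    if h1 is not None:
        return c1, _unit(h1 - c1)
    # reconstruct H1 direction from tetrahedral geometry: opposite to the
    # resultant of the heavy-atom bond directions at C1
    heavy = []
    for a in res:
        if a.name == c1_name or a.is_hydrogen():
            continue
        pos = np.array([a.pos.x, a.pos.y, a.pos.z])
        d = np.linalg.norm(pos - c1)
        if 0.8 < d < 1.8:
            heavy.append(_unit(pos - c1))
    if not heavy:
        raise ValueError(f"{rid}: cannot place H1, no bonded heavy atoms found")
    warnings.warn(
        f"{rid}: H1 missing; C1-H1 vector reconstructed from standard "
        "tetrahedral geometry",
        stacklevel=2,
    )
    return c1, _unit(-np.sum(heavy, axis=0))


def _model_sites(model, spec):
    sites = []
    lanthanide_pos = None
    for chain in model:
        for res in chain:
            if res.name in spec["lanthanide_resnames"]:
                a = res[0]
                lanthanide_pos = np.array([a.pos.x, a.pos.y, a.pos.z])
            if res.name in spec["protein_methyls"]:
                code = gemmi.find_tabulated_residue(res.name)
                one = code.one_letter_code.upper() if code else "X"
                for methyl, parent in spec["protein_methyls"][res.name]:
                    mpos = _atom_pos(res, methyl)
                    ppos = _atom_pos(res, parent)
                    if mpos is None or ppos is None:
                        continue
                    suffix = f"-{methyl}" if len(spec["protein_methyls"][res.name]) > 1 else ""
                    sites.append(
                        LabeledSite(
                            id=f"{one}{res.seqid.num}{suffix}",
                            site_class=SiteClass.protein_methyl,
                            position=mpos,
                            vector=_unit(mpos - ppos),
                            vector_kind=VectorKind.methyl_axis,
                        )
                    )
    c1_name, h1_name = spec["anomeric"]
    aco_name, acm_name = spec["acetyl"]
    for label, residues in spec["glyco_sites"].items():
        for k, (chain_name, seqid) in enumerate(residues, start=1):
            res = _find_residue(model, chain_name, seqid)
            if res.name not in spec["glycan_resnames"]:
                raise ValueError(
                    f"{label}: residue {chain_name}/{seqid} is {res.name}, "
                    f"expected one of {spec['glycan_resnames']}"
                )
            rid = f"{label}/G{k}"
            cls = SiteClass.first_C1 if k == 1 else SiteClass.second_C1
            c1, vec = _anomeric_vector(res, c1_name, h1_name, rid)
            sites.append(
                LabeledSite(
                    id=f"{rid}/{c1_name}",
                    site_class=cls,
                    position=c1,
                    vector=vec,
                    vector_kind=VectorKind.ch_bond,
                    glyco_site=label,
                )
            )
            aco = _atom_pos(res, aco_name)
            acm = _atom_pos(res, acm_name)
            if aco is None or acm is None:
                raise ValueError(f"{rid}: acetyl atoms {aco_name}/{acm_name} missing")
            sites.append(
                LabeledSite(
                    id=f"{rid}/Ac",
                    site_class=SiteClass.acetyl,
                    position=acm,
                    vector=_unit(acm - aco),
                    vector_kind=VectorKind.methyl_axis,
                    glyco_site=label,
                    glcnac_index=k,
                )
            )
    return sites, lanthanide_pos


def read_structure(path, selection: dict | None = None):
    """Labeled sites from a (possibly multi-model) PDB file.

    Returns (site sets, lanthanide position or None): a list with one site
    list per model.  Vectors are computed from parent-atom coordinates
    (C1->H1 bond; carbonyl->methyl carbon for acetyls; missing H1 is
    rebuilt from tetrahedral geometry with a warning).
    """
    spec = _merged_selection(selection)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    out = []
    lanthanide_pos = None
    for model in st:
        sites, ln = _model_sites(model, spec)
        if not sites:
            names = sorted({r.name for ch in model for r in ch})
            raise ValueError(
                f"{path}: selection matched nothing; residue names present: {names}"
            )
        out.append(sites)
        if ln is not None:
            lanthanide_pos = ln
    return out, lanthanide_pos


# ---------------------------------------------------------------------------
# frame series (multi-model PDB + energies CSV)


def write_frames_pdb(path, series: FrameSeries, atom_names: Sequence[str] | None = None) -> None:
    """Write selection coordinates as a multi-model PDB (one model per
    frame, pseudo-atoms in a single chain)."""
    n_atoms = series.coords.shape[1]
    names = list(atom_names) if atom_names else [f"X{i + 1}" for i in range(n_atoms)]
    st = gemmi.Structure()
    st.name = "frames"
    for f in range(len(series)):
        model = gemmi.Model(f + 1)
        chain = gemmi.Chain("A")
        res = gemmi.Residue()
        res.name = "SEL"
        res.seqid = gemmi.SeqId(1, " ")
        for i in range(n_atoms):
            atom = gemmi.Atom()
            atom.name = names[i]
            atom.element = gemmi.Element("C")
            x, y, z = series.coords[f, i]
            atom.pos = gemmi.Position(x, y, z)
            res.add_atom(atom)
        chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


def write_representative_pdb(path, series: FrameSeries, frame_index: int) -> None:
    """Export one frame as a single-model PDB."""
    pos = int(np.nonzero(series.indices == frame_index)[0][0])
    one = FrameSeries(
        coords=series.coords[pos : pos + 1],
        energy=series.energy[pos : pos + 1],
        boost=series.boost[pos : pos + 1],
        indices=series.indices[pos : pos + 1],
    )
    write_frames_pdb(path, one)


def write_energies_csv(path, series: FrameSeries, cfg=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_hash_header(cfg))
        pd.DataFrame(
            {
                "frame": series.indices,
                "energy_kcal_mol": series.energy,
                "boost_kcal_mol": series.boost,
            }
        ).to_csv(fh, index=False)


def read_energies_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    need = {"frame", "energy_kcal_mol", "boost_kcal_mol"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return df


def frame_series_from_pdb(pdb_path, energies_path) -> FrameSeries:
    """Assemble a FrameSeries from a multi-model selection PDB plus the
    per-frame energies CSV (keyed by frame index, in model order)."""
    st = gemmi.read_structure(str(pdb_path))
    coords = []
    for model in st:
        xyz = [
            [a.pos.x, a.pos.y, a.pos.z]
            for chain in model
            for res in chain
            for a in res
        ]
        coords.append(xyz)
    coords = np.array(coords)
    df = read_energies_csv(energies_path)
    if len(df) != len(coords):
        raise ValueError(
            f"energy rows ({len(df)}) do not match frames ({len(coords)})"
        )
    return FrameSeries(
        coords=coords,
        energy=df["energy_kcal_mol"].to_numpy(),
        boost=df["boost_kcal_mol"].to_numpy(),
        indices=df["frame"].to_numpy(),
    )


def write_cluster_labels_csv(path, series: FrameSeries, labels, cfg=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_hash_header(cfg))
        pd.DataFrame({"frame": series.indices, "label": np.asarray(labels)}).to_csv(
            fh, index=False
        )


def write_cluster_summary_json(path, cs: ClusterSet, reps: dict | None = None, cfg=None) -> None:
    payload = {
        "cutoff": cs.cutoff,
        "n_clusters": cs.n_clusters,
        "clusters": [
            {**c, "representative": None if reps is None else reps.get(c["id"])}
            for c in cs.clusters
        ],
        "config_hash": config_hash(cfg) if cfg is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# scalar field export (OpenDX)


def write_dx(path, fld: PcsField, cfg=None) -> None:
    """OpenDX-style regular grid of the PCS field, for external isosurface
    rendering; NaN (masked near-field) points are written as 0."""
    nx, ny, nz = fld.values.shape
    o = fld.grid_origin
    d = fld.spacing
    lines = [
        _hash_header(cfg).rstrip("\n"),
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {o[0]:.4f} {o[1]:.4f} {o[2]:.4f}",
        f"delta {d:.4f} 0 0",
        f"delta 0 {d:.4f} 0",
        f"delta 0 0 {d:.4f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    vals = np.nan_to_num(fld.values, nan=0.0).ravel()
    for i in range(0, len(vals), 3):
        lines.append(" ".join(f"{v:.6e}" for v in vals[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "pcs_ppm" class field')
    Path(path).write_text("\n".join(lines) + "\n")
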