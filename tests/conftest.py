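import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from glynmr.sites import LabeledSite, SiteClass, VectorKind
from glynmr.synthetic import default_scenario


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic study: 3 glyco sites x 4 conformers, 20-site
    pseudo-protein, Tb-like / Tm-like tensors."""
    return default_scenario(seed=0)


@pytest.fixture(scope="session")
def noiseless_obs(scenario):
    return scenario.observables(noise_scale=0.0)


def random_site(rng, rmin=8.0, rmax=40.0, kind=VectorKind.ch_bond):
    pos = rng.normal(size=3)
    pos = pos / np.linalg.norm(pos) * rng.uniform(rmin, rmax)
    vec = rng.normal(size=3)
    vec /= np.linalg.norm(vec)
    return LabeledSite(
        id="s",
        site_class=SiteClass.protein_methyl,
        position=pos,
        vector=vec,
        vector_kind=kind,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_fixture_pdb(path, n_models=1, drop_h1=False):
    """Write a small synthetic PDB: a Tb ion, two ALA/VAL methyl residues,
    and three glycosylation sites with two NAG residues each (ring atoms,
    anomeric C1/H1, acetyl C7/C8)."""
    lines = []
    serial = 1

    def atom(name, resname, chain, seq, x, y, z, element):
        nonlocal serial
        rec = "HETATM" if resname in ("NAG", "TB") else "ATOM  "
        lines.append(
            f"{rec}{serial:5d} {name:<4s}{resname:>4s} {chain}{seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
        )
        serial += 1

    rng = np.random.default_rng(99)
    for m in range(1, n_models + 1):
        lines.append(f"MODEL     {m:4d}")
        off = 0.5 * (m - 1)
        atom("TB", "TB", "A", 200, 0.0, 0.0, 0.0, "TB")
        # protein methyls: one ALA, one VAL (two methyls)
        atom("CA", "ALA", "A", 10, 10.0, 0.0, off, "C")
        atom("CB", "ALA", "A", 10, 11.0, 0.5, off, "C")
        atom("CB", "VAL", "A", 20, 0.0, 12.0, off, "C")
        atom("CG1", "VAL", "A", 20, 1.0, 13.0, off, "C")
        atom("CG2", "VAL", "A", 20, -1.0, 13.0, off, "C")
        seq = 301
        for g in range(3):
            base = rng.normal(size=3)
            base = base / np.linalg.norm(base) * (14.0 + 4 * g)
            for k in range(2):
                o = base + np.array([4.5 * k, 0.6 * k, off])
                x, y, z = o
                atom("C1", "NAG", "B", seq, x, y, z, "C")
                if not drop_h1:
                    atom("H1", "NAG", "B", seq, x + 0.63, y + 0.63, z + 0.63, "H")
                atom("C2", "NAG", "B", seq, x + 1.4, y + 0.4, z, "C")
                atom("O5", "NAG", "B", seq, x - 0.8, y + 1.1, z, "O")
                atom("C4", "NAG", "B", seq, x + 2.2, y + 1.8, z + 0.4, "C")
                atom("C5", "NAG", "B", seq, x + 1.1, y + 2.6, z + 0.2, "C")
                atom("C7", "NAG", "B", seq, x + 2.4, y - 1.0, z - 0.5, "C")
                atom("C8", "NAG", "B", seq, x + 3.3, y - 1.9, z - 1.1, "C")
                seq += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
    glyco_sites = {f"S{g + 1}": [["B", 301 + 2 * g], ["B", 302 + 2 * g]] for g in range(3)}
    return glyco_sites
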