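"""Independent oracles used by the test suite.

These deliberately avoid the library's computation paths: forward models
are evaluated in SI units from the full 3x3 matrix without any
principal-frame rotation; eigenvalues come from explicit
characteristic-polynomial roots; assignments from exhaustive enumeration.
"""

import itertools
import math

import numpy as np

H = 6.62607015e-34
KB = 1.380649e-23
GAMMA_H = 2.6752218744e8
GAMMA_C = 6.728284e7


def chi_matrix_si(c5_units):
    """Full matrix in m^3 from the five components in 1e-32 m^3."""
    xx, yy, xy, xz, yz = np.asarray(c5_units, dtype=float) * 1e-32
    return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, -(xx + yy)]])


def pcs_matrix_oracle(c5_units, lanthanide_pos_A, pos_A):
    """PCS in ppm: delta = r_hat^T chi r_hat / (4 pi R^3), all SI."""
    chi = chi_matrix_si(c5_units)
    r = (np.asarray(pos_A, float) - np.asarray(lanthanide_pos_A, float)) * 1e-10
    dist = np.linalg.norm(r)
    rhat = r / dist
    return float(rhat @ chi @ rhat / (4.0 * math.pi * dist**3) * 1e6)


def rdc_matrix_oracle(c5_units, bond_unit, b0, temperature, rch_A, methyl_factor=None):
    """RDC in Hz: D = -prefactor * 3 b^T chi b, all SI; ``methyl_factor``
    applies the three-fold axis projection when given."""
    chi = chi_matrix_si(c5_units)
    b = np.asarray(bond_unit, dtype=float)
    pref = (
        H * b0**2 * GAMMA_C * GAMMA_H
        / (240.0 * math.pi**3 * KB * temperature * (rch_A * 1e-10) ** 3)
    )
    d = -pref * 3.0 * float(b @ chi @ b)
    if methyl_factor is not None:
        d *= methyl_factor
    return d


def eigenvalues_charpoly_oracle(matrix):
    """Eigenvalues of a symmetric 3x3 matrix from explicit characteristic
    polynomial coefficients (no eigen-solver)."""
    m = np.asarray(matrix, dtype=float)
    tr = m[0, 0] + m[1, 1] + m[2, 2]
    # sum of principal 2x2 minors
    c1 = (
        m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        + m[0, 0] * m[2, 2] - m[0, 2] * m[2, 0]
        + m[1, 1] * m[2, 2] - m[1, 2] * m[2, 1]
    )
    det = (
        m[0, 0] * (m[1, 1] * m[2, 2] - m[1, 2] * m[2, 1])
        - m[0, 1] * (m[1, 0] * m[2, 2] - m[1, 2] * m[2, 0])
        + m[0, 2] * (m[1, 0] * m[2, 1] - m[1, 1] * m[2, 0])
    )
    roots = np.roots([1.0, -tr, c1, -det])
    return np.sort(roots.real)


def assignment_bruteforce(obs, predictions):
    """Minimum total cost over all class-constrained injective mappings of
    observations to (site, slot) pairs; returns (cost, one optimal mapping).

    Enumerates permutations per chemical class independently (the classes
    do not share slots), choosing the best candidate conformer per pairing.
    """
    sites = sorted(predictions["glyco_site"].unique())

    def pair_cost(o, g, slot):
        rows = predictions[(predictions.glyco_site == g) & (predictions.slot == slot)]
        best = math.inf
        best_conf = None
        for _, row in rows.iterrows():
            c, n = 0.0, 0
            if o.pcs_ppm is not None and np.isfinite(row.pcs_ppm):
                c += ((row.pcs_ppm - o.pcs_ppm) / o.pcs_err) ** 2
                n += 1
            if o.rdc_hz is not None and np.isfinite(row.rdc_hz):
                c += ((row.rdc_hz - o.rdc_hz) / o.rdc_err) ** 2
                n += 1
            if n and c < best:
                best, best_conf = c, row.conformer
        return best, best_conf

    total = 0.0
    mapping = {}
    for cls, slots in (
        ("first_C1", [(g, "first_C1") for g in sites]),
        ("second_C1", [(g, "second_C1") for g in sites]),
        ("acetyl", [(g, s) for g in sites for s in ("acetyl_1", "acetyl_2")]),
    ):
        cls_obs = sorted(
            (o for o in obs if o.site_class.value == cls), key=lambda o: o.id
        )
        if not cls_obs:
            continue
        best_cost, best_map = math.inf, None
        for perm in itertools.permutations(slots, len(cls_obs)):
            c = 0.0
            m = {}
            for o, (g, slot) in zip(cls_obs, perm):
                pc, conf = pair_cost(o, g, slot)
                c += pc
                m[o.id] = (g, conf, slot)
            if c < best_cost:
                best_cost, best_map = c, m
        total += best_cost
        mapping.update(best_map)
    return total, mapping
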