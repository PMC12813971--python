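"""Physical constants and unit conventions.

Conventions used throughout the package:

* coordinates in Angstrom,
* susceptibility tensor components in units of 1e-32 m^3,
* PCS in ppm, RDC in Hz, energies in kcal/mol.

Internally forward models work in SI; the two scale factors below fold the
unit conversions into single prefactors.
"""

import math

#: Planck constant, J s
H_PLANCK = 6.62607015e-34
#: Boltzmann constant, J / K
KB_SI = 1.380649e-23
#: Boltzmann constant, kcal / (mol K)  (for MD energies)
KB_KCAL_MOL = 1.987204259e-3
#: 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_H = 2.6752218744e8
#: 13C gyromagnetic ratio, rad s^-1 T^-1
GAMMA_C = 6.728284e7

#: tensor I/O unit: 1e-32 m^3
CHI_UNIT = 1.0e-32
#: Angstrom in metres
ANGSTROM = 1.0e-10

#: default effective C-H bond length, Angstrom (aliphatic)
RCH_DEFAULT = 1.095
#: default temperature, K (25 C)
T_DEFAULT = 298.15
#: default 1H spectrometer frequency, Hz (900 MHz instrument)
NU_H_DEFAULT = 900.0e6

#: angle between a methyl C-H bond and the three-fold symmetry axis, degrees
METHYL_BETA_CH_DEG = 110.5


def methyl_projection_factor(beta_deg: float = METHYL_BETA_CH_DEG) -> float:
    """Scaling of a C-H dipolar coupling projected on a fast-rotating
    three-fold methyl axis: P2(cos beta) = (3 cos^2(beta) - 1)/2.

    For beta = 110.5 deg this is -0.31603, i.e. "about 1/3" in magnitude.
    """
    c = math.cos(math.radians(beta_deg))
    return (3.0 * c * c - 1.0) / 2.0


def b0_from_proton_frequency(nu_h: float = NU_H_DEFAULT) -> float:
    """Static field B0 (Tesla) of a spectrometer specified by its 1H
    frequency: B0 = 2 pi nu_H / gamma_H.  900 MHz -> 21.14 T."""
    return 2.0 * math.pi * nu_h / GAMMA_H


#: PCS prefactor: delta_ppm = PCS_PREFACTOR * bracket / R_Angstrom^3
#: where bracket carries tensor components in 1e-32 m^3.
#: 1e6 (ppm) * 1e-32 (chi) / 1e-30 (A^3) = 1e4.
PCS_PREFACTOR = 1.0e4 / (12.0 * math.pi)


def rdc_prefactor(b0: float, temperature: float, rch: float) -> float:
    """RDC prefactor K in Hz per unit (1e-32 m^3) of susceptibility:

    D = -K * [dchi_ax (3cos^2 th - 1) + 3/2 dchi_rh sin^2 th cos 2phi]

    K = h B0^2 gammaC gammaH / (240 pi^3 kB T rCH^3), rch in Angstrom.
    """
    rch_m = rch * ANGSTROM
    num = H_PLANCK * b0 * b0 * GAMMA_C * GAMMA_H
    den = 240.0 * math.pi**3 * KB_SI * temperature * rch_m**3
    return num / den * CHI_UNIT
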