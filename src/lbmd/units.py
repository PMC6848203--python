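"""Internal unit system and physical constants.

Everything inside the package is expressed in Å (length), fs (time),
amu (mass) and kcal/mol (energy).  File formats that use other units
(GRO is nm, configs accept s⁻¹ shear rates and m²/s viscosities)
convert at the I/O boundary; the lattice-Boltzmann solver runs in
lattice units behind its own conversion layer.

Because kcal/mol is not the natural energy of the (amu, Å, fs) system,
forces returned by the force field (kcal mol⁻¹ Å⁻¹) are converted to
accelerations with ``KCAL_MOL`` (1 kcal/mol expressed in amu Å² fs⁻²).
"""

# 1 kcal/mol in amu Å²/fs²:  4184 J/mol / N_A / (1.66054e-27 kg · 1e-20 m²/ 1e-30 s²)
KCAL_MOL = 4.184e-4

#: Boltzmann constant, kcal mol⁻¹ K⁻¹
KB = 1.987204259e-3

#: Coulomb constant, kcal Å mol⁻¹ e⁻²
COULOMB = 332.06371

#: nm → Å
NM = 10.0

#: bulk water mass density, amu Å⁻³  (0.997 g/cm³)
WATER_DENSITY = 0.6004

#: bulk water kinematic viscosity, Å² fs⁻¹  (1.0e-6 m² s⁻¹)
WATER_NU = 0.1

#: 1 poise (dyn s cm⁻²) in amu Å⁻¹ fs⁻¹; water (0.01 P) / WATER_DENSITY gives WATER_NU
POISE = 6.0221408


def kinetic_temperature(masses, velocities):
    """Instantaneous kinetic temperature (K) of a set of particles."""
    import numpy as np

    ke = 0.5 * float(np.sum(masses * np.sum(velocities**2, axis=1)))  # amu Å²/fs²
    ndof = 3 * len(masses)
    return 2.0 * ke / (ndof * KB * KCAL_MOL)


def shear_rate_per_fs(gamma_dot_per_s: float) -> float:
    """Convert a shear rate from s⁻¹ (config units) to fs⁻¹."""
    return gamma_dot_per_s * 1e-15


def viscosity_m2s_to_A2fs(nu_m2_per_s: float) -> float:
    """Convert a kinematic viscosity from m²/s to Å²/fs."""
    return nu_m2_per_s * 1e20 / 1e15
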