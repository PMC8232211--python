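"""Unit conventions used throughout the package.

Internally: lengths in nm, energies and frequencies in cm^-1, time in fs.
With hbar = 1, a wavenumber ``w`` (cm^-1) corresponds to an angular
frequency ``w * CM1_TO_RAD_FS`` in rad/fs.
"""

import math

#: speed of light in cm/fs
C_CM_PER_FS = 2.99792458e-5

#: angular frequency (rad/fs) per cm^-1
CM1_TO_RAD_FS = 2.0 * math.pi * C_CM_PER_FS

#: vacuum wavelength (nm) <-> transition energy (cm^-1): E = 1e7 / lambda
NM_WAVELENGTH_TO_CM1 = 1.0e7


def wavenumber_to_angular_fs(w_cm1):
    """Convert energy/frequency in cm^-1 to angular frequency in rad/fs."""
    return w_cm1 * CM1_TO_RAD_FS


def period_fs(w_cm1):
    """Oscillation period (fs) of a mode with frequency ``w_cm1`` in cm^-1."""
    return 1.0 / (C_CM_PER_FS * w_cm1)
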