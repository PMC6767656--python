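"""Physical constants and default dielectric parameters.

All lengths in this package are in centimetres; frequencies in Hz.
Complex permittivity follows the e^{+jwt} engineering convention,
eps = eps' - j*eps'', so the loss term eps'' is non-negative and the
complex wavenumber k = k0*sqrt(eps) has non-positive imaginary part
(outgoing waves decay as e^{-jkr}).
"""

import numpy as np

#: speed of light in vacuum, cm/s
C0_CM = 2.99792458e10

#: tissue label codes used throughout
LABEL_EXTERIOR = 0
LABEL_SKIN = 1
LABEL_FAT = 2
LABEL_FIBROGLANDULAR = 3
LABEL_TUMOR = 4

LABEL_NAMES = {
    LABEL_EXTERIOR: "exterior",
    LABEL_SKIN: "skin",
    LABEL_FAT: "fat",
    LABEL_FIBROGLANDULAR: "fibroglandular",
    LABEL_TUMOR: "tumor",
}

#: default complex relative permittivity per tissue label at the default
#: operating frequency (1 GHz).  Mid-range single-frequency literature
#: values chosen to give the strong fibroglandular/fat contrast typical of
#: microwave breast imaging; the immersion (matching) medium is a lossy
#: glycerin-like liquid.  These are configurable assumptions, not measured
#: values.
DEFAULT_TISSUE_TABLE = {
    LABEL_EXTERIOR: 23.0 - 1.0j,
    LABEL_SKIN: 36.0 - 4.0j,
    LABEL_FAT: 5.0 - 0.5j,
    LABEL_FIBROGLANDULAR: 35.0 - 6.0j,
    LABEL_TUMOR: 50.0 - 10.0j,
}

#: default operating frequency, Hz (typical for quantitative microwave
#: breast tomography)
DEFAULT_FREQUENCY = 1.0e9


def wavenumber(frequency, eps):
    """Complex wavenumber k = (2*pi*f/c0) * sqrt(eps), rad/cm.

    The principal square root of eps' - j*eps'' has Im <= 0, which makes
    e^{-jkr} an outgoing, decaying wave under the e^{+jwt} convention.
    """
    return 2.0 * np.pi * frequency / C0_CM * np.sqrt(np.asarray(eps, dtype=complex))


def wavelength(frequency, eps):
    """Wavelength in a medium of relative permittivity eps, cm."""
    return float(C0_CM / frequency / np.sqrt(np.real(eps)))
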