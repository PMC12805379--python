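"""Physical constants and unit conversions shared across the package."""

from __future__ import annotations

#: |gamma_X / gamma_H| for the supported heteronuclei.  The sign of the
#: 15N gyromagnetic ratio is irrelevant for the offset geometry used here
#: (profiles are reported on the ppm axis), so magnitudes are stored.
GAMMA_RATIO = {
    "N15": 0.10136767,
    "C13": 0.25144953,
}

#: Spectrometer fields (Tesla) mapped to their nominal 1H frequencies (MHz).
_CANONICAL_FIELDS = {
    11.7: 500.0,
    16.4: 700.0,
    18.8: 800.0,
}

#: 1H gyromagnetic ratio over 2*pi, MHz per Tesla (fallback for
#: non-canonical fields).
GAMMA_H_MHZ_PER_T = 42.577478518

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Default experimental temperature: 11.5 degrees C.
DEFAULT_TEMPERATURE_K = 284.65

#: Default transition-state prefactor (s^-1) for free-energy barriers.
DEFAULT_C_REF = 1.0e7


def proton_frequency_mhz(b0_tesla: float) -> float:
    """1H Larmor frequency (MHz) at a static field given in Tesla.

    Canonical spectrometer fields (11.7, 16.4, 18.8 T) map to their nominal
    500/700/800 MHz frequencies; other fields use gamma_H * B0.
    """
    for field, mhz in _CANONICAL_FIELDS.items():
        if abs(b0_tesla - field) < 0.05:
            return mhz
    return GAMMA_H_MHZ_PER_T * b0_tesla


def larmor_mhz(b0_tesla: float, nucleus: str) -> float:
    """Heteronucleus Larmor frequency magnitude (MHz) at ``b0_tesla``.

    Because ppm * MHz = Hz, this value is also the Hz-per-ppm conversion
    factor for chemical-shift offsets of the given nucleus.
    """
    try:
        ratio = GAMMA_RATIO[nucleus]
    except KeyError:
        raise ValueError(
            f"unknown nucleus {nucleus!r}; expected one of {sorted(GAMMA_RATIO)}"
        ) from None
    return ratio * proton_frequency_mhz(b0_tesla)
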