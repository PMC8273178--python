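"""Munsell colorimetry for the patch stimuli.

The colored patches are specified in the Munsell system: ten hues (5R, 5YR,
5Y, 5GY, 5G, 5BG, 5B, 5PB, 5P, 5RP), Value fixed at 5/, and Chroma at /0,
/2, /4 or /6.  Chromaticities come from an embedded table of the Munsell
renotation data (Newhall, Nickerson & Judd, 1943) chromatically adapted from
illuminant C to D65, so the achromatic point is the D65 white.  Absolute
luminance follows the Munsell Value alone, via the ASTM D1535 quintic
luminance-factor polynomial scaled by a configurable white luminance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MunsellChip",
    "D65_WHITE",
    "HUE_CODES",
    "CHROMA_CONDITIONS",
    "munsell_value_to_Y",
    "white_luminance_for_value5",
    "munsell_to_xyY",
    "chip_set",
    "excitation_purity",
]

#: CIE 1931 chromaticity of the D65 white point (achromatic reference).
D65_WHITE = (0.31270, 0.32900)

#: The ten principal hues used for the patches, in Munsell hue-circle order.
HUE_CODES = ("5R", "5YR", "5Y", "5GY", "5G", "5BG", "5B", "5PB", "5P", "5RP")

#: Valid Chroma condition labels.
CHROMA_CONDITIONS = ("/0", "/2", "/4", "/6")

# Munsell renotation chromaticities at Value 5, adapted C -> D65.
# Keyed by (hue_code, chroma); ("N", 0) is the achromatic chip and sits at
# the D65 white point by construction.
_RENOTATION_XY_D65: dict[tuple[str, int], tuple[float, float]] = {
    ("N", 0): (0.31270, 0.32900),
    ("5R", 2): (0.34233, 0.33086),
    ("5R", 4): (0.37833, 0.33250),
    ("5R", 6): (0.41178, 0.33387),
    ("5YR", 2): (0.35592, 0.35232),
    ("5YR", 4): (0.39904, 0.37264),
    ("5YR", 6): (0.44346, 0.38992),
    ("5Y", 2): (0.35230, 0.37546),
    ("5Y", 4): (0.39172, 0.41611),
    ("5Y", 6): (0.42913, 0.45180),
    ("5GY", 2): (0.33002, 0.37349),
    ("5GY", 4): (0.34819, 0.42321),
    ("5GY", 6): (0.36370, 0.47216),
    ("5G", 2): (0.30010, 0.35273),
    ("5G", 4): (0.28432, 0.37724),
    ("5G", 6): (0.26874, 0.40210),
    ("5BG", 2): (0.28660, 0.33484),
    ("5BG", 4): (0.26052, 0.33916),
    ("5BG", 6): (0.23699, 0.34383),
    ("5B", 2): (0.28182, 0.31740),
    ("5B", 4): (0.25065, 0.30136),
    ("5B", 6): (0.22252, 0.28338),
    ("5PB", 2): (0.29156, 0.30491),
    ("5PB", 4): (0.26848, 0.28141),
    ("5PB", 6): (0.24744, 0.25722),
    ("5P", 2): (0.30769, 0.30560),
    ("5P", 4): (0.30271, 0.28245),
    ("5P", 6): (0.29777, 0.25985),
    ("5RP", 2): (0.32847, 0.31838),
    ("5RP", 4): (0.34527, 0.30730),
    ("5RP", 6): (0.36319, 0.29461),
}

#: Munsell Values covered by the embedded table.
SUPPORTED_VALUE = 5


class UnsupportedChipError(ValueError):
    """Requested Munsell chip is outside the embedded renotation table."""


@dataclass(frozen=True)
class MunsellChip:
    """One calibrated colored (or neutral) patch color.

    Attributes
    ----------
    hue_code : str
        Munsell principal hue ("5R" ... "5RP") or "N" for neutral.
    value : float
        Munsell Value (lightness); fixed at 5 for all stimuli here.
    chroma : int
        Munsell Chroma (saturation); 0, 2, 4 or 6.
    chromaticity : tuple of float
        CIE 1931 (x, y). Equals the D65 white point when chroma is 0.
    luminance : float
        Absolute luminance in cd/m^2; a function of Value only.
    """

    hue_code: str
    value: float
    chroma: int
    chromaticity: tuple[float, float]
    luminance: float


def munsell_value_to_Y(value: float) -> float:
    """Luminance factor Y (% of white) for a Munsell Value, ASTM D1535.

    The quintic is normalised so that Value 10 gives Y = 100.
    """
    v = float(value)
    return (
        1.1914 * v
        - 0.22533 * v**2
        + 0.23352 * v**3
        - 0.020484 * v**4
        + 0.00081939 * v**5
    )


def white_luminance_for_value5(value5_luminance: float) -> float:
    """White luminance (cd/m^2) that puts a Value-5 chip at the given level.

    Both experiments state the patch luminance rather than the display
    white: 16.0 cd/m^2 on the projector, 19.8 cd/m^2 on the CRT.
    """
    return 100.0 * float(value5_luminance) / munsell_value_to_Y(SUPPORTED_VALUE)


def munsell_to_xyY(
    hue_code: str,
    value: float,
    chroma: int,
    white_luminance: float = white_luminance_for_value5(16.0),
) -> MunsellChip:
    """Look up a Munsell chip's D65 chromaticity and absolute luminance.

    Parameters
    ----------
    hue_code, value, chroma
        Munsell designation. Coverage is the embedded table: the ten
        principal hues at Value 5, Chroma 2/4/6, plus N 5/ (chroma 0).
    white_luminance
        Luminance of a perfect white (Y = 100) on the display, in cd/m^2.
        The chip luminance is ``white_luminance * Y(value) / 100``.

    Raises
    ------
    UnsupportedChipError
        For hue codes or chroma levels outside the table, or Value != 5.
    """
    if value != SUPPORTED_VALUE:
        raise UnsupportedChipError(
            f"only Munsell Value {SUPPORTED_VALUE} is tabulated, got {value!r}"
        )
    chroma = int(chroma)
    if chroma == 0:
        key = ("N", 0)
        hue_code = "N"
    else:
        key = (hue_code, chroma)
    if key not in _RENOTATION_XY_D65:
        raise UnsupportedChipError(
            f"Munsell chip {hue_code} {value}/{chroma} is not in the embedded "
            f"renotation table (hues {HUE_CODES}, chroma 0/2/4/6)"
        )
    luminance = white_luminance * munsell_value_to_Y(value) / 100.0
    return MunsellChip(
        hue_code=hue_code,
        value=float(value),
        chroma=chroma,
        chromaticity=_RENOTATION_XY_D65[key],
        luminance=luminance,
    )


def parse_chroma_condition(condition: "str | int") -> int:
    """Normalise a Chroma condition ('/4', '4', 4) to an int in {0,2,4,6}."""
    if isinstance(condition, str):
        condition = condition.lstrip("/")
        if not condition.isdigit():
            raise ValueError(f"invalid Chroma condition label: {condition!r}")
        condition = int(condition)
    if condition not in (0, 2, 4, 6):
        raise ValueError(f"Chroma condition must be one of /0,/2,/4,/6, got /{condition}")
    return int(condition)


def chip_set(
    chroma_condition: "str | int",
    white_luminance: float = white_luminance_for_value5(16.0),
) -> list[MunsellChip]:
    """The ten patch colors for one Chroma condition.

    In the /0 condition all ten patches are the identical neutral gray
    (N 5/); otherwise there is one chip per principal hue, all at the given
    Chroma and Value 5.  Luminance is identical across the set.
    """
    chroma = parse_chroma_condition(chroma_condition)
    if chroma == 0:
        return [munsell_to_xyY("N", 5, 0, white_luminance) for _ in HUE_CODES]
    return [munsell_to_xyY(h, 5, chroma, white_luminance) for h in HUE_CODES]


def excitation_purity(chromaticity: tuple[float, float]) -> float:
    """Distance-based saturation proxy: |xy - D65 white| in the CIE diagram.

    Monotone in true excitation purity along a fixed hue line, which is all
    the stimulus checks need (purity grows with Chroma).
    """
    dx = chromaticity[0] - D65_WHITE[0]
    dy = chromaticity[1] - D65_WHITE[1]
    return float(np.hypot(dx, dy))
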