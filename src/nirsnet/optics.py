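"""Optical constants for continuous-wave NIRS at 690/830 nm.

Extinction coefficients follow the standard compiled hemoglobin tabulation
(Gratzer/Kollias compilation) at the two instrument wavelengths.  The table
is stored base-10 in cm^-1 M^-1, the form the compilation publishes, and
converted once to the natural-log, micromolar, millimetre convention the
Beer-Lambert code uses.

Version: hb-extinction-v1 (690 nm and 830 nm rows only).
"""

from __future__ import annotations

import numpy as np

#: Differential pathlength factors (dimensionless) at (690 nm, 830 nm).
DEFAULT_DPF: tuple[float, float] = (6.4, 5.8)

#: Base-10 molar extinction coefficients, cm^-1 M^-1, rows = wavelengths
#: (690, 830 nm), columns = (HbO2, HbR).
_EXTINCTION_LOG10_CM_M = {
    690.0: (276.0, 2051.96),
    830.0: (974.0, 693.04),
}

_LN10 = float(np.log(10.0))


def extinction_matrix(wavelengths_nm: tuple[float, float] = (690.0, 830.0)) -> np.ndarray:
    """2x2 extinction matrix in natural-log units of OD / (uM * mm).

    Rows are wavelengths, columns (HbO2, HbR).  Raises for wavelengths
    outside the stored table.
    """
    rows = []
    for wl in wavelengths_nm:
        try:
            eps = _EXTINCTION_LOG10_CM_M[float(wl)]
        except KeyError:
            raise ValueError(f"no extinction entry for {wl} nm (table has 690, 830)")
        # cm^-1 M^-1 -> mm^-1 uM^-1 is a factor 1e-7; ln-base adds ln(10).
        rows.append([e * 1e-7 * _LN10 for e in eps])
    return np.asarray(rows, dtype=float)
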