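"""Published bench measurements used as model inputs.

These are the printed summary statistics from the liver-heart study that
the package treats as data: calibration series for the metabolism model,
the PDMS absorption table (see :mod:`liverheart.pdms`), and the reference
values the coupling pipeline and the reproduction scripts consume.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "cisapride_metabolism_series",
    "EC50_CAPD80_NM",
    "ETPC_RANGE_NM",
    "KETOCONAZOLE_UM",
    "RLU_CONTROL",
    "RLU_KETOCONAZOLE",
    "ALBUMIN_MPS",
    "ALBUMIN_2D",
    "UREA_MPS",
    "UREA_2D",
    "RELATIVE_CLEARANCE_WITH_KETO",
]

#: Cardiac EC50 of cisapride for cAPD80 prolongation (nM, PDMS-corrected doses).
EC50_CAPD80_NM = 9.63
#: Estimated therapeutic plasma concentration range of cisapride (nM).
ETPC_RANGE_NM = (2.6, 4.9)
#: Ketoconazole concentration used for CYP3A4 inhibition (uM).
KETOCONAZOLE_UM = 10.0

#: CYP3A4 luminescence in the liver device (relative light units, mean, sem).
RLU_CONTROL = (2640.0, 247.0)
RLU_KETOCONAZOLE = (361.0, 13.0)

#: Albumin / urea secretion (ug per 1e6 cells per day, mean, sem) in the
#: device vs conventional 2-D culture at the end of the time course.
ALBUMIN_MPS = (41.41, 3.53)
ALBUMIN_2D = (12.47, 0.53)
UREA_MPS = (49.75, 5.04)
UREA_2D = (7.37, 1.12)

#: Relative metabolite-formation clearance remaining under 10 uM
#: ketoconazole (fraction of the uninhibited control) at 1 and 10 uM
#: cisapride in conventional culture.
RELATIVE_CLEARANCE_WITH_KETO = (0.3487, 0.3518)


def cisapride_metabolism_series() -> pd.DataFrame:
    """Percent of cisapride converted to norcisapride over time.

    Long-format table of the 3/6/24-h dish-culture measurements at 1 uM
    cisapride, with and without 10 uM ketoconazole (mean and sem of the
    metabolized percentage).
    """
    return pd.DataFrame(
        {
            "time_h": [3.0, 6.0, 24.0, 3.0, 6.0, 24.0],
            "inhibitor_um": [0.0, 0.0, 0.0, 10.0, 10.0, 10.0],
            "fraction_pct": [2.66, 6.19, 9.33, 0.85, 0.99, 2.87],
            "sem_pct": [0.92, 0.69, 0.23, 0.02, 0.06, 0.97],
        }
    )
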