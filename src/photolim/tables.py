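"""Published treatment-mean values the package's defaults emulate.

These are the leaf-level means from a drought-and-recovery experiment
on the evergreen shrub *Rhododendron delavayi*: gas-exchange and FvCB
parameters per treatment × day cell (``treatment_means``), and the
corresponding published limitation partition (``limitation_means``).
Each treatment row is paired with the control row measured on the same
day; stomatal conductance is printed on a CO2 basis.

They serve two purposes: seeding the synthetic-data generator with
realistic parameter magnitudes, and providing reference inputs for the
limitation-partition layer.
"""

from __future__ import annotations

import pandas as pd

from .limitations import LeafState

# columns: phase, day, treatment, A_N, g_sc (CO2 basis), V_cmax, J_max, g_m, C_c
_TREATMENT_MEANS = [
    # water-stress phase (day = days without irrigation)
    ("stress", 4, "control", 15.26, 0.25, 33.71, 144.59, 0.074, 121.43),
    ("stress", 4, "stress", 13.69, 0.24, 26.34, 124.92, 0.069, 122.35),
    ("stress", 8, "control", 12.18, 0.21, 32.62, 148.93, 0.070, 120.35),
    ("stress", 8, "stress", 6.59, 0.09, 24.74, 123.07, 0.037, 106.42),
    # recovery phase (day = days after re-watering)
    ("recovery", 1, "control", 13.33, 0.25, 33.08, 153.75, 0.057, 125.49),
    ("recovery", 1, "recovery", 10.66, 0.18, 27.23, 118.87, 0.060, 137.20),
    ("recovery", 3, "control", 13.22, 0.23, 30.21, 128.51, 0.087, 122.09),
    ("recovery", 3, "recovery", 10.90, 0.20, 30.40, 135.67, 0.054, 103.03),
]

# columns: treatment, day, S_L, MC_L, B_L, D_L, NS_L, T_L (all %)
_LIMITATION_MEANS = [
    ("stress", 4, 0.5, 6.7, 10.7, 7.4, 17.4, 17.9),
    ("stress", 8, 11.9, 27.9, 8.0, 39.8, 35.9, 47.8),
    ("recovery", 1, 4.0, 11.1, 8.8, 15.1, 19.9, 23.9),
    ("recovery", 3, 2.5, 16.9, 3.6, 19.4, 20.5, 23.0),
]


def treatment_means() -> pd.DataFrame:
    """Published per-cell means of A_N, g_sc, V_cmax, J_max, g_m, C_c."""
    return pd.DataFrame(
        _TREATMENT_MEANS,
        columns=["phase", "day", "treatment", "A_N", "g_sc", "V_cmax", "J_max", "g_m", "C_c"],
    )


def limitation_means() -> pd.DataFrame:
    """Published limitation partition (%) per treatment × day cell."""
    return pd.DataFrame(
        _LIMITATION_MEANS,
        columns=["treatment", "day", "S_L", "MC_L", "B_L", "D_L", "NS_L", "T_L"],
    )


def leaf_state(phase: str, day: int, treatment: str) -> LeafState:
    """Build a :class:`LeafState` from one published mean row."""
    df = treatment_means()
    row = df[(df.phase == phase) & (df.day == day) & (df.treatment == treatment)]
    if row.empty:
        raise KeyError(f"no published cell ({phase!r}, {day}, {treatment!r})")
    r = row.iloc[0]
    return LeafState(
        A_N=r.A_N, g_sc=r.g_sc, g_m=r.g_m, V_cmax=r.V_cmax, C_c=r.C_c, J_max=r.J_max
    )


def headline_ratios() -> dict:
    """Treatment/control ratios summarizing the published responses.

    Percentages rounded to integer percent:
    the g_m of day-8 stressed leaves relative to control, the day-4
    reductions of V_cmax and J_max, and the A_N of day-1 recovery leaves
    relative to control.
    """
    df = treatment_means().set_index(["phase", "day", "treatment"])

    def pct(x):
        return int(round(100.0 * x))

    return {
        "gm_stress8_vs_control_pct": pct(
            df.loc[("stress", 8, "stress"), "g_m"] / df.loc[("stress", 8, "control"), "g_m"]
        ),
        "vcmax_day4_reduction_pct": pct(
            1.0
            - df.loc[("stress", 4, "stress"), "V_cmax"]
            / df.loc[("stress", 4, "control"), "V_cmax"]
        ),
        "jmax_day4_reduction_pct": pct(
            1.0
            - df.loc[("stress", 4, "stress"), "J_max"]
            / df.loc[("stress", 4, "control"), "J_max"]
        ),
        "an_recovery1_vs_control_pct": pct(
            df.loc[("recovery", 1, "recovery"), "A_N"]
            / df.loc[("recovery", 1, "control"), "A_N"]
        ),
    }
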