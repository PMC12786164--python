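"""Published kinetic and Arrhenius estimates for minimally processed cherry
tomatoes, used as a validation surface and as demonstration inputs.

The study design behind these numbers: two processing arms (``control``:
conventional packaging; ``prototype``: plasma-activated-water wash + edible
coating + active antioxidant packaging), storage at 1/4/8 degC, sampling at
0/2/5/7/9/15 days, triplicate measurements.  Quality indices: pH and
titratable acidity (TA, zero-order kinetics), total polyphenol content
(TPC, zero-order) and antioxidant capacity (AOC, first-order).

``k`` values are day^-1 (mean of three replicates, with the reported SD);
``Ea`` is kJ mol^-1; ``k_ref`` is the rate at T_ref = 277.45 K.  Stars code
the reported treatment effect (* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

ATTRIBUTES = ("pH", "TA", "TPC", "AOC")
TREATMENTS = ("control", "prototype")
TEMPERATURES_C = (1.0, 4.0, 8.0)
TIMES_D = (0.0, 2.0, 5.0, 7.0, 9.0, 15.0)

#: reaction order and direction of change for each quality index
ORDERS = {"pH": 0, "TA": 0, "TPC": 0, "AOC": 1}
DIRECTIONS = {"pH": +1, "TA": -1, "TPC": -1, "AOC": -1}

#: day-0 raw means in native units (pH units; mL NaOH; mg GAE eq/g dw;
#: mg Trolox eq/g dw)
BASELINES = {"pH": 4.12, "TA": 3.52, "TPC": 1.9, "AOC": 16.85}


def reference_kinetics() -> dict:
    """Published per-temperature rate constants, keyed
    ``[attribute][treatment][temperature_C]``.

    Each leaf carries ``k`` and its reported SD, the goodness-of-fit
    statistics, the reaction order, and the treatment-effect star code
    attached to the prototype row (empty string on control rows).
    """

    def row(k, k_sd, r2, rmse, order, stars=""):
        return {
            "k": k, "k_sd": k_sd, "R2": r2, "RMSE": rmse,
            "order": order, "stars": stars,
        }

    return {
        "pH": {
            "control": {
                1.0: row(0.006, 0.0001, 0.93, 0.01, 0),
                4.0: row(0.009, 0.0002, 0.94, 0.03, 0),
                8.0: row(0.011, 0.0001, 0.95, 0.01, 0),
            },
            "prototype": {
                1.0: row(0.003, 0.0001, 0.93, 0.01, 0, "***"),
                4.0: row(0.004, 0.0003, 0.91, 0.02, 0, "***"),
                8.0: row(0.009, 0.0002, 0.96, 0.01, 0, "***"),
            },
        },
        "TA": {
            "control": {
                1.0: row(0.013, 0.0002, 0.95, 0.02, 0),
                4.0: row(0.016, 0.0004, 0.94, 0.02, 0),
                8.0: row(0.019, 0.0001, 0.99, 0.01, 0),
            },
            "prototype": {
                1.0: row(0.008, 0.0001, 0.98, 0.01, 0, "***"),
                4.0: row(0.010, 0.0002, 0.95, 0.03, 0, "***"),
                8.0: row(0.013, 0.0003, 0.94, 0.02, 0, "***"),
            },
        },
        "TPC": {
            "control": {
                1.0: row(0.025, 0.0002, 0.82, 0.06, 0),
                4.0: row(0.027, 0.0005, 0.83, 0.05, 0),
                8.0: row(0.031, 0.0010, 0.90, 0.04, 0),
            },
            "prototype": {
                1.0: row(0.015, 0.0003, 0.88, 0.02, 0, "***"),
                4.0: row(0.019, 0.0010, 0.91, 0.06, 0, "***"),
                8.0: row(0.023, 0.0020, 0.96, 0.02, 0, "**"),
            },
        },
        "AOC": {
            "control": {
                1.0: row(0.064, 0.001, 0.95, 0.05, 1),
                4.0: row(0.071, 0.003, 0.94, 0.04, 1),
                8.0: row(0.083, 0.003, 0.94, 0.06, 1),
            },
            "prototype": {
                1.0: row(0.031, 0.003, 0.98, 0.02, 1, "***"),
                4.0: row(0.040, 0.001, 0.85, 0.06, 1, "***"),
                8.0: row(0.051, 0.004, 0.92, 0.04, 1, "***"),
            },
        },
    }


def reference_arrhenius() -> dict:
    """Published Arrhenius parameters, keyed ``[attribute][treatment]``."""

    def row(k_ref, k_ref_sd, ea, ea_sd, r2, stars=""):
        return {
            "k_ref": k_ref, "k_ref_sd": k_ref_sd,
            "Ea": ea, "Ea_sd": ea_sd, "R2": r2, "stars": stars,
        }

    return {
        "pH": {
            "control": row(0.008, 0.01, 51, 2, 0.98, "***"),
            "prototype": row(0.005, 0.02, 92, 4, 0.94),
        },
        "TA": {
            "control": row(0.03, 0.02, 35, 3, 0.97, "*"),
            "prototype": row(0.02, 0.01, 46, 1, 0.98),
        },
        "TPC": {
            "control": row(0.03, 0.01, 19, 3, 0.97, "*"),
            "prototype": row(0.02, 0.01, 38, 6, 0.98),
        },
        "AOC": {
            "control": row(0.07, 0.02, 24, 2, 0.98, "***"),
            "prototype": row(0.04, 0.01, 46, 1, 0.96),
        },
    }
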