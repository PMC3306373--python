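"""Published ancestry-diabetes table inputs and their recomputed decompositions.

The odds ratios, regression coefficients and case/control counts below are
the printed inputs of the reference African-American admixture study
(three pooled cohorts: ARIC, JHS, MEC). They exist so the attenuation
decompositions — percent excess odds explained and percent effect
explained — can be recomputed from rounded printed inputs, independently
of any fitted model ("from-printed-values" mode).
"""

from __future__ import annotations

import pandas as pd

from .epi import effect_explained, excess_odds_explained

# Odds ratio of diabetes by African-ancestry tertile (reference: tertile 1),
# nested covariate ladder. Counts are diabetic/non-diabetic per tertile.
TABLE2_ODDS_RATIOS = {
    "ARIC+JHS+MEC": {
        "counts": {1: (774, 1574), 2: (763, 1612), 3: (836, 1462)},
        "cuts_percent": (79.4, 87.2),
        "models": {
            1: {2: 1.25, 3: 1.48},
            2: {2: 1.21, 3: 1.40},
        },
    },
    "ARIC+JHS": {
        "counts": {1: (296, 1088), 2: (255, 1000), 3: (406, 962)},
        "cuts_percent": (80.5, 87.5),
        "models": {
            1: {2: 1.35, 3: 1.47},
            2: {2: 1.32, 3: 1.40},
            3: {2: 1.27, 3: 1.37},
            4: {2: 1.26, 3: 1.33},
        },
    },
}

# Mean trait difference by African-ancestry tertile (reference: tertile 1),
# treated individuals excluded. HbA1c in %, glucose mg/dL, insulin mU/L.
TABLE3_COEFFICIENTS = {
    "hba1c": {1: {2: 0.10, 3: 0.10}, 2: {2: 0.08, 3: 0.09}, 3: {2: 0.07, 3: 0.07}, 4: {2: 0.06, 3: 0.06}},
    "glucose": {1: {2: 1.20, 3: 1.57}, 2: {2: 0.93, 3: 1.16}, 3: {2: 0.48, 3: 0.73}, 4: {2: 0.30, 3: 0.41}},
    "insulin": {1: {2: 0.87, 3: 0.68}, 2: {2: 0.58, 3: 0.23}, 3: {2: 0.81, 3: 0.60}, 4: {2: 0.60, 3: 0.25}},
    "homa_ir": {1: {2: 0.28, 3: 0.23}, 2: {2: 0.20, 3: 0.10}, 3: {2: 0.24, 3: 0.17}, 4: {2: 0.17, 3: 0.07}},
}


def recompute_excess_odds_table() -> pd.DataFrame:
    """Percent excess odds explained for every adjusted printed cell."""
    rows = []
    for group, data in TABLE2_ODDS_RATIOS.items():
        base = data["models"][1]
        for mid, ors in data["models"].items():
            if mid == 1:
                continue
            for tert in (2, 3):
                rows.append(
                    {
                        "group": group,
                        "model_id": mid,
                        "tertile": tert,
                        "theta1": base[tert],
                        "theta2": ors[tert],
                        "percent_explained": excess_odds_explained(base[tert], ors[tert]),
                    }
                )
    return pd.DataFrame(rows)


def recompute_effect_explained_table() -> pd.DataFrame:
    """Percent effect explained for every adjusted printed trait cell."""
    rows = []
    for trait, models in TABLE3_COEFFICIENTS.items():
        base = models[1]
        for mid, betas in models.items():
            if mid == 1:
                continue
            for tert in (2, 3):
                rows.append(
                    {
                        "trait": trait,
                        "model_id": mid,
                        "tertile": tert,
                        "beta1": base[tert],
                        "beta2": betas[tert],
                        "percent_explained": effect_explained(base[tert], betas[tert]),
                    }
                )
    return pd.DataFrame(rows)


def unadjusted_tertile_or(tertile: int, group: str = "ARIC+JHS+MEC") -> float:
    """Cross-product odds ratio of a tertile vs tertile 1 from printed counts."""
    counts = TABLE2_ODDS_RATIOS[group]["counts"]
    a, b = counts[tertile]  # cases, controls in the comparison tertile
    c, d = counts[1]
    return (a * d) / (c * b)
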