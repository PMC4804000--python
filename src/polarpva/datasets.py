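"""Published 2013 status-assessment values for Canada's 13 polar bear
subpopulations.

These are the printed inputs the comparison layer operates on: per
subpopulation, the unharvested growth rate and probability of decline
from the viability assessment, the mark-recapture sampling protocol
(whole seasonal range vs partial), the community traditional-knowledge
trend call and the PVA trend call; plus mark-recapture, simulation and
aerial-survey abundance estimates for the three subpopulations where an
independent aerial survey exists.  The two-letter codes are the
standard Canadian subpopulation identifiers (BB Baffin Bay, DS Davis
Strait, FB Foxe Basin, GB Gulf of Boothia, KB Kane Basin, LS Lancaster
Sound, MC M'Clintock Channel, NB Northern Beaufort Sea, NW Norwegian
Bay, SB Southern Beaufort Sea, SH Southern Hudson Bay, VM Viscount
Melville Sound, WH Western Hudson Bay).
"""

from __future__ import annotations

import pandas as pd

from .metrics import AbundanceEstimate
from .stats import ContingencyTable2x2, StatusPoint

__all__ = [
    "status_points",
    "viability_table",
    "tek_by_trend_table",
    "tek_by_protocol_table",
    "aerial_survey_comparisons",
    "abundance_table",
]

SUBPOPS = [
    "BB", "DS", "FB", "GB", "KB", "LS", "MC", "NB", "NW", "SB", "SH", "VM", "WH",
]

# Viability assessment: deterministic and stochastic unharvested growth
# rates (run-to-run SD in parentheses in the source), the zero-harvest
# probability of decline, and the truncated-run count (zero throughout).
_VIABILITY = {
    # subpop: (lambda_det, lambda_stoch, lambda_se, p_decline, p_decline_se, trunc)
    "BB": (1.0551, 1.0547, 0.0274, 0.0026, 0.0007, 0),
    "DS": (1.0387, 1.0385, 0.0175, 0.0160, 0.0018, 0),
    "FB": (1.0501, 1.0491, 0.0196, 0.0076, 0.0012, 0),
    "GB": (1.0646, 1.0639, 0.0369, 0.0472, 0.0030, 0),
    "KB": (1.0064, 1.0098, 0.0359, 0.4008, 0.0069, 0),
    "LS": (1.0247, 1.0249, 0.0189, 0.0908, 0.0041, 0),
    "MC": (1.0263, 1.0245, 0.0345, 0.2054, 0.0057, 0),
    "NB": (0.9947, 0.9887, 0.0794, 0.5198, 0.0071, 0),
    "NW": (1.0077, 1.0077, 0.0189, 0.3574, 0.0068, 0),
    "SB": (0.9808, 0.9795, 0.0415, 0.6734, 0.0066, 0),
    "SH": (1.0014, 0.9999, 0.0397, 0.4876, 0.0071, 0),
    "VM": (1.0652, 1.0621, 0.0426, 0.0732, 0.0037, 0),
    "WH": (1.0004, 0.9991, 0.0135, 0.5326, 0.0071, 0),
}

# Harvested (post-2013) probability of decline used as the status
# metric.  KB was not simulated onward (depleted by 2013; treated as a
# certain decline), so its value is 1.0 by convention.  Where several
# variants were published the first-listed natural-survival
# mark-recapture value is used.
_P_DECLINE_HARVESTED = {
    "BB": 0.9340, "DS": 0.3894, "FB": 0.2892, "GB": 0.2016, "KB": 1.0,
    "LS": 0.3632, "MC": 0.3178, "NB": 0.8348, "NW": 0.4034, "SB": 0.8890,
    "SH": 0.9816, "VM": 0.1884, "WH": 0.9954,
}

_SAMPLING = {
    "BB": "entire", "DS": "entire", "FB": "entire", "GB": "entire",
    "KB": "entire", "LS": "entire", "MC": "entire", "NB": "partial",
    "NW": "entire", "SB": "partial", "SH": "partial", "VM": "entire",
    "WH": "partial",
}

# Trend calls: the PVA call follows the harvested probability of decline
# (> 0.5 declining); the TEK call is the community consensus.
_PVA_CALL = {
    s: ("declining" if s in ("BB", "KB", "NB", "SB", "SH", "WH") else "stable_increasing")
    for s in SUBPOPS
}
_TEK_CALL = {s: ("declining" if s == "KB" else "stable_increasing") for s in SUBPOPS}

# Mark-recapture abundance estimates (year, N, SE) anchoring projections.
_ABUNDANCE = {
    "BB": (1997, 2074, 265.0),
    "DS": (2007, 2158, 180.0),
    "FB": (1994, 2200, 260.0),
    "GB": (2000, 1592, 361.0),
    "KB": (1997, 164, 34.6),
    "LS": (1997, 2541, 391.0),
    "MC": (2000, 284, 59.3),
    "NB": (2006, 1004, 275.5),
    "NW": (1997, 203, 44.0),
    "SB": (2006, 1526, 160.7),
    "SH": (2005, 771, 143.3),
    "VM": (1999, 215, 57.5),
    "WH": (2004, 935, 72.0),
}

# Five-year mean annual removals (bears/year) and female proportion.
_HARVEST_5YR = {
    "BB": (164.0, 0.36), "DS": (81.2, 0.36), "FB": (108.8, 0.40),
    "GB": (59.8, 0.39), "KB": (5.0, 0.48), "LS": (84.6, 0.31),
    "MC": (2.8, 0.20), "NB": (32.4, 0.41), "NW": (1.8, 0.0),
    "SB": (36.8, 0.33), "SH": (57.2, 0.33), "VM": (4.4, 0.19),
    "WH": (21.6, 0.33),
}

# Simulation vs aerial-survey comparisons (natural-survival simulations
# projected from the mark-recapture anchor to the aerial-survey year).
_AERIAL = {
    "FB": {
        "mark_recapture": (1994, 2200.0, 260.0),
        "simulation": (2010, 2772.7, 1307.4),
        "aerial": (2010, 2580.0, 278.0),
    },
    "SH": {
        "mark_recapture": (2005, 771.0, 143.3),
        "simulation": (2012, 435.2, 276.8),
        "aerial": (2012, 969.0, 202.0),
    },
    "WH": {
        "mark_recapture": (2004, 935.0, 72.0),
        "simulation": (2011, 773.0, 110.6),
        "aerial": (2011, 1013.0, 151.0),
    },
}


def viability_table() -> pd.DataFrame:
    """Unharvested viability results, one row per subpopulation."""
    rows = [
        {
            "subpop": s,
            "lambda_det": v[0],
            "lambda_stoch": v[1],
            "lambda_stoch_se": v[2],
            "p_decline_h0": v[3],
            "p_decline_h0_se": v[4],
            "trunc": v[5],
        }
        for s, v in _VIABILITY.items()
    ]
    return pd.DataFrame(rows).set_index("subpop")


def abundance_table() -> pd.DataFrame:
    """Mark-recapture anchors and 5-year mean removals per subpopulation."""
    rows = []
    for s in SUBPOPS:
        year, n, se = _ABUNDANCE[s]
        kill, pf = _HARVEST_5YR[s]
        rows.append(
            {
                "subpop": s,
                "year": year,
                "N": n,
                "se": se,
                "harvest_5yr_mean": kill,
                "prop_female": pf,
            }
        )
    return pd.DataFrame(rows).set_index("subpop")


def status_points() -> list:
    """The 13 status points feeding the clustering and U tests:
    stochastic unharvested growth rate paired with the harvested
    probability of decline."""
    return [
        StatusPoint(
            s,
            _VIABILITY[s][1],
            _P_DECLINE_HARVESTED[s],
            _SAMPLING[s],
            _TEK_CALL[s],
            _PVA_CALL[s],
        )
        for s in SUBPOPS
    ]


def tek_by_trend_table() -> ContingencyTable2x2:
    """PVA trend vs TEK agreement: rows stable/increasing vs declining,
    columns TEK supports vs TEK disputes."""
    return _crosstab(lambda p: p.pva_call == "stable_increasing")


def tek_by_protocol_table() -> ContingencyTable2x2:
    """Sampling protocol vs TEK agreement: rows entirely vs partially
    surveyed, columns TEK supports vs TEK disputes."""
    return _crosstab(lambda p: p.sampling == "entire")


def _crosstab(row_pred) -> ContingencyTable2x2:
    a = b = c = d = 0
    for p in status_points():
        agree = p.tek_call == p.pva_call
        if row_pred(p):
            a, b = a + agree, b + (not agree)
        else:
            c, d = c + agree, d + (not agree)
    return ContingencyTable2x2(a, b, c, d)


def aerial_survey_comparisons() -> dict:
    """Per subpopulation (FB, SH, WH): mark-recapture anchor, simulation
    estimate and aerial-survey estimate as :class:`AbundanceEstimate`."""
    out = {}
    for s, entries in _AERIAL.items():
        out[s] = {
            kind: AbundanceEstimate(n, se, year, _SOURCE_NAMES[kind])
            for kind, (year, n, se) in entries.items()
        }
    return out


_SOURCE_NAMES = {
    "mark_recapture": "mark_recapture",
    "simulation": "simulated",
    "aerial": "aerial",
}
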