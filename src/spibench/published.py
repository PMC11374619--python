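"""Published composite road-safety scores for 11 Southeast Asian countries.

These are the printed net-flow scores and integer ranks of the regional
case study (study years 2009, 2013, 2015 and 2018), reported to three
decimals, together with the published three-group partitions and their
best-in-class countries.  They serve as worked-example inputs: the
underlying indicator panel is not publicly deposited, but the printed
scores alone determine the ranking, the flow-conservation check and the
benchmark-selection rule.

Note: in 2015 two countries (MM, TL) share the printed score -1.283 yet
carry distinct printed ranks 10 and 11; the tie is an artifact of the
3-decimal rounding.
"""

from __future__ import annotations

COUNTRIES = {
    "BN": "Brunei", "ID": "Indonesia", "KH": "Cambodia", "LA": "Laos",
    "MM": "Myanmar", "MY": "Malaysia", "PH": "Philippines",
    "SG": "Singapore", "TH": "Thailand", "TL": "Timor-Leste",
    "VN": "Vietnam",
}

YEARS = (2009, 2013, 2015, 2018)

#: Printed net-flow score per country and year (3 decimals).
SCORES = {
    2009: {"BN": 0.566, "ID": 0.204, "KH": -0.719, "LA": -0.680,
           "MM": -0.109, "MY": -0.057, "PH": 1.460, "SG": 0.484,
           "TH": -0.461, "TL": -0.531, "VN": -0.157},
    2013: {"BN": 5.648, "ID": -0.373, "KH": -1.736, "LA": -1.354,
           "MM": -1.607, "MY": 0.407, "PH": -1.701, "SG": 3.146,
           "TH": -0.518, "TL": -2.462, "VN": 0.550},
    2015: {"BN": 4.498, "ID": -0.142, "KH": -0.970, "LA": -0.600,
           "MM": -1.283, "MY": 0.289, "PH": -0.886, "SG": 1.887,
           "TH": -0.859, "TL": -1.283, "VN": -0.650},
    2018: {"BN": 1.678, "ID": -0.136, "KH": -0.491, "LA": -0.605,
           "MM": -0.500, "MY": -0.067, "PH": -0.533, "SG": 1.149,
           "TH": -0.515, "TL": -0.221, "VN": 0.241},
}

#: Printed integer rank per country and year (1 = best).
RANKS = {
    2009: {"BN": 2, "ID": 4, "KH": 11, "LA": 10, "MM": 6, "MY": 5,
           "PH": 1, "SG": 3, "TH": 8, "TL": 9, "VN": 7},
    2013: {"BN": 1, "ID": 5, "KH": 10, "LA": 7, "MM": 8, "MY": 4,
           "PH": 9, "SG": 2, "TH": 6, "TL": 11, "VN": 3},
    2015: {"BN": 1, "ID": 4, "KH": 9, "LA": 5, "MM": 10, "MY": 3,
           "PH": 8, "SG": 2, "TH": 7, "TL": 11, "VN": 6},
    2018: {"BN": 1, "ID": 5, "KH": 7, "LA": 11, "MM": 8, "MY": 4,
           "PH": 10, "SG": 2, "TH": 9, "TL": 6, "VN": 3},
}

#: Published three-group partition (group I best) per year.
GROUPS = {
    2009: {"I": ["BN", "MY", "SG"], "II": ["ID", "PH", "TH", "VN"],
           "III": ["KH", "LA", "MM", "TL"]},
    2013: {"I": ["BN", "MY", "SG", "ID"], "II": ["PH", "TH", "VN"],
           "III": ["KH", "LA", "MM", "TL"]},
    2015: {"I": ["BN", "SG", "MY"], "II": ["ID", "KH", "PH", "TH", "VN"],
           "III": ["LA", "MM", "TL"]},
    2018: {"I": ["BN", "SG", "MY"], "II": ["ID", "KH", "PH", "TH", "VN"],
           "III": ["LA", "MM", "TL"]},
}

#: Published best-in-class country per group and year.
BENCHMARKS = {
    2009: {"I": "BN", "II": "PH", "III": "TL"},
    2013: {"I": "BN", "II": "VN", "III": "LA"},
    2015: {"I": "BN", "II": "ID", "III": "LA"},
    2018: {"I": "BN", "II": "VN", "III": "TL"},
}


def score_vector(year: int) -> tuple[list[str], list[float]]:
    """Country codes (sorted) and their printed scores for one year."""
    codes = sorted(SCORES[year])
    return codes, [SCORES[year][c] for c in codes]
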