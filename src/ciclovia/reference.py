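"""Published per-city category counts from the four-program survey.

These are the printed per-city frequencies (Bogota N=1001, Mexico City
N=721, Santiago de Cali N=1159, Santiago de Chile N=401; 3282 adults,
2015-2019) for the variables whose pooled shares the descriptive pipeline
reproduces exactly.  Cities that did not collect a variable are simply
absent from its mapping (complete-case pooling).
"""

PUBLISHED_COUNTS: dict[str, dict[str, dict[str, int]]] = {
    "sex": {
        "bogota": {"male": 619, "female": 382},
        "mexico_city": {"male": 370, "female": 351},
        "santiago_cali": {"male": 583, "female": 572},
        "santiago_chile": {"male": 142, "female": 259},
    },
    "meets_pa_program": {
        "bogota": {"yes": 453, "no": 548},
        "mexico_city": {"yes": 629, "no": 92},
        "santiago_cali": {"yes": 487, "no": 672},
        "santiago_chile": {"yes": 109, "no": 292},
    },
    "activity": {
        "bogota": {"cycling": 603, "rollerblading": 52, "walking": 222,
                   "running": 118, "other": 4},
        "mexico_city": {"cycling": 634, "rollerblading": 25, "walking": 23,
                        "running": 38, "other": 1},
        "santiago_cali": {"cycling": 205, "rollerblading": 21, "walking": 464,
                          "running": 163, "other": 286},
        "santiago_chile": {"cycling": 275, "rollerblading": 29, "walking": 16,
                           "running": 73, "other": 8},
    },
    "companion": {
        "bogota": {"alone": 567, "accompanied": 434},
        "mexico_city": {"alone": 473, "accompanied": 247},
        "santiago_cali": {"alone": 763, "accompanied": 396},
    },
    "safety3": {
        "bogota": {"unsafe": 37, "safe": 915, "neither": 48},
        "santiago_cali": {"unsafe": 494, "safe": 383, "neither": 282},
        "santiago_chile": {"unsafe": 22, "safe": 379, "neither": 0},
    },
    "bmi_cat": {
        "bogota": {"underweight": 20, "normal": 644, "overweight": 297,
                   "obese": 40},
        "mexico_city": {"underweight": 4, "normal": 352, "overweight": 270,
                        "obese": 95},
        "santiago_cali": {"underweight": 11, "normal": 511, "overweight": 469,
                          "obese": 168},
    },
}
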