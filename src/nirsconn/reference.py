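"""Published cohort summary statistics used as simulation inputs.

Group-level demographic summaries (mean, s.d.) for the heroin-dependent
group (HD, n=8) and the community control group (CG, n=7).  The synthetic
cohort generator draws covariates from these distributions, and the
demographic-comparison statistics are recomputed from them.
"""

N_HD = 8
N_CG = 7

# variable -> {"HD": (mean, sd), "CG": (mean, sd)}
COHORT_SUMMARY = {
    "age": {"HD": (47.6, 6.1), "CG": (45.7, 6.8)},
    "education": {"HD": (5.9, 2.8), "CG": (7.0, 2.4)},
    "iq": {"HD": (82.9, 11.4), "CG": (83.1, 9.3)},
    "cigarettes": {"HD": (22.8, 9.7), "CG": (20.0, 10.7)},
    "smoking_years": {"HD": (33.6, 6.7), "CG": (28.7, 7.3)},
    "stai": {"HD": (95.4, 22.1), "CG": (74.1, 15.2)},
}

# HD-only treatment variable (mg/day).
METHADONE_MG = (30.0, 26.9)

# Plausible truncation ranges for the simulated covariates.
COVARIATE_RANGES = {
    "age": (18.0, 65.0),
    "education": (0.0, 20.0),
    "iq": (55.0, 130.0),
    "cigarettes": (1.0, 60.0),
    "smoking_years": (1.0, 50.0),
    "stai": (40.0, 160.0),
}
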