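"""Shared study conditions for the analysis scripts.

One place defines the cohort, the dose model and the seed so every script
operates on the same reproducible study.
"""
from contourdose import (SweepConfig, default_prostate_cohort,
                         default_prostate_params)

SEED = 7
N_SUBJECTS = 5


def cohort(perturbed: bool = True):
    return default_prostate_cohort(n_subjects=N_SUBJECTS, seed=SEED,
                                   perturbed=perturbed)


def params():
    return default_prostate_params()


def sweep():
    return SweepConfig(seed=SEED)
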