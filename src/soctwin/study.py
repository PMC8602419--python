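"""Default study configuration: a FinnTwin12-like synthetic cohort.

The generator emulates the structure of the twin sample the package's
analyses are designed for: 254 MZ, 176 same-sex DZ and 156 opposite-sex DZ
complete pairs plus 121 singleton twins; sex-specific trait means, SDs and
AE-dominated heritabilities in the published range (a² 0.19-0.66); strong
negative genetic correlations of sense of coherence with depression and
neuroticism; and polygenic scores explaining a few percent of trait
variance.  Where the study tables pin a value (means, SDs, per-sex a²,
SOC-trait rA/rE) the generator uses it; the one quantity the tables do not
determine — the depression-neuroticism factor correlations — is set to a
plausible positive value consistent with positive-definiteness.
"""

from __future__ import annotations

import numpy as np

from .synthetic_data import SimulationConfig, TraitSpec

#: complete-pair group sizes and singleton count of the emulated cohort
N_MZ, N_DZSS, N_DZOS, N_SINGLETONS = 254, 176, 156, 121

#: per-sex (mean, SD, a-squared) for the three core traits
TRAIT_TABLE = {
    # trait:        men                 women
    "soc":         ((64.1, 10.00, 0.30), (61.7, 10.63, 0.51)),
    "depression":  ((13.6, 4.10, 0.37), (15.3, 4.94, 0.63)),
    "neuroticism": ((1.4, 0.63, 0.43), (1.9, 0.70, 0.58)),
}

#: factor correlations among (soc, depression, neuroticism); the
#: SOC rows/columns follow the study's women estimates, the
#: depression-neuroticism entries are plausible fill-ins
RA = np.array([[1.00, -0.84, -0.85],
               [-0.84, 1.00, 0.70],
               [-0.85, 0.70, 1.00]])
RE = np.array([[1.00, -0.43, -0.59],
               [-0.43, 1.00, 0.45],
               [-0.59, 0.45, 1.00]])

#: polygenic scores to attach: name -> (target trait, variance explained)
PGS_TABLE = {
    "pgs_depression": ("soc", 0.03),
    "pgs_neuroticism": ("soc", 0.03),
}


def study_config(seed: int = 0) -> SimulationConfig:
    """Simulation configuration emulating the study cohort's structure."""
    traits = {
        name: TraitSpec.by_sex(*men, *women)
        for name, (men, women) in TRAIT_TABLE.items()
    }
    return SimulationConfig(N_MZ, N_DZSS, N_DZOS, traits,
                            n_singletons=N_SINGLETONS,
                            rA=RA.copy(), rE=RE.copy(), seed=seed)


def study_cohort(seed: int = 0, with_pgs: bool = True):
    """Simulate the default cohort, optionally with polygenic scores."""
    from .synthetic_data import attach_pgs, simulate_cohort

    cohort = simulate_cohort(study_config(seed))
    if with_pgs:
        for i, (name, (trait, r2)) in enumerate(PGS_TABLE.items()):
            cohort = attach_pgs(cohort, trait, r2, seed=seed + 1000 + i,
                                name=name)
    return cohort
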