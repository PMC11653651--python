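import pytest
from hypothesis import HealthCheck, settings

from mirlame.simulate import (PlantedDE, PlantedPattern, PlantedSpecific,
                              PlantedTimepointSpecific, default_longitudinal_config,
                              default_w0_config, simulate_counts,
                              simulate_recovery_cohort)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def w0_sim():
    """Small W0 cross-section with planted DE and phenotype-specific miRNAs."""
    cfg = default_w0_config(
        seed=11,
        n_mirnas=150,
        planted_de=[
            PlantedDE("bta-mir-s0100", "HC", "DD", 2.0),
            PlantedDE("bta-mir-s0101", "HC", "DD", -2.0),
        ],
        planted_specific=[
            PlantedSpecific("spec-DD", "DD", 5.0),
            PlantedSpecific("spec-FR", "FR", 4.0),
        ],
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def longitudinal_sim():
    """Three-week cohort with planted patterns and time-point-specific miRNAs."""
    cfg = default_longitudinal_config(
        seed=23,
        n_mirnas=120,
        group_sizes={"DD": 24, "TTN": 14, "FRDD": 20},
        planted_patterns=[
            PlantedPattern("bta-mir-s0060", "DD", "UNR", "U-D"),
            PlantedPattern("bta-mir-s0061", "DD", "RE", "D-U"),
        ],
        planted_timepoint_specific=[
            PlantedTimepointSpecific("tp-DD-W1", "DD", "W1", 5.0),
            PlantedTimepointSpecific("tp-TTN-W2", "TTN", "W2", 6.0),
        ],
    )
    return simulate_recovery_cohort(cfg)
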