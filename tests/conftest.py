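import numpy as np
import pandas as pd
import pytest

from ironsig import SimulationConfig, simulate_cohort

CAUSAL_EFFECTS = {"G1": 0.8, "G2": 0.8, "G3": -0.8}


def planted_config(seed: int, n_samples: int = 300, n_genes: int = 61,
                   effects: dict | None = None, **overrides) -> SimulationConfig:
    """LGG-shaped cohort with named causal genes G1..G3 among nulls N*."""
    effects = CAUSAL_EFFECTS if effects is None else effects
    named = sorted(set(effects) | set(overrides.get("aberrance_hazard_multipliers", {})))
    names = tuple(named + [f"N{i:02d}" for i in range(n_genes - len(named))])
    kwargs = dict(
        n_samples=n_samples,
        n_genes=n_genes,
        gene_names=names,
        planted_effects=effects,
        baseline_hazard=np.log(2) / 90.0,
        censor_time=30.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture
def planted_cohort():
    """One LGG-shaped cohort with three planted hazard effects."""
    return simulate_cohort(planted_config(seed=7))


@pytest.fixture
def tiny_clinical():
    return pd.DataFrame(
        {
            "os_months": [10.0, 20.0, 30.0, 40.0],
            "event": [True, True, True, False],
            "grade": ["II", "II", "III", "III"],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
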