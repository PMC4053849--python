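import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from thiorate.core_model import ExpressionSet, SampleMeta
from thiorate.synthetic_data import SimulationConfig, simulate_experiment

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_expression_set(
    amounts: dict[float, dict[str, np.ndarray]],
    gene_ids: list[str],
    n_replicates: int = 1,
    labeling_times: dict[float, float] | None = None,
    calls: pd.DataFrame | None = None,
) -> ExpressionSet:
    """Hand-build an ExpressionSet from per-temperature fraction vectors."""
    labeling_times = labeling_times or {t: 1.0 for t in amounts}
    samples, cols = [], {}
    for temp, by_fraction in amounts.items():
        for fraction, vec in by_fraction.items():
            for rep in range(1, n_replicates + 1):
                sid = f"T{temp:g}_{fraction}_r{rep}"
                cols[sid] = np.asarray(vec, dtype=float)
                samples.append(
                    SampleMeta(
                        sample_id=sid,
                        temperature=temp,
                        fraction=fraction,
                        replicate=rep,
                        labeling_time=None
                        if fraction == "total_start"
                        else labeling_times[temp],
                    )
                )
    samples.sort(key=lambda s: s.key)
    values = pd.DataFrame({s.sample_id: cols[s.sample_id] for s in samples}, index=gene_ids)
    return ExpressionSet(values=values, samples=samples, calls=calls)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Small noise-free steady-state cohort with ground truth."""
    cfg = SimulationConfig(n_genes=200, noise_sd=0.0, seed=42)
    es, truth = simulate_experiment(cfg)
    return cfg, es, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-noise cohort used for recovery tests."""
    cfg = SimulationConfig(n_genes=2000, noise_sd=0.1, seed=7)
    es, truth = simulate_experiment(cfg)
    return cfg, es, truth
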