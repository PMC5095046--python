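import numpy as np
import pytest

import esnpath as ep


@pytest.fixture(scope="session")
def small_dataset():
    """Two small studies with one planted pathway; shared across tests."""
    cfg = ep.SimulationConfig(
        n_studies=2,
        samples_per_study=[(300, 700), (250, 750)],
        n_snps=300,
        n_genes=100,
        gene_sets=[("A", "KEGG", 10), ("B", "KEGG", 20), ("C", "GO", 5)],
        planted_pathways=[("A", 0.4)],
        seed=3,
    )
    return ep.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_scan():
    """Global-null simulation (no planted effects) and its association scan,
    used for calibration and score/Wald agreement checks."""
    cfg = ep.SimulationConfig(
        n_studies=2,
        samples_per_study=[(400, 600), (350, 650)],
        n_snps=5000,
        n_genes=400,
        planted_pathways=[],
        gene_sets=[(f"P{i:02d}", "KEGG", 20) for i in range(10)],
        seed=101,
    )
    data = ep.simulate_dataset(cfg)
    scan = ep.run_association_scan(data.cohorts)
    return data, scan


def brute_force_es(statistics, hit_flags, weight_p):
    """Independent running-sum oracle: plain Python loop over the ranked
    list, no shared code with the implementation."""
    n = len(statistics)
    n_h = sum(hit_flags)
    n_r = sum(abs(s) ** weight_p for s, h in zip(statistics, hit_flags) if h)
    running = 0.0
    best = 0.0
    for s, h in zip(statistics, hit_flags):
        if h:
            running += (abs(s) ** weight_p) / n_r if n_r > 0 else 1.0 / n_h
        else:
            running -= 1.0 / (n - n_h)
        if abs(running) > abs(best):
            best = running
    return best
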