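import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def small_orfs():
    """A tiny deterministic ORF set for codon-level checks."""
    rng = np.random.default_rng(42)
    from compscape._codons import random_orf

    return {f"g{i}": random_orf(50, rng) for i in range(5)}


@pytest.fixture
def fitness_table():
    """Replicate-level fitness table with two deletion genotypes and controls.

    Genotype gA (initial 0.7) is fully compensated (end 1.0), gB (initial 0.8)
    only drifts like the controls (x1.05).  Noise-free.
    """
    rows = []
    for j in range(1, 9):
        for day, f in ((0, 1.0), (104, 1.03 + 0.005 * j)):
            for rep in range(1, 7):
                rows.append(("control", f"control_L{j}", "control", day, rep,
                             f + 0.001 * rep))
    for genotype, f0, f1 in (("gA", 0.7, 1.0), ("gB", 0.8, 0.82)):
        for i in range(1, 5):
            for day, f in ((0, f0), (104, f1)):
                for rep in range(1, 7):
                    rows.append((genotype, f"{genotype}_L{i}", "deletion", day, rep,
                                 f + 0.001 * rep))
    return pd.DataFrame(
        rows, columns=["genotype", "line", "role", "day", "replicate", "fitness"]
    )
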