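import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_metric_table(
    delta_genotype=0.0,
    delta_drug=0.0,
    interaction=0.0,
    sigma_animal=1.5,
    sigma_resid=0.5,
    n_per_genotype=6,
    baseline_mean=10.0,
    drug="atropine",
    metric="sdrr",
    rng=None,
):
    """Synthetic tidy metric table for the mixed-model stage.

    One value per (animal, condition) with a persistent animal offset —
    the generative model the genotype-x-drug analysis assumes.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    for g, glab in ((0, "WT"), (1, "TGAC8")):
        for j in range(n_per_genotype):
            a = rng.normal(0.0, sigma_animal) if sigma_animal else 0.0
            for d, dlab in ((0, "basal"), (1, drug)):
                value = (
                    baseline_mean
                    + delta_genotype * g
                    + delta_drug * d
                    + interaction * g * d
                    + a
                    + (rng.normal(0.0, sigma_resid) if sigma_resid else 0.0)
                )
                rows.append(
                    dict(
                        animal_id=f"{glab}{j}",
                        genotype=glab,
                        condition=dlab,
                        metric=metric,
                        value=value,
                        segment_index=0,
                        provenance="",
                    )
                )
    return pd.DataFrame(rows)


def brute_force_sampen_counts(x, m, r):
    """Exhaustive O(n^2) ordered-pair template match counts (A, B).

    Independent oracle for sample entropy: direct loops over all
    template pairs with Chebyshev distance, self-pairs excluded.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    n_templ = n - m
    a = b = 0
    for i in range(n_templ):
        for j in range(n_templ):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b
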