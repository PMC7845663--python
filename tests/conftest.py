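import numpy as np
import pandas as pd
import pytest

from survivormr.sumstats import HarmonizedDataset, SummaryStatsTable


def make_table(ids, betas, ses, trait_id="x", eaf=0.3, ea="A", oa="G",
               pvals=None, n=10_000, sample_id=""):
    """Build a summary-statistics table from parallel value lists."""
    k = len(ids)
    df = pd.DataFrame({
        "variant_id": ids,
        "effect_allele": [ea] * k if isinstance(ea, str) else ea,
        "other_allele": [oa] * k if isinstance(oa, str) else oa,
        "eaf": [eaf] * k if np.isscalar(eaf) else eaf,
        "beta": betas,
        "se": ses,
        "pval": pvals if pvals is not None else [0.5] * k,
        "n": n,
    })
    return SummaryStatsTable(df, trait_id=trait_id, sample_id=sample_id)


def random_harmonized(k, K, seed, se_bx_scale=0.02, se_by_scale=0.05,
                      theta=None, noise=True):
    """Fixed-seed harmonized dataset with by generated from a linear model."""
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.05, 0.3, size=(k, K)) * rng.choice([-1.0, 1.0], size=(k, K))
    se_bx = np.full((k, K), se_bx_scale)
    se_by = np.full(k, se_by_scale)
    if theta is None:
        theta = rng.normal(0, 0.3, K)
    by = bx @ np.asarray(theta)
    if noise:
        by = by + rng.normal(0, se_by_scale, k)
    return HarmonizedDataset(
        variant_ids=[f"v{i}" for i in range(k)],
        bx=bx, se_bx=se_bx, by=by, se_by=se_by,
        exposure_ids=[f"e{j}" for j in range(K)],
    )


@pytest.fixture
def harmonized_20x2():
    return random_harmonized(20, 2, seed=7)


@pytest.fixture
def harmonized_30x2():
    return random_harmonized(30, 2, seed=13)
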