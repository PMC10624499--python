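"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lipidmr.harmonize import HarmonizedInstruments
from lipidmr.sumstats import LDMatrix, SummaryDataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_dataset(
    pvalues=None,
    betas=None,
    ses=None,
    chroms=None,
    positions=None,
    eafs=None,
    ids=None,
    trait_name="trait",
    trait_type="continuous",
    n=None,
):
    """Build a small SummaryDataset with sensible defaults."""
    J = next(
        (
            len(arg)
            for arg in (pvalues, betas, ses, chroms, positions, eafs, ids)
            if arg is not None
        ),
        3,
    )
    ids = ids or [f"rs{i + 1}" for i in range(J)]
    table = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chroms if chroms is not None else ["1"] * J,
            "pos": positions if positions is not None else np.arange(J) * 1000 + 1000,
            "effect_allele": ["A"] * J,
            "other_allele": ["G"] * J,
            "eaf": eafs if eafs is not None else [0.3] * J,
            "beta": betas if betas is not None else [0.1] * J,
            "se": ses if ses is not None else [0.01] * J,
            "pvalue": pvalues if pvalues is not None else [1e-10] * J,
            "n": n if n is not None else 10000,
        }
    )
    return SummaryDataset(trait_name=trait_name, trait_type=trait_type, table=table)


def make_harmonized(bx, sx, by, sy, outcome_type="continuous"):
    bx = np.asarray(bx, dtype=float)
    return HarmonizedInstruments(
        variant_ids=[f"rs{i + 1}" for i in range(len(bx))],
        beta_x=bx,
        se_x=np.asarray(sx, dtype=float),
        beta_y=np.asarray(by, dtype=float),
        se_y=np.asarray(sy, dtype=float),
        outcome_type=outcome_type,
    )


def random_harmonized(rng, J, outcome_type="continuous"):
    return make_harmonized(
        bx=rng.normal(0, 0.1, J),
        sx=rng.uniform(0.005, 0.05, J),
        by=rng.normal(0, 0.05, J),
        sy=rng.uniform(0.005, 0.05, J),
        outcome_type=outcome_type,
    )


def random_psd_correlation(rng, J):
    """Random well-conditioned correlation matrix (factor structure + ridge)."""
    f = rng.normal(size=(J, max(2, J // 2)))
    cov = f @ f.T + np.eye(J) * J
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def identity_ld(J):
    return LDMatrix([f"rs{i + 1}" for i in range(J)], np.eye(J))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
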