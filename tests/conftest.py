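"""Shared fixtures: small synthetic cohorts and count tables."""

from __future__ import annotations

import numpy as np
import pytest

from pairdmr.io_formats import Cohort, CpGRecord, Individual, MethylomeSample


def make_cohort(n_pairs: int, sexes: str = "MF") -> Cohort:
    """Deterministic sibling cohort: pair p has members P{p}E (exposed) and
    P{p}C (control), sexes alternating through ``sexes``."""
    individuals = []
    for p in range(n_pairs):
        sex = sexes[p % len(sexes)]
        individuals.append(
            Individual(f"P{p}E", f"pair{p}", True, sex, 58.0, "B1")
        )
        individuals.append(
            Individual(f"P{p}C", f"pair{p}", False, sex, 57.0, "B1")
        )
    return Cohort(individuals=individuals)


def make_sample(sample_id: str, triples) -> MethylomeSample:
    """Sample from (pos, methylated, total) triples on chr1."""
    return MethylomeSample(
        sample_id=sample_id,
        records=[CpGRecord("chr1", pos, m, t) for pos, m, t in triples],
    )


@pytest.fixture
def six_pair_cohort() -> Cohort:
    return make_cohort(6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
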