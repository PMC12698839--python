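"""Shared fixtures: small simulated cohorts and hand-built records."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from ctcdiv.datatypes import VariantCall
from ctcdiv.simulate import SimConfig, simulate_cohort

# lifelines warns about small samples / low variance in stress fixtures;
# those conditions are the point of the tests
warnings.filterwarnings("ignore", module="lifelines")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A light 8-patient cohort for structural tests."""
    return SimConfig(
        n_patients=8, seed=7,
        n_variants_range=(40, 80), n_segments_range=(30, 60),
        msi_prob=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


def make_variant(total=50, alt=20, gene="", consequence="silent",
                 chrom="1", pos=1000, ref="A", alt_allele="T") -> VariantCall:
    return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt_allele,
                       total_reads=total, alt_reads=alt, gene=gene,
                       consequence=consequence)


def variants_from_vafs(vafs, depth=1000, **kw) -> list[VariantCall]:
    """Variants whose VAFs are exactly the given fractions (at high depth)."""
    out = []
    for i, v in enumerate(vafs):
        alt = int(round(v * depth))
        out.append(make_variant(total=depth, alt=alt, pos=1000 + i, **kw))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
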