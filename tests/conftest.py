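"""Shared fixtures: tiny hand-built vocabularies and toy datasets."""

from __future__ import annotations

import numpy as np
import pytest

from twodcg import (
    CodeVocabulary,
    DomainEntry,
    DomainVocabulary,
    PooledSubstitution,
    SixDDPDataset,
    SixDDPRecord,
)
from twodcg.divergence_proxy import PopulationOrder


@pytest.fixture
def small_domains() -> DomainVocabulary:
    """Two-protein vocabulary: 3 motor domains then 2 partner domains
    (block boundary 3|4)."""
    return DomainVocabulary(
        (
            DomainEntry(1, "CL", "MYH7-heavy-chain", (359, 377)),
            DomainEntry(2, "ML", "MYH7-heavy-chain"),
            DomainEntry(3, "SW", "MYH7-heavy-chain"),
            DomainEntry(4, "L8", "MYBPC3"),
            DomainEntry(5, "C5", "MYBPC3"),
        )
    )


@pytest.fixture
def small_populations() -> CodeVocabulary:
    return CodeVocabulary(
        (("AFE", "East Africa"), ("NAF", "North Africa"),
         ("EUR", "Europe"), ("EAS", "East Asia")),
        code_length=3,
    )


@pytest.fixture
def small_order(small_populations) -> PopulationOrder:
    return PopulationOrder(
        codes=("AFE", "NAF", "EUR", "EAS"),
        distances_km=(500.0, 2500.0, 6000.0, 13000.0),
    )


@pytest.fixture
def small_phenotypes() -> CodeVocabulary:
    return CodeVocabulary(
        (("FH", "familial hypertrophic cardiomyopathy"),
         ("CM", "cardiomyopathy"), ("LV", "left ventricular noncompaction")),
        code_length=2,
    )


def make_record(cd="CL", ref="K", sub="G", po="AFE", af=0, ph="FH", pa="pt"):
    return SixDDPRecord(cd=cd, re=PooledSubstitution(ref, sub), po=po, af=af,
                        ph=ph, pa=pa)


@pytest.fixture
def record_factory():
    return make_record


def random_toy_dataset(
    rng: np.random.Generator,
    domains: DomainVocabulary,
    order: PopulationOrder,
    phenotypes: CodeVocabulary,
    n: int = 50,
) -> SixDDPDataset:
    """Random fulfilled dataset over the small vocabularies."""
    pooled = ("K", "E", "T", "Q", "L", "G")
    pas = ("pt", "lp", "be", "lb")
    records = [
        make_record(
            cd=domains.codes[rng.integers(len(domains))],
            ref=pooled[rng.integers(len(pooled))],
            sub=pooled[rng.integers(len(pooled))],
            po=order.codes[rng.integers(len(order))],
            af=int(rng.integers(2)),
            ph=phenotypes.codes[rng.integers(len(phenotypes))],
            pa=pas[rng.integers(len(pas))],
        )
        for _ in range(n)
    ]
    return SixDDPDataset(records, provenance="toy")


@pytest.fixture
def toy_dataset_factory(small_domains, small_order, small_phenotypes):
    def build(seed: int = 0, n: int = 50) -> SixDDPDataset:
        rng = np.random.default_rng(seed)
        return random_toy_dataset(rng, small_domains, small_order,
                                  small_phenotypes, n)

    return build
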