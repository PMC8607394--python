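"""Synthetic 6ddp generator with planted co-domain structure.

The generator states a world in which one or more inter-protein domain pairs
carry an SNV-probability trend over the divergence-ordered population axis:
both members follow a common logistic ramp (SNV probability rising toward
low-divergence populations), with the partner's ramp displaced by a phase
shift in population-index units.  A positive phase displaces the partner
toward *higher* index (lower divergence), so the first member leads.
Background domains draw SNVs uniformly across populations.  Records are
multinomial draws: population uniform over the order, domain weighted by the
planted per-population rates, pooled residue classes and allele-frequency
category at fixed background rates, and outcomes drawn from planted or
background class distributions.

Defaults mirror the scale of the real complexes: 39+26 domains, 30
populations, 4x10^4 records, planted effect doubling-to-tripling the
planted domains' SNV rate at full ramp with 90% pathogenicity purity.  The
generator works in the completed-data regime by default (as if imputation
already ran); a masking fraction re-introduces unknown outcomes to exercise
the imputation stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .divergence_proxy import PopulationOrder
from .vocab_io import (
    POOLED_CLASSES,
    UNKNOWN_PATHOGENICITY,
    UNKNOWN_PHENOTYPE,
    CodeVocabulary,
    DomainEntry,
    DomainVocabulary,
    PooledSubstitution,
    SixDDPDataset,
    SixDDPRecord,
)

__all__ = [
    "PlantedPair",
    "PlantedTruth",
    "make_domain_vocabulary",
    "make_population_order",
    "make_phenotype_vocabulary",
    "planted_profiles",
    "expected_cell_probabilities",
    "simulate_dataset",
    "simulate_learnable_dataset",
]

#: background outcome distributions (completed-data regime: no unknowns)
BACKGROUND_PA = {"pt": 0.12, "lp": 0.08, "be": 0.48, "lb": 0.32}
#: a few phenotypes predominate, as in real submissions
BACKGROUND_PH_WEIGHTS = (0.45, 0.25, 0.12, 0.08, 0.06, 0.04)
#: most SNVs are rare: allele-frequency category 0 probability
RARE_AF_PROB = 0.9

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class PlantedPair:
    """One planted inter-protein co-domain.

    ``effect`` is the fractional rate increase at full ramp (4.0 means the
    planted domains' SNV rate quintuples across the population axis — a
    strong hot-spot, so planted pairs dominate the amplitude map the way the
    real complex's top cross-peaks stand far above the map RMS and carry
    unambiguous directional calls); ``phase`` is the partner's ramp
    displacement in index units (positive: domain_i leads); ``pa_class``
    concentrates the planted records' pathogenicity ('pathogenic' or
    'benign') with ``purity`` probability.
    """

    domain_i: str
    domain_j: str
    effect: float = 4.0
    phase: float = 3.0
    pa_class: str = "pathogenic"
    purity: float = 0.9


@dataclass(frozen=True)
class PlantedTruth:
    pairs: tuple[PlantedPair, ...] = ()
    background_noise: float = 0.0
    seed: int = 0


def make_domain_vocabulary(
    n_a: int = 39,
    n_b: int = 26,
    protein_a: str = "MYH7-heavy-chain",
    protein_b: str = "MYBPC3",
) -> DomainVocabulary:
    """Synthetic two-protein domain vocabulary with generated 2-letter codes
    (stand-in for a real domain table; block boundary at n_a | n_a+1)."""
    codes = [
        _LETTERS[i // len(_LETTERS)] + _LETTERS[i % len(_LETTERS)]
        for i in range(n_a + n_b)
    ]
    entries = tuple(
        DomainEntry(i + 1, codes[i], protein_a if i < n_a else protein_b)
        for i in range(n_a + n_b)
    )
    return DomainVocabulary(entries)


def make_population_order(n: int = 30) -> tuple[CodeVocabulary, PopulationOrder]:
    """Synthetic population vocabulary plus an equally spaced order whose
    migration distances grow linearly from the origin."""
    codes = tuple(
        "P" + _LETTERS[i // len(_LETTERS)] + _LETTERS[i % len(_LETTERS)]
        for i in range(n)
    )
    vocab = CodeVocabulary(tuple((c, f"synthetic population {k}") for k, c in
                                 enumerate(codes, 1)), code_length=3)
    distances = tuple(1000.0 * k for k in range(n))
    return vocab, PopulationOrder(codes=codes, distances_km=distances)


def make_phenotype_vocabulary(n: int = 6) -> CodeVocabulary:
    codes = tuple("f" + str(i) for i in range(n))
    return CodeVocabulary(tuple((c, f"synthetic phenotype {c}") for c in codes),
                          code_length=2)


def planted_profiles(
    effect: float,
    phase: float,
    n_populations: int,
    trend: str = "logistic",
    base: float = 1.0,
    width: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative SNV-rate profiles for the two members of a planted pair.

    Both follow ``base * (1 + effect * g(k))`` with g a logistic ramp
    centered on the population axis; the partner's ramp is shifted by
    ``phase`` index units toward higher index when positive (so the first
    profile leads).  ``effect=0`` gives flat background profiles.
    """
    if n_populations < 4:
        raise ValueError("need np >= 4")
    if abs(phase) >= n_populations / 2:
        raise ValueError(
            f"phase magnitude {abs(phase)} must be < np/2 = {n_populations / 2}"
        )
    if trend != "logistic":
        raise ValueError(f"unknown trend {trend!r}")
    w = width if width is not None else n_populations / 8.0
    k = np.arange(1, n_populations + 1, dtype=float)
    center = (n_populations + 1) / 2.0

    def ramp(kk: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(kk - center) / w))

    profile_i = base * (1.0 + effect * ramp(k))
    profile_j = base * (1.0 + effect * ramp(k - phase))
    return profile_i, profile_j


def _weight_matrix(
    domains: DomainVocabulary,
    order: PopulationOrder,
    truth: PlantedTruth,
) -> np.ndarray:
    nd, npop = len(domains), len(order)
    weights = np.ones((nd, npop))
    for pair in truth.pairs:
        prof_i, prof_j = planted_profiles(pair.effect, pair.phase, npop)
        i = domains.index_of(pair.domain_i) - 1
        j = domains.index_of(pair.domain_j) - 1
        weights[i] = prof_i
        weights[j] = prof_j
    if truth.background_noise > 0:
        rng = np.random.default_rng(truth.seed + 7919)
        jitter = rng.lognormal(0.0, truth.background_noise, size=weights.shape)
        weights = weights * jitter
    return weights


def expected_cell_probabilities(
    domains: DomainVocabulary,
    order: PopulationOrder,
    truth: PlantedTruth,
) -> np.ndarray:
    """Probability of a record landing in each (domain, population) cell:
    population uniform, domain multinomial within each population column."""
    w = _weight_matrix(domains, order, truth)
    return (w / w.sum(axis=0, keepdims=True)) / len(order)


def _planted_pa_dist(pa_class: str, purity: float) -> dict[str, float]:
    spread = (1.0 - purity) / 2.0
    if pa_class == "pathogenic":
        return {"pt": purity / 2, "lp": purity / 2, "be": spread, "lb": spread}
    if pa_class == "benign":
        return {"be": purity / 2, "lb": purity / 2, "pt": spread, "lp": spread}
    raise ValueError(f"pa_class must be 'pathogenic' or 'benign', got {pa_class!r}")


def simulate_dataset(
    domains: DomainVocabulary,
    order: PopulationOrder,
    phenotypes: CodeVocabulary,
    truth: PlantedTruth,
    n_records: int = 40_000,
    seed: int = 0,
    masking_fraction: float = 0.0,
) -> tuple[SixDDPDataset, PlantedTruth]:
    """Multinomial draw of ``n_records`` 6ddp records from the stated world.

    Reproducible given ``seed``.  ``masking_fraction`` of records get their
    phenotype, pathogenicity, or both set unknown (uniformly among the three
    modes) to exercise imputation; 0 leaves the dataset fully fulfilled.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    for pair in truth.pairs:
        for code in (pair.domain_i, pair.domain_j):
            if code not in domains:
                raise ValueError(f"planted domain {code!r} absent from vocabulary")
    rng = np.random.default_rng(seed)
    nd, npop = len(domains), len(order)
    weights = _weight_matrix(domains, order, truth)
    col_probs = weights / weights.sum(axis=0, keepdims=True)

    po_idx = rng.integers(0, npop, size=n_records)
    cd_idx = np.empty(n_records, dtype=int)
    for j in range(npop):
        sel = po_idx == j
        n_j = int(sel.sum())
        if n_j:
            cd_idx[sel] = rng.choice(nd, size=n_j, p=col_probs[:, j])

    ref_idx = rng.integers(0, len(POOLED_CLASSES), size=n_records)
    sub_idx = rng.integers(0, len(POOLED_CLASSES), size=n_records)
    af = (rng.random(n_records) >= RARE_AF_PROB).astype(int)

    ph_codes = phenotypes.codes
    ph_w = np.array(BACKGROUND_PH_WEIGHTS[: len(ph_codes)], dtype=float)
    ph_w = ph_w / ph_w.sum()
    ph_idx = rng.choice(len(ph_codes), size=n_records, p=ph_w)

    # pathogenicity: planted domains use their pair's concentrated
    # distribution, everything else the background mixture
    pa_dist_by_domain: dict[int, dict[str, float]] = {}
    for pair in truth.pairs:
        d = _planted_pa_dist(pair.pa_class, pair.purity)
        pa_dist_by_domain[domains.index_of(pair.domain_i) - 1] = d
        pa_dist_by_domain[domains.index_of(pair.domain_j) - 1] = d

    pa_classes = list(BACKGROUND_PA)
    bg = np.array([BACKGROUND_PA[c] for c in pa_classes])
    pa_out = np.empty(n_records, dtype=object)
    for d in np.unique(cd_idx):
        sel = cd_idx == d
        dist = pa_dist_by_domain.get(int(d))
        p = np.array([dist[c] for c in pa_classes]) if dist else bg
        pa_out[sel] = np.array(pa_classes)[
            rng.choice(len(pa_classes), size=int(sel.sum()), p=p)
        ]

    ph_out = np.array(ph_codes)[ph_idx].astype(object)
    if masking_fraction > 0:
        masked = rng.random(n_records) < masking_fraction
        mode = rng.integers(0, 3, size=n_records)  # 0: ph, 1: pa, 2: both
        ph_out[masked & (mode != 1)] = UNKNOWN_PHENOTYPE
        pa_out[masked & (mode != 0)] = UNKNOWN_PATHOGENICITY

    codes = domains.codes
    po_codes = order.codes
    pooled = POOLED_CLASSES
    records = [
        SixDDPRecord(
            cd=codes[cd_idx[r]],
            re=PooledSubstitution(pooled[ref_idx[r]], pooled[sub_idx[r]]),
            po=po_codes[po_idx[r]],
            af=int(af[r]),
            ph=str(ph_out[r]),
            pa=str(pa_out[r]),
        )
        for r in range(n_records)
    ]
    return SixDDPDataset(records, provenance=f"synthetic(seed={seed})"), truth


def simulate_learnable_dataset(
    domains: DomainVocabulary,
    order: PopulationOrder,
    phenotypes: CodeVocabulary,
    n_records: int = 500,
    seed: int = 0,
    noise: float = 0.0,
    masking_fraction: float = 0.0,
) -> tuple[SixDDPDataset, dict[str, tuple[str, str]]]:
    """Dataset with a deterministic domain -> (phenotype, pathogenicity) rule.

    Useful for validating the imputation stage against a planted truth: a
    classifier that learns the rule reproduces 100% of known records in the
    noiseless limit.  Returns the dataset and the rule.
    """
    rng = np.random.default_rng(seed)
    ph_codes = phenotypes.codes
    pa_codes = [c for c in BACKGROUND_PA]
    rule = {
        code: (ph_codes[i % len(ph_codes)], pa_codes[i % len(pa_codes)])
        for i, code in enumerate(domains.codes)
    }
    nd = len(domains)
    cd_idx = rng.integers(0, nd, size=n_records)
    ref_idx = rng.integers(0, len(POOLED_CLASSES), size=n_records)
    sub_idx = rng.integers(0, len(POOLED_CLASSES), size=n_records)
    po_idx = rng.integers(0, len(order), size=n_records)
    af = (rng.random(n_records) >= RARE_AF_PROB).astype(int)

    records = []
    for r in range(n_records):
        cd = domains.codes[cd_idx[r]]
        ph, pa = rule[cd]
        if noise > 0 and rng.random() < noise:
            ph = ph_codes[rng.integers(0, len(ph_codes))]
            pa = pa_codes[rng.integers(0, len(pa_codes))]
        if masking_fraction > 0 and rng.random() < masking_fraction:
            ph, pa = UNKNOWN_PHENOTYPE, UNKNOWN_PATHOGENICITY
        records.append(
            SixDDPRecord(
                cd=cd,
                re=PooledSubstitution(
                    POOLED_CLASSES[ref_idx[r]], POOLED_CLASSES[sub_idx[r]]
                ),
                po=order.codes[po_idx[r]],
                af=int(af[r]),
                ph=ph,
                pa=pa,
            )
        )
    return (
        SixDDPDataset(records, provenance=f"learnable(seed={seed})"),
        rule,
    )
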