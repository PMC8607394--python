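"""Discrete Bayes model: conditional probability tables and the
domain x population SNV probability matrices.

The joint density over one SNV's six discrete variables factorizes as

    P[cd, re, po, af, ph, pa] = P(pa | ph, cd, re, po, af) * P(ph | cd, re, po, af)

with both factors estimated as maximum-likelihood (frequency) conditional
probability tables from a fully fulfilled dataset.  The SNV probability for
domain i in population j at pathogenicity class k sums the joint over all
observed allele-frequency, residue-substitution and phenotype values:

    p{cd_i, po_j, pa_k} = sum_{af, re, ph} P(pa_k | ph, c) P(ph | c),
    c = (cd_i, re, po_j, af)

and pathogenicity is made binary by combining k in {lp, pt} (pathogenic) or
k in {lb, be} (benign).  Conditioning tuples never observed contribute 0 (no
pseudocounts by default): the sum is the literal unweighted form, so matrix
entries are non-negative but not normalized over domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .divergence_proxy import PopulationOrder
from .vocab_io import (
    BENIGN_CLASSES,
    PATHOGENIC_CLASSES,
    PATHOGENICITY_CODES,
    DomainVocabulary,
    SixDDPDataset,
)

__all__ = [
    "ConditionalTables",
    "ProbabilityMatrix",
    "build_cpts",
    "joint_probability",
    "domain_population_probability",
    "probability_matrix",
    "write_probability_matrix",
]

Tuple4 = tuple[str, tuple[str, str], str, int]  # (cd, (re_ref, re_sub), po, af)


@dataclass
class ConditionalTables:
    """Frequency-estimated CPTs for the two-factor joint density.

    ``t_ph[c]`` maps phenotype -> P(ph | c) and ``t_pa[(ph, c)]`` maps
    pathogenicity -> P(pa | ph, c) for conditioning tuples
    ``c = (cd, (re_ref, re_sub), po, af)`` in ``support``.
    """

    t_ph: dict[Tuple4, dict[str, float]]
    t_pa: dict[tuple[str, Tuple4], dict[str, float]]
    support: set[Tuple4] = field(default_factory=set)

    def tuples_for(self, cd: str, po: str) -> list[Tuple4]:
        return [c for c in self.support if c[0] == cd and c[2] == po]


@dataclass
class ProbabilityMatrix:
    """p{cd_i, po_j, class} over domains (rows) x ordered populations."""

    values: np.ndarray
    pathogenicity_class: str
    domains: DomainVocabulary
    population_order: PopulationOrder

    def __post_init__(self) -> None:
        nd, npop = self.values.shape
        if nd != len(self.domains) or npop != len(self.population_order):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.domains)} domains x {len(self.population_order)} populations"
            )
        if np.any(self.values < 0):
            raise ValueError("probability matrix has negative entries")


def _frame(dataset: SixDDPDataset) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cd": [r.cd for r in dataset.records],
            "re_ref": [r.re.ref_class for r in dataset.records],
            "re_sub": [r.re.sub_class for r in dataset.records],
            "po": [r.po for r in dataset.records],
            "af": [r.af for r in dataset.records],
            "ph": [r.ph for r in dataset.records],
            "pa": [r.pa for r in dataset.records],
        }
    )


_COND = ["cd", "re_ref", "re_sub", "po", "af"]


def build_cpts(completed: SixDDPDataset, laplace: float = 0.0) -> ConditionalTables:
    """Estimate both CPTs by counting over a fully fulfilled dataset.

    ``laplace`` adds that pseudocount to every *observed* outcome cell
    (an option; the default 0 is the plain ML estimate).  Unknown outcomes
    must have been imputed away first.
    """
    if len(completed) == 0:
        raise ValueError("empty dataset")
    if not all(completed.fulfilled_mask):
        raise ValueError(
            "dataset contains unknown ph/pa outcomes; impute before building CPTs"
        )
    df = _frame(completed)

    # raw outcome counts per conditioning tuple
    ph_counts: dict[Tuple4, dict[str, int]] = {}
    pa_counts: dict[tuple[str, Tuple4], dict[str, int]] = {}
    for idx, n in df.groupby(_COND + ["ph"], sort=False).size().items():
        cd, rr, rs, po, af, ph = idx
        c: Tuple4 = (cd, (rr, rs), po, int(af))
        ph_counts.setdefault(c, {})[ph] = int(n)
    for idx, n in df.groupby(_COND + ["ph", "pa"], sort=False).size().items():
        cd, rr, rs, po, af, ph, pa = idx
        c = (cd, (rr, rs), po, int(af))
        pa_counts.setdefault((ph, c), {})[pa] = int(n)

    def normalize(counts: dict[str, int]) -> dict[str, float]:
        total = sum(counts.values()) + laplace * len(counts)
        return {k: (n + laplace) / total for k, n in counts.items()}

    t_ph = {c: normalize(cnt) for c, cnt in ph_counts.items()}
    t_pa = {key: normalize(cnt) for key, cnt in pa_counts.items()}
    return ConditionalTables(t_ph=t_ph, t_pa=t_pa, support=set(t_ph))


def joint_probability(
    cpts: ConditionalTables,
    cd: str,
    re: tuple[str, str],
    po: str,
    af: int,
    ph: str,
    pa: str,
) -> float:
    """The two-factor joint P[cd, re, po, af, ph, pa]; 0 outside support."""
    if pa not in PATHOGENICITY_CODES:
        raise ValueError(f"invalid pathogenicity code {pa!r}")
    c: Tuple4 = (cd, (re[0], re[1]), po, int(af))
    p_ph = cpts.t_ph.get(c, {}).get(ph, 0.0)
    if p_ph == 0.0:
        return 0.0
    p_pa = cpts.t_pa.get((ph, c), {}).get(pa, 0.0)
    return p_pa * p_ph


def domain_population_probability(
    cpts: ConditionalTables, cd: str, po: str, pa: str
) -> float:
    """p{cd, po, pa}: the joint summed over observed af, re, ph values."""
    total = 0.0
    for c in cpts.tuples_for(cd, po):
        for ph, p_ph in cpts.t_ph[c].items():
            total += cpts.t_pa.get((ph, c), {}).get(pa, 0.0) * p_ph
    return total


def _class_codes(pathogenicity_class: str) -> tuple[str, ...]:
    if pathogenicity_class == "pathogenic":
        return PATHOGENIC_CLASSES
    if pathogenicity_class == "benign":
        return BENIGN_CLASSES
    raise ValueError(
        f"class must be 'pathogenic' or 'benign', got {pathogenicity_class!r}"
    )


def probability_matrix(
    cpts: ConditionalTables,
    domains: DomainVocabulary,
    population_order: PopulationOrder,
    pathogenicity_class: Literal["pathogenic", "benign"],
) -> ProbabilityMatrix:
    """Binarized domain x population SNV probability matrix.

    Entry (i, j) sums ``domain_population_probability`` over the two classes
    of the binary label — {lp, pt} for pathogenic, {lb, be} for benign; the
    unknown class never contributes.  Rows of a domain with no observed SNVs
    are all zero.
    """
    codes = _class_codes(pathogenicity_class)
    nd, npop = len(domains), len(population_order)
    values = np.zeros((nd, npop))

    # accumulate per conditioning tuple once: cheaper than per-cell scans
    po_index = {po: j for j, po in enumerate(population_order.codes)}
    cd_index = {cd: i for i, cd in enumerate(domains.codes)}
    for c in cpts.support:
        cd, _, po, _ = c
        i = cd_index.get(cd)
        j = po_index.get(po)
        if i is None or j is None:
            continue
        for ph, p_ph in cpts.t_ph[c].items():
            pa_table = cpts.t_pa.get((ph, c), {})
            values[i, j] += p_ph * sum(pa_table.get(k, 0.0) for k in codes)
    return ProbabilityMatrix(values, pathogenicity_class, domains, population_order)


def write_probability_matrix(matrix: ProbabilityMatrix, path: str | Path) -> None:
    """TSV with domain codes as row labels, ordered population codes as columns."""
    frame = pd.DataFrame(
        matrix.values,
        index=list(matrix.domains.codes),
        columns=list(matrix.population_order.codes),
    )
    frame.to_csv(path, sep="\t", index_label="domain")
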