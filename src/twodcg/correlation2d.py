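"""Generalized 2D correlation over the divergence-ordered population axis.

Given domain SNV probability profiles p_i(k) over equally spaced population
indices k = 1..np, the synchronous and asynchronous correlation intensities
are

    Phi_ij = 1/(np-1) * sum_k p_i(k) p_j(k)
    Psi_ij = 1/(np-1) * sum_{k1} p_i(k1) sum_{k2} nf[k1,k2] p_j(k2)

with the Hilbert-Noda factor nf[k1,k2] = 0 if k1 == k2 else 1/(pi*(k2-k1)).
Phi is symmetric with non-negative diagonal (auto-correlation); Psi is
antisymmetric and detects which member of a domain pair responds at higher
vs lower genetic divergence (lead/lag).  Profiles enter *raw* — the
equations are applied to the probabilities as-is, not to mean-centered
"dynamic" profiles; ``center=True`` switches to the classical centered
convention but defaults off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .bayes_probability import ProbabilityMatrix
from .vocab_io import DomainVocabulary

__all__ = [
    "CorrelationMaps",
    "noda_factor",
    "noda_matrix",
    "synchronous_map",
    "asynchronous_map",
    "compute_maps",
    "lead_lag",
    "write_map",
]


@dataclass
class CorrelationMaps:
    phi: np.ndarray
    psi: np.ndarray
    n_populations: int
    pathogenicity_class: str
    domains: Optional[DomainVocabulary] = None

    def __post_init__(self) -> None:
        if self.phi.shape != self.psi.shape or self.phi.shape[0] != self.phi.shape[1]:
            raise ValueError("phi/psi must be square matrices of equal shape")


def noda_factor(k1: int, k2: int) -> float:
    """Hilbert-Noda factor: 0 on the diagonal, else 1/(pi*(k2-k1))."""
    if k1 == k2:
        return 0.0
    return 1.0 / (math.pi * (k2 - k1))


def noda_matrix(n: int) -> np.ndarray:
    k = np.arange(1, n + 1)
    diff = k[None, :] - k[:, None]
    with np.errstate(divide="ignore"):
        nf = np.where(diff == 0, 0.0, 1.0 / (np.pi * np.where(diff == 0, 1, diff)))
    return nf


def _profiles(P: ProbabilityMatrix | np.ndarray, center: bool) -> np.ndarray:
    values = P.values if isinstance(P, ProbabilityMatrix) else np.asarray(P, float)
    if values.ndim != 2:
        raise ValueError("expected a 2D domain x population array")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 populations (np >= 2)")
    if center:
        values = values - values.mean(axis=1, keepdims=True)
    return values


def synchronous_map(P: ProbabilityMatrix | np.ndarray, center: bool = False) -> np.ndarray:
    """Phi: population-synchronous cross-correlation of domain profiles."""
    v = _profiles(P, center)
    npop = v.shape[1]
    return v @ v.T / (npop - 1)


def asynchronous_map(P: ProbabilityMatrix | np.ndarray, center: bool = False) -> np.ndarray:
    """Psi: asynchronous cross-correlation through the Hilbert-Noda factor."""
    v = _profiles(P, center)
    npop = v.shape[1]
    return v @ noda_matrix(npop) @ v.T / (npop - 1)


def compute_maps(P: ProbabilityMatrix, center: bool = False) -> CorrelationMaps:
    return CorrelationMaps(
        phi=synchronous_map(P, center),
        psi=asynchronous_map(P, center),
        n_populations=len(P.population_order),
        pathogenicity_class=P.pathogenicity_class,
        domains=P.domains,
    )


#: lead/lag call labels
IN_PHASE = "in-phase"
I_LEADS = "i-leads-j"
J_LEADS = "j-leads-i"
INDETERMINATE = "indeterminate-sync"


def lead_lag(phi_ij: float, psi_ij: float, tol: float = 1e-12) -> str:
    """Noda's rules for the (i, j) pair.

    Psi ~ 0 means the two profiles vary in phase over the population axis.
    Otherwise Phi*Psi > 0 means domain i responds at higher genetic
    divergence (i leads); Phi*Psi < 0 means j leads.  A vanishing Phi with
    non-zero Psi cannot be signed by this rule and is reported as
    indeterminate (the sign of Psi is still available to the caller).
    """
    if not (np.isfinite(phi_ij) and np.isfinite(psi_ij)):
        raise ValueError("non-finite correlation intensities")
    if abs(psi_ij) <= tol:
        return IN_PHASE
    if abs(phi_ij) <= tol:
        return INDETERMINATE
    return I_LEADS if phi_ij * psi_ij > 0 else J_LEADS


def write_map(
    matrix: np.ndarray, domains: DomainVocabulary, path: str | Path
) -> None:
    """TSV matrix with domain-code headers on both axes."""
    codes = list(domains.codes)
    pd.DataFrame(matrix, index=codes, columns=codes).to_csv(
        path, sep="\t", index_label="domain"
    )
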