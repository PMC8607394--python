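"""End-to-end convenience: completed dataset -> ranked co-domain hits."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .bayes_probability import ProbabilityMatrix, build_cpts, probability_matrix
from .correlation2d import CorrelationMaps, compute_maps
from .divergence_proxy import PopulationOrder
from .significance import AmplitudeMap, CoDomainHit, analyze_maps, top_codomains
from .vocab_io import DomainVocabulary, SixDDPDataset


@dataclass
class ComplexAnalysis:
    probability: ProbabilityMatrix
    maps: CorrelationMaps
    amplitude: AmplitudeMap
    hits: list[CoDomainHit]

    @property
    def least_significant_z(self) -> float:
        return min(h.z for h in self.hits)

    @property
    def most_significant_z(self) -> float:
        return max(h.z for h in self.hits)


def analyze_complex(
    completed: SixDDPDataset,
    domains: DomainVocabulary,
    order: PopulationOrder,
    pathogenicity_class: Literal["pathogenic", "benign"] = "pathogenic",
    k: int = 6,
    boundary: Optional[int] = None,
    center: bool = False,
) -> ComplexAnalysis:
    """Run CPT estimation, 2D correlation, amplitude z-scoring, and top-K
    inter-protein co-domain extraction on a fully fulfilled dataset."""
    cpts = build_cpts(completed)
    P = probability_matrix(cpts, domains, order, pathogenicity_class)
    maps = compute_maps(P, center=center)
    amp = analyze_maps(maps)
    hits = top_codomains(
        amp, maps, boundary=boundary or domains.block_boundary, domains=domains, k=k
    )
    return ComplexAnalysis(probability=P, maps=maps, amplitude=amp, hits=hits)
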