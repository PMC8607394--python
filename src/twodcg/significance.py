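"""Amplitude combination, z-scoring, top co-domain extraction, and the
control-relative significance ratio.

The combined cross-correlate amplitude for a domain pair is

    a_ij = |Phi_ij| + pi * |Psi_ij|

where the factor pi balances the synchronous weight against the
nearest-neighbour asynchronous weight (|nf| = 1/pi at unit index gap).  The
set {a_ij} union {-a_ij} is symmetric with mean exactly 0; a normal
approximation to it has sigma equal to the root-mean-square amplitude, and
z = a/sigma measures each pair's significance in standard deviations.

The K most significant *inter-protein* pairs (the off-diagonal block between
the two proteins' domain index ranges) are the co-domain candidates.
Comparing complexes, the relative p-value is the standard-normal upper-tail
area beyond the least significant of the unknown complex's top-K hits
divided by the tail beyond the control complex's most significant amplitude;
values <= 0.05 declare the unknown's co-domains significant relative to
control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .correlation2d import CorrelationMaps, lead_lag
from .vocab_io import DomainVocabulary

__all__ = [
    "AmplitudeMap",
    "CoDomainHit",
    "amplitude_map",
    "zscores",
    "analyze_maps",
    "top_codomains",
    "relative_p_value",
    "render_report",
]


@dataclass
class AmplitudeMap:
    a: np.ndarray
    sigma: float = 0.0
    z: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if np.any(self.a < 0):
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class CoDomainHit:
    """One ranked inter-protein cross-peak."""

    domain_i: str
    domain_j: str
    index_i: int  # 1-based, protein-A block
    index_j: int  # 1-based, protein-B block
    amplitude: float
    z: float
    phi_sign: int
    psi_sign: int
    call: str
    rank: int


def amplitude_map(phi: np.ndarray, psi: np.ndarray) -> AmplitudeMap:
    """a = |Phi| + pi*|Psi|; symmetric and non-negative by construction."""
    if phi.shape != psi.shape:
        raise ValueError(f"shape mismatch: {phi.shape} vs {psi.shape}")
    return AmplitudeMap(a=np.abs(phi) + math.pi * np.abs(psi))


def _default_mask(n: int) -> np.ndarray:
    """Unique off-diagonal pairs: strict upper triangle."""
    return np.triu(np.ones((n, n), dtype=bool), k=1)


def zscores(
    a: np.ndarray, region_mask: Optional[np.ndarray] = None
) -> tuple[float, np.ndarray]:
    """Normal fit to the +/-a symmetrized amplitude sample.

    The symmetrized set has mean 0 by construction, so the fitted normal has
    sigma = sqrt(mean(a^2)) over the masked pairs; z = a/sigma.
    """
    mask = _default_mask(a.shape[0]) if region_mask is None else region_mask
    sample = a[mask]
    sigma = float(np.sqrt(np.mean(np.square(sample))))
    if sigma == 0.0:
        raise ValueError("all masked amplitudes are zero; scale undefined")
    return sigma, a / sigma


def analyze_maps(maps: CorrelationMaps, region_mask: Optional[np.ndarray] = None) -> AmplitudeMap:
    amp = amplitude_map(maps.phi, maps.psi)
    sigma, z = zscores(amp.a, region_mask)
    return AmplitudeMap(a=amp.a, sigma=sigma, z=z)


def top_codomains(
    amp: AmplitudeMap,
    maps: CorrelationMaps,
    boundary: int,
    domains: Optional[DomainVocabulary] = None,
    k: int = 6,
) -> list[CoDomainHit]:
    """Rank the K largest amplitudes among inter-protein pairs.

    Only unordered pairs (i, j) with i in the first protein block
    (index <= boundary) and j in the second (index > boundary) are eligible:
    intra-protein peaks never qualify regardless of magnitude.  Ties break by
    (i, j) lexicographic order; ranks run 1..K strictly by amplitude.
    """
    n = amp.a.shape[0]
    if not 1 <= boundary < n:
        raise ValueError(f"boundary {boundary} outside 1..{n - 1}")
    pairs = [(i, j) for i in range(boundary) for j in range(boundary, n)]
    if k > len(pairs):
        raise ValueError(f"K={k} exceeds {len(pairs)} inter-protein pairs")
    if amp.z is None:
        raise ValueError("z-scores missing; run zscores/analyze_maps first")
    pairs.sort(key=lambda ij: (-amp.a[ij], ij))
    hits = []
    for rank, (i, j) in enumerate(pairs[:k], start=1):
        phi_ij, psi_ij = maps.phi[i, j], maps.psi[i, j]
        code_i = domains.code_at(i + 1) if domains else str(i + 1)
        code_j = domains.code_at(j + 1) if domains else str(j + 1)
        hits.append(
            CoDomainHit(
                domain_i=code_i,
                domain_j=code_j,
                index_i=i + 1,
                index_j=j + 1,
                amplitude=float(amp.a[i, j]),
                z=float(amp.z[i, j]),
                phi_sign=int(np.sign(phi_ij)),
                psi_sign=int(np.sign(psi_ij)),
                call=lead_lag(phi_ij, psi_ij),
                rank=rank,
            )
        )
    return hits


def relative_p_value(z_unknown_least_of_topk: float, z_control_max: float) -> float:
    """Tail-area ratio Q(z_unknown)/Q(z_control) for the standard normal.

    Strictly decreasing in the first argument, strictly increasing in the
    second; equal arguments give exactly 1.
    """
    if not (np.isfinite(z_unknown_least_of_topk) and np.isfinite(z_control_max)):
        raise ValueError("z-scores must be finite")
    return float(norm.sf(z_unknown_least_of_topk) / norm.sf(z_control_max))


def render_report(
    maps: CorrelationMaps,
    amp: AmplitudeMap,
    hits: Sequence[CoDomainHit],
    out_dir: str | Path,
    boundary: Optional[int] = None,
    prefix: str = "map",
) -> dict[str, Path]:
    """Write grayscale rasters of Phi, Psi and Z plus the directed-linkage TSV.

    Rasters are nd x nd pixel PNGs (one pixel per domain pair) with the
    inter-protein region boundary burned in as an orange separator line and
    the top-K cross-peaks marked by correlation-square corner dots.  The
    linkage table lists one directed row per hit, leading domain first.
    """
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import cm
    from matplotlib import image as mimage

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def raster(matrix: np.ndarray, name: str) -> None:
        lo, hi = float(matrix.min()), float(matrix.max())
        scale = (matrix - lo) / (hi - lo) if hi > lo else np.zeros_like(matrix)
        rgb = cm.gray(scale)[:, :, :3]
        if boundary is not None:
            rgb[boundary - 1: boundary + 1, :, :] = [1.0, 0.65, 0.0]
            rgb[:, boundary - 1: boundary + 1, :] = [1.0, 0.65, 0.0]
        for h in hits:
            for (r, c) in ((h.index_i - 1, h.index_j - 1), (h.index_j - 1, h.index_i - 1)):
                rgb[r, c] = [0.0, 1.0, 0.0]
        path = out_dir / f"{prefix}_{name}.png"
        mimage.imsave(path, rgb)
        written[name] = path

    raster(maps.phi, "phi")
    raster(maps.psi, "psi")
    if amp.z is not None:
        raster(amp.z, "z")

    linkage = out_dir / f"{prefix}_linkage.tsv"
    with open(linkage, "w", encoding="utf-8") as fh:
        fh.write("leading\tlagging\tcall\tamplitude\tz\trank\n")
        for h in hits:
            if h.call == "j-leads-i":
                lead, lag = h.domain_j, h.domain_i
            else:
                lead, lag = h.domain_i, h.domain_j
            fh.write(
                f"{lead}\t{lag}\t{h.call}\t{h.amplitude:.6g}\t{h.z:.4f}\t{h.rank}\n"
            )
    written["linkage"] = linkage
    return written
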