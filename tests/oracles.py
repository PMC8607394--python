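"""Independent brute-force oracles, coded separately from the package.

Everything here works by plain nested loops over raw records or matrix
indices; nothing is shared with the implementation under test.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def oracle_joint(records, cd, re_pair, po, af, ph, pa) -> float:
    """P(pa|ph,c)·P(ph|c) by direct counting over the raw record list."""
    cond = [
        r for r in records
        if (r.cd, (r.re.ref_class, r.re.sub_class), r.po, r.af) == (cd, re_pair, po, af)
    ]
    if not cond:
        return 0.0
    n_ph = sum(1 for r in cond if r.ph == ph)
    if n_ph == 0:
        return 0.0
    n_ph_pa = sum(1 for r in cond if r.ph == ph and r.pa == pa)
    return (n_ph_pa / n_ph) * (n_ph / len(cond))


def oracle_domain_population(records, cd, po, pa) -> float:
    """Eq.-2-style sum over every observed (re, af, ph) value."""
    tuples = {
        ((r.re.ref_class, r.re.sub_class), r.af)
        for r in records
        if r.cd == cd and r.po == po
    }
    phenos = {r.ph for r in records}
    total = 0.0
    for re_pair, af in tuples:
        for ph in phenos:
            total += oracle_joint(records, cd, re_pair, po, af, ph, pa)
    return total


def oracle_matrix(records, domain_codes, po_codes, pa_classes) -> np.ndarray:
    out = np.zeros((len(domain_codes), len(po_codes)))
    for i, cd in enumerate(domain_codes):
        for j, po in enumerate(po_codes):
            out[i, j] = sum(
                oracle_domain_population(records, cd, po, pa) for pa in pa_classes
            )
    return out


def oracle_noda(k1: int, k2: int) -> float:
    return 0.0 if k1 == k2 else 1.0 / (math.pi * (k2 - k1))


def oracle_phi(P: np.ndarray) -> np.ndarray:
    nd, npop = P.shape
    phi = np.zeros((nd, nd))
    for i in range(nd):
        for j in range(nd):
            s = 0.0
            for k in range(npop):
                s += P[i, k] * P[j, k]
            phi[i, j] = s / (npop - 1)
    return phi


def oracle_psi(P: np.ndarray) -> np.ndarray:
    nd, npop = P.shape
    psi = np.zeros((nd, nd))
    for i in range(nd):
        for j in range(nd):
            s = 0.0
            for k1 in range(npop):
                inner = 0.0
                for k2 in range(npop):
                    inner += oracle_noda(k1 + 1, k2 + 1) * P[j, k2]
                s += P[i, k1] * inner
            psi[i, j] = s / (npop - 1)
    return psi


def oracle_amplitude(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    nd = phi.shape[0]
    a = np.zeros_like(phi)
    for i in range(nd):
        for j in range(nd):
            a[i, j] = abs(phi[i, j]) + math.pi * abs(psi[i, j])
    return a


def oracle_haversine(lat1, lon1, lat2, lon2, radius=6371.0) -> float:
    """Second, independently coded great-circle distance (vector form)."""
    p1 = np.radians([lat1, lon1])
    p2 = np.radians([lat2, lon2])
    v1 = np.array([
        np.cos(p1[0]) * np.cos(p1[1]), np.cos(p1[0]) * np.sin(p1[1]), np.sin(p1[0])
    ])
    v2 = np.array([
        np.cos(p2[0]) * np.cos(p2[1]), np.cos(p2[0]) * np.sin(p2[1]), np.sin(p2[0])
    ])
    angle = np.arctan2(np.linalg.norm(np.cross(v1, v2)), np.dot(v1, v2))
    return float(radius * angle)


def oracle_majority(values, unknown):
    counts = Counter(values)
    top, n = counts.most_common(1)[0]
    return top if 2 * n > len(values) else unknown
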