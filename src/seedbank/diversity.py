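"""Quadrat-level diversity indices.

With S species, counts n_i and N = Σ n_i seeds in a quadrat
(p_i = n_i / N):

* Shannon diversity        H′ = −Σ p_i ln p_i                (nats)
* Simpson diversity        λ  = 1 − Σ p_i²
* Evenness                 E  = (1/D − 1) / (e^{H′} − 1),  D = Σ p_i²
* Ecological dominance     C  = Σ n_i (n_i − 1) / (N (N − 1))

The evenness default is the modified-Hill ratio (Alatalo): the ratio of
the Simpson and Shannon effective species numbers, shifted by one, which
equals 1 for a perfectly even community of any richness.  A
``literal`` variant replacing D by the Simpson diversity λ itself
is kept for auditability; it is pathological on even communities
(E = 1/(S−1)² rather than 1) and not recommended.

C is the finite-sample (Hurlbert-corrected) probability that two seeds
drawn without replacement belong to the same species; it converges to
D = 1 − λ as N grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .phytosociology import counts_to_density
from .types import QuadratCounts, ValidationError

EVENNESS_VARIANTS = ("modified_hill", "literal")


def _proportions(counts: Sequence[float]) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or arr.sum() <= 0:
        raise ValidationError("diversity indices undefined for an empty quadrat")
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    arr = arr[arr > 0]
    return arr / arr.sum()


def shannon(counts: Sequence[float]) -> float:
    """Shannon diversity H′ = −Σ p ln p (natural log)."""
    p = _proportions(counts)
    return float(-(p * np.log(p)).sum())


def simpson(counts: Sequence[float]) -> float:
    """Simpson diversity λ = 1 − Σ p²."""
    p = _proportions(counts)
    return float(1.0 - (p * p).sum())


def evenness(counts: Sequence[float], variant: str = "modified_hill") -> float:
    """Evenness E; see module docstring for the two variants.

    Undefined (raises) for a single-species quadrat, where both
    numerator and denominator vanish.
    """
    if variant not in EVENNESS_VARIANTS:
        raise ValidationError(f"unknown evenness variant {variant!r}")
    p = _proportions(counts)
    if p.size < 2:
        raise ValidationError("evenness undefined for a single-species quadrat (0/0)")
    d = float((p * p).sum())
    h = float(-(p * np.log(p)).sum())
    ratio_base = d if variant == "modified_hill" else 1.0 - d  # λ in the literal form
    return (1.0 / ratio_base - 1.0) / (np.expm1(h))


def dominance(counts: Sequence[float]) -> float:
    """Ecological dominance C = Σ n(n−1) / (N(N−1)); needs N ≥ 2."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    n_total = arr.sum()
    if n_total < 2:
        raise ValidationError("dominance undefined for fewer than 2 seeds")
    return float((arr * (arr - 1)).sum() / (n_total * (n_total - 1)))


@dataclass(frozen=True)
class DiversityRecord:
    """Per-quadrat diversity summary."""

    site_id: str
    mode: str
    field_id: int
    quadrat_id: int
    N: int
    S: int
    H_prime: float
    lambda_simpson: float
    evenness_E: float
    dominance_C: float
    total_density: float


def diversity_profile(
    quadrats: Sequence[QuadratCounts], evenness_variant: str = "modified_hill"
) -> pd.DataFrame:
    """One row of N, S, H′, λ, E, C and total density per quadrat.

    E is NaN for single-species quadrats and C is NaN for quadrats with
    fewer than 2 seeds (both undefined); empty quadrats raise, naming
    the quadrat.
    """
    rows = []
    for q in quadrats:
        counts = [n for n in q.counts.values() if n > 0]
        if not counts:
            raise ValidationError(
                f"quadrat ({q.site_id},{q.field_id},{q.quadrat_id}) is empty; "
                "diversity indices undefined"
            )
        n_total = int(sum(counts))
        s = len(counts)
        e = evenness(counts, evenness_variant) if s >= 2 else float("nan")
        c = dominance(counts) if n_total >= 2 else float("nan")
        rows.append(
            {
                "site": q.site_id,
                "mode": q.mode,
                "field": q.field_id,
                "quadrat": q.quadrat_id,
                "N": n_total,
                "S": s,
                "H_prime": shannon(counts),
                "lambda_simpson": simpson(counts),
                "evenness_E": e,
                "dominance_C": c,
                "total_density": sum(counts_to_density(q).values()),
            }
        )
    return pd.DataFrame(rows)
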