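"""Naive reference implementations used as independent oracles.

Everything here is written directly from the defining equations with
plain Python loops — deliberately independent of the package's
vectorized implementations.
"""

from __future__ import annotations

import math


def naive_phytosociology(quadrats):
    """Per-species AF/RF/AD/RD/AA/RA/IV from the printed equations.

    ``quadrats`` is a list of dicts species → count, all sharing one
    sampled area per quadrat (3 × 0.016 m² default) supplied as
    ``(counts, area)`` tuples.
    """
    species = sorted({sp for counts, _ in quadrats for sp, n in counts.items() if n > 0})
    n_q = len(quadrats)
    total_area = sum(area for _, area in quadrats)
    out = {}
    for sp in species:
        present = sum(1 for counts, _ in quadrats if counts.get(sp, 0) > 0)
        total = sum(counts.get(sp, 0) for counts, _ in quadrats)
        out[sp] = {"AF": present / n_q, "AD": total / total_area, "AA": total / present}
    for rel, absname in (("RF", "AF"), ("RD", "AD"), ("RA", "AA")):
        s = sum(v[absname] for v in out.values())
        for v in out.values():
            v[rel] = v[absname] / s
    for v in out.values():
        v["IV"] = v["RF"] + v["RD"] + v["RA"]
    return out


def naive_shannon(counts):
    n = sum(counts)
    return -sum((c / n) * math.log(c / n) for c in counts if c > 0)


def naive_simpson(counts):
    n = sum(counts)
    return 1.0 - sum((c / n) ** 2 for c in counts if c > 0)


def naive_evenness(counts, variant="modified_hill"):
    n = sum(counts)
    p = [c / n for c in counts if c > 0]
    d = sum(x * x for x in p)
    h = -sum(x * math.log(x) for x in p)
    base = d if variant == "modified_hill" else 1.0 - d
    return (1.0 / base - 1.0) / (math.exp(h) - 1.0)


def naive_dominance(counts):
    n = sum(counts)
    return sum(c * (c - 1) for c in counts) / (n * (n - 1))


def naive_bray_curtis(x, y):
    shared = sum(min(a, b) for a, b in zip(x, y))
    total = sum(x) + sum(y)
    return 1.0 - 2.0 * shared / total
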