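"""Independent brute-force transcription of the Weir-Cockerham (1984)
variance components, written as the general r-population formulas with
explicit Python loops.  Used only as a test oracle; deliberately shares no
code with stockid.fst.
"""

from __future__ import annotations

import math


def wc_components(genotype_lists):
    """(a, b, c) for one locus from per-population genotype lists.

    ``genotype_lists`` is a list of r lists of dosages in {0, 1, 2} (missing
    calls already removed).  Returns None when any population has fewer than
    two genotypes.
    """
    r = len(genotype_lists)
    ns, ps, hs = [], [], []
    for g in genotype_lists:
        if len(g) < 2:
            return None
        ns.append(len(g))
        ps.append(sum(g) / (2.0 * len(g)))
        hs.append(sum(1 for x in g if x == 1) / len(g))

    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)

    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1.0))
        * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc_theta(genotype_lists):
    comps = wc_components(genotype_lists)
    if comps is None:
        return None
    a, b, c = comps
    denom = a + b + c
    return None if denom == 0 else a / denom
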