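"""Site filtering and Weir-Cockerham F_ST estimation.

Per-site variance components follow the classic moment estimator for the
two-population (r = 2) case: with sample sizes ``n_i``, ALT frequencies
``p_i`` and observed heterozygote proportions ``h_i``,

    nbar = (n1 + n2) / 2
    n_c  = (n1 + n2) - (n1^2 + n2^2) / (n1 + n2)
    pbar = (n1 p1 + n2 p2) / (n1 + n2)
    s2   = (n1 (p1 - pbar)^2 + n2 (p2 - pbar)^2) / nbar
    hbar = (n1 h1 + n2 h2) / (n1 + n2)

    a = (nbar / n_c) * (s2 - (pbar(1-pbar) - s2/2 - hbar/4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar(1-pbar) - s2/2 - (2 nbar - 1)/(4 nbar) * hbar)
    c = hbar / 2

and theta = a / (a + b + c), undefined when a + b + c = 0 (a locus
monomorphic across the pair).  Multi-locus theta is the ratio of sums,
``sum(a) / sum(a + b + c)``, never the mean of per-locus ratios; negative
per-locus components are retained so the ratio stays unbiased.

Missing genotypes are handled pairwise-complete per locus; there is no
imputation in estimation.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

FST_COLUMNS = ["locus_id", "chrom", "pos", "pop_a", "pop_b", "a", "b", "c", "theta"]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def apply_site_filters(
    matrix: GenotypeMatrix,
    qual_min: float = 0.0,
    ns_min: int = 0,
    maf_min: float = 0.0,
) -> GenotypeMatrix:
    """Retain loci with QUAL >= qual_min, NS >= ns_min and pooled MAF >= maf_min.

    NS is the number of samples with data at the locus; the pooled minor
    allele frequency is computed over all non-missing calls ignoring
    population labels.  Loci without a QUAL value pass the quality filter
    only when ``qual_min`` is 0.  Sample set and locus order are unchanged.
    """
    if qual_min < 0 or ns_min < 0 or maf_min < 0:
        raise ValueError("filter thresholds must be non-negative")
    qual = matrix.loci["qual"].to_numpy(dtype=float)
    keep_qual = np.where(np.isnan(qual), qual_min == 0, qual >= qual_min)
    ns = matrix.ns_per_locus()
    keep_ns = ns >= ns_min
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        alt_freq = np.nanmean(matrix.dosages, axis=0) / 2.0
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep_maf = np.where(np.isnan(maf), maf_min == 0, maf >= maf_min)
    keep = keep_qual & keep_ns & keep_maf
    if not keep.any():
        warnings.warn("all loci removed by site filters", stacklevel=2)
    return matrix.subset_loci(keep)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def _pop_indices(matrix: GenotypeMatrix, pop_map: dict[str, str]) -> dict[str, np.ndarray]:
    unmapped = [s for s in matrix.sample_ids if s not in pop_map]
    if unmapped:
        raise KeyError(f"samples without a population: {unmapped[:5]}")
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(matrix.sample_ids):
        groups.setdefault(pop_map[s], []).append(i)
    return {p: np.array(ix) for p, ix in groups.items()}


def allele_frequencies(
    matrix: GenotypeMatrix, pop_map: dict[str, str]
) -> pd.DataFrame:
    """Per-population ALT allele frequencies (NaN where a population has no data).

    Frequency = ALT allele count / (2 x non-missing samples) per population
    and locus.  Returned frame: index = locus_id, one column per population.
    """
    groups = _pop_indices(matrix, pop_map)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for pop, idx in groups.items():
            out[pop] = np.nanmean(matrix.dosages[idx], axis=0) / 2.0
    return pd.DataFrame(out, index=matrix.loci["locus_id"])


# ---------------------------------------------------------------------------
# Weir-Cockerham components
# ---------------------------------------------------------------------------


def _wc_pair_components(g1: np.ndarray, g2: np.ndarray):
    """Vectorised per-locus (a, b, c) for two dosage blocks (samples x loci).

    Loci where either population has fewer than 2 non-missing calls get NaN
    components.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n1 = (~np.isnan(g1)).sum(axis=0).astype(float)
        n2 = (~np.isnan(g2)).sum(axis=0).astype(float)
        p1 = np.nanmean(g1, axis=0) / 2.0
        p2 = np.nanmean(g2, axis=0) / 2.0
        # heterozygote proportion over observed calls only
        h1 = (g1 == 1.0).sum(axis=0) / np.where(n1 > 0, n1, np.nan)
        h2 = (g2 == 1.0).sum(axis=0) / np.where(n2 > 0, n2, np.nan)

        N = n1 + n2
        nbar = N / 2.0
        n_c = N - (n1**2 + n2**2) / N
        pbar = (n1 * p1 + n2 * p2) / N
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / N

        inner = pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0
        a = (nbar / n_c) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / 2.0 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0

    bad = (n1 < 2) | (n2 < 2)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_components_pair(
    matrix: GenotypeMatrix, pop_map: dict[str, str], pair: tuple[str, str]
) -> pd.DataFrame:
    """Per-locus WC84 components and theta for one population pair.

    Theta is NaN where undefined (monomorphic across the pair, or fewer than
    two genotyped individuals in either population).  The result is
    symmetric in the two populations.
    """
    groups = _pop_indices(matrix, pop_map)
    pa, pb = pair
    for p in pair:
        if p not in groups:
            raise KeyError(f"population {p!r} has no samples")
    a, b, c = _wc_pair_components(
        matrix.dosages[groups[pa]], matrix.dosages[groups[pb]]
    )
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    return pd.DataFrame(
        {
            "locus_id": matrix.loci["locus_id"],
            "chrom": matrix.loci["chrom"],
            "pos": matrix.loci["pos"],
            "pop_a": pa,
            "pop_b": pb,
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
        }
    )


def wc_theta_site(
    matrix: GenotypeMatrix,
    pop_map: dict[str, str],
    pair: tuple[str, str],
    locus_id: str,
) -> pd.Series:
    """WC84 row (a, b, c, theta) for a single locus and population pair."""
    sub = matrix.subset_loci([locus_id])
    return wc_components_pair(sub, pop_map, pair).iloc[0]


def wc_theta_multilocus(table: pd.DataFrame) -> float:
    """Multi-locus theta by ratio of sums over loci with defined components."""
    ok = table[["a", "b", "c"]].notna().all(axis=1)
    if not ok.any():
        return float("nan")
    num = table.loc[ok, "a"].sum()
    den = (table.loc[ok, ["a", "b", "c"]].to_numpy()).sum()
    return float("nan") if den == 0 else float(num / den)


def pairwise_fst_matrix(
    matrix: GenotypeMatrix,
    pop_map: dict[str, str],
    loci_subset=None,
) -> pd.DataFrame:
    """Symmetric K x K matrix of multi-locus theta (zero diagonal).

    ``loci_subset`` may be a PanelSpec, a locus_id list, or None (all loci).
    A population with fewer than 2 samples yields NaN in its row/column.
    """
    if loci_subset is not None:
        ids = getattr(loci_subset, "locus_ids", None)
        ids = ids() if callable(ids) else (ids if ids is not None else loci_subset)
        matrix = matrix.subset_loci(list(ids))
    pops = sorted(set(pop_map[s] for s in matrix.sample_ids))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    groups = _pop_indices(matrix, pop_map)
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for pa, pb in itertools.combinations(pops, 2):
        if len(groups[pa]) < 2 or len(groups[pb]) < 2:
            out.loc[pa, pb] = out.loc[pb, pa] = np.nan
            continue
        tab = wc_components_pair(matrix, pop_map, (pa, pb))
        out.loc[pa, pb] = out.loc[pb, pa] = wc_theta_multilocus(tab)
    return out
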