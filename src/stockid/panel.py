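"""Ancestry-informative SNP panel design.

Pipeline order: per-pair top-k selection by theta -> deduplication with
provenance -> windowed-greedy LD pruning -> genomic hotspot summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, chrom_sort_key

PANEL_COLUMNS = [
    "locus_id", "chrom", "pos", "contributing_pairs", "best_rank", "best_theta",
]


@dataclass
class PanelSpec:
    """Ordered, deduplicated panel of selected loci with provenance.

    ``entries``: DataFrame with columns ``locus_id, chrom, pos,
    contributing_pairs (set of 'A|B' strings), best_rank, best_theta``,
    ordered by (chrom, pos).  ``r2_max``/``window``/``step`` record the LD
    pruning parameters applied (None before pruning); ``provenance`` is a
    free-text note on the input cohort.
    """

    entries: pd.DataFrame
    k: int
    r2_max: float | None = None
    window: int | None = None
    step: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.entries["locus_id"].duplicated().any():
            raise ValueError("panel locus_ids must be unique")

    def locus_ids(self) -> list[str]:
        return self.entries["locus_id"].tolist()

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str, loci_meta: pd.DataFrame | None = None) -> None:
        df = self.entries.copy()
        df["contributing_pairs"] = [
            ";".join(sorted(s)) for s in df["contributing_pairs"]
        ]
        if loci_meta is not None:
            df = df.merge(
                loci_meta[["locus_id", "ref", "alt"]], on="locus_id", how="left"
            )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "PanelSpec":
        df = pd.read_csv(path, sep="\t")
        df["contributing_pairs"] = [
            set(str(s).split(";")) if pd.notna(s) else set()
            for s in df["contributing_pairs"]
        ]
        return cls(entries=df[[c for c in df.columns if c in PANEL_COLUMNS
                               or c in ("ref", "alt")]], k=0)


def _pair_key(pop_a: str, pop_b: str) -> str:
    return "|".join(sorted((str(pop_a), str(pop_b))))


def _ordered(entries: pd.DataFrame) -> pd.DataFrame:
    key = entries["chrom"].map(chrom_sort_key)
    return (
        entries.assign(_ck=key)
        .sort_values(["_ck", "pos"], kind="stable")
        .drop(columns="_ck")
        .reset_index(drop=True)
    )


def select_top_candidates(fst_tables: dict, k: int) -> PanelSpec:
    """Union of the per-pair top-k loci by theta, duplicates merged.

    For each population pair's FstTable, the k loci with largest defined
    theta are taken (ties broken by ascending (chrom, pos), stable); pairs
    with fewer than k defined loci contribute all of them.  Duplicates across
    pairs are merged, recording every contributing pair, the best (smallest)
    rank and the largest theta.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    merged: dict[str, dict] = {}
    for key, table in fst_tables.items():
        if len(table) == 0:
            raise ValueError(f"empty F_ST table for pair {key!r}")
        pair = (
            _pair_key(table["pop_a"].iloc[0], table["pop_b"].iloc[0])
            if {"pop_a", "pop_b"}.issubset(table.columns)
            else str(key)
        )
        ok = table[table["theta"].notna()].copy()
        ok["_ck"] = ok["chrom"].map(chrom_sort_key)
        ok = ok.sort_values(
            ["theta", "_ck", "pos"], ascending=[False, True, True], kind="stable"
        )
        top = ok.head(k)
        for rank, row in enumerate(top.itertuples(index=False), start=1):
            e = merged.get(row.locus_id)
            if e is None:
                merged[row.locus_id] = {
                    "locus_id": row.locus_id,
                    "chrom": row.chrom,
                    "pos": row.pos,
                    "contributing_pairs": {pair},
                    "best_rank": rank,
                    "best_theta": row.theta,
                }
            else:
                e["contributing_pairs"].add(pair)
                e["best_rank"] = min(e["best_rank"], rank)
                e["best_theta"] = max(e["best_theta"], row.theta)
    entries = _ordered(pd.DataFrame(list(merged.values()), columns=PANEL_COLUMNS))
    return PanelSpec(entries=entries, k=k)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared genotype correlation between columns, pairwise-complete samples.

    A constant column (or a pair with < 2 complete samples) has r^2 = 0 with
    everything, so it can never exceed a pruning threshold.
    """
    m = dosages.shape[1]
    r2 = np.zeros((m, m))
    obs = ~np.isnan(dosages)
    for i in range(m):
        for j in range(i + 1, m):
            both = obs[:, i] & obs[:, j]
            if both.sum() < 2:
                continue
            x, y = dosages[both, i], dosages[both, j]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2[i, j] = r2[j, i] = r * r
    return r2


def ld_prune(
    matrix: GenotypeMatrix,
    candidates: PanelSpec,
    r2_max: float = 0.5,
    window: int = 50,
    step: int = 5,
) -> PanelSpec:
    """Windowed greedy LD pruning of a candidate panel.

    Candidates are ordered by (chrom, pos) and scanned in sliding windows of
    ``window`` loci advanced by ``step``.  Within a window, while any
    surviving pair has r^2 > ``r2_max``, the pair with the largest r^2 is
    resolved by removing its lower-``best_theta`` member (tie: the later
    locus in genome order).  The output is a subset of the candidates, order
    preserved, with pairwise r^2 <= r2_max inside every window.
    """
    if not (0.0 < r2_max <= 1.0):
        raise ValueError("r2_max must be in (0, 1]")
    if window < 2 or step < 1:
        raise ValueError("window must be >= 2 and step >= 1")
    entries = _ordered(candidates.entries)
    ids = entries["locus_id"].tolist()
    missing = set(ids) - set(matrix.locus_ids)
    if missing:
        raise KeyError(f"candidates absent from matrix: {sorted(missing)[:5]}")
    sub = matrix.subset_loci(ids)  # columns in candidate order
    theta = entries["best_theta"].to_numpy()

    alive = np.ones(len(ids), dtype=bool)
    n = len(ids)
    for start in range(0, n, step):
        win = np.arange(start, min(start + window, n))
        win = win[alive[win]]
        if len(win) < 2:
            if start + window >= n:
                break
            continue
        r2 = _pairwise_r2(sub.dosages[:, win])
        np.fill_diagonal(r2, 0.0)
        while True:
            live = alive[win]
            r2_live = r2[np.ix_(live, live)]
            if r2_live.size == 0 or r2_live.max() <= r2_max:
                break
            live_idx = win[live]
            i_loc, j_loc = np.unravel_index(np.argmax(r2_live), r2_live.shape)
            gi, gj = live_idx[i_loc], live_idx[j_loc]
            if theta[gi] < theta[gj]:
                drop = gi
            elif theta[gj] < theta[gi]:
                drop = gj
            else:
                drop = max(gi, gj)  # tie: remove the later locus
            alive[drop] = False
        if start + window >= n:
            break
    return PanelSpec(
        entries=entries[alive].reset_index(drop=True),
        k=candidates.k,
        r2_max=r2_max,
        window=window,
        step=step,
        provenance=candidates.provenance,
    )


def panel_genome_summary(panel: PanelSpec) -> pd.DataFrame:
    """Per-chromosome locus counts and fractions, sorted descending by count."""
    if len(panel) == 0:
        raise ValueError("panel is empty")
    counts = panel.entries.groupby("chrom", sort=False)["locus_id"].count()
    df = (
        counts.rename("n_loci")
        .reset_index()
        .sort_values(["n_loci", "chrom"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    df["fraction"] = df["n_loci"] / len(panel)
    return df
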