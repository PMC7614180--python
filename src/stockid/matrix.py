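"""Genotype containers and file IO.

The central container is :class:`GenotypeMatrix`: an individuals x loci
matrix of ALT-allele dosages (0, 1, 2 or missing) together with per-locus
metadata (chromosome, 1-based position, REF/ALT alleles, optional call
quality) and ordered sample identifiers.  Missing genotypes are stored as
``numpy.nan`` so that vectorised statistics can use the ``nan*`` reductions.

Only biallelic SNPs are represented; multi-allelic VCF records must be
split upstream and are skipped (with a warning) on import.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = np.nan

#: columns of the locus-metadata frame, in storage order
LOCUS_COLUMNS = ["locus_id", "chrom", "pos", "ref", "alt", "qual"]

_CHROM_NUM = re.compile(r"(\d+)$")


def chrom_sort_key(chrom: str) -> tuple:
    """Sort key placing chr2 before chr10 (natural order, then lexicographic)."""
    m = _CHROM_NUM.search(str(chrom))
    if m:
        return (str(chrom)[: m.start()], int(m.group(1)))
    return (str(chrom), -1)


@dataclass
class GenotypeMatrix:
    """Diploid SNP genotypes for a cohort.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample labels (length n).
    loci
        DataFrame with columns ``locus_id, chrom, pos, ref, alt, qual``
        (length L); ``qual`` may be NaN for loci without a call quality.
    dosages
        ``(n, L)`` float array of ALT-allele counts in {0, 1, 2, NaN}.
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.loci = self.loci.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n, L = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"dosage rows ({n}) != number of samples ({len(self.sample_ids)})"
            )
        if L != len(self.loci):
            raise ValueError(
                f"dosage columns ({L}) != number of loci ({len(self.loci)})"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        missing_cols = [c for c in LOCUS_COLUMNS if c not in self.loci.columns]
        if missing_cols:
            raise ValueError(f"loci frame lacks columns {missing_cols}")
        if self.loci["locus_id"].duplicated().any():
            dup = self.loci.loc[self.loci["locus_id"].duplicated(), "locus_id"]
            raise ValueError(f"duplicate locus_ids: {sorted(set(dup))[:5]}")
        if (self.loci["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = np.unique(vals[~np.isin(vals, (0.0, 1.0, 2.0))])
            raise ValueError(f"dosages outside {{0,1,2,missing}}: {bad[:5]}")

    # -- basic accessors ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return self.loci["locus_id"].tolist()

    def ns_per_locus(self) -> np.ndarray:
        """Number of samples with data (non-missing calls) per locus."""
        return (~np.isnan(self.dosages)).sum(axis=0)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids), self.loci.copy(), self.dosages.copy()
        )

    # -- subsetting ---------------------------------------------------------
    def subset_loci(self, keep) -> "GenotypeMatrix":
        """Subset by boolean mask, integer positions, or locus_id list."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            pos = {lid: i for i, lid in enumerate(self.loci["locus_id"])}
            try:
                idx = np.array([pos[lid] for lid in keep], dtype=int)
            except KeyError as e:
                raise KeyError(f"unknown locus_id {e.args[0]!r}") from None
        return GenotypeMatrix(
            list(self.sample_ids),
            self.loci.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx],
        )

    def subset_samples(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            pos = {sid: i for i, sid in enumerate(self.sample_ids)}
            try:
                idx = np.array([pos[sid] for sid in keep], dtype=int)
            except KeyError as e:
                raise KeyError(f"unknown sample_id {e.args[0]!r}") from None
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx], self.loci.copy(), self.dosages[idx]
        )

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write an uncompressed VCFv4.2 file with GT genotypes (``./.`` missing)."""
    chroms = sorted(set(matrix.loci["chrom"]), key=chrom_sort_key)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=stockid\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        quals = matrix.loci["qual"].to_numpy()
        for j, row in enumerate(matrix.loci.itertuples(index=False)):
            q = "." if pd.isna(quals[j]) else f"{quals[j]:g}"
            gts = "\t".join(
                _GT_STRINGS.get(d, "./.") for d in matrix.dosages[:, j]
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.locus_id}\t{row.ref}\t{row.alt}"
                f"\t{q}\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` (biallelic records only)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        g = var.gt_types.astype(float)
        g[g == 3] = MISSING
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        rows.append(
            (lid, var.CHROM, var.POS, var.REF, var.ALT[0],
             var.QUAL if var.QUAL is not None else MISSING)
        )
        dosage_cols.append(g)
    vcf.close()
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} non-biallelic record(s); split them upstream",
            stacklevel=2,
        )
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    dosages = (
        np.column_stack(dosage_cols)
        if dosage_cols
        else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples, loci, dosages)


# ---------------------------------------------------------------------------
# population maps / panels
# ---------------------------------------------------------------------------


def read_pop_map(path: str, population_column: str = "population") -> dict[str, str]:
    """Read a sample->population CSV (columns ``sample_id`` and a label column).

    Truth CSVs written by the simulator carry ``true_population`` and
    ``traditional_label`` columns; pass ``population_column`` to pick one.
    """
    df = pd.read_csv(path, dtype=str)
    if population_column not in df.columns:
        for alt in ("population", "true_population", "traditional_label"):
            if alt in df.columns:
                population_column = alt
                break
        else:
            raise ValueError(f"no population column in {path}")
    return dict(zip(df["sample_id"], df[population_column]))


def write_pop_map(pop_map: dict[str, str], path: str) -> None:
    pd.DataFrame(
        {"sample_id": list(pop_map), "population": list(pop_map.values())}
    ).to_csv(path, index=False)
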