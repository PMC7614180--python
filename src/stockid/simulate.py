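"""Synthetic genotype cohorts with the structure of a mixed-stock study.

The generator emulates the statistical features the downstream analysis
depends on, without touching sequencing reads:

* **Hierarchical drift** — per-population allele frequencies follow the
  Balding–Nichols model, ``p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` around an
  ancestral frequency ``p``, on a two-level star tree: designated subgroups
  share a branch (drift ``F_shared``) before each population drifts along
  its terminal branch.  A single-level star cannot reproduce divergence
  patterns where one population is uniformly farther from the rest.
* **Outlier loci** — a configurable number of loci receive drift scaled by
  ``outlier_drift_scale``, and a configurable fraction of them sit on one
  "hotspot" chromosome, mimicking islands of divergence in an otherwise
  homogeneous genome.
* **Assessment cohorts with label error** — a row-stochastic
  ``mixing_matrix`` gives P(true origin | traditional label); genotypes are
  drawn from the true origin's frequencies while the (possibly wrong)
  traditional label is recorded, so label-vs-genetics agreement statistics
  have a known ground truth.
* **Technical degradation** — genotyping dropout (missingness) and symmetric
  genotype errors, plus duplicated individuals standing in for technical
  replicates.

Default scenario constants reproduce the published four-stock Atlantic
herring setting (NSSH/ISSH/NSAH/FASH): panel-scale pairwise F_ST between
0.13 and 0.45 over a genome-wide background of 0.0007-0.0046, baseline
sample sizes 29/30/17/27, a 240-individual assessment cohort with 28
technical replicate pairs, and half of the outlier loci on one chromosome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .matrix import MISSING, LOCUS_COLUMNS, GenotypeMatrix

# ---------------------------------------------------------------------------
# published herring-study scenario constants
# ---------------------------------------------------------------------------

HERRING_POPS = ["FASH", "ISSH", "NSAH", "NSSH"]

#: baseline cohort sizes per stock (traditional assignment)
HERRING_BASELINE_SIZES = {"NSSH": 29, "ISSH": 30, "NSAH": 17, "FASH": 27}

#: pairwise F_ST between baseline stocks on the 118-SNP panel
HERRING_PANEL_FST = pd.DataFrame(
    [
        [0.0, 0.1313, 0.3495, 0.4271],
        [0.1313, 0.0, 0.3815, 0.4468],
        [0.3495, 0.3815, 0.0, 0.4357],
        [0.4271, 0.4468, 0.4357, 0.0],
    ],
    index=HERRING_POPS,
    columns=HERRING_POPS,
)

#: pairwise F_ST between baseline stocks on the genome-wide SNP set
HERRING_GENOME_FST = pd.DataFrame(
    [
        [0.0, 0.0007, 0.0046, 0.0019],
        [0.0007, 0.0, 0.0045, 0.0032],
        [0.0046, 0.0045, 0.0, 0.0037],
        [0.0019, 0.0032, 0.0037, 0.0],
    ],
    index=HERRING_POPS,
    columns=HERRING_POPS,
)

#: FASH and ISSH are sister stocks (lowest mutual divergence): they share a branch
HERRING_SUBGROUPS = {"FASH-ISSH": ["FASH", "ISSH"]}

HERRING_PANEL_SIZE = 118
HERRING_ASSESSMENT_SIZE = 240
HERRING_REPLICATE_PAIRS = 28
HERRING_HOTSPOT_CHROM = "chr12"
HERRING_N_CHROMOSOMES = 26


# ---------------------------------------------------------------------------
# drift-parameter fitting
# ---------------------------------------------------------------------------


def expected_pairwise_theta(
    terminal_drift: dict[str, float],
    shared_drift: dict[str, float],
    subgroups: dict[str, list[str]],
) -> pd.DataFrame:
    """Expected pairwise F_ST under the two-level star tree.

    Two populations in the same subgroup diverge only along their terminal
    branches, so the expected pairwise theta is the mean of their terminal
    drifts.  Populations in different subgroups (or ungrouped) diverge along
    their full root-to-tip paths, with total drift
    ``1 - (1 - F_shared)(1 - F_terminal)``.

    The approximation E[theta_ij] ~ (F_i + F_j) / 2 for a pair with drifts
    F_i, F_j is calibrated empirically against the Monte-Carlo oracle in the
    test suite rather than assumed exact.
    """
    pops = list(terminal_drift)
    group_of = {p: g for g, members in subgroups.items() for p in members}
    total = {}
    for p in pops:
        fs = shared_drift.get(group_of.get(p), 0.0)
        total[p] = 1.0 - (1.0 - fs) * (1.0 - terminal_drift[p])
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for a, b in itertools.combinations(pops, 2):
        if group_of.get(a) is not None and group_of.get(a) == group_of.get(b):
            th = 0.5 * (terminal_drift[a] + terminal_drift[b])
        else:
            th = 0.5 * (total[a] + total[b])
        out.loc[a, b] = out.loc[b, a] = th
    return out


def fit_drift_two_level(
    target_fst: pd.DataFrame,
    subgroups: dict[str, list[str]] | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Least-squares fit of per-population drifts to a target pairwise F_ST matrix.

    Parameters are one terminal drift per population plus one shared-branch
    drift per subgroup, optimised (on a logit scale, bounded to (1e-5, 0.95))
    so that :func:`expected_pairwise_theta` matches ``target_fst``.

    Returns
    -------
    (terminal_drift, shared_drift)
        Dicts keyed by population name and subgroup name respectively.
    """
    subgroups = dict(subgroups or {})
    pops = list(target_fst.index)
    groups = list(subgroups)
    pairs = list(itertools.combinations(pops, 2))

    lo, hi = 1e-5, 0.95

    def unpack(x):
        f = lo + (hi - lo) / (1.0 + np.exp(-x))  # logistic into (lo, hi)
        term = dict(zip(pops, f[: len(pops)]))
        shared = dict(zip(groups, f[len(pops):]))
        return term, shared

    def resid(x):
        term, shared = unpack(x)
        exp = expected_pairwise_theta(term, shared, subgroups)
        return np.array([exp.loc[a, b] - target_fst.loc[a, b] for a, b in pairs])

    x0 = np.zeros(len(pops) + len(groups))
    sol = least_squares(resid, x0, method="lm", max_nfev=5000)
    return unpack(sol.x)


# ---------------------------------------------------------------------------
# configuration and truth records
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of one simulated study.

    Attributes
    ----------
    pop_names
        Population labels (K >= 2).
    sample_sizes
        Baseline diploid counts per population, same order as ``pop_names``.
    terminal_drift
        Per-population Balding-Nichols drift F in (0, 1) on the terminal
        branch of the two-level star tree.
    subgroups, shared_drift
        Designated subgroups sharing an internal branch, and that branch's
        drift.  Populations outside any subgroup attach directly to the root.
    n_background_loci, n_outlier_loci
        Locus counts; outlier loci get drift scaled by ``outlier_drift_scale``
        (scaled drift must stay below 1) and ``outlier_chrom_fraction`` of
        them (floor) are placed on ``hotspot_chrom``.
    maf_range
        Ancestral minor-allele-frequency interval, within (0, 0.5].
    mixing_matrix
        Row-stochastic DataFrame, rows = traditional labels, columns = true
        origins: P(true origin | traditional label) for assessment cohorts.
    n_assessment, assessment_label_counts
        Assessment cohort size; optional per-label counts (default: even
        split of ``n_assessment`` over ``pop_names``, remainder to the first
        labels).
    replicate_pairs
        Number of duplicated individuals appended to the assessment cohort.
    missing_rate, genotype_error_rate
        Degradation probabilities in [0, 1].
    """

    pop_names: list[str]
    sample_sizes: list[int]
    terminal_drift: dict[str, float]
    shared_drift: dict[str, float] = field(default_factory=dict)
    subgroups: dict[str, list[str]] = field(default_factory=dict)
    n_background_loci: int = 1000
    n_outlier_loci: int = 0
    outlier_drift_scale: float = 10.0
    outlier_chrom_fraction: float = 0.5
    hotspot_chrom: str = HERRING_HOTSPOT_CHROM
    n_chromosomes: int = HERRING_N_CHROMOSOMES
    maf_range: tuple[float, float] = (0.1, 0.5)
    mixing_matrix: pd.DataFrame | None = None
    n_assessment: int = 0
    assessment_label_counts: dict[str, int] | None = None
    replicate_pairs: int = 0
    missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        K = len(self.pop_names)
        if K < 2:
            raise ValueError("need at least 2 populations")
        if len(self.sample_sizes) != K:
            raise ValueError("sample_sizes must match pop_names")
        if any(n <= 0 for n in self.sample_sizes):
            raise ValueError("sample sizes must be strictly positive")
        if self.n_background_loci < 1 or self.n_outlier_loci < 0:
            raise ValueError("need n_background_loci >= 1 and n_outlier_loci >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        for p in self.pop_names:
            F = self.terminal_drift.get(p)
            if F is None or not (0.0 < F < 1.0):
                raise ValueError(f"terminal drift for {p} must be in (0,1), got {F}")
        for g, Fs in self.shared_drift.items():
            if not (0.0 <= Fs < 1.0):
                raise ValueError(f"shared drift for {g} must be in [0,1), got {Fs}")
        if self.n_outlier_loci > 0:
            if self.outlier_drift_scale <= 1.0:
                raise ValueError("outlier_drift_scale must be > 1")
            for p in self.pop_names:
                if self.terminal_drift[p] * self.outlier_drift_scale >= 1.0:
                    raise ValueError(
                        f"scaled outlier drift >= 1 for population {p}"
                    )
            for g, Fs in self.shared_drift.items():
                if Fs * self.outlier_drift_scale >= 1.0:
                    raise ValueError(f"scaled outlier drift >= 1 for subgroup {g}")
        if not (0.0 <= self.outlier_chrom_fraction <= 1.0):
            raise ValueError("outlier_chrom_fraction must be in [0,1]")
        for name, rate in (
            ("missing_rate", self.missing_rate),
            ("genotype_error_rate", self.genotype_error_rate),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        if self.mixing_matrix is not None:
            mm = self.mixing_matrix
            if (mm.values < -1e-12).any() or (mm.values > 1 + 1e-12).any():
                raise ValueError("mixing_matrix probabilities must be in [0,1]")
            rowsums = mm.sum(axis=1)
            if not np.allclose(rowsums, 1.0, atol=1e-9):
                raise ValueError("mixing_matrix rows must sum to 1 +/- 1e-9")
            unknown = set(mm.columns) - set(self.pop_names)
            if unknown:
                raise KeyError(f"mixing_matrix origins not in pop_names: {unknown}")
        if self.replicate_pairs < 0 or self.n_assessment < 0:
            raise ValueError("counts must be non-negative")
        if self.replicate_pairs > self.n_assessment and self.n_assessment > 0:
            raise ValueError("replicate_pairs cannot exceed n_assessment")


@dataclass
class CohortTruth:
    """Ground truth for one simulated cohort.

    ``samples``: DataFrame(sample_id, true_population, traditional_label,
    replicate_of);  ``loci``: DataFrame(locus_id, is_outlier);
    ``pop_freqs``: DataFrame of realised per-population ALT frequencies,
    index = locus_id, columns = population names.
    """

    samples: pd.DataFrame
    loci: pd.DataFrame
    pop_freqs: pd.DataFrame

    def validate(self) -> None:
        ids = set(self.samples["sample_id"])
        for tgt in self.samples["replicate_of"].dropna():
            if tgt not in ids:
                raise ValueError(f"replicate_of target {tgt!r} does not exist")
        vals = self.pop_freqs.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("allele frequencies outside [0,1]")

    def to_csv(self, path: str) -> None:
        self.samples.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def sample_ancestral_freqs(
    n_loci: int, maf_range: tuple[float, float], seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ancestral ALT frequencies uniformly on ``[lo, hi]``."""
    lo, hi = maf_range
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"invalid maf_range {maf_range}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.uniform(lo, hi, size=n_loci)


def _bn_draw(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Balding-Nichols frequency draw around ancestral p with drift F."""
    if F < 1e-9:
        return p.copy()
    ratio = (1.0 - F) / F
    return rng.beta(np.maximum(p * ratio, 1e-12), np.maximum((1.0 - p) * ratio, 1e-12))


def _locus_metadata(config: SimulationConfig, is_outlier: np.ndarray) -> pd.DataFrame:
    """Deterministic chromosome/position assignment.

    Background loci cycle over all chromosomes; ``floor(fraction * n_outlier)``
    outlier loci go to the hotspot chromosome, the rest cycle over the others.
    """
    chroms_all = [f"chr{i}" for i in range(1, config.n_chromosomes + 1)]
    others = [c for c in chroms_all if c != config.hotspot_chrom] or chroms_all
    n_out = int(is_outlier.sum())
    n_hot = int(np.floor(config.outlier_chrom_fraction * n_out))
    chrom = []
    bg_i = out_i = 0
    hot_assigned = 0
    for flag in is_outlier:
        if flag:
            if hot_assigned < n_hot:
                chrom.append(config.hotspot_chrom)
                hot_assigned += 1
            else:
                chrom.append(others[out_i % len(others)])
                out_i += 1
        else:
            chrom.append(chroms_all[bg_i % len(chroms_all)])
            bg_i += 1
    pos_counter: dict[str, int] = {}
    pos = []
    for c in chrom:
        pos_counter[c] = pos_counter.get(c, 0) + 1
        pos.append(pos_counter[c] * 1000)  # 1 kb spacing, deterministic
    df = pd.DataFrame(
        {
            "locus_id": [f"{c}:{p}" for c, p in zip(chrom, pos)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "qual": 60.0,
        }
    )
    return df[LOCUS_COLUMNS]


def simulate_baseline(config: SimulationConfig) -> tuple[GenotypeMatrix, CohortTruth]:
    """Simulate the baseline cohort under the two-level Balding-Nichols model.

    Returns the genotype matrix (``sum(sample_sizes)`` x
    ``n_background_loci + n_outlier_loci``) and the ground truth, including
    the realised per-population allele frequencies that
    :func:`simulate_assessment` reuses.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_background_loci + config.n_outlier_loci
    is_outlier = np.zeros(L, dtype=bool)
    is_outlier[config.n_background_loci:] = True

    p0 = sample_ancestral_freqs(L, config.maf_range, rng)
    group_of = {p: g for g, members in config.subgroups.items() for p in members}

    # shared-branch frequencies per subgroup, then terminal drift per population
    group_freqs: dict[str, np.ndarray] = {}
    for g, Fs in config.shared_drift.items():
        freqs = np.empty(L)
        for flag in (False, True):
            m = is_outlier == flag
            F = min(Fs * (config.outlier_drift_scale if flag else 1.0), 1 - 1e-9)
            freqs[m] = _bn_draw(rng, p0[m], F)
        group_freqs[g] = freqs

    pop_freqs = np.empty((len(config.pop_names), L))
    for i, pop in enumerate(config.pop_names):
        base = group_freqs.get(group_of.get(pop), p0)
        freqs = np.empty(L)
        for flag in (False, True):
            m = is_outlier == flag
            F = config.terminal_drift[pop] * (
                config.outlier_drift_scale if flag else 1.0
            )
            freqs[m] = _bn_draw(rng, base[m], F)
        pop_freqs[i] = freqs

    sample_ids = []
    true_pop = []
    blocks = []
    for i, (pop, n) in enumerate(zip(config.pop_names, config.sample_sizes)):
        blocks.append(rng.binomial(2, pop_freqs[i], size=(n, L)).astype(float))
        sample_ids += [f"{pop}-{j + 1:03d}" for j in range(n)]
        true_pop += [pop] * n
    dosages = np.vstack(blocks)

    loci = _locus_metadata(config, is_outlier)
    gm = GenotypeMatrix(sample_ids, loci, dosages)
    truth = CohortTruth(
        samples=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "true_population": true_pop,
                "traditional_label": true_pop,
                "replicate_of": pd.Series([pd.NA] * len(sample_ids), dtype=object),
            }
        ),
        loci=pd.DataFrame(
            {"locus_id": loci["locus_id"], "is_outlier": is_outlier}
        ),
        pop_freqs=pd.DataFrame(
            pop_freqs.T, index=loci["locus_id"], columns=config.pop_names
        ),
    )
    truth.validate()
    return gm, truth


def _assessment_label_counts(config: SimulationConfig) -> dict[str, int]:
    if config.assessment_label_counts is not None:
        return dict(config.assessment_label_counts)
    K = len(config.pop_names)
    base, rem = divmod(config.n_assessment, K)
    return {
        p: base + (1 if i < rem else 0) for i, p in enumerate(config.pop_names)
    }


def simulate_assessment(
    config: SimulationConfig, baseline_freqs: pd.DataFrame
) -> tuple[GenotypeMatrix, CohortTruth]:
    """Simulate an assessment cohort with (possibly wrong) traditional labels.

    Each individual carries a traditional label drawn from the configured
    label margins; its true origin is drawn from the ``mixing_matrix`` row
    for that label and its genotypes from the origin's realised baseline
    frequencies.  ``replicate_pairs`` individuals are duplicated (suffix
    ``-rep``) with genotypes identical before any degradation.
    """
    mm = config.mixing_matrix
    if mm is None:
        mm = pd.DataFrame(
            np.eye(len(config.pop_names)),
            index=config.pop_names,
            columns=config.pop_names,
        )
    for origin in mm.columns:
        if origin not in baseline_freqs.columns:
            raise KeyError(f"no baseline frequencies for population {origin!r}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    label_counts = _assessment_label_counts(config)
    L = len(baseline_freqs)

    sample_ids, labels, origins = [], [], []
    rows = []
    i = 0
    for label, count in label_counts.items():
        if label not in mm.index:
            raise KeyError(f"traditional label {label!r} not in mixing_matrix")
        probs = mm.loc[label].to_numpy(dtype=float)
        for _ in range(count):
            i += 1
            origin = mm.columns[rng.choice(len(probs), p=probs)]
            freqs = baseline_freqs[origin].to_numpy()
            rows.append(rng.binomial(2, freqs).astype(float))
            sample_ids.append(f"AS-{i:04d}")
            labels.append(label)
            origins.append(origin)

    replicate_of = [pd.NA] * len(sample_ids)
    if config.replicate_pairs:
        chosen = rng.choice(len(sample_ids), size=config.replicate_pairs, replace=False)
        for j in sorted(chosen):
            rows.append(rows[j].copy())
            sample_ids.append(f"{sample_ids[j]}-rep")
            labels.append(labels[j])
            origins.append(origins[j])
            replicate_of.append(sample_ids[j])

    loci = pd.DataFrame(
        {
            "locus_id": baseline_freqs.index,
            "chrom": [lid.split(":")[0] for lid in baseline_freqs.index],
            "pos": [int(lid.split(":")[1]) for lid in baseline_freqs.index],
            "ref": "A",
            "alt": "G",
            "qual": 60.0,
        }
    )[LOCUS_COLUMNS]
    gm = GenotypeMatrix(sample_ids, loci, np.vstack(rows))
    truth = CohortTruth(
        samples=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "true_population": origins,
                "traditional_label": labels,
                "replicate_of": pd.Series(replicate_of, dtype=object),
            }
        ),
        loci=pd.DataFrame(
            {"locus_id": loci["locus_id"], "is_outlier": False}
        ),
        pop_freqs=baseline_freqs.copy(),
    )
    truth.validate()
    return gm, truth


def degrade_genotypes(
    matrix: GenotypeMatrix,
    missing_rate: float,
    genotype_error_rate: float,
    seed: int | np.random.Generator,
) -> GenotypeMatrix:
    """Apply genotyping dropout and symmetric genotype errors.

    Each call is independently set missing with ``missing_rate``; each
    surviving call is moved to one of the other two dosages (equal
    probability) with ``genotype_error_rate``.  The input is not modified.
    """
    for name, rate in (("missing_rate", missing_rate), ("genotype_error_rate", genotype_error_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must be in [0,1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = matrix.copy()
    d = out.dosages
    obs = ~np.isnan(d)
    drop = obs & (rng.random(d.shape) < missing_rate)
    d[drop] = MISSING
    survive = obs & ~drop
    err = survive & (rng.random(d.shape) < genotype_error_rate)
    if err.any():
        # symmetric move: +1 or +2 mod 3 with equal probability
        shift = rng.integers(1, 3, size=int(err.sum()))
        d[err] = np.mod(d[err] + shift, 3)
    return out


# ---------------------------------------------------------------------------
# canned herring-study configurations
# ---------------------------------------------------------------------------


def herring_panel_config(
    seed: int = 0,
    n_loci: int = HERRING_PANEL_SIZE,
    sample_sizes: dict[str, int] | None = None,
) -> SimulationConfig:
    """Four-stock configuration matched to the published panel-scale F_ST matrix.

    Drifts are least-squares fitted (FASH+ISSH sharing a branch) so expected
    pairwise theta reproduces the published SNP-panel values; all loci are
    panel-like (no separate background class).
    """
    term, shared = fit_drift_two_level(HERRING_PANEL_FST, HERRING_SUBGROUPS)
    sizes = dict(sample_sizes or HERRING_BASELINE_SIZES)
    return SimulationConfig(
        pop_names=HERRING_POPS,
        sample_sizes=[sizes[p] for p in HERRING_POPS],
        terminal_drift=term,
        shared_drift=shared,
        subgroups=HERRING_SUBGROUPS,
        n_background_loci=n_loci,
        n_outlier_loci=0,
        maf_range=(0.1, 0.5),
        seed=seed,
    )


def herring_genome_config(
    seed: int = 0,
    n_background_loci: int = 4000,
    n_outlier_loci: int = 400,
    outlier_drift_scale: float = 100.0,
    n_assessment: int = HERRING_ASSESSMENT_SIZE,
    replicate_pairs: int = HERRING_REPLICATE_PAIRS,
    missing_rate: float = 0.02,
    genotype_error_rate: float = 0.005,
) -> SimulationConfig:
    """Genome-like configuration: low background divergence plus outlier hotspots.

    Background drifts are fitted to the published genome-wide pairwise F_ST
    (0.0007-0.0046); outlier loci carry ``outlier_drift_scale`` times that
    drift, with half of them on the hotspot chromosome.  The assessment
    mixing scenario plants the reported qualitative pattern: one third of the
    FASH-labelled individuals originate from ISSH and one third from NSAH,
    and a fifth of ISSH-labelled individuals originate from FASH.
    """
    term, shared = fit_drift_two_level(HERRING_GENOME_FST, HERRING_SUBGROUPS)
    mixing = pd.DataFrame(
        np.eye(4), index=HERRING_POPS, columns=HERRING_POPS
    )
    mixing.loc["FASH"] = [0.34, 0.33, 0.33, 0.0]
    mixing.loc["ISSH"] = [0.20, 0.80, 0.0, 0.0]
    return SimulationConfig(
        pop_names=HERRING_POPS,
        sample_sizes=[HERRING_BASELINE_SIZES[p] for p in HERRING_POPS],
        terminal_drift=term,
        shared_drift=shared,
        subgroups=HERRING_SUBGROUPS,
        n_background_loci=n_background_loci,
        n_outlier_loci=n_outlier_loci,
        outlier_drift_scale=outlier_drift_scale,
        outlier_chrom_fraction=0.5,
        mixing_matrix=mixing,
        n_assessment=n_assessment,
        replicate_pairs=replicate_pairs,
        missing_rate=missing_rate,
        genotype_error_rate=genotype_error_rate,
        seed=0,
    )


# ---------------------------------------------------------------------------
# YAML config round-trip (CLI)
# ---------------------------------------------------------------------------


def config_from_yaml(path: str) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "mixing_matrix" in raw and raw["mixing_matrix"] is not None:
        mm = raw["mixing_matrix"]
        raw["mixing_matrix"] = pd.DataFrame(
            [mm["rows"][lbl] for lbl in mm["labels"]],
            index=mm["labels"],
            columns=mm["origins"],
        )
    if "maf_range" in raw:
        raw["maf_range"] = tuple(raw["maf_range"])
    return SimulationConfig(**raw)


def config_to_yaml(config: SimulationConfig, path: str) -> None:
    import yaml

    raw = {
        "pop_names": list(config.pop_names),
        "sample_sizes": [int(n) for n in config.sample_sizes],
        "terminal_drift": {k: float(v) for k, v in config.terminal_drift.items()},
        "shared_drift": {k: float(v) for k, v in config.shared_drift.items()},
        "subgroups": {k: list(v) for k, v in config.subgroups.items()},
        "n_background_loci": config.n_background_loci,
        "n_outlier_loci": config.n_outlier_loci,
        "outlier_drift_scale": config.outlier_drift_scale,
        "outlier_chrom_fraction": config.outlier_chrom_fraction,
        "hotspot_chrom": config.hotspot_chrom,
        "n_chromosomes": config.n_chromosomes,
        "maf_range": [float(x) for x in config.maf_range],
        "n_assessment": config.n_assessment,
        "replicate_pairs": config.replicate_pairs,
        "missing_rate": config.missing_rate,
        "genotype_error_rate": config.genotype_error_rate,
        "seed": config.seed,
    }
    if config.mixing_matrix is not None:
        mm = config.mixing_matrix
        raw["mixing_matrix"] = {
            "labels": list(mm.index),
            "origins": list(mm.columns),
            "rows": {lbl: [float(x) for x in mm.loc[lbl]] for lbl in mm.index},
        }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
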