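"""Individual assignment to baseline populations.

Three independent engines and an all-agree consensus rule:

* ``BAYES`` — the Rannala-Mountain Bayesian predictive assignment: for each
  candidate population the probability of the query genotype is the
  Dirichlet-multinomial predictive given the baseline allele counts (prior
  alpha = 1/J per allele, J = 2 for SNPs), with alleles drawn sequentially
  (counts updating between the two draws) and a factor 2 for heterozygotes.
  Supports leave-one-out scoring of baseline members.
* ``DAPC`` — PCA on the baseline (mean-imputed, centred) followed by linear
  discriminant analysis with shared within-class covariance on the retained
  PCs; queries are projected with the baseline's imputation means and
  rotations and scored with Gaussian posteriors.
* ``MCCV`` — the same PCA+LDA classifier retrained on Monte-Carlo resamples
  of the baseline, with a majority vote over resamples (posterior scores =
  vote fractions).

An individual is "assigned" only when all three engines agree; otherwise it
is UNASSIGNED.  Exactly equal posteriors are resolved towards the
lexicographically smallest population name (deterministic, logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .fst import _pop_indices
from .matrix import GenotypeMatrix
from .structure import pca_genotypes

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"
METHODS = ("BAYES", "DAPC", "MCCV")


# ---------------------------------------------------------------------------
# baseline model
# ---------------------------------------------------------------------------


@dataclass
class BaselineModel:
    """Reference allele counts (and sample bookkeeping) per population.

    ``alt_counts``/``tot_counts``: K x L arrays of ALT allele counts and
    total non-missing allele counts (2 x genotyped individuals).
    """

    populations: list[str]
    locus_ids: list[str]
    alt_counts: np.ndarray
    tot_counts: np.ndarray
    samples_by_pop: dict[str, list[str]]

    @classmethod
    def from_matrix(
        cls, matrix: GenotypeMatrix, pop_map: dict[str, str]
    ) -> "BaselineModel":
        groups = _pop_indices(matrix, pop_map)
        pops = sorted(groups)
        alt = np.zeros((len(pops), matrix.n_loci))
        tot = np.zeros_like(alt)
        for i, p in enumerate(pops):
            block = matrix.dosages[groups[p]]
            alt[i] = np.nansum(block, axis=0)
            tot[i] = 2.0 * (~np.isnan(block)).sum(axis=0)
        if (alt > tot).any():
            raise ValueError("ALT count exceeds total allele count")
        return cls(
            populations=pops,
            locus_ids=matrix.locus_ids,
            alt_counts=alt,
            tot_counts=tot,
            samples_by_pop={
                p: [matrix.sample_ids[i] for i in groups[p]] for p in pops
            },
        )


def _argmax_label(scores: dict[str, float]) -> str:
    """Largest score; exact ties resolved by lexicographic population order."""
    best = max(scores.values())
    tied = sorted(p for p, s in scores.items() if s == best)
    if len(tied) > 1:
        logger.info("posterior tie between %s; choosing %s", tied, tied[0])
    return tied[0]


def _records_frame(
    sample_ids: list[str], method: str, pops: list[str], post: np.ndarray
) -> pd.DataFrame:
    df = pd.DataFrame(post, columns=pops)
    df.insert(0, "sample_id", sample_ids)
    df.insert(1, "method", method)
    df["label"] = [
        _argmax_label({p: row[p] for p in pops}) for _, row in df.iterrows()
    ]
    return df


# ---------------------------------------------------------------------------
# engine 1: Rannala-Mountain Bayesian predictive
# ---------------------------------------------------------------------------


def _rm_log_predictive(
    g: np.ndarray, alt: np.ndarray, tot: np.ndarray, alpha: float
) -> np.ndarray:
    """Per-locus log predictive probability of dosage g given counts (alt, tot).

    Sequential allele draws with count updating:
      P(g=2) = (x+a)(x+1+a) / ((n+2a)(n+1+2a))
      P(g=0) = (y+a)(y+1+a) / ((n+2a)(n+1+2a))      y = n - x
      P(g=1) = 2 (x+a)(y+a) / ((n+2a)(n+1+2a))
    which is exactly the Dirichlet(a, a)-multinomial marginal of the genotype.
    NaN where g is missing (caller must skip).
    """
    x, n = alt, tot
    y = n - x
    denom = (n + 2 * alpha) * (n + 1 + 2 * alpha)
    p2 = (x + alpha) * (x + 1 + alpha) / denom
    p0 = (y + alpha) * (y + 1 + alpha) / denom
    p1 = 2.0 * (x + alpha) * (y + alpha) / denom
    out = np.where(g == 2.0, p2, np.where(g == 1.0, p1, p0))
    out = np.where(np.isnan(g), np.nan, out)
    return np.log(out)


def rm_bayes_assign(
    baseline: BaselineModel,
    queries: GenotypeMatrix,
    leave_one_out: bool = False,
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Rannala-Mountain Bayesian assignment of query individuals.

    Posterior over populations is proportional to the multilocus predictive
    likelihood (product over non-missing loci) with a uniform population
    prior.  With ``leave_one_out``, a query that is a baseline member has its
    own alleles removed from its population's counts before scoring.  Query
    loci absent from the baseline are skipped with a warning.
    """
    pos = {lid: j for j, lid in enumerate(baseline.locus_ids)}
    shared = [lid for lid in queries.locus_ids if lid in pos]
    absent = [lid for lid in queries.locus_ids if lid not in pos]
    if absent:
        warnings.warn(
            f"{len(absent)} query locus/loci absent from baseline; skipped",
            stacklevel=2,
        )
    qsub = queries.subset_loci(shared)
    bidx = np.array([pos[lid] for lid in shared], dtype=int)
    alt = baseline.alt_counts[:, bidx]
    tot = baseline.tot_counts[:, bidx]
    member_of = {
        s: p for p, ss in baseline.samples_by_pop.items() for s in ss
    }

    K = len(baseline.populations)
    post = np.zeros((qsub.n_samples, K))
    for i, sid in enumerate(qsub.sample_ids):
        g = qsub.dosages[i]
        logl = np.zeros(K)
        for k, popname in enumerate(baseline.populations):
            a_k, t_k = alt[k], tot[k]
            if leave_one_out and member_of.get(sid) == popname:
                obs = ~np.isnan(g)
                a_k = a_k.copy()
                t_k = t_k.copy()
                a_k[obs] -= g[obs]
                t_k[obs] -= 2.0
                if (a_k < -1e-9).any() or (t_k < -1e-9).any():
                    raise ValueError(
                        f"leave-one-out removed more alleles than present for {sid}"
                    )
            lp = _rm_log_predictive(g, a_k, t_k, alpha)
            logl[k] = np.nansum(lp)
        logl -= logl.max()
        w = np.exp(logl)
        post[i] = w / w.sum()
    return _records_frame(qsub.sample_ids, "BAYES", baseline.populations, post)


# ---------------------------------------------------------------------------
# engine 2: DAPC (PCA + LDA)
# ---------------------------------------------------------------------------


@dataclass
class DapcModel:
    populations: list[str]
    locus_ids: list[str]
    kept_loci: np.ndarray
    locus_means: np.ndarray
    loadings: np.ndarray
    lda: LinearDiscriminantAnalysis
    n_pcs: int

    @property
    def n_discriminant_axes(self) -> int:
        return min(self.n_pcs, len(self.populations) - 1)

    def project(self, queries: GenotypeMatrix) -> np.ndarray:
        order = {lid: j for j, lid in enumerate(queries.loci["locus_id"])}
        try:
            idx = np.array([order[lid] for lid in self.locus_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"query lacks baseline locus {e.args[0]!r}") from None
        X = queries.dosages[:, idx][:, self.kept_loci].copy()
        ix = np.where(np.isnan(X))
        X[ix] = self.locus_means[ix[1]]
        return (X - self.locus_means) @ self.loadings

    def predict_proba(self, queries: GenotypeMatrix) -> np.ndarray:
        return self.lda.predict_proba(self.project(queries))


def dapc_fit(
    baseline_matrix: GenotypeMatrix,
    baseline_labels: dict[str, str],
    n_pcs: int = 10,
) -> DapcModel:
    """Fit the PCA + shared-covariance LDA classifier on the baseline."""
    pops = sorted(set(baseline_labels[s] for s in baseline_matrix.sample_ids))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    pca = pca_genotypes(baseline_matrix, n_axes=n_pcs)
    y = np.array([baseline_labels[s] for s in baseline_matrix.sample_ids])
    lda = LinearDiscriminantAnalysis(solver="svd")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            lda.fit(pca.scores, y)
        except np.linalg.LinAlgError:
            logger.warning("singular within-class covariance; ridge applied")
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-3)
            lda.fit(pca.scores, y)
    return DapcModel(
        populations=pops,
        locus_ids=baseline_matrix.locus_ids,
        kept_loci=pca.kept_loci,
        locus_means=pca.locus_means,
        loadings=pca.loadings,
        lda=lda,
        n_pcs=pca.scores.shape[1],
    )


def dapc_fit_assign(
    baseline_matrix: GenotypeMatrix,
    baseline_labels: dict[str, str],
    queries: GenotypeMatrix,
    n_pcs: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit DAPC on the baseline and assign the query individuals."""
    model = dapc_fit(baseline_matrix, baseline_labels, n_pcs=n_pcs)
    post = model.predict_proba(queries)
    cols = list(model.lda.classes_)
    post = post[:, [cols.index(p) for p in model.populations]]
    return _records_frame(queries.sample_ids, "DAPC", model.populations, post)


# ---------------------------------------------------------------------------
# engine 3: Monte-Carlo resampled classifier (assignPOP-style)
# ---------------------------------------------------------------------------


def mccv_assign(
    baseline_matrix: GenotypeMatrix,
    baseline_labels: dict[str, str],
    queries: GenotypeMatrix,
    train_frac: float = 0.5,
    n_resamples: int = 30,
    n_pcs: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Majority vote over PCA+LDA classifiers trained on baseline resamples.

    Each resample is a stratified ``train_frac`` subsample of the baseline;
    reported scores are the vote fractions across resamples.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0,1)")
    rng = np.random.default_rng(seed)
    pops = sorted(set(baseline_labels[s] for s in baseline_matrix.sample_ids))
    votes = np.zeros((queries.n_samples, len(pops)))
    pop_i = {p: i for i, p in enumerate(pops)}
    for _ in range(n_resamples):
        train_ids = _stratified_subset(
            baseline_matrix.sample_ids, baseline_labels, train_frac, rng
        )
        model = dapc_fit(
            baseline_matrix.subset_samples(train_ids), baseline_labels, n_pcs=n_pcs
        )
        post = model.predict_proba(queries)
        cols = list(model.lda.classes_)
        for i in range(queries.n_samples):
            scores = {p: post[i, cols.index(p)] for p in model.populations}
            votes[i, pop_i[_argmax_label(scores)]] += 1
    return _records_frame(
        queries.sample_ids, "MCCV", pops, votes / n_resamples
    )


def _stratified_subset(
    sample_ids: list[str],
    labels: dict[str, str],
    frac: float,
    rng: np.random.Generator,
) -> list[str]:
    """Per-population random subsample keeping at least one sample per pop.

    One global permutation of sample positions drives the draw, so the
    result is invariant under renaming populations (label-permutation
    equivariance of the downstream engines).
    """
    quota: dict[str, int] = {}
    for s in sample_ids:
        quota[labels[s]] = quota.get(labels[s], 0) + 1
    quota = {p: max(1, int(round(frac * n))) for p, n in quota.items()}
    chosen: list[str] = []
    taken: dict[str, int] = {}
    for i in rng.permutation(len(sample_ids)):
        s = sample_ids[i]
        p = labels[s]
        if taken.get(p, 0) < quota[p]:
            taken[p] = taken.get(p, 0) + 1
            chosen.append(s)
    return chosen


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation self-assignment
# ---------------------------------------------------------------------------


@dataclass
class SelfAssignMatrix:
    """Mean +/- sd assignment proportions, true population x assigned."""

    mean: pd.DataFrame
    sd: pd.DataFrame
    per_iteration: list[pd.DataFrame]

    def validate(self) -> None:
        if not np.allclose(self.mean.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("mean rows must sum to 1")
        if (self.sd.to_numpy() < 0).any():
            raise ValueError("sd must be non-negative")


def mc_cv_self_assignment(
    baseline_matrix: GenotypeMatrix,
    labels: dict[str, str],
    train_frac: float = 0.5,
    iterations: int = 90,
    n_pcs: int = 10,
    seed: int = 0,
) -> SelfAssignMatrix:
    """Monte-Carlo cross-validation self-assignment of the baseline.

    Per iteration: stratified random split at ``train_frac``; the DAPC
    engine is trained on the training half and assigns the held-out
    individuals; rows of the resulting confusion matrix (true population x
    assigned population) are normalised and averaged over iterations.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0,1)")
    pops = sorted(set(labels[s] for s in baseline_matrix.sample_ids))
    counts = pd.Series([labels[s] for s in baseline_matrix.sample_ids]).value_counts()
    if len(pops) == 1:
        one = pd.DataFrame([[1.0]], index=pops, columns=pops)
        return SelfAssignMatrix(mean=one, sd=one * 0.0, per_iteration=[one])
    if (counts < 2).any():
        raise ValueError("every population must contribute >= 2 samples")
    rng = np.random.default_rng(seed)
    mats = []
    for _ in range(iterations):
        for _attempt in range(100):
            train_ids = set(
                _stratified_subset(baseline_matrix.sample_ids, labels, train_frac, rng)
            )
            test_ids = [s for s in baseline_matrix.sample_ids if s not in train_ids]
            if set(labels[s] for s in train_ids) == set(pops) and test_ids:
                break
            logger.info("degenerate split; resampling")
        model = dapc_fit(
            baseline_matrix.subset_samples(sorted(train_ids)), labels, n_pcs=n_pcs
        )
        test = baseline_matrix.subset_samples(test_ids)
        post = model.predict_proba(test)
        cols = list(model.lda.classes_)
        conf = pd.DataFrame(0.0, index=pops, columns=pops)
        for i, sid in enumerate(test_ids):
            scores = {p: post[i, cols.index(p)] for p in model.populations}
            conf.loc[labels[sid], _argmax_label(scores)] += 1
        rowsum = conf.sum(axis=1)
        conf = conf.div(rowsum.where(rowsum > 0, 1.0), axis=0)
        # a population fully in training contributes its long-run identity row
        for p in pops:
            if rowsum[p] == 0:
                conf.loc[p, p] = 1.0
        mats.append(conf)
    stack = np.stack([m.to_numpy() for m in mats])
    mean = pd.DataFrame(stack.mean(axis=0), index=pops, columns=pops)
    sd = pd.DataFrame(stack.std(axis=0, ddof=1), index=pops, columns=pops)
    out = SelfAssignMatrix(mean=mean, sd=sd, per_iteration=mats)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def consensus_assign(records: pd.DataFrame) -> pd.DataFrame:
    """All-agree consensus over the three per-method assignment records.

    ``records`` is the concatenation of the three engines' outputs.  Every
    sample must have exactly one record per method; the consensus label is
    the shared argmax when all three agree, else UNASSIGNED.
    """
    wide = {}
    for method in METHODS:
        sub = records[records["method"] == method]
        dup = sub["sample_id"].duplicated()
        if dup.any():
            raise ValueError(f"duplicate {method} records for {sub['sample_id'][dup].tolist()[:3]}")
        wide[method] = dict(zip(sub["sample_id"], sub["label"]))
    samples = sorted(
        set(records["sample_id"]), key=list(records["sample_id"]).index
    )
    rows = []
    for sid in samples:
        labels = {}
        for method in METHODS:
            if sid not in wide[method]:
                raise ValueError(f"sample {sid!r} lacks a {method} record")
            labels[method.lower()] = wide[method][sid]
        vals = set(labels.values())
        rows.append(
            {
                "sample_id": sid,
                **labels,
                "consensus": labels["bayes"] if len(vals) == 1 else UNASSIGNED,
            }
        )
    return pd.DataFrame(rows)


def assign_all_methods(
    baseline_matrix: GenotypeMatrix,
    baseline_labels: dict[str, str],
    queries: GenotypeMatrix,
    n_pcs: int = 10,
    mccv_resamples: int = 30,
    mccv_train_frac: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all three engines and the consensus rule; returns (records, consensus)."""
    baseline = BaselineModel.from_matrix(baseline_matrix, baseline_labels)
    recs = pd.concat(
        [
            rm_bayes_assign(baseline, queries),
            dapc_fit_assign(
                baseline_matrix, baseline_labels, queries, n_pcs=n_pcs, seed=seed
            ),
            mccv_assign(
                baseline_matrix,
                baseline_labels,
                queries,
                train_frac=mccv_train_frac,
                n_resamples=mccv_resamples,
                n_pcs=n_pcs,
                seed=seed + 1,
            ),
        ],
        ignore_index=True,
    )
    return recs, consensus_assign(recs)
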