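"""Model selection by clustering stability and multi-model consensus.

The number of patterns M is chosen by repeated holdout cross-validation:
for each candidate M, several models are trained on random 80% subsamples
of the discovery set, every model labels the full patient set, and the
mean pairwise adjusted Rand index (ARI) across the fold labelings measures
how reproducible an M-pattern solution is. The M with the highest mean
pairwise ARI wins (ties to the smaller M).

The final probabilities come from a consensus of (by default) 30
independently seeded models: the model whose hard labeling agrees best
with the others is the template, every other model's pattern columns are
permuted to maximally overlap the template's labeling (optimal assignment
on the M×M contingency table), and the aligned probability matrices are
averaged — the mean of simplex points is again on the simplex.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from . import gan
from .io import ROITable, concat

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# adjusted Rand index and label matching
# ---------------------------------------------------------------------------

def adjusted_rand_index(a, b) -> float:
    """Chance-corrected partition agreement from the contingency table.

    1 for identical partitions up to relabeling; expectation 0 for two
    independent random partitions; both-single-cluster degenerate case is 1.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings have different lengths")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))


def match_labels(template, other, M: int) -> np.ndarray:
    """Permutation sigma (length M) relabeling ``other`` onto ``template``.

    sigma[k] is the template-side label for other-label k, chosen to
    maximize the total contingency overlap. For M <= 8 all M! permutations
    are enumerated so ties break to the lexicographically smallest
    permutation; beyond that the Hungarian assignment is used.
    Labels must lie in 0..M-1.
    """
    template = np.asarray(template)
    other = np.asarray(other)
    if template.shape != other.shape:
        raise ValueError("labelings have different lengths")
    C = np.zeros((M, M), dtype=int)  # C[t, o] = count(template==t & other==o)
    np.add.at(C, (template, other), 1)
    if M <= 8:
        best_perm, best_score = None, -1
        for perm in itertools.permutations(range(M)):
            score = sum(C[perm[k], k] for k in range(M))
            if score > best_score:
                best_perm, best_score = perm, score
        return np.asarray(best_perm, dtype=int)
    rows, cols = linear_sum_assignment(-C)
    sigma = np.empty(M, dtype=int)
    sigma[cols] = rows
    return sigma


def apply_permutation_to_labels(labels, sigma: np.ndarray) -> np.ndarray:
    return np.asarray(sigma)[np.asarray(labels)]


def apply_permutation_to_probs(probs: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Move each pattern column k to position sigma[k]."""
    out = np.empty_like(probs)
    out[:, np.asarray(sigma)] = probs
    return out


# ---------------------------------------------------------------------------
# holdout stability and M selection
# ---------------------------------------------------------------------------

@dataclass
class StabilityEntry:
    """Stability of one candidate M over repeated holdout folds."""

    M: int
    labelings: list  # per fold: labels of ALL discovery PT rows, or None if failed
    pairwise_ari: list[float]
    mean_ari: float
    sd_ari: float
    n_failed: int


@dataclass
class StabilityReport:
    entries: dict[int, StabilityEntry] = field(default_factory=dict)
    chosen_M: int | None = None

    def summary(self) -> str:
        lines = ["  M   mean ARI     SD   folds failed"]
        for M, e in sorted(self.entries.items()):
            mark = " *" if M == self.chosen_M else ""
            lines.append(f"  {M}   {e.mean_ari:8.3f} {e.sd_ari:6.3f}   {e.n_failed}{mark}")
        return "\n".join(lines)


def holdout_stability(
    pt: ROITable,
    cn: ROITable,
    M: int,
    folds: int = 10,
    holdout_frac: float = 0.2,
    hp: gan.HyperParams | None = None,
    rng: np.random.Generator | None = None,
    train_fn=gan.train,
) -> StabilityEntry:
    """Train one model per fold on a random (1 − holdout_frac) subsample of
    the discovery set (CN and patient rows dropped jointly, without
    stratification), label ALL discovery patient rows with each fold's
    model, and report all pairwise ARIs among the fold labelings.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = rng if rng is not None else np.random.default_rng(0)
    hp = hp or gan.HyperParams()
    hp = gan.replace_hp(hp, M=M)
    n_cn, n_pt = len(cn), len(pt)
    n_total = n_cn + n_pt
    n_keep = int(round((1.0 - holdout_frac) * n_total))

    labelings: list = []
    for fold in range(folds):
        keep = rng.permutation(n_total)[:n_keep]
        cn_keep = keep[keep < n_cn]
        pt_keep = keep[keep >= n_cn] - n_cn
        fold_seed = int(rng.integers(0, 2**31 - 1))
        try:
            model = train_fn(cn.subset(cn_keep), pt.subset(pt_keep), gan.replace_hp(hp, seed=fold_seed))
            labels = gan.predict_probabilities(model, pt).argmax_labels()
        except gan.ModelCollapseError:
            logger.warning("fold %d collapsed for M=%d; recorded as missing", fold, M)
            labels = None
        labelings.append(labels)

    ok = [l for l in labelings if l is not None]
    pairs = [
        adjusted_rand_index(ok[i], ok[j])
        for i in range(len(ok))
        for j in range(i + 1, len(ok))
    ]
    mean = float(np.mean(pairs)) if pairs else float("nan")
    sd = float(np.std(pairs, ddof=1)) if len(pairs) > 1 else float("nan")
    return StabilityEntry(
        M=M,
        labelings=labelings,
        pairwise_ari=pairs,
        mean_ari=mean,
        sd_ari=sd,
        n_failed=len(labelings) - len(ok),
    )


def select_M(
    pt: ROITable,
    cn: ROITable,
    M_range,
    folds: int = 10,
    holdout_frac: float = 0.2,
    hp: gan.HyperParams | None = None,
    rng: np.random.Generator | None = None,
    train_fn=gan.train,
) -> tuple[int, StabilityReport]:
    """Pick the M with the highest mean pairwise ARI; ties go to smaller M."""
    M_range = list(M_range)
    if not M_range:
        raise ValueError("M_range is empty")
    rng = rng if rng is not None else np.random.default_rng(0)
    report = StabilityReport()
    for M in M_range:
        report.entries[M] = holdout_stability(
            pt, cn, M, folds=folds, holdout_frac=holdout_frac, hp=hp, rng=rng, train_fn=train_fn
        )
    usable = {M: e.mean_ari for M, e in report.entries.items() if np.isfinite(e.mean_ari)}
    if not usable:
        raise RuntimeError("stability could not be computed for any M")
    best = max(usable.values())
    chosen = min(M for M, v in usable.items() if v >= best - 1e-12)
    report.chosen_M = chosen
    return chosen, report


# ---------------------------------------------------------------------------
# consensus over repeated runs
# ---------------------------------------------------------------------------

@dataclass
class ConsensusEnsemble:
    """Aligned ensemble of independently trained models.

    The template's permutation is the identity; every other model's pattern
    columns are permuted onto the template before averaging.
    """

    models: list[gan.TrainedModel]
    template_index: int
    permutations: list[np.ndarray]
    consensus: gan.ProbabilityMatrix  # averaged probabilities on the reference cohort

    @property
    def M(self) -> int:
        return self.models[0].M

    def predict(self, rows) -> gan.ProbabilityMatrix:
        """Aligned average probability for new rows."""
        acc = None
        for model, sigma in zip(self.models, self.permutations):
            p = apply_permutation_to_probs(gan.predict_probabilities(model, rows).probs, sigma)
            acc = p if acc is None else acc + p
        return gan.ProbabilityMatrix(acc / len(self.models), provenance="consensus")


def build_consensus(models: list[gan.TrainedModel], reference_pt: ROITable) -> ConsensusEnsemble:
    """Align models to the most-agreeing template and average probabilities."""
    if not models:
        raise ValueError("no models given")
    M = models[0].M
    if any(m.M != M for m in models):
        raise ValueError("models disagree on M")
    names = models[0].roi_names
    if any(m.roi_names != names for m in models):
        raise ValueError("models disagree on ROI names")

    prob_list = [gan.predict_probabilities(m, reference_pt).probs for m in models]
    label_list = [np.argmax(p, axis=1) for p in prob_list]

    n = len(models)
    if n == 1:
        template = 0
    else:
        mean_ari = np.zeros(n)
        for i in range(n):
            mean_ari[i] = np.mean(
                [adjusted_rand_index(label_list[i], label_list[j]) for j in range(n) if j != i]
            )
        template = int(np.argmax(mean_ari))

    sigmas = [match_labels(label_list[template], lab, M) for lab in label_list]
    aligned = [apply_permutation_to_probs(p, s) for p, s in zip(prob_list, sigmas)]
    consensus = gan.ProbabilityMatrix(np.mean(aligned, axis=0), provenance="consensus")
    return ConsensusEnsemble(
        models=models, template_index=template, permutations=sigmas, consensus=consensus
    )


def jackknife_consensus_shift(ensemble: ConsensusEnsemble, reference_pt: ROITable) -> float:
    """Stability diagnostic: rebuild the consensus without the template.

    Returns the maximum absolute change in any consensus probability when
    the template model is removed and the alignment is redone. A large
    shift means the consensus leans heavily on a single model. Logged at
    INFO level.
    """
    if len(ensemble.models) < 2:
        raise ValueError("need at least 2 models to jackknife")
    rest = [m for i, m in enumerate(ensemble.models) if i != ensemble.template_index]
    rebuilt = build_consensus(rest, reference_pt)
    # align the rebuilt consensus onto the original before comparing
    sigma = match_labels(
        ensemble.consensus.argmax_labels(), rebuilt.consensus.argmax_labels(), ensemble.M
    )
    shift = float(
        np.abs(
            apply_permutation_to_probs(rebuilt.consensus.probs, sigma)
            - ensemble.consensus.probs
        ).max()
    )
    logger.info("jackknife-over-models consensus shift: %.4f", shift)
    return shift


def train_ensemble(
    cn: ROITable,
    pt: ROITable,
    hp: gan.HyperParams | None = None,
    n_models: int = 30,
    base_seed: int | None = None,
) -> ConsensusEnsemble:
    """Train ``n_models`` models with seeds base..base+n−1 and build the consensus."""
    hp = hp or gan.HyperParams()
    base = hp.seed if base_seed is None else base_seed
    models = [gan.train(cn, pt, gan.replace_hp(hp, seed=base + i)) for i in range(n_models)]
    return build_consensus(models, pt)


# ---------------------------------------------------------------------------
# permutation reproducibility test (reconstructed protocol)
# ---------------------------------------------------------------------------

def permutation_reproducibility_test(
    pt: ROITable,
    cn: ROITable,
    M: int,
    n_permutations: int = 19,
    folds: int = 10,
    holdout_frac: float = 0.2,
    hp: gan.HyperParams | None = None,
    rng: np.random.Generator | None = None,
    train_fn=gan.train,
) -> tuple[float, float, np.ndarray]:
    """Permutation test of clustering stability (reconstructed protocol).

    The observed statistic is the mean pairwise holdout ARI. The null is
    built by randomly reassigning the CN/patient group labels (group sizes
    preserved) and recomputing the statistic; p = (1 + #null >= obs) /
    (1 + n_permutations). The protocol is this package's reconstruction of
    a stability-significance check; returns (p, observed, null draws).
    """
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations")
    rng = rng if rng is not None else np.random.default_rng(0)
    observed = holdout_stability(
        pt, cn, M, folds=folds, holdout_frac=holdout_frac, hp=hp, rng=rng, train_fn=train_fn
    ).mean_ari

    pooled = concat([cn, pt])
    n_cn = len(cn)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(len(pooled))
        cn_b = pooled.subset(perm[:n_cn])
        pt_b = pooled.subset(perm[n_cn:])
        null[b] = holdout_stability(
            pt_b, cn_b, M, folds=folds, holdout_frac=holdout_frac, hp=hp, rng=rng, train_fn=train_fn
        ).mean_ari
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_permutations)
    return float(p), float(observed), null
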