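"""Evaluation machinery for ranked gene-GO relevance predictions.

Given ground-truth labels (``bm_truth``: is this annotation relevant in the
biological context?) and per-pair adjusted p-values from any method, this
module computes the rank-correspondence and classification metrics used to
compare relevance-ranking methods: per-gene Kendall's tau-b with specific
tie/NaN conventions, AUROC on the -log10(padj + 1e-16) score, a
random-selection negative-control baseline, conversion of Bayesian (MGSA)
posteriors to padj-equivalents, propagation of significant ancestor scores
to insignificant child annotations ("parental enhancement"), and a
multinomial likelihood-ratio test for whether the number of relevant terms
per gene is uniform given the number of annotated terms.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .assembly import OntologyTerm

#: padj at or above this threshold is treated as entirely non-significant.
DEFAULT_THRESHOLD = 0.1


def clamp_padj(padj: float, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Insignificant padj values carry no ranking information: >= threshold -> 1."""
    return padj if padj < threshold else 1.0


def kendall_tau_vs_truth(
    predicted_padj: dict[str, float],
    truth: dict[str, bool],
    threshold: float = DEFAULT_THRESHOLD,
) -> float:
    """Kendall's tau-b between a gene's predicted and ground-truth rankings.

    Predictions are clamped (padj >= threshold -> 1) and ranked ascending
    with ties tied; the ground truth puts every relevant annotation at tied
    rank 1 and the rest at tied rank 2. Degenerate cases where tau is
    undefined (a constant ranking on either side): if every annotation is
    truly relevant and every prediction is significant (a perfect tied-top
    prediction) the correspondence is perfect, tau = 1; any other constant
    ranking carries no information, tau = 0.
    """
    if set(predicted_padj) != set(truth):
        raise ValueError("prediction and truth annotation sets differ")
    if not any(truth.values()):
        raise ValueError("gene has no relevant annotation in the ground truth")
    keys = sorted(predicted_padj)
    pred = np.array([clamp_padj(predicted_padj[k], threshold) for k in keys])
    truth_rank = np.array([1 if truth[k] else 2 for k in keys])
    tau = sps.kendalltau(pred, truth_rank).statistic
    if np.isnan(tau):
        if np.all(truth_rank == 1) and np.all(pred < threshold):
            return 1.0
        return 0.0
    return float(tau)


def mgsa_convert(ppost: float) -> float:
    """Convert an MGSA posterior probability into a padj-equivalent.

    padj = 1 - ppost/10 if ppost > 0.5 (significant, ranked by descending
    posterior), else 1.
    """
    if not 0.0 <= ppost <= 1.0:
        raise ValueError("posterior probability must lie in [0, 1]")
    return 1.0 - ppost / 10.0 if ppost > 0.5 else 1.0


def relevance_score(padj) -> np.ndarray:
    """Quantitative relevance score -log10(padj + 1e-16)."""
    return -np.log10(np.asarray(padj, dtype=float) + 1e-16)


def auroc(bm_truth, padj) -> float:
    """AUROC of the relevance score against the binary ground truth."""
    y = np.asarray(bm_truth, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("AUROC requires both classes present")
    return float(roc_auc_score(y, relevance_score(padj)))


def random_baseline(
    truth: dict[str, dict[str, bool]],
    n_samples: int = 100,
    seed: int | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    surrogate_padj: float = 0.05,
) -> tuple[dict[str, float], float]:
    """Random-selection negative-control model.

    For each gene g with n_g annotations, draw N^g uniform in {0..n_g} and
    mark that many randomly chosen annotations as relevant (a tied
    significant padj below the threshold); the rest get padj = 1. Per-gene
    Kendall tau and the pooled AUROC are computed per sample and averaged
    over ``n_samples`` repeats.

    Returns (mean tau per gene, mean AUROC).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    taus: dict[str, list[float]] = {g: [] for g in truth}
    aurocs = []
    flat_truth = [v for g in sorted(truth) for k, v in sorted(truth[g].items())]
    for _ in range(n_samples):
        preds: dict[str, dict[str, float]] = {}
        for g in sorted(truth):
            anns = sorted(truth[g])
            n_sel = int(rng.integers(0, len(anns) + 1))
            chosen = set(rng.choice(len(anns), size=n_sel, replace=False))
            preds[g] = {
                a: (surrogate_padj if i in chosen else 1.0)
                for i, a in enumerate(anns)
            }
            taus[g].append(
                kendall_tau_vs_truth(preds[g], truth[g], threshold)
            )
        flat_pred = [
            preds[g][k] for g in sorted(truth) for k in sorted(truth[g])
        ]
        aurocs.append(auroc(flat_truth, flat_pred))
    mean_tau = {g: float(np.mean(v)) for g, v in taus.items()}
    return mean_tau, float(np.mean(aurocs))


def _ancestors(go_id: str, ontology: dict[str, OntologyTerm]) -> set[str]:
    out: set[str] = set()
    frontier = set(ontology[go_id].parent_ids)
    while frontier:
        out |= frontier
        frontier = {
            p for t in frontier if t in ontology
            for p in ontology[t].parent_ids
        } - out
    return out


def parental_enhance(
    predictions: dict[tuple[str, str], float],
    ontology: dict[str, OntologyTerm],
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[tuple[str, str], float]:
    """Propagate significant ancestor padj values to insignificant children.

    For each (gene, term) with padj >= threshold, if any is_a ancestor of
    the term has a significant padj for the same gene, assign the minimal
    such ancestor padj; otherwise leave unchanged. Idempotent; never
    increases a padj.
    """
    for _, go_id in predictions:
        if go_id not in ontology:
            raise KeyError(f"unknown GO term {go_id}")
    out = dict(predictions)
    for (gene, go_id), padj in predictions.items():
        if padj < threshold:
            continue
        candidates = [
            predictions[(gene, anc)]
            for anc in _ancestors(go_id, ontology)
            if (gene, anc) in predictions and predictions[(gene, anc)] < threshold
        ]
        if candidates:
            out[(gene, go_id)] = min(candidates)
    return out


@dataclass
class UniformityTestResult:
    """Outcome of the likelihood-ratio uniformity test, with audit counts."""

    statistic: float
    df: int
    p_value: float
    x_max: int
    counts: dict[tuple[int, int], int]   # (y, x) -> n_{y,x}
    totals: dict[int, int]               # x -> N_x


def lr_uniformity_test(
    observations, df_mode: str = "as-published"
) -> UniformityTestResult:
    """Likelihood-ratio test of Y|X=x ~ Uniform{0..x} against free multinomials.

    ``observations`` is a sequence of (x, y) integer pairs with 1 <= x and
    0 <= y <= x (e.g. x = number of annotated GO terms of a gene, y = number
    called relevant). With n_{y,x} the count of (y, x) and N_x their total
    per x, the statistic is

        -2 log(Lambda) = -2 * sum_x [ N_x log(N_x / (x+1))
                                      - sum_y n_{y,x} log n_{y,x} ]

    (0 log 0 := 0), compared against chi-square with
    df = x_max(x_max+3)/2 degrees of freedom. ``df_mode="constrained"``
    instead uses x_max(x_max+1)/2, subtracting one sum-to-one constraint per
    multinomial.
    """
    observations = list(observations)
    if not observations:
        raise ValueError("no observations")
    counts: Counter = Counter()
    for x, y in observations:
        x, y = int(x), int(y)
        if x < 1:
            raise ValueError(f"x must be >= 1, got {x}")
        if not 0 <= y <= x:
            raise ValueError(f"require 0 <= y <= x, got (x={x}, y={y})")
        counts[(y, x)] += 1
    totals = Counter()
    for (y, x), n in counts.items():
        totals[x] += n
    x_max = max(totals)
    stat = 0.0
    for x, N_x in totals.items():
        stat += N_x * np.log(N_x / (x + 1))
        for y in range(x + 1):
            n = counts.get((y, x), 0)
            if n > 0:
                stat -= n * np.log(n)
    stat *= -2.0
    if df_mode == "as-published":
        df = x_max * (x_max + 3) // 2
    elif df_mode == "constrained":
        df = x_max * (x_max + 1) // 2
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    p = float(sps.chi2.sf(stat, df))
    return UniformityTestResult(
        statistic=float(stat), df=df, p_value=p, x_max=x_max,
        counts=dict(counts), totals=dict(totals),
    )
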