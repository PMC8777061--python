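"""Benchmark metrics for comparing normalization arms.

Four procedures quantify how much non-biological variation survives
normalization, each runnable on any probes x samples beta matrix:

* technical-replicate probe-level variance (lower is better);
* train/test consistency of case-control differential calls, scored as an
  ROC/AUC with the training calls as gold standard;
* per-probe Pearson correlation against a continuous covariate such as
  age, with counts above |r| thresholds 0.5/0.6/0.7;
* mean absolute beta difference between genomically adjacent probe pairs
  (which share methylation state biologically) versus random control
  pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError

__all__ = [
    "ReplicateVarianceResult",
    "CaseControlResult",
    "CovariateResult",
    "AdjacentPairResult",
    "replicate_variance",
    "case_control_consistency",
    "covariate_correlation",
    "adjacent_pair_difference",
    "select_adjacent_pairs",
    "select_random_pairs",
]


@dataclass
class ReplicateVarianceResult:
    per_probe: pd.Series = field(repr=False)
    mean_variance: float = float("nan")
    n_groups: int = 0
    n_excluded_groups: int = 0


def replicate_variance(beta: pd.DataFrame, replicate_groups) -> ReplicateVarianceResult:
    """Probe-level variance within replicate groups, averaged across groups.

    ``replicate_groups`` maps each sample (column) to its group; singleton
    groups are excluded.  Sample variance uses the n-1 denominator.
    """
    groups = pd.Series(replicate_groups, index=beta.columns)
    per_group = []
    excluded = 0
    for _, cols in groups.groupby(groups).groups.items():
        if len(cols) < 2:
            excluded += 1
            continue
        per_group.append(beta[list(cols)].var(axis=1, ddof=1))
    if not per_group:
        raise ValidationError("no replicate group has >= 2 samples")
    per_probe = pd.concat(per_group, axis=1).mean(axis=1)
    return ReplicateVarianceResult(
        per_probe=per_probe,
        mean_variance=float(per_probe.mean()),
        n_groups=len(per_group),
        n_excluded_groups=excluded,
    )


@dataclass
class CaseControlResult:
    auc: float
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    n_gold_positive: int = 0
    n_probes: int = 0
    train_samples: list = field(default_factory=list, repr=False)
    test_samples: list = field(default_factory=list, repr=False)


def _welch_p(beta: pd.DataFrame, case_cols, ctrl_cols) -> pd.Series:
    a = beta[list(case_cols)].to_numpy(float)
    b = beta[list(ctrl_cols)].to_numpy(float)
    res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    return pd.Series(np.asarray(res.pvalue, float), index=beta.index)


def case_control_consistency(
    beta: pd.DataFrame,
    labels,
    split_ratio: tuple[int, int] = (2, 1),
    seed: int = 0,
    alpha: float = 0.05,
    split: tuple[list, list] | None = None,
    permute_test_seed: int | None = None,
) -> CaseControlResult:
    """Train/test consistency of per-probe Welch t-tests, as ROC/AUC.

    Samples are split train:test at ``split_ratio`` (stratified by label,
    seeded) unless an explicit ``(train, test)`` column split is given.
    Training calls (Benjamini-Hochberg at ``alpha``) are the gold standard;
    test probes are ranked by -log10 p.  ``permute_test_seed`` shuffles the
    test-split labels, for null calibration on data without test-side
    signal (on signal-bearing test samples a label shuffle leaves the
    truly differential probes correlated through the realized imbalance,
    so single-shuffle AUCs are heavy-tailed there).
    """
    labels = pd.Series(labels, index=beta.columns)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValidationError(f"need exactly two groups, got {classes}")
    if split is None:
        rng = np.random.default_rng(seed)
        train, test = [], []
        frac_train = split_ratio[0] / (split_ratio[0] + split_ratio[1])
        for cls in classes:
            cols = list(labels.index[labels == cls])
            if len(cols) < 6:
                raise ValidationError(f"group {cls!r} has {len(cols)} samples; need >= 6")
            perm = rng.permutation(len(cols))
            k = int(round(frac_train * len(cols)))
            train += [cols[i] for i in perm[:k]]
            test += [cols[i] for i in perm[k:]]
    else:
        train, test = list(split[0]), list(split[1])
    test_labels = labels[test].copy()
    if permute_test_seed is not None:
        rng = np.random.default_rng(permute_test_seed)
        test_labels = pd.Series(
            rng.permutation(test_labels.to_numpy()), index=test_labels.index
        )
    case, ctrl = classes[0], classes[1]
    p_train = _welch_p(
        beta, [c for c in train if labels[c] == case], [c for c in train if labels[c] == ctrl]
    )
    p_test = _welch_p(
        beta,
        [c for c in test if test_labels[c] == case],
        [c for c in test if test_labels[c] == ctrl],
    )
    ok = p_train.notna() & p_test.notna()
    p_train, p_test = p_train[ok], p_test[ok]
    gold = multipletests(p_train.to_numpy(), alpha=alpha, method="fdr_bh")[0]
    if gold.all() or not gold.any():
        raise ValidationError(
            f"degenerate gold standard: {int(gold.sum())}/{gold.size} positives"
        )
    score = -np.log10(np.maximum(p_test.to_numpy(), 1e-300))
    fpr, tpr, _ = roc_curve(gold, score)
    return CaseControlResult(
        auc=float(roc_auc_score(gold, score)),
        fpr=fpr,
        tpr=tpr,
        n_gold_positive=int(gold.sum()),
        n_probes=int(gold.size),
        train_samples=train,
        test_samples=test,
    )


@dataclass
class CovariateResult:
    r: pd.Series = field(repr=False)
    counts: dict[float, int] = field(default_factory=dict)
    n_excluded: int = 0


def covariate_correlation(
    beta: pd.DataFrame,
    covariate,
    thresholds: tuple[float, ...] = (0.5, 0.6, 0.7),
) -> CovariateResult:
    """Per-probe Pearson r against a continuous covariate; |r| threshold counts."""
    cov = np.asarray(covariate, dtype=float)
    if cov.size != beta.shape[1]:
        raise ParameterError("covariate length must equal the number of samples")
    if not np.isfinite(cov).all():
        raise ValidationError("covariate contains non-finite values")
    if cov.size < 10:
        raise ValidationError("need >= 10 samples for covariate correlation")
    x = beta.to_numpy(float)
    xm = x - np.nanmean(x, axis=1, keepdims=True)
    zm = cov - cov.mean()
    mask = np.isfinite(x)
    xm = np.where(mask, xm, 0.0)
    num = xm @ zm
    denom = np.sqrt((xm * xm).sum(axis=1) * (zm * zm).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, np.nan)
    r = pd.Series(r, index=beta.index)
    valid = r.dropna()
    counts = {t: int((valid.abs() >= t).sum()) for t in thresholds}
    return CovariateResult(r=r, counts=counts, n_excluded=int(r.isna().sum()))


@dataclass
class AdjacentPairResult:
    adjacent_mean_per_sample: pd.Series = field(repr=False)
    random_mean_per_sample: pd.Series = field(repr=False)
    adjacent_mean: float = float("nan")
    random_mean: float = float("nan")
    ratio: float = float("nan")
    n_skipped_pairs: int = 0


def _pair_mean_absdiff(beta: pd.DataFrame, pairs) -> tuple[pd.Series, int]:
    a_ids = [p[0] for p in pairs]
    b_ids = [p[1] for p in pairs]
    known = beta.index
    valid = [i for i, (a, b) in enumerate(pairs) if a in known and b in known]
    skipped = len(pairs) - len(valid)
    a = beta.reindex([a_ids[i] for i in valid]).to_numpy(float)
    b = beta.reindex([b_ids[i] for i in valid]).to_numpy(float)
    diff = np.abs(a - b)
    return pd.Series(np.nanmean(diff, axis=0), index=beta.columns), skipped


def adjacent_pair_difference(
    beta: pd.DataFrame, pairs, random_pairs
) -> AdjacentPairResult:
    """Mean |delta beta| over adjacent pairs vs random control pairs, per sample."""
    adj, skipped_a = _pair_mean_absdiff(beta, list(pairs))
    rnd, skipped_r = _pair_mean_absdiff(beta, list(random_pairs))
    adj_mean = float(adj.mean())
    rnd_mean = float(rnd.mean())
    return AdjacentPairResult(
        adjacent_mean_per_sample=adj,
        random_mean_per_sample=rnd,
        adjacent_mean=adj_mean,
        random_mean=rnd_mean,
        ratio=adj_mean / rnd_mean if rnd_mean > 0 else float("nan"),
        n_skipped_pairs=skipped_a + skipped_r,
    )


def select_adjacent_pairs(
    annotation: pd.DataFrame, max_distance: int = 10
) -> list[tuple[str, str]]:
    """Non-overlapping same-chromosome pairs with position distance < max_distance.

    Greedy left-to-right along each chromosome; each probe enters at most
    one pair.  The inequality is strict (distance 10 with max_distance 10
    does not pair).
    """
    pairs = []
    for _, chrom_ann in annotation.groupby("chromosome", sort=True):
        ordered = chrom_ann.sort_values(["position"], kind="stable")
        ids = list(ordered.index)
        pos = ordered["position"].to_numpy()
        i = 0
        while i + 1 < len(ids):
            if abs(int(pos[i + 1]) - int(pos[i])) < max_distance:
                pairs.append((ids[i], ids[i + 1]))
                i += 2
            else:
                i += 1
    return pairs


def select_random_pairs(
    annotation: pd.DataFrame, n_pairs: int, seed: int = 0
) -> list[tuple[str, str]]:
    """Disjoint random probe pairs as controls for the adjacent-pair metric."""
    probes = list(annotation.index)
    if 2 * n_pairs > len(probes):
        raise ParameterError(f"cannot draw {n_pairs} disjoint pairs from {len(probes)} probes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(probes))
    return [(probes[perm[2 * i]], probes[perm[2 * i + 1]]) for i in range(n_pairs)]
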