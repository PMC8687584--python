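"""Experiment-split (leave-one-source-out) evaluation and k-fold baselines.

The protocol this package exists for: annotated sites come from many
experimental sources, and mixing them before a random train/test split lets
information from every experiment leak into both sides, inflating measured
generalization.  The experiment-split test instead holds out one experimental
source at a time:

* test positives = the held-out source's windows, minus any window also
  attributed to another source (those sit in the training positives);
* training positives = windows of all remaining sources;
* a fixed pool of negatives (40,000 by default) is sampled from the
  unannotated lysines and cut into two disjoint halves, one per side;
* a held-out source yielding fewer than 5 surviving test positives is
  dropped, and the protocol is declared inapplicable when fewer than 5
  sources survive — tiny test sets make the estimate unreliable.

Each surviving source gives one independent test; metrics are ROC-AUC and
sensitivity at specificity >= 0.9, aggregated as mean +/- SD across tests and
compared against mixed-source ten-fold cross-validation with t-tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .corpus import SequenceWindow, SourceCorpus
from .models import ModelSpec, build_model
from .train import TrainConfig, train


class ProtocolInapplicableError(RuntimeError):
    """Too few eligible held-out sources for a reliable estimate."""


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _check_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise EvaluationError("both classes must be present")


def auc(scores, labels) -> float:
    """Area under the ROC curve, ties handled by the midrank convention.

    Equals the probability that a random positive outscores a random negative,
    counting ties as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_classes(labels)
    return float(roc_auc_score(labels, scores))


def sensitivity_at_specificity(scores, labels, target_specificity: float = 0.9) -> float:
    """Sensitivity at the loosest threshold with specificity >= target.

    Candidate thresholds sit between distinct adjacent scores; the constraint
    is specificity >= target (conservative), so the reported sensitivity is
    the largest achievable under it.
    """
    if not 0.0 < target_specificity < 1.0:
        raise EvaluationError("target_specificity must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_classes(labels)
    # keep every ROC point: dropped "intermediate" points can be exactly the
    # best operating point satisfying the specificity constraint
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    ok = fpr <= (1.0 - target_specificity) + 1e-12
    return float(tpr[ok].max())


# ---------------------------------------------------------------------------
# split construction
# ---------------------------------------------------------------------------

@dataclass
class SplitConfig:
    """Protocol settings; defaults follow the full-scale benchmark.

    ``n_negatives_total`` negatives are drawn without replacement and halved
    into disjoint train/test pools.  By default the draw is repeated
    independently per held-out source (keeping the tests exchangeable);
    ``shared_negatives`` reuses a single draw for every split.
    """

    n_negatives_total: int = 40_000
    min_test_sets: int = 5
    min_positives_per_test: int = 5
    seed: int = 0
    shared_negatives: bool = False

    def __post_init__(self) -> None:
        if self.n_negatives_total % 2:
            raise EvaluationError("n_negatives_total must be even (split into halves)")
        if self.min_test_sets < 1 or self.min_positives_per_test < 1:
            raise EvaluationError("minimums must be >= 1")


@dataclass
class Split:
    """One held-out-source test: disjoint train/test window sets."""

    held_out_source: str
    train_positives: list[SequenceWindow]
    train_negatives: list[SequenceWindow]
    test_positives: list[SequenceWindow]
    test_negatives: list[SequenceWindow]

    def validate(self) -> None:
        tp = {w.sequence for w in self.test_positives}
        if tp & {w.sequence for w in self.train_positives}:
            raise EvaluationError("positive window leaks between train and test")
        tn = {w.sequence for w in self.test_negatives}
        if tn & {w.sequence for w in self.train_negatives}:
            raise EvaluationError("negative window leaks between train and test")
        for w in self.test_positives:
            if self.held_out_source not in w.sources:
                raise EvaluationError("test positive not from the held-out source")


def make_experiment_splits(
    corpus: SourceCorpus, mod_type: str, config: SplitConfig
) -> list[Split]:
    """One candidate split per experimental source, filtered for reliability.

    Windows attributed to the held-out source *and* to any training source are
    removed from the test side (they are already present in the training
    positives).  Sources with fewer than ``min_positives_per_test`` surviving
    positives are dropped; fewer than ``min_test_sets`` surviving sources
    raises :class:`ProtocolInapplicableError`.
    """
    by_source: dict[str, list[SequenceWindow]] = {}
    for src, seqs in corpus.source_index.items():
        # sort: set iteration order is hash-randomized across processes and
        # would otherwise leak into training order and negative sampling
        ws = [corpus.positives[s] for s in sorted(seqs)
              if mod_type in corpus.positives[s].labels]
        if ws:
            by_source[src] = ws
    if not by_source:
        raise EvaluationError(f"no positives labeled {mod_type!r} in corpus")
    if len(by_source) < 2:
        raise EvaluationError("need >= 2 sources with positives of this type")

    negatives = corpus.negative_windows()
    if len(negatives) < config.n_negatives_total:
        raise EvaluationError(
            f"only {len(negatives)} negatives available; request "
            f"{config.n_negatives_total} — lower n_negatives_total"
        )

    seed_seq = np.random.SeedSequence(config.seed)
    shared_rng = np.random.default_rng(seed_seq) if config.shared_negatives else None
    child_seeds = seed_seq.spawn(len(by_source))

    splits: list[Split] = []
    for child, src in zip(child_seeds, sorted(by_source)):
        train_pos = [
            w
            for other in by_source
            if other != src
            for w in by_source[other]
        ]
        # dedup: a window in several training sources appears once
        train_pos = list({w.sequence: w for w in train_pos}.values())
        train_seqs = {w.sequence for w in train_pos}
        test_pos = [w for w in by_source[src] if w.sequence not in train_seqs]
        if len(test_pos) < config.min_positives_per_test:
            continue
        rng = shared_rng if shared_rng is not None else np.random.default_rng(child)
        if config.shared_negatives and splits:
            neg_sample = splits[0].train_negatives + splits[0].test_negatives
        else:
            idx = rng.choice(len(negatives), size=config.n_negatives_total, replace=False)
            neg_sample = [negatives[i] for i in idx]
        half = config.n_negatives_total // 2
        splits.append(
            Split(src, train_pos, neg_sample[:half], test_pos, neg_sample[half:])
        )

    if len(splits) < config.min_test_sets:
        raise ProtocolInapplicableError(
            f"{len(splits)} eligible test sets for {mod_type!r} "
            f"(need >= {config.min_test_sets}): experiment-split protocol "
            f"inapplicable for this modification type"
        )
    for s in splits:
        s.validate()
    return splits


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-unit metrics (one unit = one fold or one held-out source)."""

    protocol: str  # "cv" or "experiment_split"
    unit_ids: list[str]
    aucs: list[float]
    sns: list[float]
    target_specificity: float = 0.9
    p_values: dict[str, float] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0

    def summary(self) -> str:
        lines = [
            f"protocol: {self.protocol}   units: {len(self.unit_ids)}",
            f"AUC mean +/- SD: {self.mean:.4f} +/- {self.sd:.4f}",
            f"{'unit':<16}{'AUC':>8}{'Sn@Sp' + format(self.target_specificity, '.2f'):>10}",
        ]
        for uid, a, s in zip(self.unit_ids, self.aucs, self.sns):
            lines.append(f"{uid:<16}{a:>8.4f}{s:>10.4f}")
        for name, p in self.p_values.items():
            lines.append(f"p[{name}] = {p:.3g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "units": self.unit_ids,
            "auc": self.aucs,
            "sn_at_sp": self.sns,
            "target_specificity": self.target_specificity,
            "auc_mean": self.mean,
            "auc_sd": self.sd,
            "p_values": self.p_values,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def _fit_and_score(spec, train_pos, train_neg, test_pos, test_neg,
                   train_config, seed, target_specificity):
    model = build_model(spec, seed=seed)
    cfg_seed = int(np.random.SeedSequence([seed, 1]).generate_state(1)[0] % (2**31))
    cfg = TrainConfig(**{**train_config.__dict__, "seed": cfg_seed})
    fitted = train(model, train_pos, train_neg, cfg)
    scores = fitted.score(list(test_pos) + list(test_neg))
    labels = np.r_[np.ones(len(test_pos)), np.zeros(len(test_neg))]
    return auc(scores, labels), sensitivity_at_specificity(
        scores, labels, target_specificity)


def stratified_folds(y, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Class-stratified k-fold partition (shuffled once with ``seed``).

    Test folds are disjoint, cover all indices, and per-class fold sizes
    differ by at most one.
    """
    y = np.asarray(y)
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in folds.split(np.zeros(len(y)), y)]


def kfold_cv(
    positives,
    negatives,
    spec: ModelSpec,
    train_config: TrainConfig,
    k: int = 10,
    balanced: bool = True,
    seed: int = 0,
    target_specificity: float = 0.9,
) -> EvalReport:
    """Mixed-source k-fold cross-validation baseline.

    Data are shuffled once with ``seed`` and partitioned into k folds
    stratified by class; with ``balanced`` (the default) negatives are first
    subsampled without replacement to the number of positives.
    """
    if k < 2:
        raise EvaluationError("k must be >= 2")
    positives, negatives = list(positives), list(negatives)
    rng = np.random.default_rng(seed)
    if balanced and len(negatives) > len(positives):
        idx = rng.choice(len(negatives), size=len(positives), replace=False)
        negatives = [negatives[i] for i in idx]
    data = positives + negatives
    y = np.r_[np.ones(len(positives), dtype=int), np.zeros(len(negatives), dtype=int)]
    if min(np.bincount(y)) < k:
        raise EvaluationError("too few samples per class for the requested k")

    unit_ids, aucs, sns = [], [], []
    fold_seeds = np.random.SeedSequence(seed).spawn(k)
    for fold, (tr, te) in enumerate(stratified_folds(y, k, seed)):
        tr_pos = [data[i] for i in tr if y[i] == 1]
        tr_neg = [data[i] for i in tr if y[i] == 0]
        te_pos = [data[i] for i in te if y[i] == 1]
        te_neg = [data[i] for i in te if y[i] == 0]
        if not te_pos or not te_neg:
            raise EvaluationError(f"fold {fold} has a single class")
        model_seed = int(fold_seeds[fold].generate_state(1)[0] % (2**31))
        a, s = _fit_and_score(spec, tr_pos, tr_neg, te_pos, te_neg,
                              train_config, model_seed, target_specificity)
        unit_ids.append(f"fold{fold + 1}")
        aucs.append(a)
        sns.append(s)
    return EvalReport("cv", unit_ids, aucs, sns, target_specificity)


def run_experiment_split(
    corpus: SourceCorpus,
    mod_type: str,
    spec: ModelSpec,
    train_config: TrainConfig,
    split_config: SplitConfig,
    target_specificity: float = 0.9,
) -> EvalReport:
    """Train one fresh model per held-out source and score its test set.

    Models are retrained from scratch with split-derived seeds (no
    warm-starting), keeping the per-source tests independent.
    """
    splits = make_experiment_splits(corpus, mod_type, split_config)
    unit_ids, aucs, sns = [], [], []
    seeds = np.random.SeedSequence([split_config.seed, len(splits)]).spawn(len(splits))
    for split, child in zip(splits, seeds):
        model_seed = int(child.generate_state(1)[0] % (2**31))
        a, s = _fit_and_score(
            spec, split.train_positives, split.train_negatives,
            split.test_positives, split.test_negatives,
            train_config, model_seed, target_specificity,
        )
        unit_ids.append(split.held_out_source)
        aucs.append(a)
        sns.append(s)
    return EvalReport("experiment_split", unit_ids, aucs, sns, target_specificity)


# ---------------------------------------------------------------------------
# statistical comparisons
# ---------------------------------------------------------------------------

def compare_reports(
    a,
    b=None,
    reference: float | None = None,
    test: str = "two_sample",
) -> float:
    """Two-sided p-value of the named t-test between metric vectors.

    ``single_sample`` compares ``a`` against the scalar ``reference``;
    ``paired`` requires equal-length matched vectors; ``two_sample`` is
    Welch's unequal-variance test (the appropriate default when comparing a
    k-fold vector against an n-split vector, which have no natural pairing).
    Zero-variance inputs make the statistic undefined and raise.
    """
    a = np.asarray(a, dtype=float)
    if len(a) < 2:
        raise EvaluationError("need n >= 2 values")
    if test == "single_sample":
        if reference is None:
            raise EvaluationError("single_sample needs a reference value")
        if np.std(a, ddof=1) == 0:
            raise EvaluationError("zero variance: single-sample t-test undefined")
        return float(stats.ttest_1samp(a, reference).pvalue)
    b = np.asarray(b, dtype=float)
    if test == "paired":
        if len(a) != len(b):
            raise EvaluationError("paired test needs equal-length vectors")
        d = a - b
        if np.std(d, ddof=1) == 0:
            raise EvaluationError(
                "zero variance of differences: paired t-test undefined "
                "(identical vectors?)"
            )
        return float(stats.ttest_rel(a, b).pvalue)
    if test == "two_sample":
        if len(b) < 2:
            raise EvaluationError("need n >= 2 values")
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            raise EvaluationError("zero variance in both samples: t-test undefined")
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    raise EvaluationError(f"unknown test {test!r}")
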