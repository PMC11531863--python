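"""Chromosome-holdout benchmarking (AUROC/AUPR over replicates) and in-silico
SNP effect prediction.

Held-out test sets keep the natural class imbalance of the genome (balancing
is a training-time device only), which is why the precision-recall area is the
headline metric. Pseudo-labeled examples inherit their source peak's
labeled-genome chromosome, and any example deriving from a test chromosome —
directly or via homology — is excluded from every training phase.

The effect of a single-nucleotide variant on the model output is scored as

    effect = (p_alt - p_ref) * max(0, p_alt, p_ref)

where p_ref and p_alt are the predicted probabilities of the window carrying
the reference and alternative allele. The score is antisymmetric under allele
swap and bounded by 1 in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .core_io import Genome, SNPRecord, Window, fetch_sequence
from .labeling import LabeledDataset, SequenceExample, balance_dataset
from .models import ModelSpec
from .training import (TrainConfig, TrainedModel, train_ssl, train_ssl_ns,
                       train_supervised)


@dataclass
class EvalResult:
    strategy: str
    family: str
    auroc: float
    aupr: float
    n_pos: int
    n_neg: int
    replicate_seeds: list[int]
    per_replicate: list[dict]
    pct_change_vs_sl: Optional[dict] = None


@dataclass(frozen=True)
class SNPEffect:
    snp: SNPRecord
    p_ref: float
    p_alt: float

    @property
    def effect(self) -> float:
        return snp_effect_score(self.p_ref, self.p_alt)


def snp_effect_score(p_ref: float, p_alt: float) -> float:
    """(p_alt - p_ref) * max(0, p_alt, p_ref); antisymmetric under swap."""
    return (p_alt - p_ref) * max(0.0, p_alt, p_ref)


def split_by_chromosome(
    examples: Sequence[SequenceExample], test_chroms: Sequence[str]
) -> tuple[list[SequenceExample], list[SequenceExample]]:
    """Partition examples by source chromosome for leakage-free holdout.

    Labeled examples from test chromosomes form the test set; pseudo-labeled
    examples homologous to test-chromosome peaks are dropped entirely (they
    may appear in neither training phase nor the test set).
    """
    test_chroms = set(test_chroms)
    all_chroms = {e.source_chrom for e in examples}
    if all_chroms and all_chroms <= test_chroms:
        raise ValueError("test_chroms cover every chromosome; nothing left to train on")
    train: list[SequenceExample] = []
    test: list[SequenceExample] = []
    for e in examples:
        if e.source_chrom in test_chroms:
            if e.origin == "labeled":
                test.append(e)
        else:
            train.append(e)
    return train, test


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUROC undefined: both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def aupr(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Average precision (step-wise area under the precision-recall curve)."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPR undefined: no positive examples")
    return float(average_precision_score(labels, np.asarray(scores, dtype=np.float64)))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on mid-ranks, ties averaged)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def predict_snp_effect(model, genome: Genome, snp: SNPRecord,
                       window_length: int) -> SNPEffect:
    """Score one variant by predicting the reference and alternative windows.

    The window places the variant at offset floor(L/2) (0-based). The genome
    base at the variant position must equal the reference allele.
    """
    if snp.chrom not in genome:
        raise KeyError(f"unknown chromosome {snp.chrom!r}")
    half = window_length // 2
    start = snp.pos0 - half
    seq = fetch_sequence(genome, Window(snp.chrom, start, start + window_length))
    observed = seq[half]
    if observed != snp.ref:
        raise ValueError(
            f"reference mismatch at {snp.chrom}:{snp.pos}: genome has "
            f"{observed!r}, variant says {snp.ref!r}"
        )
    alt_seq = seq[:half] + snp.alt + seq[half + 1:]
    p_ref, p_alt = model.predict([seq, alt_seq])
    return SNPEffect(snp=snp, p_ref=float(p_ref), p_alt=float(p_alt))


def _test_arrays(test_examples: Sequence[SequenceExample]) -> tuple[list[str], np.ndarray]:
    return [e.sequence for e in test_examples], np.array([e.label for e in test_examples])


def run_benchmark(
    labeled_positives: Sequence[SequenceExample],
    negative_pool: Sequence[SequenceExample],
    pseudo_positives: Sequence[SequenceExample],
    test_examples: Sequence[SequenceExample],
    strategies: Sequence[str],
    specs: Sequence[ModelSpec],
    config: TrainConfig,
    n_replicates: int = 3,
    seeds: Optional[Sequence[int]] = None,
) -> list[EvalResult]:
    """Train each (strategy, spec) ``n_replicates`` times with distinct seeds
    and report mean AUROC/AUPR on the untouched test set, plus the percent
    change of each strategy relative to SL: 100 * (m_strat - m_SL) / m_SL.

    Identical seed lists across strategies make the comparison paired (the
    same negative draws and initializations enter each strategy).
    """
    if seeds is None:
        seeds = [config.seed + r for r in range(n_replicates)]
    if len(seeds) != n_replicates:
        raise ValueError("need one seed per replicate")
    test_seqs, test_labels = _test_arrays(test_examples)
    n_pos = int(test_labels.sum())
    n_neg = int(len(test_labels) - n_pos)

    results: list[EvalResult] = []
    for spec in specs:
        sl_means: Optional[dict] = None
        for strategy in strategies:
            per_rep: list[dict] = []
            for seed in seeds:
                cfg = replace(config, seed=seed)
                rep_spec = replace(spec, seed=seed)
                labeled = balance_dataset(labeled_positives, negative_pool, seed=seed)
                if strategy == "SL":
                    trained = train_supervised(rep_spec, labeled, cfg)
                elif strategy == "SSL":
                    pretrain = balance_dataset(pseudo_positives, negative_pool,
                                               seed=seed + 10_000)
                    trained = train_ssl(rep_spec, pretrain, labeled, cfg)
                elif strategy == "SSL-NS":
                    trained = train_ssl_ns(rep_spec, labeled, pseudo_positives,
                                           negative_pool, cfg)
                else:
                    raise ValueError(f"unknown strategy {strategy!r}")
                scores = trained.model.predict(test_seqs)
                per_rep.append({
                    "seed": seed,
                    "auroc": auroc(test_labels, scores),
                    "aupr": aupr(test_labels, scores),
                })
            mean_auroc = float(np.mean([r["auroc"] for r in per_rep]))
            mean_aupr = float(np.mean([r["aupr"] for r in per_rep]))
            pct = None
            if strategy == "SL":
                sl_means = {"auroc": mean_auroc, "aupr": mean_aupr}
            elif sl_means is not None:
                pct = {
                    m: 100.0 * (v - sl_means[m]) / sl_means[m]
                    for m, v in (("auroc", mean_auroc), ("aupr", mean_aupr))
                    if sl_means[m] > 0
                }
            results.append(EvalResult(
                strategy=strategy, family=spec.family,
                auroc=mean_auroc, aupr=mean_aupr,
                n_pos=n_pos, n_neg=n_neg,
                replicate_seeds=list(seeds), per_replicate=per_rep,
                pct_change_vs_sl=pct,
            ))
    return results
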