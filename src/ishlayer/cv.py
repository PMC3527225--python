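"""Gene-grouped, label-stratified cross-validation folds.

Labels attach to genes, but samples are images; any fold assignment must
keep all images of a gene on one side of every split, otherwise held-out
performance is inflated by near-duplicate slices of the same gene. Folds
are therefore assigned at the gene level and mapped down to images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CVPlan", "make_cv_plan"]


@dataclass(frozen=True)
class CVPlan:
    """Gene -> fold assignment for one round of k-fold cross-validation."""

    n_folds: int
    assignment: dict[str, int]
    seed: int

    def __post_init__(self) -> None:
        folds = np.asarray(list(self.assignment.values()))
        if folds.size and (folds.min() < 0 or folds.max() >= self.n_folds):
            raise ValueError("fold indices out of range")
        sizes = np.bincount(folds, minlength=self.n_folds)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most one gene")

    def gene_folds(self, gene_ids) -> np.ndarray:
        """Fold index for each entry of ``gene_ids`` (genes or per-image ids)."""
        return np.asarray([self.assignment[g] for g in gene_ids], dtype=int)

    def test_genes(self, fold: int) -> frozenset[str]:
        return frozenset(g for g, f in self.assignment.items() if f == fold)

    def train_genes(self, fold: int) -> frozenset[str]:
        return frozenset(g for g, f in self.assignment.items() if f != fold)


def make_cv_plan(gene_ids, labels, n_folds: int = 5, seed: int = 0) -> CVPlan:
    """Stratified, gene-level fold assignment, deterministic under ``seed``.

    Genes are shuffled within each label and dealt round-robin to folds with
    a fold pointer that persists across labels, so overall fold sizes differ
    by at most one gene and each fold's per-label count differs from an even
    split by at most one gene.
    """
    gene_ids = [str(g) for g in gene_ids]
    labels = list(labels)
    if len(gene_ids) != len(labels):
        raise ValueError("gene_ids and labels must align")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene_ids must be unique")
    by_label: dict[object, list[str]] = {}
    for g, y in zip(gene_ids, labels):
        by_label.setdefault(y, []).append(g)
    smallest = min(len(v) for v in by_label.values())
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > smallest:
        raise ValueError(
            f"n_folds={n_folds} exceeds the smaller class size ({smallest} genes)"
        )
    rng = np.random.default_rng(seed)
    fold_order = rng.permutation(n_folds)
    assignment: dict[str, int] = {}
    pointer = 0
    for y in sorted(by_label, key=str):
        genes = np.asarray(by_label[y])
        rng.shuffle(genes)
        for g in genes:
            assignment[str(g)] = int(fold_order[pointer % n_folds])
            pointer += 1
    return CVPlan(n_folds=n_folds, assignment=assignment, seed=seed)
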