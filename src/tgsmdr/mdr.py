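"""Multifactor dimensionality reduction (MDR) epistasis search.

MDR collapses the multilocus genotype table of each candidate attribute
combination into a one-dimensional high-risk/low-risk classifier: a cell is
labelled high-risk when its case:control ratio reaches the cohort ratio in
the training data.  Combinations are compared by balanced classification
accuracy under stratified k-fold cross-validation, and the model selected
most often across folds (the cross-validation consistency, CVC) is reported
together with its mean training and testing balanced accuracies.

Labelling by the training case:control ratio is exactly the rule that
maximises training balanced accuracy over all 2^cells labellings, which is
what makes the exhaustive combination search meaningful for unbalanced
case-control designs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .panel import (
    APOE_EPSILON,
    DEFAULT_PANEL,
    GenotypeRecord,
    apoe_epsilon_category,
    panel_by_name,
)

#: Default attribute set: the seven score components (six three-level SNPs
#: plus binary APOE e4 carrier status).
COMPONENT_ATTRIBUTES = (
    "ANKK1",
    APOE_EPSILON,
    "APOE_rs405509",
    "BDNF_AS",
    "COMT",
    "MAPT",
    "NOS3",
)

#: Alternative set treating rs429358 and rs7412 as separate raw genotypes.
RAW_SNP_ATTRIBUTES = (
    "ANKK1",
    "APOE_rs429358",
    "APOE_rs7412",
    "APOE_rs405509",
    "BDNF_AS",
    "COMT",
    "MAPT",
    "NOS3",
)


@dataclass(frozen=True)
class MdrAttribute:
    """A categorical attribute entering the search (>= 2 observed levels)."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"{self.name}: an MDR attribute needs >= 2 levels")


@dataclass(frozen=True)
class MdrCellTable:
    """Case/control counts and risk labels for one attribute combination.

    ``cells`` maps a tuple of category levels to (cases, controls, label)
    with label in {"high", "low", "empty"}.
    """

    combination: tuple[str, ...]
    threshold: float
    cells: dict[tuple[str, ...], tuple[int, int, str]]


@dataclass(frozen=True)
class MdrModel:
    """A selected attribute combination with cross-validation metrics."""

    combination: tuple[str, ...]
    k: int
    per_fold_selection: tuple[tuple[str, ...], ...]
    mean_training_ba: float
    mean_testing_ba: float
    cvc: int
    folds: int


@dataclass(frozen=True)
class MdrResult:
    best: MdrModel
    by_size: dict[int, MdrModel]
    seed: int
    n_used: int


def attribute_value(record: GenotypeRecord, name: str) -> Optional[str]:
    if name == APOE_EPSILON:
        return apoe_epsilon_category(record)
    return record.call(name)


def _encode(
    records: Sequence[GenotypeRecord],
    attribute_names: Sequence[str],
    case_groups: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, list[MdrAttribute]]:
    """Complete-case integer encoding of the attribute matrix and case vector."""
    raw = []
    y = []
    for r in records:
        vals = [attribute_value(r, a) for a in attribute_names]
        if any(v is None for v in vals):
            continue
        raw.append(vals)
        y.append(r.group in case_groups)
    if not raw:
        raise ValueError("no complete-case records for the requested attributes")
    y_arr = np.asarray(y, dtype=bool)

    attrs: list[MdrAttribute] = []
    cols: list[np.ndarray] = []
    keep: list[int] = []
    for j, name in enumerate(attribute_names):
        column = [row[j] for row in raw]
        levels = tuple(sorted(set(column)))
        if len(levels) < 2:
            warnings.warn(f"attribute {name!r} has a single observed level; excluded")
            continue
        index = {lv: i for i, lv in enumerate(levels)}
        cols.append(np.asarray([index[v] for v in column], dtype=np.int64))
        attrs.append(MdrAttribute(name, levels))
        keep.append(j)
    if not attrs:
        raise ValueError("no attribute has two or more observed levels")
    return np.column_stack(cols), y_arr, attrs


def label_cells(
    cells: dict[tuple[str, ...], tuple[int, int]],
    threshold: float,
    combination: tuple[str, ...] = (),
) -> MdrCellTable:
    """Label multilocus cells high/low risk by their case:control ratio.

    A cell is high-risk iff cases/controls >= threshold (a cell with cases
    but no controls is high); cells with neither cases nor controls are
    labelled ``"empty"`` and treated as low-risk at prediction time.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    labelled = {}
    for key, (cases, controls) in cells.items():
        if cases < 0 or controls < 0:
            raise ValueError("cell counts must be non-negative")
        if cases == 0 and controls == 0:
            label = "empty"
        elif cases >= threshold * controls:
            label = "high"
        else:
            label = "low"
        labelled[key] = (cases, controls, label)
    return MdrCellTable(combination=combination, threshold=threshold, cells=labelled)


def cell_table(
    records: Sequence[GenotypeRecord],
    combination: Sequence[str],
    case_groups: Sequence[str],
    threshold: Optional[float] = None,
) -> MdrCellTable:
    """Build and label the observed cell table for one attribute combination.

    The default threshold is the overall case:control ratio of the records.
    """
    X, y, attrs = _encode(records, list(combination), case_groups)
    if threshold is None:
        n_ctrl = int((~y).sum())
        if n_ctrl == 0:
            raise ValueError("no control records; cannot derive a threshold")
        threshold = float(y.sum()) / n_ctrl
    counts: dict[tuple[str, ...], tuple[int, int]] = {}
    for levels in itertools.product(*(a.levels for a in attrs)):
        counts[levels] = (0, 0)
    for row, is_case in zip(X, y):
        key = tuple(attrs[j].levels[row[j]] for j in range(len(attrs)))
        cases, controls = counts[key]
        counts[key] = (cases + int(is_case), controls + int(not is_case))
    return label_cells(counts, threshold, tuple(a.name for a in attrs))


def _balanced_accuracy(pred: np.ndarray, y: np.ndarray) -> float:
    """Mean of sensitivity and specificity; requires both classes present."""
    n_case = int(y.sum())
    n_ctrl = int((~y).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("balanced accuracy needs both classes")
    sens = float(pred[y].sum()) / n_case
    spec = float((~pred[~y]).sum()) / n_ctrl
    return 0.5 * (sens + spec)


def _fit_high_mask(
    cell_idx: np.ndarray, y: np.ndarray, mask: np.ndarray, n_cells: int
) -> tuple[np.ndarray, np.ndarray]:
    """High-risk mask per cell from a training split; also a seen-cell mask."""
    cases = np.bincount(cell_idx[mask & y], minlength=n_cells)
    controls = np.bincount(cell_idx[mask & ~y], minlength=n_cells)
    n_case = cases.sum()
    n_ctrl = controls.sum()
    if n_ctrl == 0 or n_case == 0:
        raise ValueError("training split must contain both classes")
    threshold = n_case / n_ctrl
    seen = (cases + controls) > 0
    high = (cases >= threshold * controls) & seen
    return high, seen


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    fold_of = np.empty(len(y), dtype=np.int64)
    for cls in (True, False):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % folds
    return fold_of


def mdr_search(
    records: Sequence[GenotypeRecord],
    *,
    case_groups: Sequence[str],
    attributes: Optional[Sequence[str]] = None,
    k_range: Sequence[int] = (1, 2),
    folds: int = 10,
    seed: int = 0,
    empty_cell: str = "low",
) -> MdrResult:
    """Exhaustive MDR search with stratified k-fold cross-validation.

    For every combination of each size in ``k_range``, each training split
    (the other folds) yields a labelled cell table whose training balanced
    accuracy ranks the combinations; the per-fold winner is evaluated on the
    held-out fold.  Per size, the modal winner's cross-validation consistency
    (CVC) is the number of folds that selected it, and its mean training and
    testing balanced accuracies are averaged over all folds.  The final model
    is the per-size candidate with the highest CVC, ties broken by higher
    mean testing balanced accuracy.

    ``folds=1`` disables cross-validation: selection maximises whole-sample
    balanced accuracy and testing accuracy equals training accuracy.

    Parameters
    ----------
    empty_cell
        Prediction for individuals falling in a cell unseen in training:
        ``"low"`` (default) predicts control; ``"abstain"`` excludes them
        from the testing balanced accuracy.
    """
    if folds < 1:
        raise ValueError("folds must be >= 1")
    if empty_cell not in ("low", "abstain"):
        raise ValueError(f"unknown empty-cell policy {empty_cell!r}")
    names = list(attributes if attributes is not None else COMPONENT_ATTRIBUTES)
    X, y, attrs = _encode(records, names, case_groups)
    if int(y.sum()) < 2 or int((~y).sum()) < 2:
        raise ValueError("need at least 2 records per class")
    n = len(y)
    m = len(attrs)
    sizes = sorted(set(k_range))
    if any(k < 1 or k > m for k in sizes):
        raise ValueError(f"combination sizes must lie in 1..{m}")

    rng = np.random.default_rng(seed)
    if folds == 1:
        fold_of = np.zeros(n, dtype=np.int64)
        train_masks = [np.ones(n, dtype=bool)]
        test_masks = [np.ones(n, dtype=bool)]
    else:
        fold_of = _stratified_folds(y, folds, rng)
        train_masks = [fold_of != f for f in range(folds)]
        test_masks = [fold_of == f for f in range(folds)]

    # attribute order / category relabelling invariance: combinations are
    # ranked by name-sorted tuples with deterministic lexicographic tie-break
    order = sorted(range(m), key=lambda j: attrs[j].name)
    n_levels = np.asarray([len(a.levels) for a in attrs])

    combo_cache: dict[tuple[int, ...], tuple[np.ndarray, int]] = {}

    def combo_cells(combo: tuple[int, ...]) -> tuple[np.ndarray, int]:
        if combo not in combo_cache:
            dims = tuple(int(n_levels[j]) for j in combo)
            idx = np.ravel_multi_index(tuple(X[:, j] for j in combo), dims)
            combo_cache[combo] = (idx, int(np.prod(dims)))
        return combo_cache[combo]

    def evaluate(combo: tuple[int, ...], train: np.ndarray, test: np.ndarray):
        idx, n_cells = combo_cells(combo)
        high, seen = _fit_high_mask(idx, y, train, n_cells)
        train_ba = _balanced_accuracy(high[idx[train]], y[train])
        test_idx = idx[test]
        if empty_cell == "abstain":
            keep = seen[test_idx]
            if keep.sum() == 0 or len(set(y[test][keep])) < 2:
                test_ba = float("nan")
            else:
                test_ba = _balanced_accuracy(high[test_idx[keep]], y[test][keep])
        else:
            test_ba = _balanced_accuracy(high[test_idx], y[test])
        return train_ba, test_ba

    by_size: dict[int, MdrModel] = {}
    for k in sizes:
        combos = [
            tuple(sorted(c, key=lambda j: attrs[j].name))
            for c in itertools.combinations(order, k)
        ]
        combos.sort(key=lambda c: tuple(attrs[j].name for j in c))
        winners: list[tuple[int, ...]] = []
        for f in range(len(train_masks)):
            best_combo, best_ba = None, -1.0
            for combo in combos:
                train_ba, _ = evaluate(combo, train_masks[f], test_masks[f])
                if train_ba > best_ba + 1e-12:
                    best_combo, best_ba = combo, train_ba
            winners.append(best_combo)
        # modal winner; ties resolved toward the lexicographically first combo
        tally: dict[tuple[int, ...], int] = {}
        for wsel in winners:
            tally[wsel] = tally.get(wsel, 0) + 1
        max_count = max(tally.values())
        modal = min(
            (c for c, cnt in tally.items() if cnt == max_count),
            key=lambda c: tuple(attrs[j].name for j in c),
        )
        train_bas, test_bas = [], []
        for f in range(len(train_masks)):
            tr, te = evaluate(modal, train_masks[f], test_masks[f])
            train_bas.append(tr)
            test_bas.append(te)
        by_size[k] = MdrModel(
            combination=tuple(attrs[j].name for j in modal),
            k=k,
            per_fold_selection=tuple(
                tuple(attrs[j].name for j in wsel) for wsel in winners
            ),
            mean_training_ba=float(np.mean(train_bas)),
            mean_testing_ba=float(np.nanmean(test_bas)),
            cvc=max_count,
            folds=len(train_masks),
        )

    best = max(by_size.values(), key=lambda mdl: (mdl.cvc, mdl.mean_testing_ba))
    return MdrResult(best=best, by_size=by_size, seed=seed, n_used=n)


# --- carrier combination frequencies ---------------------------------------

@dataclass(frozen=True)
class CombinationFrequency:
    group: str
    n: int  #: individuals with complete calls at every listed locus
    carriers: float  #: carrier count (or combination allele count in allele mode)
    proportion: float
    mode: str


def carrier_combination_frequency(
    records: Sequence[GenotypeRecord],
    pairs: Sequence[tuple[str, str]],
    *,
    mode: str = "carrier",
) -> dict[str, CombinationFrequency]:
    """Per-group frequency of carrying an allele combination.

    An individual is a combination carrier iff they carry at least one copy
    of the listed allele at every listed locus (``mode="carrier"``, the
    default, with individuals as the denominator).  ``mode="allele"`` counts,
    per individual, the largest number of haplotypes that could carry the
    full combination under unknown phase (the minimum per-locus dosage of the
    listed alleles) over a denominator of 2N chromosomes.

    Only individuals with complete calls at all listed loci contribute.
    """
    if mode not in ("carrier", "allele"):
        raise ValueError(f"unknown counting mode {mode!r}")
    by_name = panel_by_name()
    for locus, allele in pairs:
        if locus not in by_name:
            raise ValueError(f"unknown locus {locus!r}")
        if allele not in by_name[locus].alleles:
            raise ValueError(f"{locus}: allele {allele!r} not in {by_name[locus].alleles}")

    out: dict[str, CombinationFrequency] = {}
    grouped: dict[str, list[GenotypeRecord]] = {}
    for r in records:
        grouped.setdefault(r.group, []).append(r)
    for group, recs in grouped.items():
        n = 0
        numer = 0.0
        for r in recs:
            dosages = [r.dosage(locus, allele) for locus, allele in pairs]
            if any(d is None for d in dosages):
                continue
            n += 1
            if mode == "carrier":
                numer += all(d >= 1 for d in dosages)
            else:
                numer += min(dosages)
        denom = n if mode == "carrier" else 2 * n
        out[group] = CombinationFrequency(
            group=group,
            n=n,
            carriers=numer,
            proportion=numer / denom if denom else float("nan"),
            mode=mode,
        )
    return out
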