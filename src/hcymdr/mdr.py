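"""Multifactor dimensionality reduction (MDR) for matched case-control data.

MDR pools the 3^k multilocus genotype cells of a k-marker model into
high- and low-risk classes by comparing each cell's case:control ratio
with a threshold (1 for a 1:1 matched cohort), then scores the pooled
classifier by repeated m-fold cross-validation.  Model selection uses
testing accuracy (TA, mean held-out balanced accuracy) and
cross-validation consistency (CVC, the number of splits in which the
model has the best training accuracy among models of its size).
Significance of the selected model is assessed by permutation of the
case/control labels with the full search re-run on each permuted
dataset, so the null distribution accounts for selection optimism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .genotype_data import MISSING, GenotypeDataset

HIGH, LOW, UNASSIGNED = "high", "low", "unassigned"


class MissingGenotypeError(ValueError):
    """MDR requires a complete matrix; impute first (see impute_mode)."""


class PairingError(ValueError):
    """Paired analysis requested on incompletely paired subjects."""


@dataclass
class MdrConfig:
    """Search and cross-validation settings.

    ``folds`` × ``reps`` fold-evaluations are performed per model
    (10 × 10 = 100 by default).  ``ratio_threshold`` of ``None`` means
    each training split's own case:control ratio (exactly 1 for paired
    data).  ``tie_policy`` labels cells whose ratio equals the threshold;
    ``empty_cell_prediction`` controls how unassigned/unseen cells are
    scored ('low' predicts control, 'exclude' drops the subject from the
    accuracy denominator).
    """

    k_min: int = 1
    k_max: int = 3
    folds: int = 10
    reps: int = 10
    paired: bool = True
    tie_policy: str = UNASSIGNED  # 'high' | 'low' | 'unassigned'
    empty_cell_prediction: str = "low"  # 'low' | 'exclude'
    ratio_threshold: float | None = None
    accuracy: str = "balanced"  # 'balanced' | 'raw'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.tie_policy not in (HIGH, LOW, UNASSIGNED):
            raise ValueError(f"bad tie_policy {self.tie_policy!r}")
        if self.empty_cell_prediction not in ("low", "exclude"):
            raise ValueError(f"bad empty_cell_prediction {self.empty_cell_prediction!r}")
        if self.accuracy not in ("balanced", "raw"):
            raise ValueError(f"bad accuracy {self.accuracy!r}")
        if self.ratio_threshold is not None and self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be positive")

    @property
    def n_splits(self) -> int:
        return self.folds * self.reps


@dataclass(frozen=True)
class CellRisk:
    label: str
    n_case: int
    n_control: int


@dataclass
class RiskModel:
    """A marker subset with per-cell risk labels fitted on training data."""

    markers: tuple[str, ...]
    cells: dict[tuple[int, ...], CellRisk]
    threshold: float

    @property
    def k(self) -> int:
        return len(self.markers)


@dataclass
class ModelEvaluation:
    markers: tuple[str, ...]
    training_accuracy: float
    testing_accuracy: float
    cvc: int
    n_splits: int
    permutation_p: float | None = None
    train_per_split: np.ndarray | None = field(default=None, repr=False)
    test_per_split: np.ndarray | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return len(self.markers)

    @property
    def label(self) -> str:
        return "_".join(self.markers)


@dataclass
class MdrSearchResult:
    evaluations: list[ModelEvaluation]
    best_per_size: dict[int, ModelEvaluation]
    best: ModelEvaluation


@dataclass
class PermutationResult:
    n_permutations: int
    observed_ta: float
    null_tas: np.ndarray
    p_value: float


@dataclass
class RiskCellSummary:
    markers: tuple[str, ...]
    cells: dict[tuple[int, ...], CellRisk]
    high_cases: int
    high_controls: int
    low_cases: int
    low_controls: int
    unassigned_cases: int
    unassigned_controls: int


# ---------------------------------------------------------------------------
# model enumeration and single-split fitting
# ---------------------------------------------------------------------------


def enumerate_models(markers: Sequence[str], k: int) -> list[tuple[str, ...]]:
    """All C(n, k) marker subsets in lexicographic (input) order."""
    if not 1 <= k <= len(markers):
        raise ValueError(f"k={k} out of range for {len(markers)} markers")
    return list(combinations(markers, k))


def _require_complete(ds: GenotypeDataset) -> None:
    if ds.has_missing:
        raise MissingGenotypeError(
            "dataset contains missing genotypes; run impute_mode first"
        )


def _genotype_matrix(ds: GenotypeDataset, markers: Iterable[str]) -> np.ndarray:
    cols = [ds.marker_index(m) for m in markers]
    return ds.calls[:, cols].astype(np.int64)


def fit_risk_model(
    ds: GenotypeDataset, markers: Sequence[str], cfg: MdrConfig | None = None
) -> RiskModel:
    """Label every multilocus genotype cell high/low/unassigned risk.

    A cell is high-risk when its training case:control ratio exceeds the
    threshold, low-risk when below; exact ties follow ``cfg.tie_policy``
    and unobserved cells are unassigned.
    """
    cfg = cfg or MdrConfig()
    _require_complete(ds)
    markers = tuple(markers)
    G = _genotype_matrix(ds, markers)
    y = ds.is_case.astype(np.int64)
    n_case, n_ctrl = int(y.sum()), int((1 - y).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("training data must contain both cases and controls")
    T = cfg.ratio_threshold if cfg.ratio_threshold is not None else n_case / n_ctrl

    k = len(markers)
    idx = np.zeros(len(y), dtype=np.int64)
    for j in range(k):
        idx = idx * 3 + G[:, j]
    counts = np.zeros((3**k, 2), dtype=np.int64)
    np.add.at(counts, (idx, y), 1)

    cells: dict[tuple[int, ...], CellRisk] = {}
    for flat in range(3**k):
        combo = tuple((flat // 3**p) % 3 for p in reversed(range(k)))
        c_ctrl, c_case = int(counts[flat, 0]), int(counts[flat, 1])
        if c_ctrl + c_case == 0:
            label = UNASSIGNED
        elif c_case > T * c_ctrl:
            label = HIGH
        elif c_case < T * c_ctrl:
            label = LOW
        else:
            label = cfg.tie_policy
        cells[combo] = CellRisk(label=label, n_case=c_case, n_control=c_ctrl)
    return RiskModel(markers=markers, cells=cells, threshold=float(T))


def predict(model: RiskModel, ds: GenotypeDataset, cfg: MdrConfig | None = None) -> np.ndarray:
    """Predicted status per subject: 1 = case, 0 = control, -1 = excluded.

    High-risk cells predict case; low-risk cells predict control;
    unassigned cells follow ``cfg.empty_cell_prediction``.
    """
    cfg = cfg or MdrConfig()
    _require_complete(ds)
    G = _genotype_matrix(ds, model.markers)
    out = np.empty(ds.n_subjects, dtype=np.int64)
    for i in range(ds.n_subjects):
        cell = model.cells[tuple(G[i])]
        if cell.label == HIGH:
            out[i] = 1
        elif cell.label == LOW:
            out[i] = 0
        else:
            out[i] = -1 if cfg.empty_cell_prediction == "exclude" else 0
    return out


def balanced_accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    """(sensitivity + specificity) / 2 over non-excluded subjects."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    keep = predicted != -1
    pred, t = predicted[keep], true[keep]
    n_case = int((t == 1).sum())
    n_ctrl = int((t == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("accuracy undefined: need both classes among scored subjects")
    sens = float((pred[t == 1] == 1).sum() / n_case)
    spec = float((pred[t == 0] == 0).sum() / n_ctrl)
    return (sens + spec) / 2


# ---------------------------------------------------------------------------
# cross-validation machinery
# ---------------------------------------------------------------------------


def make_folds(
    ds: GenotypeDataset, cfg: MdrConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """(reps, n_subjects) fold assignments in 0..folds-1.

    In paired mode each case-control pair is kept intact in one fold and
    fold sizes differ by at most one pair, so every fold holds both
    classes in a 1:1 ratio.  Deterministic given (cfg.seed, folds, reps).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = ds.n_subjects
    assign = np.empty((cfg.reps, n), dtype=np.int64)
    if cfg.paired:
        pairs = ds.pairs()  # raises FormatError on orphan subjects
        # ordering by pair id keeps fold assignment invariant under label swaps
        pair_rows = np.array([pairs[pid] for pid in sorted(pairs)])
        n_pairs = len(pair_rows)
        if n_pairs < cfg.folds:
            raise ValueError(f"{n_pairs} pairs cannot fill {cfg.folds} folds")
        for r in range(cfg.reps):
            order = rng.permutation(n_pairs)
            fold_of_pair = np.empty(n_pairs, dtype=np.int64)
            for f, chunk in enumerate(np.array_split(order, cfg.folds)):
                fold_of_pair[chunk] = f
            assign[r, pair_rows[:, 0]] = fold_of_pair
            assign[r, pair_rows[:, 1]] = fold_of_pair
    else:
        if n < cfg.folds:
            raise ValueError(f"{n} subjects cannot fill {cfg.folds} folds")
        for r in range(cfg.reps):
            order = rng.permutation(n)
            for f, chunk in enumerate(np.array_split(order, cfg.folds)):
                assign[r, chunk] = f
    return assign


def _split_accuracies(
    cell_idx: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    n_cells: int,
    cfg: MdrConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Training and testing accuracy per split for one model, vectorized.

    ``cell_idx`` maps subjects to flattened multilocus cells; ``folds``
    is the (reps, n) assignment.  Returns two (reps·folds,) arrays.
    Risk labels depend only on per-cell training counts, so accuracies
    are computed from (split, cell, class) count tensors without
    materializing per-subject predictions.
    """
    R, n = folds.shape
    m = cfg.folds
    S = R * m
    split_of = np.arange(R)[:, None] * m + folds  # (R, n)
    flat = (split_of * n_cells + cell_idx[None, :]) * 2 + y[None, :]
    held = np.bincount(flat.ravel(), minlength=S * n_cells * 2).reshape(S, n_cells, 2)
    totals = held.reshape(R, m, n_cells, 2).sum(axis=1)  # per-rep totals
    train = np.repeat(totals, m, axis=0) - held  # (S, n_cells, 2)

    tc_ctrl = train[:, :, 0]
    tc_case = train[:, :, 1]
    observed = (tc_ctrl + tc_case) > 0
    if cfg.ratio_threshold is None:
        C = tc_case.sum(axis=1, keepdims=True)  # train cases per split
        D = tc_ctrl.sum(axis=1, keepdims=True)
        lhs, rhs = tc_case * D, tc_ctrl * C  # integer cross-multiplication
    else:
        lhs, rhs = tc_case.astype(float), cfg.ratio_threshold * tc_ctrl
    high = observed & (lhs > rhs)
    tie = observed & (lhs == rhs)
    if cfg.tie_policy == HIGH:
        high = high | tie
        unassigned = ~observed
    elif cfg.tie_policy == LOW:
        unassigned = ~observed
    else:
        unassigned = ~observed | tie

    pred_case = high
    excluded = unassigned if cfg.empty_cell_prediction == "exclude" else np.zeros_like(high)
    pred_ctrl = ~pred_case & ~excluded

    def _score(counts: np.ndarray) -> np.ndarray:
        cases = np.where(~excluded, counts[:, :, 1], 0)
        ctrls = np.where(~excluded, counts[:, :, 0], 0)
        tp = np.where(pred_case, counts[:, :, 1], 0).sum(axis=1)
        tn = np.where(pred_ctrl, counts[:, :, 0], 0).sum(axis=1)
        n_case = cases.sum(axis=1)
        n_ctrl = ctrls.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            if cfg.accuracy == "balanced":
                acc = 0.5 * (tp / n_case + tn / n_ctrl)
            else:
                acc = (tp + tn) / (n_case + n_ctrl)
        return acc

    return _score(train), _score(held)


def evaluate_models(ds: GenotypeDataset, cfg: MdrConfig | None = None) -> MdrSearchResult:
    """Exhaustive MDR search over model sizes k_min..k_max.

    For every marker subset and every (rep, fold) split the model is fit
    on the training portion and scored on both portions.  TA is the mean
    held-out accuracy over all splits; CVC counts the splits where the
    model attains the strictly highest training accuracy within its size
    (exact ties go to the lexicographically first subset).  Per-size best
    models maximize CVC then TA; the overall best maximizes TA then CVC
    then parsimony.
    """
    cfg = cfg or MdrConfig()
    _require_complete(ds)
    y = ds.is_case.astype(np.int64)
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError("dataset must contain both cases and controls")
    folds = make_folds(ds, cfg)
    return _search(ds, y, folds, cfg)


def _search(
    ds: GenotypeDataset, y: np.ndarray, folds: np.ndarray, cfg: MdrConfig
) -> MdrSearchResult:
    names = ds.marker_names
    if cfg.k_max > len(names):
        raise ValueError(f"k_max={cfg.k_max} exceeds {len(names)} markers")
    evaluations: list[ModelEvaluation] = []
    best_per_size: dict[int, ModelEvaluation] = {}
    S = cfg.n_splits
    for k in range(cfg.k_min, cfg.k_max + 1):
        subsets = enumerate_models(names, k)
        train_mat = np.empty((len(subsets), S))
        test_mat = np.empty((len(subsets), S))
        for i, subset in enumerate(subsets):
            G = _genotype_matrix(ds, subset)
            idx = np.zeros(len(y), dtype=np.int64)
            for j in range(k):
                idx = idx * 3 + G[:, j]
            train_mat[i], test_mat[i] = _split_accuracies(idx, y, folds, 3**k, cfg)
        # CVC: first-argmax implements the lexicographic tie rule
        winners = np.nanargmax(train_mat, axis=0)
        size_evals = []
        for i, subset in enumerate(subsets):
            ev = ModelEvaluation(
                markers=subset,
                training_accuracy=float(np.nanmean(train_mat[i])),
                testing_accuracy=float(np.nanmean(test_mat[i])),
                cvc=int((winners == i).sum()),
                n_splits=S,
                train_per_split=train_mat[i].copy(),
                test_per_split=test_mat[i].copy(),
            )
            size_evals.append(ev)
        evaluations.extend(size_evals)
        # max() keeps the first (lexicographically earliest) subset on full ties
        best_per_size[k] = max(size_evals, key=lambda e: (e.cvc, e.testing_accuracy))
    best = select_best(list(best_per_size.values()))
    return MdrSearchResult(evaluations=evaluations, best_per_size=best_per_size, best=best)


def select_best(evaluations: Sequence[ModelEvaluation]) -> ModelEvaluation:
    """Overall best: highest TA, then higher CVC, then smaller model size."""
    if not evaluations:
        raise ValueError("no model evaluations to select from")
    return max(evaluations, key=lambda e: (e.testing_accuracy, e.cvc, -e.k))


# ---------------------------------------------------------------------------
# permutation testing
# ---------------------------------------------------------------------------


def permutation_test(
    ds: GenotypeDataset, cfg: MdrConfig | None = None, n_perm: int = 1000
) -> PermutationResult:
    """Permutation P for the best model's testing accuracy.

    Each permutation randomizes case/control labels (in paired mode each
    pair's two labels are swapped independently with probability 1/2,
    preserving the matched design), re-runs the full search over all
    model sizes and records the permuted best TA.  The add-one estimator
    p = (1 + #{null TA >= observed TA}) / (1 + n_perm) is returned.
    """
    cfg = cfg or MdrConfig()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _require_complete(ds)
    observed = evaluate_models(ds, cfg).best.testing_accuracy

    y = ds.is_case.astype(np.int64)
    pair_rows = None
    if cfg.paired:
        pairs = ds.pairs()
        pair_rows = np.array([pairs[pid] for pid in sorted(pairs)])
    null_tas = np.empty(n_perm)
    for b in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, b]))
        y_perm = y.copy()
        if pair_rows is not None:
            swap = rng.random(len(pair_rows)) < 0.5
            ci, qi = pair_rows[swap, 0], pair_rows[swap, 1]
            y_perm[ci], y_perm[qi] = y_perm[qi], y_perm[ci]
        else:
            y_perm = rng.permutation(y)
        perm_ds = _relabel(ds, y_perm)
        fold_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3, b]))
        folds = make_folds(perm_ds, cfg, rng=fold_rng)
        null_tas[b] = _search(perm_ds, y_perm, folds, cfg).best.testing_accuracy

    p = (1 + int((null_tas >= observed).sum())) / (1 + n_perm)
    return PermutationResult(
        n_permutations=n_perm, observed_ta=observed, null_tas=null_tas, p_value=p
    )


def _relabel(ds: GenotypeDataset, y: np.ndarray) -> GenotypeDataset:
    from dataclasses import replace

    subjects = [
        replace(s, status="case" if yi else "control")
        for s, yi in zip(ds.subjects, y)
    ]
    return GenotypeDataset(ds.markers, subjects, ds.calls)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def risk_cell_summary(model: RiskModel, ds: GenotypeDataset) -> RiskCellSummary:
    """Per-cell case/control counts over ``ds`` plus collapsed risk-group totals."""
    _require_complete(ds)
    G = _genotype_matrix(ds, model.markers)
    y = ds.is_case.astype(np.int64)
    k = len(model.markers)
    idx = np.zeros(len(y), dtype=np.int64)
    for j in range(k):
        idx = idx * 3 + G[:, j]
    counts = np.zeros((3**k, 2), dtype=np.int64)
    np.add.at(counts, (idx, y), 1)

    cells: dict[tuple[int, ...], CellRisk] = {}
    totals = {HIGH: [0, 0], LOW: [0, 0], UNASSIGNED: [0, 0]}
    for combo, fitted in model.cells.items():
        flat = 0
        for g in combo:
            flat = flat * 3 + g
        c_ctrl, c_case = int(counts[flat, 0]), int(counts[flat, 1])
        cells[combo] = CellRisk(label=fitted.label, n_case=c_case, n_control=c_ctrl)
        totals[fitted.label][0] += c_case
        totals[fitted.label][1] += c_ctrl
    return RiskCellSummary(
        markers=model.markers,
        cells=cells,
        high_cases=totals[HIGH][0],
        high_controls=totals[HIGH][1],
        low_cases=totals[LOW][0],
        low_controls=totals[LOW][1],
        unassigned_cases=totals[UNASSIGNED][0],
        unassigned_controls=totals[UNASSIGNED][1],
    )
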