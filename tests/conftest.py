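"""Shared builders and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from hcymdr.genotype_data import GenotypeDataset, Marker, Subject


def build_dataset(codes, statuses, pair_ids=None, sexes=None, marker_names=None):
    """GenotypeDataset from a (n_subjects, n_markers) code array."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    marker_names = marker_names or [f"M{j+1}" for j in range(m)]
    markers = [Marker(name, allele_ref="A", allele_alt="B") for name in marker_names]
    subjects = [
        Subject(
            id=f"S{i}",
            status=statuses[i],
            pair_id=None if pair_ids is None else pair_ids[i],
            sex="unknown" if sexes is None else sexes[i],
        )
        for i in range(n)
    ]
    return GenotypeDataset(markers, subjects, codes)


def build_paired_dataset(case_codes, ctrl_codes, marker_names=None):
    """Interleaved case/control pairs from two (n_pairs, n_markers) arrays."""
    case_codes = np.asarray(case_codes, dtype=np.int8)
    ctrl_codes = np.asarray(ctrl_codes, dtype=np.int8)
    n = len(case_codes)
    codes = np.empty((2 * n, case_codes.shape[1]), dtype=np.int8)
    codes[0::2], codes[1::2] = case_codes, ctrl_codes
    statuses = ["case", "control"] * n
    pair_ids = [f"P{i:04d}" for i in range(n) for _ in range(2)]
    return build_dataset(codes, statuses, pair_ids, marker_names=marker_names)


# ---------------------------------------------------------------------------
# oracles, deliberately naive
# ---------------------------------------------------------------------------


def oracle_chi2(table) -> tuple[float, int]:
    """Pearson chi-square by direct summation; drops zero-margin columns."""
    t = np.asarray(table, dtype=float)
    t = t[:, t.sum(axis=0) > 0]
    rows, cols = t.shape
    total = t.sum()
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            e = t[i].sum() * t[:, j].sum() / total
            stat += (t[i, j] - e) ** 2 / e
    return stat, (rows - 1) * (cols - 1)


def oracle_risk_labels(genotypes, y, threshold=1.0, tie_policy="unassigned"):
    """Dict cell-tuple -> label by literal counting; unseen cells absent."""
    cells = {}
    for g, yi in zip(map(tuple, genotypes), y):
        c = cells.setdefault(g, [0, 0])
        c[yi] += 1
    labels = {}
    for g, (n_ctrl, n_case) in cells.items():
        if n_case > threshold * n_ctrl:
            labels[g] = "high"
        elif n_case < threshold * n_ctrl:
            labels[g] = "low"
        else:
            labels[g] = tie_policy
    return labels


def oracle_balanced_accuracy(genotypes, y, labels, empty="low"):
    """Score subjects against a label dict via an explicit confusion matrix."""
    tp = tn = fp = fn = 0
    for g, yi in zip(map(tuple, genotypes), y):
        label = labels.get(g, "unassigned")
        if label == "unassigned" and empty == "exclude":
            continue
        pred = 1 if label == "high" else 0
        if yi == 1 and pred == 1:
            tp += 1
        elif yi == 1:
            fn += 1
        elif pred == 0:
            tn += 1
        else:
            fp += 1
    if tp + fn == 0 or tn + fp == 0:
        return None
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
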