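"""Single-locus case-control association statistics.

Per-marker 2×3 genotype and 2×2 allele contingency tables, Pearson
chi-square tests (no continuity correction), genotype/allele frequencies,
Hardy-Weinberg goodness of fit, and pairwise LD r² screening on the
unphased additive encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_data import MISSING, GenotypeDataset

STATUS_ROWS = ("case", "control")


class DegenerateTableError(ValueError):
    """Contingency table too sparse for the requested test."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Case/control × (hom-ref, het, hom-alt) genotype counts for one marker."""

    marker: str
    stratum_label: str
    counts: np.ndarray  # shape (2, 3), rows = case, control

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (2, 3) or (c < 0).any():
            raise ValueError("counts must be a non-negative 2x3 table")
        object.__setattr__(self, "counts", c)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class AlleleCounts:
    """Case/control × (ref, alt) allele counts (chromosomes, not subjects)."""

    marker: str
    stratum_label: str
    counts: np.ndarray  # shape (2, 2)

    @property
    def row_totals(self) -> np.ndarray:
        return np.asarray(self.counts).sum(axis=1)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    test_name: str


@dataclass(frozen=True)
class HweResult:
    marker: str
    group_label: str
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    p_value: float
    allele_freq: float  # alternate-allele frequency estimate


@dataclass(frozen=True)
class LdResult:
    marker_i: str
    marker_j: str
    r2: float
    n_complete: int


@dataclass
class ScreenResult:
    retained: list[str]
    dropped: list[str]
    flagged_pairs: list[tuple[str, str, float]]
    ld: list[LdResult]


# ---------------------------------------------------------------------------


def tabulate(ds: GenotypeDataset, marker: str, sex_filter: str = "all") -> GenotypeCounts:
    """2×3 case/control genotype table at a marker; missing calls excluded."""
    j = ds.marker_index(marker)
    mask = ds.sex_mask(sex_filter)
    col = ds.calls[:, j]
    case = ds.is_case
    counts = np.zeros((2, 3), dtype=np.int64)
    for r, row_mask in enumerate((case, ~case)):
        sel = col[mask & row_mask]
        sel = sel[sel != MISSING]
        counts[r] = np.bincount(sel, minlength=3)
    return GenotypeCounts(marker=marker, stratum_label=sex_filter, counts=counts)


def genotype_chi2(gc: GenotypeCounts) -> TestResult:
    """Pearson chi-square on the 2×3 genotype table.

    Genotype columns with a zero margin are dropped first, reducing the
    degrees of freedom; no continuity correction is applied.
    """
    table = gc.counts[:, gc.col_totals > 0]
    if table.shape[1] < 2:
        raise DegenerateTableError(
            f"marker {gc.marker}: fewer than two non-empty genotype columns"
        )
    if (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"marker {gc.marker}: empty case or control row")
    statistic, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(statistic), int(dof), float(p), "genotype_chi2")


def to_allele_counts(gc: GenotypeCounts) -> AlleleCounts:
    """Collapse genotype counts to allele counts: ref = 2·hom-ref + het."""
    g = gc.counts
    alleles = np.column_stack([2 * g[:, 0] + g[:, 1], 2 * g[:, 2] + g[:, 1]])
    return AlleleCounts(marker=gc.marker, stratum_label=gc.stratum_label, counts=alleles)


def allele_chi2(ac: AlleleCounts) -> TestResult:
    """Pearson chi-square on the 2×2 allele table, df = 1, no Yates correction."""
    table = np.asarray(ac.counts)
    if (table.sum(axis=0) == 0).any():
        raise DegenerateTableError(f"marker {ac.marker}: monomorphic (one allele column empty)")
    if (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"marker {ac.marker}: empty case or control row")
    statistic, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(statistic), int(dof), float(p), "allele_chi2")


def frequencies(gc: GenotypeCounts) -> dict:
    """Per-row genotype and allele proportions.

    Returns ``{'case': {'genotype': (3,), 'allele': (2,)}, 'control': ...}``
    with proportions in [0, 1]; each vector sums to 1.
    """
    ac = to_allele_counts(gc)
    out = {}
    for r, label in enumerate(STATUS_ROWS):
        n_geno = gc.counts[r].sum()
        n_alle = np.asarray(ac.counts)[r].sum()
        if n_geno == 0:
            raise DegenerateTableError(f"marker {gc.marker}: zero {label} total")
        out[label] = {
            "genotype": gc.counts[r] / n_geno,
            "allele": np.asarray(ac.counts)[r] / n_alle,
        }
    return out


def hwe_test(observed, group_label: str = "", marker: str = "") -> HweResult:
    """1-df chi-square goodness of fit to Hardy-Weinberg proportions.

    ``observed`` is the (hom-ref, het, hom-alt) count triple for one
    group.  The alternate-allele frequency q is estimated from the
    counts and expected counts are n·((1−q)², 2q(1−q), q²).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (3,) or (obs < 0).any():
        raise ValueError("observed must be three non-negative genotype counts")
    n = obs.sum()
    if n == 0:
        raise DegenerateTableError(f"{marker} {group_label}: empty group")
    q = (2 * obs[2] + obs[1]) / (2 * n)
    if q in (0.0, 1.0):
        raise DegenerateTableError(f"{marker} {group_label}: monomorphic, HWE undefined")
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    statistic = float(((obs - expected) ** 2 / expected).sum())
    return HweResult(
        marker=marker,
        group_label=group_label,
        observed=obs,
        expected=expected,
        statistic=statistic,
        df=1,
        p_value=float(stats.chi2.sf(statistic, 1)),
        allele_freq=float(q),
    )


def ld_r2(ds: GenotypeDataset, marker_i: str, marker_j: str) -> LdResult:
    """Genotypic LD r²: squared Pearson correlation of additive encodings.

    Computed over subjects with both calls non-missing (use before
    imputation).  This is the unphased r² PLINK reports without
    haplotype estimation.
    """
    ji, jj = ds.marker_index(marker_i), ds.marker_index(marker_j)
    x, y = ds.calls[:, ji], ds.calls[:, jj]
    complete = (x != MISSING) & (y != MISSING)
    n = int(complete.sum())
    if n < 2:
        raise DegenerateTableError(
            f"{marker_i}/{marker_j}: fewer than 2 complete observations"
        )
    xv, yv = x[complete].astype(float), y[complete].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        raise DegenerateTableError(
            f"{marker_i}/{marker_j}: a marker is monomorphic on the complete subset"
        )
    r = np.corrcoef(xv, yv)[0, 1]
    return LdResult(marker_i=marker_i, marker_j=marker_j, r2=float(r * r), n_complete=n)


def collinearity_screen(ds: GenotypeDataset, threshold: float = 0.85) -> ScreenResult:
    """Flag marker pairs with r² above ``threshold``.

    From each flagged pair the marker with the lower genotyping rate is
    dropped; results list every pairwise r².
    """
    from .genotype_data import genotyping_rate

    names = ds.marker_names
    ld_results: list[LdResult] = []
    flagged: list[tuple[str, str, float]] = []
    dropped: set[str] = set()
    for a, b in combinations(names, 2):
        res = ld_r2(ds, a, b)
        ld_results.append(res)
        if res.r2 > threshold:
            flagged.append((a, b, res.r2))
            rate_a = genotyping_rate(ds, a)
            rate_b = genotyping_rate(ds, b)
            # drop the worse-typed marker; ties drop the later one
            dropped.add(b if rate_b <= rate_a else a)
    retained = [n for n in names if n not in dropped]
    return ScreenResult(
        retained=retained,
        dropped=sorted(dropped),
        flagged_pairs=flagged,
        ld=ld_results,
    )


# ---------------------------------------------------------------------------
# tidy report
# ---------------------------------------------------------------------------


def association_report(ds: GenotypeDataset, by_sex: bool = False) -> pd.DataFrame:
    """One tidy row per marker × stratum with counts, tests, HWE and frequencies."""
    strata = ["all"] + (["male", "female"] if by_sex else [])
    rows = []
    n_tests = len(ds.markers)
    for marker in ds.marker_names:
        for stratum in strata:
            gc = tabulate(ds, marker, sex_filter=stratum)
            ac = to_allele_counts(gc)
            g_test = genotype_chi2(gc)
            a_test = allele_chi2(ac)
            freq = frequencies(gc)
            row = {
                "marker": marker,
                "stratum": stratum,
                "n_case": int(gc.row_totals[0]),
                "n_control": int(gc.row_totals[1]),
                "genotype_chi2": g_test.statistic,
                "genotype_df": g_test.df,
                "genotype_p": g_test.p_value,
                "allele_chi2": a_test.statistic,
                "allele_df": a_test.df,
                "allele_p": a_test.p_value,
                "bonferroni_alpha": 0.05 / n_tests,
            }
            for r, label in enumerate(STATUS_ROWS):
                for gi, gname in enumerate(("hom_ref", "het", "hom_alt")):
                    row[f"{label}_{gname}"] = int(gc.counts[r, gi])
                    row[f"{label}_{gname}_pct"] = 100 * freq[label]["genotype"][gi]
                for ai, aname in enumerate(("ref", "alt")):
                    row[f"{label}_{aname}_allele"] = int(np.asarray(ac.counts)[r, ai])
                    row[f"{label}_{aname}_allele_pct"] = 100 * freq[label]["allele"][ai]
                hwe = hwe_test(gc.counts[r], group_label=label, marker=marker)
                row[f"{label}_hwe_chi2"] = hwe.statistic
                row[f"{label}_hwe_p"] = hwe.p_value
            rows.append(row)
    return pd.DataFrame(rows)
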