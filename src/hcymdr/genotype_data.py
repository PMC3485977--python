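"""Data model and I/O for matched case-control SNP genotype data.

Genotype calls are stored as a subjects × markers matrix of small integer
codes counting copies of the alternate allele: 0 = homozygous reference,
1 = heterozygous, 2 = homozygous alternate, -1 = missing.  Heterozygote
allele strings are unordered on input ("CT" == "TC") and rendered in the
canonical (ref, alt) order on output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: accepted spellings of a missing genotype cell
MISSING_TOKENS = {"NA", "N/A", ".", "", "00", "0 0", "NAN"}

_CASE_SYNONYMS = {"case", "cases", "affected", "2"}
_CONTROL_SYNONYMS = {"control", "controls", "unaffected", "1"}

META_COLUMNS = ("id", "status", "pair_id", "sex", "age")


class FormatError(ValueError):
    """Malformed input table or PED/MAP pair."""


class ImputationError(ValueError):
    """Imputation impossible (e.g. a marker with no observed calls)."""


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP.

    ``allele_ref``/``allele_alt`` are single characters; the alternate
    allele is the one counted by the integer genotype codes.
    """

    name: str
    allele_ref: str
    allele_alt: str
    rs_id: str | None = None
    locus_label: str | None = None

    def __post_init__(self) -> None:
        if self.allele_ref == self.allele_alt:
            raise ValueError(f"marker {self.name}: ref and alt alleles are identical")

    def genotype_string(self, code: int) -> str:
        """Render an integer call as an allele-pair string ('.' if missing)."""
        if code == MISSING:
            return "."
        return {
            0: self.allele_ref * 2,
            1: self.allele_ref + self.allele_alt,
            2: self.allele_alt * 2,
        }[int(code)]


@dataclass(frozen=True)
class Subject:
    id: str
    status: str  # 'case' or 'control'
    pair_id: str | None = None
    sex: str = "unknown"  # 'male' / 'female' / 'unknown'
    age: float | None = None

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValueError(f"subject {self.id}: bad status {self.status!r}")
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"subject {self.id}: bad sex {self.sex!r}")


class GenotypeDataset:
    """Subjects × markers genotype matrix plus subject metadata.

    Parameters
    ----------
    markers
        Ordered marker definitions; names must be unique.
    subjects
        Ordered subjects; ids must be unique.
    calls
        ``(n_subjects, n_markers)`` integer array of codes in
        ``{-1, 0, 1, 2}``.
    """

    def __init__(
        self,
        markers: Sequence[Marker],
        subjects: Sequence[Subject],
        calls: np.ndarray,
    ) -> None:
        self.markers = list(markers)
        self.subjects = list(subjects)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.subjects), len(self.markers)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.markers)} markers"
            )
        if not np.isin(calls, (-1, 0, 1, 2)).all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        self.calls = calls
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise FormatError("duplicate marker names")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate subject ids")
        self._marker_index = {m.name: i for i, m in enumerate(self.markers)}

    # -- basic accessors -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def marker_index(self, name: str) -> int:
        try:
            return self._marker_index[name]
        except KeyError:
            raise KeyError(f"unknown marker {name!r}") from None

    def marker(self, name: str) -> Marker:
        return self.markers[self.marker_index(name)]

    @property
    def is_case(self) -> np.ndarray:
        """Boolean vector, True for cases."""
        return np.array([s.status == "case" for s in self.subjects])

    def sex_mask(self, sex_filter: str) -> np.ndarray:
        if sex_filter == "all":
            return np.ones(self.n_subjects, dtype=bool)
        if sex_filter not in ("male", "female"):
            raise ValueError(f"sex_filter must be all/male/female, got {sex_filter!r}")
        return np.array([s.sex == sex_filter for s in self.subjects])

    @property
    def has_missing(self) -> bool:
        return bool((self.calls == MISSING).any())

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(self.markers, self.subjects, self.calls.copy())

    def pairs(self) -> dict[str, tuple[int, int]]:
        """Map pair_id -> (case row index, control row index).

        Raises ``FormatError`` if any pair is incomplete or overfull.
        """
        by_pair: dict[str, dict[str, int]] = {}
        orphans = []
        for i, s in enumerate(self.subjects):
            if s.pair_id is None:
                orphans.append(s.id)
                continue
            slot = by_pair.setdefault(s.pair_id, {})
            if s.status in slot:
                raise FormatError(f"pair {s.pair_id}: more than one {s.status}")
            slot[s.status] = i
        for pid, slot in by_pair.items():
            if set(slot) != {"case", "control"}:
                orphans.extend(
                    self.subjects[i].id for i in slot.values()
                )
        if orphans:
            raise FormatError(
                "incomplete case-control pairs; orphan subjects: "
                + ", ".join(sorted(orphans))
            )
        return {pid: (slot["case"], slot["control"]) for pid, slot in by_pair.items()}

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view with genotype strings, one row per subject."""
        meta = pd.DataFrame(
            {
                "id": [s.id for s in self.subjects],
                "status": [s.status for s in self.subjects],
                "pair_id": [s.pair_id for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "age": [s.age for s in self.subjects],
            }
        )
        for j, m in enumerate(self.markers):
            meta[m.name] = [m.genotype_string(c) for c in self.calls[:, j]]
        return meta


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _normalize_status(raw: str) -> str:
    token = str(raw).strip().lower()
    if token in _CASE_SYNONYMS:
        return "case"
    if token in _CONTROL_SYNONYMS:
        return "control"
    raise FormatError(f"unrecognized status value {raw!r}")


def _normalize_sex(raw) -> str:
    token = str(raw).strip().lower()
    if token in ("male", "m", "1"):
        return "male"
    if token in ("female", "f", "2"):
        return "female"
    return "unknown"


def _parse_genotype_column(
    cells: Iterable[str], marker_name: str, predefined: Marker | None
) -> tuple[Marker, np.ndarray]:
    """Turn a column of allele-pair strings into a Marker plus codes."""
    pairs: list[tuple[str, str] | None] = []
    for raw in cells:
        token = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
        if token.upper() in MISSING_TOKENS:
            pairs.append(None)
            continue
        alleles = token.replace("/", "").replace(" ", "")
        if len(alleles) != 2:
            raise FormatError(
                f"marker {marker_name}: bad genotype cell {raw!r} (expect two alleles)"
            )
        pairs.append((alleles[0].upper(), alleles[1].upper()))

    observed: dict[str, int] = {}
    for p in pairs:
        if p:
            for a in p:
                observed[a] = observed.get(a, 0) + 1
    if len(observed) > 2:
        raise FormatError(
            f"marker {marker_name}: more than two alleles observed "
            f"({', '.join(sorted(observed))})"
        )

    if predefined is not None:
        ref, alt = predefined.allele_ref, predefined.allele_alt
        unknown = set(observed) - {ref, alt}
        if unknown:
            raise FormatError(
                f"marker {marker_name}: allele(s) {sorted(unknown)} not in "
                f"definition ({ref}/{alt})"
            )
        marker = predefined
    else:
        # ref = major allele; ties broken lexicographically
        ranked = sorted(observed, key=lambda a: (-observed[a], a))
        if len(ranked) == 2:
            ref, alt = ranked
        elif len(ranked) == 1:
            ref, alt = ranked[0], "?"  # monomorphic column, alt unobserved
        else:
            ref, alt = "?", "!"  # all-missing column
        marker = Marker(name=marker_name, allele_ref=ref, allele_alt=alt)

    codes = np.full(len(pairs), MISSING, dtype=np.int8)
    for i, p in enumerate(pairs):
        if p is None:
            continue
        codes[i] = (p[0] == marker.allele_alt) + (p[1] == marker.allele_alt)
    return marker, codes


def read_genotype_table(
    source,
    sep: str | None = None,
    markers: Sequence[Marker] | None = None,
) -> GenotypeDataset:
    """Read a delimited genotype table.

    The header must contain the metadata columns ``id, status, pair_id,
    sex, age`` (``pair_id``/``sex``/``age`` optional) followed by one
    column per marker holding two-character allele strings
    (order-insensitive) or a missing token.  ``markers`` optionally
    supplies predefined allele assignments; otherwise the reference
    allele is inferred as the major allele of the column.
    """
    import csv

    try:
        df = pd.read_csv(source, sep=sep, dtype=str, engine="python", skipinitialspace=True)
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error) as exc:
        raise FormatError(f"unreadable genotype table: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    if "id" not in df.columns or "status" not in df.columns:
        raise FormatError("genotype table must have 'id' and 'status' columns")
    marker_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not marker_cols:
        raise FormatError("genotype table has no marker columns")

    predefined = {m.name: m for m in markers} if markers else {}
    subjects = []
    for _, row in df.iterrows():
        age = row.get("age")
        subjects.append(
            Subject(
                id=str(row["id"]).strip(),
                status=_normalize_status(row["status"]),
                pair_id=(str(row["pair_id"]).strip() if "pair_id" in df.columns and pd.notna(row["pair_id"]) else None),
                sex=_normalize_sex(row["sex"]) if "sex" in df.columns else "unknown",
                age=float(age) if age is not None and pd.notna(age) and str(age).strip() != "" else None,
            )
        )

    parsed_markers, columns = [], []
    for name in marker_cols:
        marker, codes = _parse_genotype_column(df[name], name, predefined.get(name))
        parsed_markers.append(marker)
        columns.append(codes)
    calls = np.column_stack(columns) if columns else np.empty((len(subjects), 0), np.int8)
    return GenotypeDataset(parsed_markers, subjects, calls)


def write_genotype_table(ds: GenotypeDataset, target, sep: str = "\t") -> None:
    """Write a dataset back to the delimited genotype-table format."""
    df = ds.to_dataframe()
    df["pair_id"] = df["pair_id"].fillna("")
    df["age"] = df["age"].map(lambda a: "" if a is None or pd.isna(a) else a)
    df.to_csv(target, sep=sep, index=False)


def read_plink(ped_source, map_source) -> GenotypeDataset:
    """Read whitespace-delimited PLINK PED + MAP files.

    PED columns: FID IID PAT MAT SEX PHENO then two allele columns per
    marker ('0' = missing allele).  PHENO 2 -> case, 1 -> control;
    SEX 1 -> male, 2 -> female; FID is used as the pair id.
    """
    map_df = pd.read_csv(map_source, sep=r"\s+", header=None, dtype=str)
    if map_df.shape[1] < 2:
        raise FormatError("MAP file needs at least chromosome and marker columns")
    marker_names = list(map_df[1])

    ped_df = pd.read_csv(ped_source, sep=r"\s+", header=None, dtype=str)
    expected = 6 + 2 * len(marker_names)
    if ped_df.shape[1] != expected:
        raise FormatError(
            f"PED has {ped_df.shape[1]} columns but MAP defines "
            f"{len(marker_names)} markers (expected {expected})"
        )

    subjects = []
    for _, row in ped_df.iterrows():
        pheno = str(row[5]).strip()
        if pheno == "2":
            status = "case"
        elif pheno == "1":
            status = "control"
        else:
            raise FormatError(f"subject {row[1]}: unsupported phenotype {pheno!r}")
        subjects.append(
            Subject(
                id=str(row[1]),
                status=status,
                pair_id=str(row[0]),
                sex={"1": "male", "2": "female"}.get(str(row[4]).strip(), "unknown"),
            )
        )

    parsed_markers, columns = [], []
    for j, name in enumerate(marker_names):
        a1 = ped_df[6 + 2 * j].astype(str).str.strip()
        a2 = ped_df[7 + 2 * j].astype(str).str.strip()
        cells = [
            "." if "0" in (x, y) else x + y for x, y in zip(a1, a2)
        ]
        marker, codes = _parse_genotype_column(cells, name, None)
        parsed_markers.append(marker)
        columns.append(codes)
    calls = np.column_stack(columns)
    return GenotypeDataset(parsed_markers, subjects, calls)


# ---------------------------------------------------------------------------
# encoding / imputation / rates
# ---------------------------------------------------------------------------


def encode_additive(ds: GenotypeDataset, marker: str, effect_allele: str) -> np.ndarray:
    """Per-subject count of ``effect_allele`` as float (NaN = missing)."""
    j = ds.marker_index(marker)
    m = ds.markers[j]
    codes = ds.calls[:, j].astype(float)
    codes[ds.calls[:, j] == MISSING] = np.nan
    if effect_allele == m.allele_alt:
        return codes
    if effect_allele == m.allele_ref:
        return 2.0 - codes
    raise KeyError(f"allele {effect_allele!r} not present at marker {marker}")


def impute_mode(ds: GenotypeDataset, per_stratum: bool = False) -> GenotypeDataset:
    """Replace missing calls with each marker's most frequent genotype.

    The mode is computed over the whole cohort by default; with
    ``per_stratum=True`` separately within cases and controls.  Ties are
    broken toward the genotype carrying fewer alternate alleles.  Returns
    a new dataset; the input is untouched.
    """
    calls = ds.calls.copy()
    groups: list[np.ndarray]
    if per_stratum:
        case = ds.is_case
        groups = [np.flatnonzero(case), np.flatnonzero(~case)]
    else:
        groups = [np.arange(ds.n_subjects)]
    for j, m in enumerate(ds.markers):
        col_all = ds.calls[:, j]
        if (col_all != MISSING).sum() == 0:
            raise ImputationError(f"marker {m.name}: no observed genotypes to impute from")
        for rows in groups:
            col = col_all[rows]
            observed = col[col != MISSING]
            if observed.size == 0:
                raise ImputationError(
                    f"marker {m.name}: no observed genotypes in stratum to impute from"
                )
            counts = np.bincount(observed, minlength=3)
            mode = int(np.argmax(counts))  # argmax takes the lowest code on ties
            sub = calls[rows, j]
            sub[sub == MISSING] = mode
            calls[rows, j] = sub
    return GenotypeDataset(ds.markers, ds.subjects, calls)


def genotyping_rate(ds: GenotypeDataset, marker: str, stratum: str = "all") -> float:
    """Fraction of non-missing calls at ``marker`` within a stratum."""
    j = ds.marker_index(marker)
    if stratum == "all":
        mask = np.ones(ds.n_subjects, dtype=bool)
    elif stratum in ("case", "control"):
        mask = ds.is_case if stratum == "case" else ~ds.is_case
    else:
        raise ValueError(f"stratum must be case/control/all, got {stratum!r}")
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"empty stratum {stratum!r}: genotyping rate undefined")
    return float((ds.calls[mask, j] != MISSING).sum() / n)
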