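"""Packaged reference cohort: homocysteine-pathway SNPs vs essential hypertension.

``REFERENCE_COUNTS`` holds the per-marker genotype counts of a published
Australian case-control study of essential hypertension (409
hypertensive cases, 409 age/sex-matched normotensive controls; 218
female and 191 male pairs) split by sex, for the four markers MTHFR
C677T, MTHFR A1298C, MTRR A66G and MTHFD1 G1958A.

``reference_cohort()`` synthesizes an individual-level dataset whose
per-marker, per-sex, per-status margins equal those counts exactly.
Only the margins are published: the joint genotype assignment across
markers is an arbitrary deterministic (blockwise) completion, so every
single-locus statistic computed from the cohort is exact while
multi-locus (MDR) output on it is illustrative only.
"""

from __future__ import annotations

import numpy as np

from .genotype_data import MISSING, GenotypeDataset, Marker, Subject

#: number of case-control pairs by sex
N_FEMALE_PAIRS = 218
N_MALE_PAIRS = 191

REFERENCE_MARKERS = [
    Marker("MTHFR677", allele_ref="C", allele_alt="T", rs_id="rs1801133", locus_label="1p36.3"),
    Marker("MTHFR1298", allele_ref="A", allele_alt="C", rs_id="rs1801131", locus_label="1p36.3"),
    Marker("MTRR", allele_ref="A", allele_alt="G", rs_id="rs1801394", locus_label="5p15.31"),
    Marker("MTHFD1", allele_ref="G", allele_alt="A", rs_id="rs2236225", locus_label="14q24"),
]

#: (hom-ref, het, hom-alt) genotype counts per marker, sex and status.
#: Subjects not covered by the triple (group size minus its sum) were not
#: successfully genotyped and appear as missing calls.
REFERENCE_COUNTS: dict[str, dict[tuple[str, str], tuple[int, int, int]]] = {
    "MTHFR677": {
        ("male", "case"): (76, 75, 14),
        ("male", "control"): (73, 93, 17),
        ("female", "case"): (94, 99, 19),
        ("female", "control"): (102, 90, 18),
    },
    "MTHFR1298": {
        ("male", "case"): (77, 68, 23),
        ("male", "control"): (86, 75, 20),
        ("female", "case"): (88, 83, 29),
        ("female", "control"): (76, 98, 31),
    },
    "MTRR": {
        ("male", "case"): (45, 81, 34),
        ("male", "control"): (40, 92, 33),
        ("female", "case"): (58, 111, 31),
        ("female", "control"): (55, 97, 41),
    },
    "MTHFD1": {
        ("male", "case"): (59, 67, 34),
        ("male", "control"): (48, 89, 32),
        ("female", "case"): (60, 101, 43),
        ("female", "control"): (56, 94, 41),
    },
}


def reference_cohort() -> GenotypeDataset:
    """Synthetic individual-level completion of the published margins.

    818 subjects in 409 sex-matched pairs (female pairs first); within
    each (sex, status) group a marker's genotypes are assigned blockwise
    (hom-ref rows, then het, then hom-alt, then missing), independently
    per marker.  Deterministic: repeated calls return identical data.
    """
    subjects: list[Subject] = []
    group_rows: dict[tuple[str, str], list[int]] = {}
    pair = 0
    for sex, n_pairs in (("female", N_FEMALE_PAIRS), ("male", N_MALE_PAIRS)):
        for _ in range(n_pairs):
            pid = f"P{pair:04d}"
            for status, suffix in (("case", "a"), ("control", "b")):
                group_rows.setdefault((sex, status), []).append(len(subjects))
                subjects.append(
                    Subject(id=f"{pid}{suffix}", status=status, pair_id=pid, sex=sex)
                )
            pair += 1

    calls = np.full((len(subjects), len(REFERENCE_MARKERS)), MISSING, dtype=np.int8)
    for j, marker in enumerate(REFERENCE_MARKERS):
        for group, triple in REFERENCE_COUNTS[marker.name].items():
            rows = group_rows[group]
            if sum(triple) > len(rows):
                raise ValueError(f"{marker.name} {group}: counts exceed group size")
            pos = 0
            for code, count in enumerate(triple):
                for _ in range(count):
                    calls[rows[pos], j] = code
                    pos += 1
            # remaining rows stay missing (not successfully genotyped)
    return GenotypeDataset(REFERENCE_MARKERS, subjects, calls)
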