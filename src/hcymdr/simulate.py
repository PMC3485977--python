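"""Synthetic matched case-control cohort generation.

Cohorts mirror the study design the pipeline targets: 1:1 age/sex
matched pairs, biallelic SNPs in Hardy-Weinberg equilibrium at stated
minor-allele frequencies, per-marker missingness, and (optionally) a
two-locus penetrance table that induces an epistatic disease signal.
Markers are simulated without LD and without population structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_data import MISSING, GenotypeDataset, Marker, Subject

#: hard cap on rejection-sampling draws when ascertaining cases/controls
MAX_DRAWS = 1_000_000


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimMarkerSpec:
    name: str
    maf: float  # alternate-allele frequency
    missing_rate: float = 0.0
    allele_ref: str = "A"
    allele_alt: str = "G"

    def __post_init__(self) -> None:
        if not 0 < self.maf < 1:
            raise ValueError(f"marker {self.name}: maf must be in (0,1), got {self.maf}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"marker {self.name}: missing_rate must be in [0,1)")


@dataclass(frozen=True)
class PenetranceModel:
    """3×3 disease probabilities indexed by the additive genotypes of two loci."""

    marker_a: str
    marker_b: str
    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.shape != (3, 3) or (t < 0).any() or (t > 1).any():
            raise ValueError("penetrance table must be 3x3 with entries in [0,1]")
        object.__setattr__(self, "table", t)


@dataclass
class SimConfig:
    n_pairs: int = 409
    markers: list[SimMarkerSpec] = field(default_factory=lambda: default_panel())
    penetrance: PenetranceModel | None = None
    female_pair_fraction: float = 0.533
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.penetrance is not None:
            names = {m.name for m in self.markers}
            for m in (self.penetrance.marker_a, self.penetrance.marker_b):
                if m not in names:
                    raise ValueError(f"penetrance marker {m!r} not in marker panel")


def default_panel(missing: bool = True) -> list[SimMarkerSpec]:
    """Four-marker panel emulating the homocysteine-pathway SNP cohort.

    Alternate-allele frequencies follow the published control group
    (MTHFR C677T 0.322, MTHFR A1298C 0.356, MTRR A66G 0.471, MTHFD1
    G1958A 0.457); missing rates follow the per-marker genotyping
    success of the same cohort.
    """
    rates = (0.059, 0.078, 0.122, 0.115) if missing else (0.0,) * 4
    return [
        SimMarkerSpec("MTHFR677", maf=0.322, missing_rate=rates[0], allele_ref="C", allele_alt="T"),
        SimMarkerSpec("MTHFR1298", maf=0.356, missing_rate=rates[1], allele_ref="A", allele_alt="C"),
        SimMarkerSpec("MTRR", maf=0.471, missing_rate=rates[2], allele_ref="A", allele_alt="G"),
        SimMarkerSpec("MTHFD1", maf=0.457, missing_rate=rates[3], allele_ref="G", allele_alt="A"),
    ]


def xor_penetrance(
    marker_a: str, marker_b: str, high: float = 0.9, low: float = 0.1
) -> PenetranceModel:
    """XOR-style epistasis: elevated risk iff exactly one locus is heterozygous."""
    table = np.full((3, 3), low)
    table[1, :] = high
    table[:, 1] = high
    table[1, 1] = low
    return PenetranceModel(marker_a=marker_a, marker_b=marker_b, table=table)


# ---------------------------------------------------------------------------


def _hwe_probs(maf: float) -> np.ndarray:
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def _draw_genotypes(rng: np.random.Generator, specs, n: int) -> np.ndarray:
    cols = [rng.choice(3, size=n, p=_hwe_probs(s.maf)) for s in specs]
    return np.column_stack(cols).astype(np.int8)


def _assemble(
    cfg: SimConfig,
    rng: np.random.Generator,
    case_calls: np.ndarray,
    ctrl_calls: np.ndarray,
) -> GenotypeDataset:
    """Interleave case/control rows into pairs, apply missingness and metadata."""
    n = cfg.n_pairs
    markers = [
        Marker(name=s.name, allele_ref=s.allele_ref, allele_alt=s.allele_alt)
        for s in cfg.markers
    ]
    calls = np.empty((2 * n, len(cfg.markers)), dtype=np.int8)
    calls[0::2] = case_calls
    calls[1::2] = ctrl_calls
    for j, s in enumerate(cfg.markers):
        if s.missing_rate > 0:
            drop = rng.random(2 * n) < s.missing_rate
            calls[drop, j] = MISSING

    female = rng.random(n) < cfg.female_pair_fraction
    subjects = []
    for p in range(n):
        sex = "female" if female[p] else "male"
        pid = f"P{p:04d}"
        subjects.append(Subject(id=f"{pid}_case", status="case", pair_id=pid, sex=sex))
        subjects.append(Subject(id=f"{pid}_ctrl", status="control", pair_id=pid, sex=sex))
    return GenotypeDataset(markers, subjects, calls)


def simulate_null(cfg: SimConfig) -> GenotypeDataset:
    """Matched cohort with genotypes independent of status (no association)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    case_calls = _draw_genotypes(rng, cfg.markers, cfg.n_pairs)
    ctrl_calls = _draw_genotypes(rng, cfg.markers, cfg.n_pairs)
    return _assemble(cfg, rng, case_calls, ctrl_calls)


def simulate_epistatic(cfg: SimConfig) -> GenotypeDataset:
    """Matched cohort with disease status driven by a two-locus penetrance table.

    Population individuals are drawn under HWE; disease is sampled from
    the penetrance cell of the two interacting loci (all other markers
    neutral); cases and controls are then ascertained by rejection
    sampling until ``n_pairs`` of each are collected.
    """
    if cfg.penetrance is None:
        raise ValueError("simulate_epistatic requires cfg.penetrance")
    pen = cfg.penetrance
    if (pen.table == 0).all() or (pen.table == 1).all():
        raise SimulationError("degenerate penetrance table: cannot form both classes")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 12]))
    names = [s.name for s in cfg.markers]
    ja, jb = names.index(pen.marker_a), names.index(pen.marker_b)

    n = cfg.n_pairs
    cases = np.empty((0, len(cfg.markers)), dtype=np.int8)
    ctrls = np.empty((0, len(cfg.markers)), dtype=np.int8)
    drawn = 0
    batch = max(4 * n, 1000)
    while (len(cases) < n or len(ctrls) < n) and drawn < MAX_DRAWS:
        G = _draw_genotypes(rng, cfg.markers, batch)
        drawn += batch
        f = pen.table[G[:, ja], G[:, jb]]
        affected = rng.random(batch) < f
        cases = np.vstack([cases, G[affected]])
        ctrls = np.vstack([ctrls, G[~affected]])
    if len(cases) < n or len(ctrls) < n:
        raise SimulationError(
            f"could not ascertain {n} cases and controls within {MAX_DRAWS} draws"
        )
    return _assemble(cfg, rng, cases[:n], ctrls[:n])


def expected_cell_ratios(penetrance: PenetranceModel, mafs: tuple[float, float]) -> np.ndarray:
    """Closed-form expected case:control ratio per two-locus cell.

    Under HWE the cell's case prevalence among ascertained cases is
    proportional to P(cell)·f and among controls to P(cell)·(1−f); the
    1:1 ascertainment normalizes by the overall prevalence odds, so
    ratio = [f/(1−f)] / [K/(1−K)] with K the population prevalence.
    Cells with penetrance 1 yield ``inf``.
    """
    pa = _hwe_probs(mafs[0])
    pb = _hwe_probs(mafs[1])
    cell_p = np.outer(pa, pb)
    f = penetrance.table
    K = float((cell_p * f).sum())
    if K in (0.0, 1.0):
        raise SimulationError("degenerate penetrance: population is single-class")
    with np.errstate(divide="ignore"):
        odds = np.where(f < 1, f / (1 - f), np.inf)
    return odds / (K / (1 - K))
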