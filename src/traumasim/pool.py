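"""Reference trauma-case pool, bone-level effective sample sizes, and
generation of once-complete samples with assigned trauma.

The pool holds 40 real-life blunt-force cranial trauma cases (sports
accidents, animal encounters, falls from a height, clinical cases,
projectile/arrow wounds, and interpersonal violence) recorded as 48-element
binary injury vectors. Simulated samples draw cases from this pool uniformly
with replacement, so minor and extensive injury patterns enter samples in
realistic proportion.

Effective sample sizes (ESS) quantify how well each of the 14 cranial bones
is typically represented in a fragmentary archaeological assemblage: counts
of preserved elements per completeness category weighted by the category
scores 0.25 / 0.5 / 0.75 / 1 (Walker's fractional-count approach, applied
per bone). The default fixture emulates an Upper Paleolithic pattern in
which vault bones and the mandible are well represented while nasal and
zygomatic bones are not; it drives the differential element-removal weights
of the missingness simulator.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .anatomy import PRESENT_1, CranialSchema, Specimen

__all__ = [
    "TraumaCase",
    "TraumaPool",
    "BoneESS",
    "POOL_SIZE",
    "effective_sample_size",
    "load_trauma_pool",
    "load_bone_ess",
    "default_pool_path",
    "default_ess_path",
    "generate_sample",
    "generate_state_matrix",
]

POOL_SIZE = 40

#: the six injury-scenario categories of the reference pool
CATEGORIES = frozenset(
    {
        "sports accident",
        "animal encounter",
        "fall from a height",
        "miscellaneous clinical",
        "projectile/arrow shot",
        "violence",
    }
)


@dataclass(frozen=True)
class TraumaCase:
    """One reference injury pattern over the 48 cranial elements."""

    case_id: str
    category: str
    pattern: np.ndarray  # uint8, length 48, 1 = element injured
    n_injured: int

    def validate(self, schema: CranialSchema) -> None:
        if self.pattern.shape != (schema.n_elements,):
            raise ValueError(
                f"case {self.case_id}: pattern length {self.pattern.shape[0]} "
                f"!= {schema.n_elements}"
            )
        total = int(self.pattern.sum())
        if total != self.n_injured:
            raise ValueError(
                f"case {self.case_id}: pattern sums to {total}, "
                f"declared n_injured={self.n_injured}"
            )
        if self.n_injured < 1:
            raise ValueError(f"case {self.case_id}: n_injured must be >= 1")
        if self.category not in CATEGORIES:
            raise ValueError(f"case {self.case_id}: unknown category {self.category!r}")


@dataclass(frozen=True)
class TraumaPool:
    """The 40-case reference pool."""

    cases: tuple[TraumaCase, ...]

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def patterns(self) -> np.ndarray:
        """(40, 48) matrix of injury vectors, row order = fixture order."""
        return np.stack([c.pattern for c in self.cases])

    def validate(self, schema: CranialSchema) -> None:
        if len(self.cases) != POOL_SIZE:
            raise ValueError(f"pool must hold {POOL_SIZE} cases, got {len(self.cases)}")
        for case in self.cases:
            case.validate(schema)


@dataclass(frozen=True)
class BoneESS:
    """Effective sample size per cranial bone (higher = better represented)."""

    ess: dict[str, float]
    source: str = "default"

    def validate(self, schema: CranialSchema) -> None:
        missing = set(schema.bones) - set(self.ess)
        if missing:
            raise ValueError(f"ESS missing for bones: {sorted(missing)}")
        extra = set(self.ess) - set(schema.bones)
        if extra:
            raise ValueError(f"ESS for unknown bones: {sorted(extra)}")
        bad = [b for b, v in self.ess.items() if not v > 0]
        if bad:
            raise ValueError(f"ESS must be > 0, offending bones: {sorted(bad)}")


_ESS_CATEGORIES = (0.25, 0.5, 0.75, 1.0)


def effective_sample_size(counts: dict[float, int]) -> float:
    """Walker-style effective sample size from completeness-category counts.

    ``counts`` maps a completeness category (0.25, 0.5, 0.75 or 1) to the
    number of elements preserved in that category; the ESS is the
    category-weighted sum sum_c count_c * c.
    """
    total = 0.0
    for cat, n in counts.items():
        if cat not in _ESS_CATEGORIES:
            raise ValueError(f"unknown completeness category {cat!r}")
        if n < 0 or int(n) != n:
            raise ValueError(f"count for category {cat} must be a non-negative integer")
        total += n * cat
    return total


def default_pool_path() -> Path:
    """Path of the shipped trauma-pool fixture CSV."""
    return Path(str(resources.files("traumasim").joinpath("data/trauma_pool.csv")))


def default_ess_path() -> Path:
    """Path of the shipped bone-ESS fixture CSV."""
    return Path(str(resources.files("traumasim").joinpath("data/bone_ess.csv")))


def load_trauma_pool(
    schema: CranialSchema, fixture_path: str | Path | None = None
) -> TraumaPool:
    """Load and validate the 40-case trauma pool from a CSV fixture.

    Expected columns: ``case_id, category, n_injured, injured_elements``
    with injured elements given as semicolon-separated element identifiers.
    Raises ``ValueError`` on pool-size, element-name or count mismatches.
    """
    path = Path(fixture_path) if fixture_path is not None else default_pool_path()
    cases: list[TraumaCase] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"case_id", "category", "n_injured", "injured_elements"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"pool fixture must have columns {sorted(required)}")
        for row in reader:
            pattern = np.zeros(schema.n_elements, dtype=np.uint8)
            elements = [e for e in row["injured_elements"].split(";") if e]
            for el in elements:
                try:
                    pattern[schema.index_of(el)] = 1
                except KeyError:
                    raise ValueError(
                        f"case {row['case_id']}: unknown element {el!r}"
                    ) from None
            if len(elements) != len(set(elements)):
                raise ValueError(f"case {row['case_id']}: duplicate elements")
            cases.append(
                TraumaCase(
                    case_id=row["case_id"],
                    category=row["category"],
                    pattern=pattern,
                    n_injured=int(row["n_injured"]),
                )
            )
    pool = TraumaPool(tuple(cases))
    pool.validate(schema)
    return pool


def load_bone_ess(
    schema: CranialSchema, fixture_path: str | Path | None = None
) -> BoneESS:
    """Load and validate per-bone effective sample sizes from a CSV fixture."""
    path = Path(fixture_path) if fixture_path is not None else default_ess_path()
    ess: dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"bone", "ess"} <= set(reader.fieldnames):
            raise ValueError("ESS fixture must have columns ['bone', 'ess']")
        for row in reader:
            ess[row["bone"]] = float(row["ess"])
    out = BoneESS(ess, source=str(path))
    out.validate(schema)
    return out


def generate_state_matrix(
    schema: CranialSchema,
    pool: TraumaPool,
    n: int,
    prevalence: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate a once-complete sample as an (n, 48) int8 state matrix.

    Exactly ``n * prevalence / 100`` specimens (must be an integer) receive a
    trauma pattern drawn uniformly with replacement from the pool; which
    specimens are affected is uniformly random. All other entries are
    PRESENT_0 and no entry is MISSING.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= prevalence <= 100:
        raise ValueError("prevalence must lie in [0, 100]")
    n_trauma_f = n * prevalence / 100.0
    n_trauma = int(round(n_trauma_f))
    if abs(n_trauma_f - n_trauma) > 1e-9:
        raise ValueError(
            f"n * prevalence / 100 = {n_trauma_f} is not an integer; "
            "the affected count is fixed by design"
        )
    states = np.zeros((n, schema.n_elements), dtype=np.int8)
    if n_trauma:
        who = rng.choice(n, size=n_trauma, replace=False)
        which = rng.integers(0, len(pool), size=n_trauma)
        states[who] = (pool.patterns[which] * PRESENT_1).astype(np.int8)
    return states


def generate_sample(
    schema: CranialSchema,
    pool: TraumaPool,
    n: int,
    prevalence: float,
    rng: np.random.Generator,
    sample_label: str = "A",
) -> list[Specimen]:
    """Generate ``n`` once-complete specimens with an exact trauma fraction.

    Thin object view over :func:`generate_state_matrix`; the returned
    specimens share no state with each other.
    """
    states = generate_state_matrix(schema, pool, n, prevalence, rng)
    return [Specimen(row, sample_label=sample_label) for row in states]
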