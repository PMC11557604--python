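"""Cranial recording schema: 48 elements partitioning 14 major bones.

The skull is subdivided into 14 bones — the unpaired frontal and occipital,
and the paired parietal, temporal, maxilla, zygomatic, nasal and mandible.
Each bone is split into four roughly equal regions, except the small nasal
and zygomatic bones which carry two regions each, giving

    10 bones x 4 regions + 4 bones x 2 regions = 48 elements.

Element identifiers are ``<bone>_<region>`` and the ordering is anatomical,
vault first then face then mandible, with left before right throughout:

    frontal, parietal_L, parietal_R, temporal_L, temporal_R, occipital,
    maxilla_L, maxilla_R, zygomatic_L, zygomatic_R, nasal_L, nasal_R,
    mandible_L, mandible_R

Region conventions (used when mapping verbal fracture descriptions onto
elements):

* frontal: 1 left anterior (incl. left sinus), 2 right anterior (incl. right
  sinus), 3 left posterior, 4 right posterior
* parietal L/R: 1 anterior-inferior, 2 anterior-superior, 3
  posterior-inferior, 4 posterior-superior
* temporal L/R: 1 squama (incl. glenoid fossa), 2 mastoid, 3 petrous,
  4 zygomatic process / tympanic
* occipital: 1 left squama, 2 right squama, 3 superior squama, 4 basilar
  (foramen magnum and condyles)
* maxilla L/R: 1 frontal process / anterior sinus wall, 2 alveolar process,
  3 palatine process, 4 zygomatic process
* zygomatic L/R: 1 body (zygoma), 2 arch (temporal process)
* nasal L/R: 1 proximal, 2 distal
* mandible L/R: 1 body, 2 angle, 3 ramus, 4 condyle / subcondylar area

Per-element state codes used throughout the package:
``MISSING = -1``, ``PRESENT_0 = 0`` (preserved, no trauma), ``PRESENT_1 = 1``
(preserved, traumatized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MISSING",
    "PRESENT_0",
    "PRESENT_1",
    "N_ELEMENTS",
    "BONES",
    "REGIONS_PER_BONE",
    "CranialSchema",
    "Specimen",
    "build_schema",
]

MISSING: int = -1
PRESENT_0: int = 0
PRESENT_1: int = 1

N_ELEMENTS: int = 48

#: the 14 bones in canonical order (left before right)
BONES: tuple[str, ...] = (
    "frontal",
    "parietal_L",
    "parietal_R",
    "temporal_L",
    "temporal_R",
    "occipital",
    "maxilla_L",
    "maxilla_R",
    "zygomatic_L",
    "zygomatic_R",
    "nasal_L",
    "nasal_R",
    "mandible_L",
    "mandible_R",
)

#: number of recording regions per bone (2 for the small nasal and zygomatic)
REGIONS_PER_BONE: dict[str, int] = {
    bone: (2 if bone.startswith(("nasal", "zygomatic")) else 4) for bone in BONES
}


@dataclass(frozen=True)
class CranialSchema:
    """Ordered 48-element recording scheme over 14 cranial bones."""

    elements: tuple[str, ...]
    bone_of: dict[str, str]
    regions_per_bone: dict[str, int]
    _index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {e: i for i, e in enumerate(self.elements)}
        )

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def bones(self) -> tuple[str, ...]:
        return tuple(self.regions_per_bone)

    def index_of(self, element: str) -> int:
        """Position of ``element`` in the canonical ordering."""
        return self._index[element]

    def elements_of(self, bone: str) -> tuple[str, ...]:
        """All elements belonging to ``bone``, in order."""
        return tuple(e for e in self.elements if self.bone_of[e] == bone)

    def bone_index(self) -> np.ndarray:
        """Integer bone id per element (index into :attr:`bones`)."""
        order = {b: i for i, b in enumerate(self.bones)}
        return np.array([order[self.bone_of[e]] for e in self.elements])

    def validate(self) -> None:
        """Raise ``ValueError`` if any structural invariant is violated."""
        if len(self.elements) != N_ELEMENTS:
            raise ValueError(f"expected {N_ELEMENTS} elements, got {len(self.elements)}")
        if len(self.regions_per_bone) != 14:
            raise ValueError("expected 14 bones")
        if len(set(self.elements)) != len(self.elements):
            raise ValueError("duplicate element identifiers")
        for bone, k in self.regions_per_bone.items():
            n = sum(1 for e in self.elements if self.bone_of[e] == bone)
            if n != k:
                raise ValueError(f"bone {bone}: {n} elements, declared {k}")
        counts = sorted(self.regions_per_bone.values())
        if counts != [2] * 4 + [4] * 10:
            raise ValueError("region counts must be 4 per bone, 2 for nasal/zygomatic")


def build_schema() -> CranialSchema:
    """Construct the canonical 48-element cranial schema.

    Deterministic: element order is the bone order of :data:`BONES` with
    region numbers ascending within each bone.
    """
    elements: list[str] = []
    bone_of: dict[str, str] = {}
    for bone in BONES:
        for region in range(1, REGIONS_PER_BONE[bone] + 1):
            name = f"{bone}_{region}"
            elements.append(name)
            bone_of[name] = bone
    schema = CranialSchema(tuple(elements), bone_of, dict(REGIONS_PER_BONE))
    schema.validate()
    return schema


@dataclass
class Specimen:
    """One simulated cranium: a per-element state vector plus sample label.

    ``state`` is an int8 vector of length 48 over {MISSING, PRESENT_0,
    PRESENT_1}. A freshly generated specimen has no MISSING entries.
    """

    state: np.ndarray
    sample_label: str = "A"

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.int8)
        if self.state.shape != (N_ELEMENTS,):
            raise ValueError(f"state must have length {N_ELEMENTS}")

    @property
    def completeness(self) -> float:
        """Percentage of the 48 elements that are preserved."""
        return 100.0 * float(np.count_nonzero(self.state != MISSING)) / N_ELEMENTS

    @property
    def has_trauma(self) -> bool:
        """True if any preserved element carries a trauma score of 1."""
        return bool(np.any(self.state == PRESENT_1))
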