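"""Per-specimen missing-data simulator.

Each specimen loses a random fraction of its 48 recording elements. The
fraction is drawn from a normal distribution (mean = scenario level, sd = 20
percentage points by default) and clipped to [0, 100]; the clipped percent
is converted to an integer element count with half-away-from-zero rounding.
Which elements are removed is decided by weighted sampling without
replacement, with per-element weights inversely related to the bone's
effective sample size, so that bones that are typically poorly represented
in the archaeological record (nasal, zygomatic) lose elements more readily
than well-represented ones (vault bones, mandible).

The without-replacement scheme is successive weighted draws with
renormalization after each draw. It is implemented through exponential race
keys (draw key_i ~ Exponential(rate=w_i) and remove the elements with the
smallest keys), which is distributionally identical to the successive-draw
process and vectorizes over whole samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .anatomy import MISSING, N_ELEMENTS, PRESENT_1, CranialSchema, Specimen
from .pool import BoneESS

__all__ = [
    "MissingnessConfig",
    "draw_missing_count",
    "draw_missing_counts",
    "element_removal_weights",
    "weight_array",
    "allocate_missing",
    "sample_without_replacement",
    "apply_missingness",
    "summarize_specimen",
    "summarize_states",
    "prob_completeness_at_least",
]


@dataclass
class MissingnessConfig:
    """Scenario parameters for the clipped-normal missingness draw.

    mean_pct: average percentage of elements lost (20/40/60/80 in the
        factorial experiment; any value in [0, 100] is allowed).
    sd_pct: standard deviation of the normal draw, in percentage points.
    weights: per-element removal weight (positive; need not be normalized).
    """

    mean_pct: float
    sd_pct: float = 20.0
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.mean_pct <= 100:
            raise ValueError("mean_pct must lie in [0, 100]")
        if self.sd_pct < 0:
            raise ValueError("sd_pct must be >= 0")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all removal weights must be > 0")


def _round_half_away(x: np.ndarray | float) -> np.ndarray | int:
    # np.round rounds half to even; elements are atomic so we commit to
    # half-away-from-zero (x >= 0 here).
    return np.floor(np.asarray(x) + 0.5).astype(int)


def draw_missing_counts(
    cfg: MissingnessConfig, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Vectorized clipped-normal draw of per-specimen missing-element counts."""
    if cfg.sd_pct == 0:
        pct = np.full(size, float(cfg.mean_pct))
    else:
        pct = rng.normal(cfg.mean_pct, cfg.sd_pct, size=size)
    pct = np.clip(pct, 0.0, 100.0)
    counts = _round_half_away(pct / 100.0 * N_ELEMENTS)
    return np.minimum(counts, N_ELEMENTS)


def draw_missing_count(cfg: MissingnessConfig, rng: np.random.Generator) -> int:
    """Number of elements (0..48) to delete for one specimen."""
    return int(draw_missing_counts(cfg, rng, 1)[0])


_TRANSFORMS = ("inverse", "max_minus", "rank")


def element_removal_weights(
    schema: CranialSchema, bone_ess: BoneESS, transform: str = "inverse"
) -> dict[str, float]:
    """Per-element removal weights from bone-level effective sample sizes.

    All elements of a bone share that bone's weight; the map is normalized
    to sum to one. Transforms (all monotone decreasing in ESS):

    * ``inverse`` (default): weight proportional to 1/ess
    * ``max_minus``: proportional to max(ess) - ess + epsilon
    * ``rank``: proportional to the descending rank of ess (ties averaged)
    """
    bone_ess.validate(schema)
    ess = np.array([bone_ess.ess[b] for b in schema.bones], dtype=float)
    if transform == "inverse":
        raw = 1.0 / ess
    elif transform == "max_minus":
        eps = 0.05 * ess.max()
        raw = ess.max() - ess + eps
    elif transform == "rank":
        raw = stats.rankdata(-ess, method="average")
    else:
        raise ValueError(f"unknown transform {transform!r}; choose from {_TRANSFORMS}")
    per_bone = dict(zip(schema.bones, raw))
    w = np.array([per_bone[schema.bone_of[e]] for e in schema.elements])
    w = w / w.sum()
    return dict(zip(schema.elements, w))


def weight_array(schema: CranialSchema, weights: dict[str, float]) -> np.ndarray:
    """Weights as a length-48 array in canonical element order."""
    missing = set(schema.elements) - set(weights)
    if missing:
        raise ValueError(f"weights missing for elements: {sorted(missing)[:3]}...")
    w = np.array([float(weights[e]) for e in schema.elements])
    if np.any(w <= 0):
        raise ValueError("all removal weights must be > 0")
    return w


def _removal_mask(
    w: np.ndarray, counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n, len(w)) mask of elements to delete; row i has counts[i]
    Trues.

    Exponential race: key_i ~ Exp(w_i); removing the ``count`` smallest keys
    reproduces successive weighted draws without replacement.
    """
    n, m = counts.shape[0], w.shape[0]
    keys = rng.exponential(size=(n, m)) / w
    order = np.argsort(keys, axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(m)[None, :], axis=1)
    return ranks < counts[:, None]


def sample_without_replacement(
    weights: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of ``count`` items drawn without replacement with probability
    proportional to ``weights`` (successive draws with renormalization,
    realized via exponential race keys). Works for any number of items."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    if not 0 <= count <= w.size:
        raise ValueError(f"count must lie in [0, {w.size}]")
    mask = _removal_mask(w, np.array([count]), rng)[0]
    return np.flatnonzero(mask)


def allocate_missing(
    specimen: Specimen,
    count: int,
    weights: dict[str, float] | np.ndarray,
    rng: np.random.Generator,
    schema: CranialSchema | None = None,
) -> Specimen:
    """Delete exactly ``count`` elements from a specimen by weighted
    sampling without replacement; surviving elements keep their trauma state
    (a multi-element fracture can survive partially).
    """
    if not 0 <= count <= N_ELEMENTS:
        raise ValueError(f"count must lie in [0, {N_ELEMENTS}]")
    if isinstance(weights, dict):
        if schema is None:
            raise ValueError("schema required when weights are given as a dict")
        w = weight_array(schema, weights)
    else:
        w = np.asarray(weights, dtype=float)
    state = specimen.state.copy()
    if count:
        mask = _removal_mask(w, np.array([count]), rng)[0]
        state[mask] = MISSING
    return Specimen(state, sample_label=specimen.sample_label)


def apply_missingness(
    states: np.ndarray,
    cfg: MissingnessConfig,
    w: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized missingness for a whole (n, 48) sample matrix.

    Draws one clipped-normal count per specimen, then removes that many
    elements by the same exponential-race scheme as :func:`allocate_missing`.
    Returns a new matrix.
    """
    out = states.copy()
    counts = draw_missing_counts(cfg, rng, states.shape[0])
    mask = _removal_mask(w, counts, rng)
    out[mask] = MISSING
    return out


def summarize_specimen(specimen: Specimen) -> tuple[float, int]:
    """(completeness %, trauma 0/1) summary of one specimen.

    A 0%-complete specimen has no observable elements, hence trauma = 0.
    """
    return specimen.completeness, int(specimen.has_trauma)


def summarize_states(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized summary: per-row completeness % and trauma indicator."""
    completeness = 100.0 * np.count_nonzero(states != MISSING, axis=1) / N_ELEMENTS
    trauma = np.any(states == PRESENT_1, axis=1).astype(int)
    return completeness, trauma


def prob_completeness_at_least(
    threshold: float, mean_pct: float, sd_pct: float
) -> float:
    """Closed-form probability that a specimen survives a completeness
    threshold under the clipped-normal missingness process.

    Completeness >= threshold iff the rounded missing-element count is at
    most k = floor(48 * (100 - threshold) / 100), i.e. iff the raw normal
    percent draw falls below (k + 0.5) * 100 / 48 (clipping at 0 only adds
    mass to count 0, which always passes for threshold <= 100).
    """
    k = int(np.floor(N_ELEMENTS * (100.0 - threshold) / 100.0))
    if k >= N_ELEMENTS:
        return 1.0
    cut = (k + 0.5) * 100.0 / N_ELEMENTS
    if sd_pct == 0:
        return float(mean_pct < cut)
    return float(stats.norm.cdf((cut - mean_pct) / sd_pct))
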