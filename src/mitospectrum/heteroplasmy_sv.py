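"""Heteroplasmy classification and read-depth SV frequency estimation.

A variant with within-isolate frequency in [0.03, 0.97] (inclusive) is
heteroplasmic; below is homoplasmic-ancestral, above homoplasmic-derived.

Large deletions and duplications are quantified from per-position read
depth on the circular reference: the focal isolate's mean depth inside the
variant relative to outside is divided by the same ratio averaged over a
cohort of SV-free isolates, giving a relative depth rho; the heteroplasmic
frequency is 1 - rho for deletions and rho - 1 for duplications (clipped to
[0, 1]).  A hypervariable control region is masked from all means, and
variants spanning the mask are computed separately on each side and
averaged.  The reference can be rotated so origin-spanning variants become
contiguous; rotation and direct circular computation agree exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .mito_model import CircularGenome, GeneAnnotation

HET_LOW = 0.03
HET_HIGH = 0.97


def classify_heteroplasmy(frequency: float, low: float = HET_LOW,
                          high: float = HET_HIGH) -> str:
    """heteroplasmic / homoplasmic-ancestral / homoplasmic-derived.

    Boundaries are inclusive: exactly ``low`` or ``high`` is heteroplasmic.
    """
    if not 0.0 <= frequency <= 1.0:
        raise ValueError(f"frequency {frequency} outside [0, 1]")
    if frequency < low:
        return "homoplasmic-ancestral"
    if frequency > high:
        return "homoplasmic-derived"
    return "heteroplasmic"


@dataclass
class DepthProfile:
    """Per-position read depth for one isolate on the circular reference."""
    isolate: str
    depth: np.ndarray
    masks: list[tuple[int, int]] = field(default_factory=list)  # 1-based inclusive

    def __post_init__(self):
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("negative depth")
        L = len(self.depth)
        for s, e in self.masks:
            if not (1 <= s <= L and 1 <= e <= L):
                raise ValueError(f"mask ({s}, {e}) outside [1, {L}]")

    def __len__(self) -> int:
        return len(self.depth)

    def mask_index(self) -> np.ndarray:
        m = np.zeros(len(self.depth), dtype=bool)
        for s, e in self.masks:
            m[_circular_index(s, e, len(self.depth))] = True
        return m


@dataclass(frozen=True)
class SVCall:
    """One structural-variant call with its estimated frequency."""
    isolate: str
    kind: str                    # deletion | duplication
    start: int                   # 1-based inclusive; start > end wraps origin
    end: int
    frequency: float
    genes: tuple[str, ...] = ()

    def size(self, L: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return L - self.start + 1 + self.end


def _circular_index(start: int, end: int, L: int) -> np.ndarray:
    if start <= end:
        return np.arange(start - 1, end)
    return np.concatenate([np.arange(start - 1, L), np.arange(0, end)])


# -- reference rotation ------------------------------------------------------

def rotate_reference(genome: CircularGenome, new_origin: int
                     ) -> tuple[CircularGenome, "CoordinateMap"]:
    """Rotate the circle so ``new_origin`` becomes position 1.

    Annotations are remapped (wrapping features stay wrapping); the
    returned coordinate map is invertible.
    """
    L = len(genome)
    if not 1 <= new_origin <= L:
        raise IndexError(f"new origin {new_origin} outside [1, {L}]")
    cmap = CoordinateMap(offset=new_origin - 1, length=L)
    seq = genome.sequence[new_origin - 1:] + genome.sequence[:new_origin - 1]
    anns = [replace(a, start=cmap.forward(a.start), end=cmap.forward(a.end))
            for a in genome.annotations]
    rotated = CircularGenome(sequence=seq, annotations=anns,
                             code_id=genome.code_id,
                             name=f"{genome.name}|rot{new_origin}")
    return rotated, cmap


@dataclass(frozen=True)
class CoordinateMap:
    """1-based circular coordinate shift by ``offset`` positions."""
    offset: int
    length: int

    def forward(self, position: int) -> int:
        return (position - 1 - self.offset) % self.length + 1

    def backward(self, position: int) -> int:
        return (position - 1 + self.offset) % self.length + 1


# -- SV frequency -------------------------------------------------------------

def _region_ratio(profile: DepthProfile, inside: np.ndarray,
                  region: Optional[np.ndarray] = None) -> float:
    """Mean depth inside / outside over unmasked positions.

    ``inside`` may be one unmasked arc of a larger variant ``region``; the
    outside mean always excludes the whole region, never just the arc.
    """
    masked = profile.mask_index()
    inside_mask = np.zeros(len(profile), dtype=bool)
    inside_mask[inside] = True
    region_mask = inside_mask.copy()
    if region is not None:
        region_mask[region] = True
    use_in = inside_mask & ~masked
    use_out = ~region_mask & ~masked
    if not use_in.any():
        raise ValueError("variant region fully masked")
    if not use_out.any():
        raise ValueError("no unmasked positions outside the variant")
    mean_in = profile.depth[use_in].mean()
    mean_out = profile.depth[use_out].mean()
    if mean_out == 0:
        return math.inf if mean_in else math.nan
    return float(mean_in / mean_out)


def _split_at_mask(inside: np.ndarray, masked: np.ndarray) -> list[np.ndarray]:
    """Split a circular index set into contiguous unmasked runs.

    Runs are contiguous in the *ordered traversal* of the variant region,
    so a variant spanning the mask yields its upstream and downstream arcs.
    """
    keep = ~masked[inside]
    runs = []
    cur = []
    for idx, ok in zip(inside, keep):
        if ok:
            cur.append(idx)
        elif cur:
            runs.append(np.array(cur))
            cur = []
    if cur:
        runs.append(np.array(cur))
    return runs


def sv_frequency(profile: DepthProfile, kind: str, start: int, end: int,
                 cohort: Sequence[DepthProfile],
                 pool_cohort_depths: bool = False) -> float:
    """Read-depth heteroplasmic frequency of one deletion or duplication.

    rho = (focal inside/outside depth ratio) / (cohort baseline ratio);
    frequency = 1 - rho for deletions, rho - 1 for duplications, clipped to
    [0, 1].  The cohort baseline is the mean of per-isolate ratios by
    default; ``pool_cohort_depths`` sums cohort depths first instead.  When
    the variant spans the masked region, each unmasked arc is evaluated
    separately and the arc frequencies averaged.
    """
    if kind not in ("deletion", "duplication"):
        raise ValueError(f"unknown SV type {kind!r}")
    if not cohort:
        raise ValueError("empty cohort")
    L = len(profile)
    inside = _circular_index(start, end, L)
    masked = profile.mask_index()
    arcs = _split_at_mask(inside, masked)
    if not arcs:
        raise ValueError("variant region fully masked")

    freqs = []
    for arc in arcs:
        r_focal = _region_ratio(profile, arc, region=inside)
        if pool_cohort_depths:
            pooled = DepthProfile(
                isolate="pooled",
                depth=np.sum([c.depth for c in cohort], axis=0),
                masks=profile.masks)
            r_base = _region_ratio(pooled, arc, region=inside)
        else:
            r_base = float(np.mean([_region_ratio(c, arc, region=inside)
                                    for c in cohort]))
        rho = r_focal / r_base
        f = 1.0 - rho if kind == "deletion" else rho - 1.0
        freqs.append(min(1.0, max(0.0, f)))
    return float(np.mean(freqs))


# -- frequency distributions ---------------------------------------------------

def frequency_histogram(frequencies: Sequence[float], bins: int = 20
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-width histogram of variant frequencies over [0, 1]."""
    f = np.asarray(frequencies, dtype=float)
    if f.size and ((f < 0) | (f > 1)).any():
        raise ValueError("frequencies outside [0, 1]")
    return np.histogram(f, bins=bins, range=(0.0, 1.0))


def mann_whitney_z(sample_a: Sequence[float], sample_b: Sequence[float]
                   ) -> tuple[float, float, float]:
    """Mann-Whitney U with the tie-corrected normal approximation.

    Returns (U of the first sample, z, two-sided p).  This is the
    large-sample form used when comparing frequency distributions between
    variant classes.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    U1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 == 0:
        return float(U1), 0.0, 1.0
    z = (U1 - mu) / math.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(U1), float(z), float(min(1.0, p))
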