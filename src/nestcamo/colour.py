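"""Receptor-noise colour discrimination and colour-pattern clustering.

Colour distances are just-noticeable differences (JNDs) under the
receptor-noise-limited model: discrimination of two stimuli is limited by
independent noise in each receptor channel, with channel noise (the Weber
fraction ω) set by receptor abundance. Scenes are reduced to a palette of
dominant colours by a two-stage clustering — a strict local threshold that
clumps smooth gradients, then a looser global threshold that links
disconnected patches of the same colour — and background matching is
summarized by the JND from the most abundant target colour to the closest
and to the coverage-weighted mean background colour.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .vision import ConeCatchImage

__all__ = [
    "WeberSet",
    "ColourCluster",
    "ColourMatchResult",
    "weber_fractions",
    "jnd_distance",
    "cluster_colours",
    "colour_match_metrics",
]

BASE_NOISE = 0.05


@dataclass
class WeberSet:
    """Per-receptor Weber fractions, shortest to longest wavelength."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if np.any(self.omega <= 0):
            raise ValueError("Weber fractions must be positive")

    def __len__(self) -> int:
        return self.omega.size


def weber_fractions(cone_ratio, base_noise: float = BASE_NOISE) -> WeberSet:
    """Weber fractions from relative receptor abundances.

    The most abundant receptor class gets ω equal to ``base_noise``
    (default 0.05); rarer classes are noisier following the square-root
    noise-pooling rule ω_i = base_noise · √(η_max / η_i). E.g. the ferret's
    1:14 S:L ratio gives ω = (0.05·√14, 0.05) ≈ (0.187, 0.05).
    """
    eta = np.asarray(list(cone_ratio.values())
                     if isinstance(cone_ratio, dict) else cone_ratio,
                     dtype=float)
    if np.any(eta <= 0):
        raise ValueError("cone abundances must be positive")
    return WeberSet(base_noise * np.sqrt(eta.max() / eta))


def _jnd_from_delta(delta_f: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Receptor-noise distance for log-catch contrasts Δf (…, n).

    General n-receptor quadratic form (n ≥ 2), which reduces to
    |Δf₁ − Δf₂| / √(ω₁² + ω₂²) for a dichromat and to the standard tri-
    and tetrachromatic expressions:

        ΔS² = Σ_{i<j} [Π_{k∉{i,j}} ω_k²] (Δf_i − Δf_j)²
              / Σ_i [Π_{k≠i} ω_k²]
    """
    delta_f = np.asarray(delta_f, dtype=float)
    n = omega.size
    e = omega ** 2
    prod_all = np.prod(e)
    num = np.zeros(delta_f.shape[:-1])
    for i in range(n):
        for j in range(i + 1, n):
            num = num + (prod_all / (e[i] * e[j])) * (
                delta_f[..., i] - delta_f[..., j]) ** 2
    den = np.sum(prod_all / e)
    return np.sqrt(num / den)


def jnd_distance(catch_a, catch_b, weber: WeberSet) -> float:
    """JND between two cone-catch vectors.

    Δf_i = ln(catch_a,i / catch_b,i); invariant under a common positive
    scaling of both stimuli, and a metric on log-catch space.
    """
    a = np.asarray(catch_a, dtype=float)
    b = np.asarray(catch_b, dtype=float)
    if a.shape != b.shape or a.size != len(weber):
        raise ValueError("catch vectors must match the Weber set length")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("quantum catches must be positive")
    return float(_jnd_from_delta(np.log(a) - np.log(b), weber.omega))


@dataclass
class ColourCluster:
    """One dominant scene colour: its mean cone catch, the fraction of the
    analysed region it covers, and its pixel count."""

    mean_catch: np.ndarray
    coverage: float
    n_pixels: int

    def __post_init__(self) -> None:
        self.mean_catch = np.asarray(self.mean_catch, dtype=float)
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must lie in (0, 1]")


@dataclass
class ColourMatchResult:
    """Background colour-match summary for one target region.

    ``best_jnd``: distance from the most abundant target colour to the
    closest background colour. ``mean_jnd``: coverage-weighted mean
    distance to all background colours (weights renormalized over the
    colours found). best ≤ mean always.
    """

    best_jnd: float
    mean_jnd: float


class _Cluster:
    __slots__ = ("log_sum", "count", "order")

    def __init__(self, order: int, n_receptors: int):
        self.log_sum = np.zeros(n_receptors)
        self.count = 0
        self.order = order

    @property
    def mean_log(self) -> np.ndarray:
        return self.log_sum / self.count

    def add(self, log_catch: np.ndarray) -> None:
        self.log_sum += log_catch
        self.count += 1

    def absorb(self, other: "_Cluster") -> None:
        self.log_sum += other.log_sum
        self.count += other.count


def cluster_colours(cone: ConeCatchImage, mask, weber: WeberSet,
                    local_thresh: float = 0.05,
                    global_thresh: float = 1.0,
                    max_colours: int = 32,
                    coverage_stop: float = 0.99,
                    local_compare: str = "pixel") -> list[ColourCluster]:
    """Reduce a masked cone-catch region to its dominant colours.

    Stage 1 (local, default 0.05 JND): region growing with 4-connectivity
    in row-major scan order; a pixel joins the growing cluster if it lies
    within ``local_thresh`` of the neighbour it was reached from
    (``local_compare="pixel"``, the default — this is what lets smooth
    colour gradients clump into one colour) or of the cluster's running
    mean (``local_compare="mean"``). Stage 2 (global, default 1 JND):
    starting from the largest cluster, each cluster absorbs any remaining
    cluster whose mean lies within ``global_thresh`` of its own, linking
    disconnected patches of the same colour. Recording stops once
    cumulative coverage reaches ``coverage_stop`` (default 99%) or
    ``max_colours`` (default 32) colours are found. Clusters are returned
    sorted by coverage, largest first; means are geometric (log-space)
    means of the member catches.
    """
    if local_compare not in ("pixel", "mean"):
        raise ValueError("local_compare must be 'pixel' or 'mean'")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    stack = cone.receptor_stack()
    k = stack.shape[0]
    logs = np.log(np.clip(stack, 1e-12, None))
    h, w = mask.shape
    labels = np.full((h, w), -1, dtype=int)
    omega = weber.omega
    clusters: list[_Cluster] = []

    # stage 1: local region growing
    for r0, c0 in zip(*np.nonzero(mask)):
        if labels[r0, c0] != -1:
            continue
        cl = _Cluster(order=len(clusters), n_receptors=k)
        clusters.append(cl)
        label = cl.order
        labels[r0, c0] = label
        cl.add(logs[:, r0, c0])
        queue = deque([(r0, c0)])
        while queue:
            r, c = queue.popleft()
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if not (0 <= rr < h and 0 <= cc < w):
                    continue
                if not mask[rr, cc] or labels[rr, cc] != -1:
                    continue
                ref = (logs[:, r, c] if local_compare == "pixel"
                       else cl.mean_log)
                d = _jnd_from_delta(logs[:, rr, cc] - ref, omega)
                if d < local_thresh:
                    labels[rr, cc] = label
                    cl.add(logs[:, rr, cc])
                    queue.append((rr, cc))

    # stage 2: global linking, largest cluster first
    alive = sorted(clusters, key=lambda c: (-c.count, c.order))
    merged: list[_Cluster] = []
    while alive:
        head = alive.pop(0)
        changed = True
        while changed:
            changed = False
            keep = []
            for other in alive:
                d = _jnd_from_delta(other.mean_log - head.mean_log, omega)
                if d < global_thresh:
                    head.absorb(other)
                    changed = True
                else:
                    keep.append(other)
            alive = keep
        merged.append(head)
        alive.sort(key=lambda c: (-c.count, c.order))

    total = int(mask.sum())
    merged.sort(key=lambda c: (-c.count, c.order))
    out: list[ColourCluster] = []
    covered = 0.0
    for cl in merged:
        if covered >= coverage_stop or len(out) >= max_colours:
            break
        coverage = cl.count / total
        out.append(ColourCluster(mean_catch=np.exp(cl.mean_log),
                                 coverage=coverage, n_pixels=cl.count))
        covered += coverage
    return out


def colour_match_metrics(target_clusters: list[ColourCluster],
                         background_clusters: list[ColourCluster],
                         weber: WeberSet) -> ColourMatchResult:
    """Best and coverage-weighted mean JND from the most abundant target
    colour to the background palette."""
    if not target_clusters or not background_clusters:
        raise ValueError("cluster lists must be non-empty")
    c_star = target_clusters[0].mean_catch
    dists = np.array([jnd_distance(c_star, b.mean_catch, weber)
                      for b in background_clusters])
    weights = np.array([b.coverage for b in background_clusters])
    return ColourMatchResult(
        best_jnd=float(dists.min()),
        mean_jnd=float(np.average(dists, weights=weights)))
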