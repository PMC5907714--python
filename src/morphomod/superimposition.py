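"""Generalized Procrustes superimposition and object-symmetry decomposition.

GPA removes position, size and orientation: configurations are centred,
scaled to unit centroid size and rotated (proper rotations only — handedness
is preserved) to a consensus that is re-estimated until convergence.  For
bilaterally symmetric structures the aligned shapes are further split into a
symmetric component (the average of each configuration with its
reflected-and-relabelled copy after joint superimposition) and the
asymmetric remainder.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import Dataset, LandmarkConfiguration

__all__ = [
    "PairingScheme",
    "ProcrustesResult",
    "SymmetryDecomposition",
    "centroid_size",
    "gpa",
    "procrustes_distance",
    "merge_views",
    "symmetric_component",
    "CRANIUM_PAIRING",
    "MANDIBLE_PAIRING",
    "read_pairing_file",
]


@dataclass(frozen=True)
class PairingScheme:
    """Bilateral landmark pairing: left/right index pairs plus midline indices.

    Indices are 0-based.  ``paired`` and ``midline`` together must partition
    ``range(k)`` with no repeats.
    """

    paired: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]

    def __post_init__(self) -> None:
        seen = [i for pair in self.paired for i in pair] + list(self.midline)
        if len(seen) != len(set(seen)):
            raise ValueError("pairing scheme repeats a landmark index")

    @property
    def k(self) -> int:
        return 2 * len(self.paired) + len(self.midline)

    def validate(self, k: int) -> None:
        indices = {i for pair in self.paired for i in pair} | set(self.midline)
        if indices != set(range(k)):
            raise ValueError(
                f"pairing scheme does not partition 0..{k - 1}: covers "
                f"{len(indices)} of {k} landmarks"
            )

    def relabel_permutation(self) -> np.ndarray:
        """Index permutation swapping left and right labels."""
        perm = np.arange(self.k)
        for left, right in self.paired:
            perm[left], perm[right] = right, left
        return perm


def _pairs_1based(pairs: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    return tuple((a - 1, b - 1) for a, b in pairs)


# Bilateral pairing of the 62 cranial landmarks.  Note the two tooth-row
# pairs (40,42) and (41,43) are non-adjacent by design of the landmark list.
CRANIUM_PAIRING = PairingScheme(
    paired=_pairs_1based(
        [
            (1, 2), (3, 4), (5, 6), (7, 8), (9, 10), (12, 13), (14, 15),
            (16, 17), (18, 19), (20, 21), (22, 23), (24, 25), (26, 27),
            (28, 29), (30, 31), (34, 35), (38, 39), (40, 42), (41, 43),
            (47, 48), (49, 51), (52, 53), (54, 55), (56, 57), (58, 59),
            (61, 62),
        ]
    ),
    midline=tuple(i - 1 for i in [11, 32, 33, 36, 37, 44, 45, 46, 50, 60]),
)

# Bilateral pairing of the 24 mandibular landmarks.
MANDIBLE_PAIRING = PairingScheme(
    paired=_pairs_1based(
        [
            (2, 3), (4, 5), (7, 8), (9, 10), (11, 12), (13, 14), (15, 16),
            (17, 18), (19, 20), (21, 22), (23, 24),
        ]
    ),
    midline=(0, 5),
)


def read_pairing_file(path: str | Path) -> PairingScheme:
    """Read a pairing scheme from a two-column text file.

    Each line is either ``left right`` (two 1-based indices forming a
    bilateral pair) or a single index (a midline landmark).  Blank lines and
    ``#`` comments are ignored.
    """
    paired: list[tuple[int, int]] = []
    midline: list[int] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) == 2:
            paired.append((int(fields[0]), int(fields[1])))
        elif len(fields) == 1:
            midline.append(int(fields[0]))
        else:
            raise ValueError(f"bad pairing line {line!r}")
    return PairingScheme(_pairs_1based(paired), tuple(i - 1 for i in midline))


@dataclass
class ProcrustesResult:
    """GPA output: aligned shapes, consensus, centroid sizes."""

    aligned: np.ndarray  # n x k x m, unit centroid size, centred
    consensus: np.ndarray  # k x m
    centroid_sizes: np.ndarray  # n
    iterations: int
    converged: bool
    residual_history: list[float] | None = None  # sum of squared residuals per iteration

    @property
    def n(self) -> int:
        return self.aligned.shape[0]


@dataclass
class SymmetryDecomposition:
    """Aligned shapes split into symmetric and asymmetric components."""

    symmetric: np.ndarray  # n x k x m
    asymmetric: np.ndarray  # n x k x m
    pairing: PairingScheme
    aligned: np.ndarray  # n x k x m (joint superimposition of the originals)
    consensus: np.ndarray  # k x m symmetric consensus


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared distances of landmarks to their centroid."""
    coords = np.asarray(coords, dtype=float)
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centred**2)))


def _center_and_scale(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre each configuration and scale to unit centroid size."""
    centred = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt(np.sum(centred**2, axis=(1, 2)))
    if np.any(sizes <= 0) or not np.all(np.isfinite(sizes)):
        bad = int(np.argmin(sizes))
        raise ValueError(f"degenerate configuration at index {bad}: zero centroid size")
    return centred / sizes[:, None, None], sizes


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||source @ R - target||_F (Kabsch)."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.ones(u.shape[1])
    flip[-1] = d
    return (u * flip) @ vt


def gpa(
    data: Dataset | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Generalized Procrustes superimposition.

    Iteratively centres, scales to unit centroid size and rotates every
    configuration onto the current consensus (mean shape), re-estimating the
    consensus until it moves by less than ``tol``.  Only proper rotations are
    used, so handedness is never flipped.
    """
    coords = data.coords if isinstance(data, Dataset) else np.asarray(data, float)
    if coords.ndim != 3:
        raise ValueError("expected an n x k x m coordinate array")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    aligned, sizes = _center_and_scale(coords)

    consensus = aligned[0].copy()
    consensus /= np.sqrt(np.sum(consensus**2))
    converged = False
    iterations = 0
    history: list[float] = []
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], consensus)
        mean = aligned.mean(axis=0)
        history.append(float(np.sum((aligned - mean) ** 2)))
        norm = np.sqrt(np.sum(mean**2))
        if norm == 0:
            raise ValueError("degenerate consensus (configurations cancel out)")
        new_consensus = mean / norm
        change = np.sqrt(np.sum((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    consensus = aligned.mean(axis=0)
    return ProcrustesResult(aligned, consensus, sizes, iterations, converged, history)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance after full superimposition of two shapes."""
    stacked = np.stack([np.asarray(a, float), np.asarray(b, float)])
    res = gpa(stacked)
    return float(np.sqrt(np.sum((res.aligned[0] - res.aligned[1]) ** 2)))


def _rigid_fit(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) with target ≈ source @ R + t."""
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    s0, t0 = source - sc, target - tc
    if np.linalg.matrix_rank(s0, tol=1e-9 * max(1.0, np.abs(s0).max())) < 2:
        raise ValueError("reference landmarks are collinear or coincident")
    rot = _optimal_rotation(s0, t0)
    t = tc - sc @ rot
    return rot, t


def merge_views(
    dorsal: LandmarkConfiguration,
    ventral: LandmarkConfiguration,
    dorsal_ref: Sequence[int],
    ventral_ref: Sequence[int],
    drop_ventral: Sequence[int] | None = None,
) -> tuple[LandmarkConfiguration, float]:
    """Map a ventral digitising view into the dorsal frame and concatenate.

    The rigid transform (rotation + translation, no scaling — both views are
    the same physical specimen in the same units) is fit by least squares on
    the shared reference landmarks.  The duplicated reference landmarks (and
    any other indices in ``drop_ventral``) are removed from the transformed
    ventral view before appending it after the dorsal landmarks.

    Returns the merged configuration and the RMS misfit over the reference
    landmarks, a digitising-error diagnostic.
    """
    dorsal_ref = list(dorsal_ref)
    ventral_ref = list(ventral_ref)
    if len(dorsal_ref) != len(ventral_ref) or len(dorsal_ref) < 3:
        raise ValueError("need at least 3 shared reference landmarks")
    src = ventral.coords[ventral_ref]
    dst = dorsal.coords[dorsal_ref]
    rot, t = _rigid_fit(src, dst)
    mapped = ventral.coords @ rot + t
    rms = float(np.sqrt(np.mean(np.sum((src @ rot + t - dst) ** 2, axis=1))))
    drop = set(ventral_ref if drop_ventral is None else drop_ventral)
    keep = [i for i in range(ventral.k) if i not in drop]
    merged = np.vstack([dorsal.coords, mapped[keep]])
    return LandmarkConfiguration(dorsal.specimen_id, merged), rms


def reflect_relabel(coords: np.ndarray, pairing: PairingScheme, axis: int = 0) -> np.ndarray:
    """Mirror a configuration and swap left/right landmark labels.

    Works on a single k x m configuration or an n x k x m stack.  The choice
    of mirrored axis is immaterial downstream: the joint superimposition
    rotates reflections back onto the originals.
    """
    reflected = np.asarray(coords, float).copy()
    reflected[..., axis] = -reflected[..., axis]
    perm = pairing.relabel_permutation()
    return reflected[..., perm, :]


def symmetric_component(
    result: ProcrustesResult, pairing: PairingScheme
) -> SymmetryDecomposition:
    """Object-symmetry decomposition of GPA-aligned shapes.

    Each aligned configuration is paired with its reflected-and-relabelled
    copy; originals and reflections are jointly superimposed, and the
    symmetric component of a specimen is the average of its two copies.  The
    asymmetric component is the remainder, so symmetric + asymmetric exactly
    reconstructs the jointly aligned originals.
    """
    aligned = result.aligned
    n, k, _ = aligned.shape
    pairing.validate(k)
    reflections = reflect_relabel(aligned, pairing)
    joint = gpa(np.concatenate([aligned, reflections], axis=0))
    originals = joint.aligned[:n]
    mirrored = joint.aligned[n:]
    symmetric = 0.5 * (originals + mirrored)
    asymmetric = originals - symmetric
    return SymmetryDecomposition(
        symmetric=symmetric,
        asymmetric=asymmetric,
        pairing=pairing,
        aligned=originals,
        consensus=symmetric.mean(axis=0),
    )
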