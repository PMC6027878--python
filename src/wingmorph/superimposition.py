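"""Generalized Procrustes superimposition with chord-tangent semilandmark sliding.

All specimens (every stage and genotype) are registered jointly: each
configuration is centred, scaled to unit centroid size and rotated
(rotation only, reflections are never allowed — all wings share one
handedness) onto an iteratively refined consensus.  Semilandmarks may then
be slid along the chord direction of their margin run to minimize their
distance to the consensus, alternating with re-registration.

The fixed point of the alignment is made reproducible by rotating the
consensus so that its principal axis lies along x.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import DEFAULT_SCHEME, LandmarkScheme, Specimen

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 100


class DegenerateConfigurationError(ValueError):
    """All landmarks coincide (zero centroid size) or a tangent is undefined."""


@dataclass
class AlignedDataset:
    """Procrustes-registered shapes.

    ``shapes`` is n x 2k with coordinates interleaved (x1, y1, ..., xk, yk)
    at unit centroid size; ``consensus`` is the k x 2 mean configuration,
    itself of unit centroid size.
    """

    shapes: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    ids: list[str]
    stages: list[str]
    genotypes: list[str]
    sexes: list[str]
    scheme: LandmarkScheme
    iterations_used: int
    converged: bool
    slid: bool = False

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    def configurations(self) -> np.ndarray:
        """Shapes as an n x k x 2 array."""
        return self.shapes.reshape(self.n, -1, 2)

    def procrustes_ss(self) -> float:
        """Total squared deviation of aligned shapes around their mean."""
        mean = self.shapes.mean(axis=0)
        return float(((self.shapes - mean) ** 2).sum())


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared deviations of points from their centroid."""
    config = np.asarray(config, dtype=float)
    centred = config - config.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs <= 0.0 or not np.isfinite(cs):
        raise DegenerateConfigurationError("all landmarks coincide: centroid size is zero")
    return cs


def _center_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    config = np.asarray(config, dtype=float)
    centred = config - config.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs <= 0.0:
        raise DegenerateConfigurationError("zero centroid size")
    return centred / cs, cs


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """2x2 proper rotation (det=+1) minimizing ||source @ R - target||."""
    a = source.T @ target
    # rotation by theta: trace(R^T a) = (a00+a11) cos + (a10-a01) sin
    c = a[0, 0] + a[1, 1]
    s = a[1, 0] - a[0, 1]
    norm = np.hypot(c, s)
    if norm == 0.0:
        return np.eye(2)
    c, s = c / norm, s / norm
    return np.array([[c, -s], [s, c]])


def procrustes_distance(shape_a: np.ndarray, shape_b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Both shapes are centred and scaled to unit centroid size, then shape_a
    is rotated (no reflection) onto shape_b; the root-sum-of-squares of the
    residual is returned.  Zero iff the shapes are similarity-equivalent.
    """
    a, _ = _center_scale(np.asarray(shape_a, dtype=float).reshape(-1, 2))
    b, _ = _center_scale(np.asarray(shape_b, dtype=float).reshape(-1, 2))
    r = optimal_rotation(a, b)
    return float(np.sqrt(max(((a @ r - b) ** 2).sum(), 0.0)))


def _principal_axis_rotation(config: np.ndarray) -> np.ndarray:
    """Rotation sending the configuration's principal axis to x.

    Sign conventions (largest-spread coordinate positive on x, then on y)
    make the orientation deterministic across platforms.
    """
    cov = np.cov(config.T)
    _, vecs = np.linalg.eigh(cov)
    major = vecs[:, -1]
    minor = vecs[:, -2] if vecs.shape[1] > 1 else np.array([-major[1], major[0]])
    rot = np.column_stack([major, minor])
    if np.linalg.det(rot) < 0:
        rot[:, 1] = -rot[:, 1]
    out = config @ rot
    if out[np.argmax(np.abs(out[:, 0])), 0] < 0:
        rot = rot @ np.diag([-1.0, -1.0])  # rotate 180 deg, keeps det=+1
        out = config @ rot
    return rot


def gpa(
    specimens: list[Specimen] | np.ndarray,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    scheme: LandmarkScheme | None = None,
) -> AlignedDataset:
    """Generalized Procrustes alignment of all specimens jointly.

    Accepts a list of :class:`Specimen` or a raw n x k x 2 array.  Iterates
    centring, unit-centroid-size scaling and rotation-only fits to the
    running consensus until the consensus moves by less than ``tol``.
    Non-convergence flags ``converged=False`` instead of raising.
    """
    if isinstance(specimens, np.ndarray):
        configs = np.asarray(specimens, dtype=float)
        ids = [f"specimen_{i + 1}" for i in range(len(configs))]
        stages = genotypes = sexes = ["unknown"] * len(configs)
        scheme = scheme or DEFAULT_SCHEME
    else:
        if len(specimens) == 0:
            raise ValueError("need at least one specimen")
        scheme = scheme or specimens[0].scheme
        configs = np.stack([s.landmarks for s in specimens])
        ids = [s.id for s in specimens]
        stages = [s.stage for s in specimens]
        genotypes = [s.genotype for s in specimens]
        sexes = [s.sex for s in specimens]
    n = configs.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 specimens")

    aligned = np.empty_like(configs)
    sizes = np.empty(n)
    for i in range(n):
        aligned[i], sizes[i] = _center_scale(configs[i])

    consensus = aligned[0].copy()
    consensus = consensus @ _principal_axis_rotation(consensus)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = aligned[i] @ optimal_rotation(aligned[i], consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus, _ = _center_scale(new_consensus)
        new_consensus = new_consensus @ _principal_axis_rotation(new_consensus)
        delta = float(np.abs(new_consensus - consensus).max())
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)
    # final pass onto the settled consensus
    for i in range(n):
        aligned[i] = aligned[i] @ optimal_rotation(aligned[i], consensus)

    return AlignedDataset(
        shapes=aligned.reshape(n, -1),
        consensus=consensus,
        centroid_sizes=sizes,
        ids=list(ids),
        stages=list(stages),
        genotypes=list(genotypes),
        sexes=list(sexes),
        scheme=scheme,
        iterations_used=iterations,
        converged=converged,
    )


def _slide_one(config: np.ndarray, consensus: np.ndarray, scheme: LandmarkScheme,
               spec_label: str = "?") -> np.ndarray:
    """Project each semilandmark along its local chord toward the consensus.

    The tangent at semilandmark j is the chord between its flanking points
    (anchors included) in the ordered margin run, taken on the specimen
    itself.  Moving the point by the tangential component of its residual
    to the consensus can only reduce its squared distance to the consensus.
    """
    out = config.copy()
    for g in range(len(scheme.semilandmark_groups)):
        seq = scheme.group_sequence(g)
        for pos in range(1, len(seq) - 1):
            j = seq[pos]
            prev_pt = config[seq[pos - 1]]
            next_pt = config[seq[pos + 1]]
            chord = next_pt - prev_pt
            norm = np.hypot(*chord)
            if norm == 0.0:
                raise DegenerateConfigurationError(
                    f"specimen {spec_label}: coincident flanking points for "
                    f"semilandmark {j + 1} in group {g}"
                )
            t = chord / norm
            out[j] = config[j] + t * float(np.dot(consensus[j] - config[j], t))
    return out


def slide_semilandmarks(
    aligned: AlignedDataset,
    scheme: LandmarkScheme | None = None,
    mode: str = "chord",
    max_iter: int = 20,
    tol: float = 1e-10,
) -> AlignedDataset:
    """Alternate chord-tangent sliding with GPA re-registration.

    mode="chord" minimizes each semilandmark's distance to its consensus
    position along the local chord direction; mode="none" returns the
    input unchanged.  The total Procrustes sum of squares is non-increasing
    across outer iterations; the loop stops when its decrease is < tol.
    """
    if mode == "none":
        return aligned
    if mode != "chord":
        raise ValueError(f"unknown sliding mode {mode!r}")
    scheme = scheme or aligned.scheme

    configs = aligned.configurations().copy()
    consensus = aligned.consensus.copy()
    ss_prev = float(((configs.reshape(aligned.n, -1) - configs.reshape(aligned.n, -1).mean(axis=0)) ** 2).sum())
    result = aligned
    for _ in range(max_iter):
        slid = np.stack([
            _slide_one(configs[i], consensus, scheme, aligned.ids[i])
            for i in range(aligned.n)
        ])
        result = gpa(slid, scheme=scheme)
        result.ids = list(aligned.ids)
        result.stages = list(aligned.stages)
        result.genotypes = list(aligned.genotypes)
        result.sexes = list(aligned.sexes)
        result.centroid_sizes = aligned.centroid_sizes.copy()
        configs = result.configurations().copy()
        consensus = result.consensus
        ss = result.procrustes_ss()
        if ss > ss_prev + 1e-9:
            logger.warning("sliding increased Procrustes SS (%.3e -> %.3e)", ss_prev, ss)
        if ss_prev - ss < tol:
            break
        ss_prev = ss
    result.slid = True
    return result


def align(
    specimens: list[Specimen],
    slide: str = "chord",
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> AlignedDataset:
    """Convenience: GPA then semilandmark sliding (the standard pipeline step)."""
    aligned = gpa(specimens, max_iter=max_iter, tol=tol)
    return slide_semilandmarks(aligned, mode=slide)


def tangent_check(aligned: AlignedDataset) -> float:
    """Correlation between Euclidean and Procrustes inter-specimen distances.

    A value near 1 indicates the tangent-space (Euclidean) approximation to
    shape space is adequate for this dataset.
    """
    n = aligned.n
    if n < 3:
        raise ValueError("tangent check needs at least 3 specimens")
    configs = aligned.configurations()
    flat = aligned.shapes
    eu, pr = [], []
    for i in range(n):
        for j in range(i + 1, n):
            eu.append(float(np.linalg.norm(flat[i] - flat[j])))
            pr.append(procrustes_distance(configs[i], configs[j]))
    return float(np.corrcoef(eu, pr)[0, 1])
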