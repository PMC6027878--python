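"""Multivariate statistics on aligned shapes.

Principal components, canonical discriminant scores, Wilks'-lambda MANOVA
with Type III cross-products, a randomization MANOVA that permutes one
component of an explicit decomposition of each observation (grand mean +
stage + genotype + interaction residual means + individual deviation),
mean shape-distance matrices between stage/genotype groups, and angles
between per-genotype developmental shape-change vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray       # n x n_axes
    loadings: np.ndarray     # p x n_axes (columns are axes)
    eigenvalues: np.ndarray  # n_axes
    mean: np.ndarray         # p
    n_axes: int


def shape_pca(shapes: np.ndarray, n_axes: int = 18) -> PCAResult:
    """Covariance PCA of shape vectors, axes ordered by decreasing eigenvalue.

    Axis signs follow the convention that each axis's largest-magnitude
    loading is positive.  ``n_axes`` beyond the matrix rank is truncated
    with a logged warning.
    """
    X = np.asarray(shapes, dtype=float)
    n, p = X.shape
    if n <= n_axes:
        raise ValueError(f"need more than n_axes={n_axes} specimens, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    rank = int(np.sum(s > s[0] * max(n, p) * np.finfo(float).eps)) if s.size else 0
    if n_axes > rank:
        logger.warning("requested %d PC axes but rank is %d; truncating", n_axes, rank)
        n_axes = rank
    loadings = vt[:n_axes].T
    for a in range(n_axes):
        col = loadings[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, a] = -col
    scores = Xc @ loadings
    return PCAResult(scores=scores, loadings=loadings,
                     eigenvalues=eig[:n_axes], mean=mean, n_axes=n_axes)


# ---------------------------------------------------------------------------
# CVA
# ---------------------------------------------------------------------------

@dataclass
class CVAResult:
    scores: np.ndarray        # n x n_axes, within-class covariance = identity
    eigenvectors: np.ndarray  # p x n_axes
    eigenvalues: np.ndarray
    classes: list
    class_means: np.ndarray   # canonical-space class means


def cva(scores: np.ndarray, class_labels: Sequence) -> CVAResult:
    """Canonical variates maximizing between/within scatter.

    Eigenvectors are scaled so canonical scores have pooled within-class
    covariance equal to the identity; the number of axes is
    min(classes - 1, variables).
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(class_labels)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("CVA needs at least 2 classes")
    n, p = X.shape
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in classes:
        Xc = X[labels == c]
        if len(Xc) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 members")
        dev = Xc - Xc.mean(axis=0)
        Sw += dev.T @ dev
        dm = (Xc.mean(axis=0) - grand)[:, None]
        Sb += len(Xc) * (dm @ dm.T)
    Sw_cov = Sw / (n - len(classes))
    try:
        vals, vecs = linalg.eigh(Sb, Sw_cov)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-class scatter; retain fewer PCs before CVA"
        ) from exc
    if not np.all(np.isfinite(vals)):
        raise ValueError("singular within-class scatter; retain fewer PCs before CVA")
    order = np.argsort(vals)[::-1]
    n_axes = min(len(classes) - 1, p)
    vecs = vecs[:, order[:n_axes]]
    vals = vals[order[:n_axes]]
    for a in range(n_axes):
        col = vecs[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            vecs[:, a] = -col
    can = (X - grand) @ vecs
    means = np.vstack([can[labels == c].mean(axis=0) for c in classes])
    return CVAResult(scores=can, eigenvectors=vecs, eigenvalues=vals,
                     classes=classes, class_means=means)


# ---------------------------------------------------------------------------
# MANOVA (Type III Wilks' lambda)
# ---------------------------------------------------------------------------

@dataclass
class WilksResult:
    effect: str
    wilks_lambda: float
    df_num: int
    df_den: int
    F: float
    p_value: float
    E: np.ndarray = field(repr=False)
    H: np.ndarray = field(repr=False)


def _sum_code(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""
    levels = sorted(pd.unique(labels).tolist())
    k = len(levels)
    idx = {lv: i for i, lv in enumerate(levels)}
    cols = np.zeros((len(labels), k - 1))
    for r, lab in enumerate(labels):
        i = idx[lab]
        if i < k - 1:
            cols[r, i] = 1.0
        else:
            cols[r, :] = -1.0
    return cols, levels


def _build_design(factors: dict[str, np.ndarray],
                  interactions: Sequence[tuple[str, str]]) -> tuple[np.ndarray, dict[str, slice]]:
    n = len(next(iter(factors.values())))
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    spans: dict[str, slice] = {}
    pos = 1
    coded = {name: _sum_code(np.asarray(labels))[0] for name, labels in factors.items()}
    for name, cols in coded.items():
        spans[name] = slice(pos, pos + cols.shape[1])
        blocks.append(cols)
        pos += cols.shape[1]
    for a, b in interactions:
        ca, cb = coded[a], coded[b]
        inter = np.einsum("ni,nj->nij", ca, cb).reshape(n, -1)
        spans[f"{a}:{b}"] = slice(pos, pos + inter.shape[1])
        blocks.append(inter)
        pos += inter.shape[1]
    return np.hstack(blocks), spans


def _rao_f(lmbda: float, p: int, q: int, df_err: int) -> tuple[int, int, float, float]:
    """Rao's F approximation for Wilks' lambda (exact for p<=2 or q<=2)."""
    if p * p + q * q - 5 > 0:
        t = np.sqrt((p * p * q * q - 4.0) / (p * p + q * q - 5.0))
    else:
        t = 1.0
    df1 = p * q
    w = df_err + q - (p + q + 1) / 2.0
    df2 = w * t - (p * q - 2) / 2.0
    lam_t = lmbda ** (1.0 / t) if lmbda > 0 else 0.0
    F = (1.0 - lam_t) / lam_t * df2 / df1 if lam_t > 0 else np.inf
    pval = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return df1, int(round(df2)), float(F), pval


class _WilksMachine:
    """Precomputed Type III machinery for repeated Wilks evaluations on a
    fixed design (used by the randomization test)."""

    def __init__(self, factors: dict[str, np.ndarray], effect: str,
                 interactions: Sequence[tuple[str, str]]):
        X, spans = _build_design(factors, interactions)
        if effect not in spans:
            raise ValueError(f"effect {effect!r} not in design ({list(spans)})")
        n, k = X.shape
        rank = np.linalg.matrix_rank(X)
        if rank < k:
            raise ValueError("design matrix is rank deficient under sum coding "
                             "(empty cells?)")
        self.X = X
        self.span = spans[effect]
        G = np.linalg.inv(X.T @ X)
        self.P = G @ X.T                       # coefficient projector
        L = np.zeros((self.span.stop - self.span.start, k))
        for r, c in enumerate(range(self.span.start, self.span.stop)):
            L[r, c] = 1.0
        self.L = L
        self.W = np.linalg.inv(L @ G @ L.T)    # Type III hypothesis metric
        self.df_err = n - k
        self.q = L.shape[0]

    def wilks(self, Y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        XtY = self.X.T @ Y
        B = self.P @ Y
        E = Y.T @ Y - B.T @ XtY
        LB = B[self.span.start:self.span.stop]
        H = LB.T @ self.W @ LB
        det_e = np.linalg.det(E)
        det_eh = np.linalg.det(E + H)
        if det_eh <= 0 or det_e < 0:
            raise ValueError("singular error matrix: reduce response dimension")
        return float(det_e / det_eh), E, H


def manova_wilks(
    response: np.ndarray,
    factors: dict[str, Sequence],
    effect: str,
    interactions: Sequence[tuple[str, str]] | None = None,
) -> WilksResult:
    """Type III Wilks' lambda for one effect of a crossed factorial design.

    ``factors`` maps factor names to label sequences; ``effect`` is a
    factor name or ``"a:b"`` for an interaction.  All main effects plus the
    listed interactions (default: all two-way) enter the model; the tested
    effect's cross-product matrix is the Type III (each-effect-last)
    hypothesis SSCP under sum-to-zero coding.
    """
    Y = np.asarray(response, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    fdict = {name: np.asarray(labels) for name, labels in factors.items()}
    if interactions is None:
        names = list(fdict)
        interactions = [
            (names[i], names[j])
            for i in range(len(names)) for j in range(i + 1, len(names))
        ]
    machine = _WilksMachine(fdict, effect, interactions)
    if Y.shape[1] >= machine.df_err:
        raise ValueError(
            f"response dimension {Y.shape[1]} >= error df {machine.df_err}; "
            "reduce to fewer PCs"
        )
    lmbda, E, H = machine.wilks(Y)
    df1, df2, F, pval = _rao_f(lmbda, Y.shape[1], machine.q, machine.df_err)
    return WilksResult(effect=effect, wilks_lambda=lmbda, df_num=df1,
                       df_den=df2, F=F, p_value=pval, E=E, H=H)


# ---------------------------------------------------------------------------
# Decomposition + randomization test
# ---------------------------------------------------------------------------

@dataclass
class RandomizationDecomposition:
    """Additive decomposition of each shape vector.

    observation = grand + stage_term + genotype_term + interaction_term +
    deviation, row-wise exact.  With ``weighted=False`` the grand/stage/
    genotype means are unweighted means of cell means (Type III spirit for
    unbalanced designs); with ``weighted=True`` they are observation means.
    """

    grand: np.ndarray              # p
    stage_terms: np.ndarray        # n x p (per-observation stage residual mean)
    genotype_terms: np.ndarray     # n x p
    interaction_terms: np.ndarray  # n x p
    deviations: np.ndarray         # n x p
    stages: np.ndarray
    genotypes: np.ndarray
    weighted: bool

    def reconstruct(self) -> np.ndarray:
        return (self.grand + self.stage_terms + self.genotype_terms
                + self.interaction_terms + self.deviations)


def decompose(
    shapes: np.ndarray,
    stage_labels: Sequence,
    genotype_labels: Sequence,
    weighted: bool = False,
) -> RandomizationDecomposition:
    Y = np.asarray(shapes, dtype=float)
    stages = np.asarray(stage_labels)
    genotypes = np.asarray(genotype_labels)
    stage_levels = sorted(pd.unique(stages).tolist())
    geno_levels = sorted(pd.unique(genotypes).tolist())
    empty = [
        (s, g) for s in stage_levels for g in geno_levels
        if not np.any((stages == s) & (genotypes == g))
    ]
    if empty:
        raise ValueError(f"empty stage x genotype cells: {empty}")
    cell_means = {
        (s, g): Y[(stages == s) & (genotypes == g)].mean(axis=0)
        for s in stage_levels for g in geno_levels
    }
    if weighted:
        grand = Y.mean(axis=0)
        stage_means = {s: Y[stages == s].mean(axis=0) for s in stage_levels}
        geno_means = {g: Y[genotypes == g].mean(axis=0) for g in geno_levels}
    else:
        grand = np.mean([cell_means[k] for k in cell_means], axis=0)
        stage_means = {
            s: np.mean([cell_means[(s, g)] for g in geno_levels], axis=0)
            for s in stage_levels
        }
        geno_means = {
            g: np.mean([cell_means[(s, g)] for s in stage_levels], axis=0)
            for g in geno_levels
        }
    r_stage = {s: stage_means[s] - grand for s in stage_levels}
    r_geno = {g: geno_means[g] - grand for g in geno_levels}
    r_inter = {
        (s, g): cell_means[(s, g)] - grand - r_stage[s] - r_geno[g]
        for s in stage_levels for g in geno_levels
    }
    n = len(Y)
    stage_terms = np.vstack([r_stage[stages[i]] for i in range(n)])
    geno_terms = np.vstack([r_geno[genotypes[i]] for i in range(n)])
    inter_terms = np.vstack([r_inter[(stages[i], genotypes[i])] for i in range(n)])
    deviations = Y - np.vstack([cell_means[(stages[i], genotypes[i])] for i in range(n)])
    return RandomizationDecomposition(
        grand=grand, stage_terms=stage_terms, genotype_terms=geno_terms,
        interaction_terms=inter_terms, deviations=deviations,
        stages=stages, genotypes=genotypes, weighted=weighted,
    )


@dataclass
class RandomizationResult:
    effect: str
    observed_lambda: float
    null_lambdas: np.ndarray
    p_value: float
    n_rand: int
    seed: int | None
    genotype_permutation: str = "within_stage"


def randomized_manova(
    shapes: np.ndarray,
    stage_labels: Sequence,
    genotype_labels: Sequence,
    effect: str = "genotype",
    n_rand: int = 1000,
    seed: int | None = None,
    genotype_permutation: str = "within_stage",
    weighted: bool = False,
    permute: str = "component_plus_deviation",
) -> RandomizationResult:
    """Randomization test of one MANOVA effect via component permutation.

    Each observation is decomposed into grand mean + stage + genotype +
    interaction residual means + individual deviation.  For each replicate,
    pseudo-observations are rebuilt with the tested component permuted
    among individuals — genotype terms within stages by default
    (``genotype_permutation="across_all"`` shuffles across stages instead,
    which is anticonservative when stages have unequal shape variance, as
    they do here), interaction terms always within stages — holding all other
    components fixed, and the effect's Wilks' lambda is recomputed.  The
    p-value is (1 + #{null <= observed}) / (n_rand + 1).

    With the default ``permute="component_plus_deviation"`` the permuted
    block is the tested residual mean *plus* the individual deviation
    (Freedman-Lane style).  This is required for a calibrated test: the
    deviations have exactly zero cell means, so permuting the residual
    means alone (``permute="component"``, the literal component shuffle)
    produces pseudo-data whose fitted effect is an order of magnitude too
    small and the test rejects every true null.
    """
    if effect not in ("genotype", "stage:genotype"):
        raise ValueError(f"unknown effect {effect!r}; use 'genotype' or 'stage:genotype'")
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if permute not in ("component_plus_deviation", "component"):
        raise ValueError(f"unknown permute mode {permute!r}")
    Y = np.asarray(shapes, dtype=float)
    stages = np.asarray(stage_labels)
    genotypes = np.asarray(genotype_labels)
    dec = decompose(Y, stages, genotypes, weighted=weighted)
    factors = {"stage": stages, "genotype": genotypes}
    machine = _WilksMachine(factors, effect, [("stage", "genotype")])
    if Y.shape[1] >= machine.df_err:
        raise ValueError(
            f"response dimension {Y.shape[1]} >= error df {machine.df_err}"
        )
    observed, _, _ = machine.wilks(Y)
    fixed = dec.grand + dec.stage_terms + (
        dec.genotype_terms if effect == "stage:genotype" else dec.interaction_terms
    )
    moved = dec.genotype_terms if effect == "genotype" else dec.interaction_terms
    if permute == "component_plus_deviation":
        moved = moved + dec.deviations
    else:
        fixed = fixed + dec.deviations
    rng = np.random.default_rng(seed)
    n = len(Y)
    stage_groups = [np.flatnonzero(stages == s) for s in pd.unique(stages)]
    nulls = np.empty(n_rand)
    for b in range(n_rand):
        perm = np.arange(n)
        if effect == "genotype" and genotype_permutation == "across_all":
            perm = rng.permutation(n)
        else:
            for idx in stage_groups:
                perm[idx] = idx[rng.permutation(len(idx))]
        Yb = fixed + moved[perm]
        nulls[b], _, _ = machine.wilks(Yb)
    p = (1.0 + float(np.sum(nulls <= observed))) / (n_rand + 1.0)
    return RandomizationResult(
        effect=effect, observed_lambda=observed, null_lambdas=nulls,
        p_value=p, n_rand=n_rand, seed=seed,
        genotype_permutation=genotype_permutation,
    )


# ---------------------------------------------------------------------------
# Group distance matrix and trajectory angles
# ---------------------------------------------------------------------------

def mean_shape_distance_matrix(
    shapes: np.ndarray,
    stage_labels: Sequence,
    genotype_labels: Sequence,
    stage_order: Sequence | None = None,
    genotype_order: Sequence | None = None,
) -> pd.DataFrame:
    """Mean Euclidean distance between shape vectors for each group pair.

    Off-diagonal entries average over all cross-group pairs; diagonal
    entries average over distinct same-group pairs (self-pairs excluded)
    and are NaN for groups of size < 2.
    """
    Y = np.asarray(shapes, dtype=float)
    stages = np.asarray(stage_labels)
    genotypes = np.asarray(genotype_labels)
    s_order = list(stage_order) if stage_order else sorted(pd.unique(stages).tolist())
    g_order = list(genotype_order) if genotype_order else sorted(pd.unique(genotypes).tolist())
    groups = [(s, g) for s in s_order for g in g_order
              if np.any((stages == s) & (genotypes == g))]
    members = {grp: Y[(stages == grp[0]) & (genotypes == grp[1])] for grp in groups}
    labels = [f"{s}:{g}" for s, g in groups]
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for a, ga in enumerate(groups):
        for b in range(a, len(groups)):
            gb = groups[b]
            D = cdist(members[ga], members[gb])
            if a == b:
                m = len(members[ga])
                if m < 2:
                    logger.warning("group %s has < 2 members; diagonal left missing", ga)
                    continue
                val = D[np.triu_indices(m, k=1)].mean()
            else:
                val = D.mean()
            out.iloc[a, b] = out.iloc[b, a] = float(val)
    return out


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle in degrees between two vectors, in [0, 180]."""
    n1 = float(np.linalg.norm(v1))
    n2 = float(np.linalg.norm(v2))
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("undefined angle: zero-length shape-change vector")
    c = float(np.dot(v1, v2) / (n1 * n2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def trajectory_angles(
    shapes: np.ndarray,
    stage_labels: Sequence,
    genotype_labels: Sequence,
    transitions: Sequence[tuple[str, str]] = (
        ("larva", "pupa"), ("pupa", "adult"), ("larva", "adult"),
    ),
    genotypes: Sequence | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Pairwise angles between per-genotype shape-change vectors.

    For each stage transition the change vector of genotype g is the
    difference of its mean shapes at the two stages; the returned matrix
    holds the angle (degrees) for every genotype pair.
    """
    Y = np.asarray(shapes, dtype=float)
    stages = np.asarray(stage_labels)
    genos = np.asarray(genotype_labels)
    g_order = list(genotypes) if genotypes else sorted(pd.unique(genos).tolist())
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for s1, s2 in transitions:
        vecs = {}
        for g in g_order:
            m1 = (stages == s1) & (genos == g)
            m2 = (stages == s2) & (genos == g)
            if not m1.any() or not m2.any():
                raise ValueError(f"genotype {g!r} missing at stage {s1!r} or {s2!r}")
            vecs[g] = Y[m2].mean(axis=0) - Y[m1].mean(axis=0)
        mat = pd.DataFrame(0.0, index=g_order, columns=g_order)
        for i, ga in enumerate(g_order):
            for j in range(i + 1, len(g_order)):
                gb = g_order[j]
                ang = angle_between(vecs[ga], vecs[gb])
                mat.loc[ga, gb] = mat.loc[gb, ga] = ang
        out[(s1, s2)] = mat
    return out
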