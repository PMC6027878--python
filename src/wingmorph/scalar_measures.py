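"""Per-specimen scalar traits and between-group ratio comparisons.

Scalar traits are computed from the raw (mm) landmark configuration:

* the 28 pairwise distances among the 8 fixed landmarks, on coordinates
  standardized by centroid size (columns ``stlen12`` ... ``stlen78``);
* polyline lengths of the anterior (1,9-14,3) and posterior (5,15-17,7)
  margin runs, standardized;
* shoelace (surveyor's formula) polygon areas for the anterior, middle,
  posterior and total wing regions, in mm^2 on raw coordinates plus
  dimensionless standardized variants;
* centroid size (mm).

Group comparisons are ratios of group means with bootstrap percentile
intervals and delta-method standard errors (zero covariance between
groups, appropriate for destructively sampled stages).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DEFAULT_SCHEME, LandmarkScheme, Specimen
from .superimposition import DegenerateConfigurationError, centroid_size

logger = logging.getLogger(__name__)

# 1-based vertex orders for the shoelace polygons.  The region definitions
# fix vertex sets but not traversal order; the order below follows the wing
# outline (anterior margin distally, posterior margin back proximally) and
# yields simple polygons for wing-like configurations.
POLYGON_VERTICES: dict[str, tuple[int, ...]] = {
    "anterior": (2, 1, 9, 10, 11, 12, 13, 14, 3, 4),
    "middle": (4, 3, 5, 6),
    "posterior": (6, 5, 15, 16, 17, 7, 8),
    "total": (2, 1, 9, 10, 11, 12, 13, 14, 3, 5, 15, 16, 17, 7, 8, 6),
}

MARGIN_VERTICES: dict[str, tuple[int, ...]] = {
    "anterior": (1, 9, 10, 11, 12, 13, 14, 3),
    "posterior": (5, 15, 16, 17, 7),
}


def standardize(config: np.ndarray) -> np.ndarray:
    """Divide every coordinate by centroid size (output has centroid size 1
    up to the original centroid offset; idempotent up to scaling)."""
    config = np.asarray(config, dtype=float)
    return config / centroid_size(config)


def pairwise_distances(std_config: np.ndarray, n_fixed: int = 8) -> dict[str, float]:
    """All C(8,2)=28 distances among the fixed landmarks, named stlen{i}{j}."""
    std_config = np.asarray(std_config, dtype=float)
    out: dict[str, float] = {}
    for i, j in itertools.combinations(range(1, n_fixed + 1), 2):
        out[f"stlen{i}{j}"] = float(
            np.linalg.norm(std_config[i - 1] - std_config[j - 1])
        )
    return out


def margin_length(std_config: np.ndarray, which: str) -> float:
    """Polyline length along one margin run (anchors included)."""
    verts = MARGIN_VERTICES[which]
    pts = np.asarray(std_config, dtype=float)[[v - 1 for v in verts]]
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def shoelace_area(vertices: np.ndarray) -> float:
    """Absolute surveyor's-formula area of an ordered simple polygon."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    signed = 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return abs(signed)


def _is_simple(v: np.ndarray) -> bool:
    n = len(v)
    segs = [(v[i], v[(i + 1) % n]) for i in range(n)]

    def _intersect(p1, p2, p3, p4) -> bool:
        def orient(a, b, c):
            return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

        d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
        d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
        return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through wrap-around
            if _intersect(*segs[i], *segs[j]):
                return False
    return True


def polygon_area(config: np.ndarray, which: str = "total",
                 check_simple: bool = True) -> float:
    """Shoelace area of one wing region from the documented vertex order."""
    if which not in POLYGON_VERTICES:
        raise ValueError(f"unknown region {which!r}; expected one of {list(POLYGON_VERTICES)}")
    config = np.asarray(config, dtype=float)
    verts = config[[v - 1 for v in POLYGON_VERTICES[which]]]
    if check_simple and not _is_simple(verts):
        logger.warning(
            "polygon %r self-intersects under the documented vertex order "
            "(signed area %.6g)", which,
            0.5 * float(np.dot(verts[:, 0], np.roll(verts[:, 1], -1))
                        - np.dot(verts[:, 1], np.roll(verts[:, 0], -1))),
        )
    return shoelace_area(verts)


def scalar_row(specimen: Specimen) -> dict[str, float | str]:
    """All scalar traits for one specimen (a ScalarTable row)."""
    cfg = specimen.landmarks
    cs = centroid_size(cfg)
    std = cfg / cs
    row: dict[str, float | str] = {
        "id": specimen.id,
        "stage": specimen.stage,
        "genotype": specimen.genotype,
        "sex": specimen.sex,
    }
    row.update(pairwise_distances(std))
    row["anterior_margin_len"] = margin_length(std, "anterior")
    row["posterior_margin_len"] = margin_length(std, "posterior")
    for region in ("anterior", "middle", "posterior", "total"):
        row[f"area_{region}"] = polygon_area(cfg, region)
        row[f"std_area_{region}"] = polygon_area(std, region, check_simple=False)
    row["centroid_size"] = cs
    return row


def scalar_table(specimens: list[Specimen]) -> pd.DataFrame:
    """ScalarTable: one row per specimen, 28 stlen + margins + areas + size."""
    return pd.DataFrame([scalar_row(s) for s in specimens])


# ---------------------------------------------------------------------------
# Ratio comparisons
# ---------------------------------------------------------------------------

@dataclass
class RatioComparison:
    trait: str
    numerator_group: str
    denominator_group: str
    point_ratio: float
    ci_low: float
    ci_high: float
    delta_se: float
    n_boot: int
    seed: int | None
    bootstrap: np.ndarray = field(repr=False)
    n_rejected: int = 0


def ratio_of_means(values_num, values_den) -> float:
    """Plain ratio of group means (no resampling)."""
    num = float(np.mean(values_num))
    den = float(np.mean(values_den))
    if den == 0.0:
        raise ZeroDivisionError("denominator group mean is zero")
    return num / den


def expanded_percentiles(n: int, level: float = 95.0) -> tuple[float, float]:
    """Expanded percentile levels correcting small-sample undercoverage.

    The raw percentile interval is too narrow in small samples (bootstrap
    means have variance shrunk by (n-1)/n and the normal quantile stands in
    for a t).  Following Hesterberg's expanded percentile interval, the
    nominal alpha/2 is replaced by Phi(-t_{n-1,1-alpha/2} * sqrt(n/(n-1))),
    which converges to the nominal levels as n grows.
    """
    from scipy import stats

    alpha = 1.0 - level / 100.0
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    lo = 100.0 * float(stats.norm.cdf(-t * math.sqrt(n / (n - 1))))
    return lo, 100.0 - lo


def bootstrap_ratio(
    values_num,
    values_den,
    n_boot: int = 1000,
    seed: int | None = None,
    trait: str = "",
    numerator_group: str = "",
    denominator_group: str = "",
    ci_method: str = "expanded",
) -> RatioComparison:
    """Bootstrap distribution for a ratio of two group means.

    Each replicate independently resamples both groups with replacement at
    their own sizes and records the ratio of resampled means.  Replicates
    with a zero denominator mean are redrawn (counted; warned if > 1% of
    n_boot).  Deterministic given ``seed``.

    The reported interval takes bootstrap-distribution percentiles:
    ``ci_method="percentile"`` uses the raw 2.5-97.5 levels;
    the default ``"expanded"`` adjusts the levels for small-sample
    undercoverage (see :func:`expanded_percentiles`, using the smaller
    group's size), approaching 2.5-97.5 for large groups.
    """
    num = np.asarray(values_num, dtype=float)
    den = np.asarray(values_den, dtype=float)
    if num.size == 0 or den.size == 0:
        raise ValueError("both groups must be non-empty")
    if ci_method == "expanded":
        n_eff = min(num.size, den.size)
        ci = expanded_percentiles(n_eff) if n_eff > 1 else (2.5, 97.5)
    elif ci_method == "percentile":
        ci = (2.5, 97.5)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    point = ratio_of_means(num, den)
    rng = np.random.default_rng(seed)
    m_num = num[rng.integers(0, num.size, (n_boot, num.size))].mean(axis=1)
    m_den = den[rng.integers(0, den.size, (n_boot, den.size))].mean(axis=1)
    rejected = 0
    bad = np.flatnonzero(m_den == 0.0)
    while bad.size:
        rejected += bad.size
        m_num[bad] = num[rng.integers(0, num.size, (bad.size, num.size))].mean(axis=1)
        m_den[bad] = den[rng.integers(0, den.size, (bad.size, den.size))].mean(axis=1)
        bad = bad[m_den[bad] == 0.0]
    draws = m_num / m_den
    if rejected > 0.01 * n_boot:
        logger.warning("bootstrap_ratio: %d replicates redrawn (zero denominator)", rejected)
    lo, hi = np.percentile(draws, ci)
    se_num = num.std(ddof=1) / math.sqrt(num.size) if num.size > 1 else 0.0
    se_den = den.std(ddof=1) / math.sqrt(den.size) if den.size > 1 else 0.0
    return RatioComparison(
        trait=trait,
        numerator_group=numerator_group,
        denominator_group=denominator_group,
        point_ratio=point,
        ci_low=float(lo),
        ci_high=float(hi),
        delta_se=ratio_se_delta(num.mean(), se_num, den.mean(), se_den),
        n_boot=n_boot,
        seed=seed,
        bootstrap=draws,
        n_rejected=rejected,
    )


def ratio_se_delta(mean_a: float, se_a: float, mean_b: float, se_b: float) -> float:
    """Delta-method SE of a ratio of independent means (zero covariance)."""
    if mean_b == 0.0:
        raise ZeroDivisionError("denominator mean is zero")
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be non-negative")
    if mean_a == 0.0:
        return se_a / abs(mean_b)
    r = mean_a / mean_b
    return abs(r) * math.sqrt((se_a / mean_a) ** 2 + (se_b / mean_b) ** 2)


def ratio_difference_test(r1: float, se1: float, r2: float, se2: float) -> tuple[float, float]:
    """Normal-approximation z test for a difference of two independent ratios."""
    from scipy import stats

    se = math.sqrt(se1**2 + se2**2)
    if se == 0.0:
        raise ValueError("both ratios have zero SE")
    z = (r1 - r2) / se
    return z, 2.0 * float(stats.norm.sf(abs(z)))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to a number of significant figures (for reported fold changes)."""
    if x == 0:
        return 0.0
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1)))


# ---------------------------------------------------------------------------
# Factorial models
# ---------------------------------------------------------------------------

def fit_factorial(
    trait_values,
    stage=None,
    genotype=None,
    sex=None,
    drop_interaction_p: float = 0.2,
    log10_transform: bool = False,
):
    """Type III factorial ANOVA with backward-dropped interactions.

    Fits the trait on the supplied crossed fixed factors (any non-None of
    stage, genotype, sex) with sum-to-zero contrasts and Type III sums of
    squares.  Two-way interactions with P > ``drop_interaction_p`` are
    removed (least significant first) and the model refit.  Returns
    ``(anova_table, tukey)`` where ``tukey`` holds Tukey-Kramer-adjusted
    pairwise genotype comparisons (None if genotype was not supplied).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    y = np.asarray(trait_values, dtype=float)
    if log10_transform:
        if np.any(y <= 0):
            raise ValueError("log10 transform requires strictly positive values")
        y = np.log10(y)
    df = pd.DataFrame({"y": y})
    factors = []
    for name, labels in (("stage", stage), ("genotype", genotype), ("sex", sex)):
        if labels is not None:
            df[name] = list(labels)
            factors.append(name)
    if not factors:
        raise ValueError("at least one factor is required")
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    dupes = [
        (a, b) for a, b in itertools.combinations(factors, 2)
        if (df.groupby(a, observed=True)[b].nunique() == 1).all()
        and (df.groupby(b, observed=True)[a].nunique() == 1).all()
    ]
    if dupes:
        raise ValueError(f"aliased factors (rank deficiency): {dupes}")

    def _formula(inter: list[tuple[str, str]]) -> str:
        terms = [f"C({f}, Sum)" for f in factors]
        terms += [f"C({a}, Sum):C({b}, Sum)" for a, b in inter]
        return "y ~ " + " + ".join(terms)

    interactions = list(itertools.combinations(factors, 2))
    while True:
        model = smf.ols(_formula(interactions), data=df).fit()
        table = sm.stats.anova_lm(model, typ=3)
        droppable = []
        for a, b in interactions:
            term = f"C({a}, Sum):C({b}, Sum)"
            if term in table.index and table.loc[term, "PR(>F)"] > drop_interaction_p:
                droppable.append((a, b))
        if not droppable:
            break
        # drop the least significant interaction first, then refit
        worst = max(droppable, key=lambda ab: table.loc[f"C({ab[0]}, Sum):C({ab[1]}, Sum)", "PR(>F)"])
        interactions.remove(worst)

    tukey = None
    if "genotype" in factors and df["genotype"].nunique() > 1:
        tukey = pairwise_tukeyhsd(df["y"].to_numpy(), df["genotype"].to_numpy())
    return table, tukey
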