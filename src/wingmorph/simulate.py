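"""Synthetic landmark datasets with the statistical structure the pipeline assumes.

Each stage (larva / pupa / adult) has a hard-coded 17-point template
outline (near-circular pouch, paddle, elongated blade); genotypes displace
the template by a fixed shape-space vector; specimens add isotropic
Gaussian shape noise and are then uniformly rescaled so that the total
polygon area follows a lognormal size law.  Generation is a pure function
of the seed; per-group RNG substreams are derived deterministically.

The default per-group sample sizes and area parameters come from
:mod:`wingmorph.reference`; templates and effect fields are package
fixtures chosen to reproduce the qualitative structure of the study system
(stage noise ordering pupa > larva > adult, mutant effects appearing at
the documented stages), not to equal any measured mean configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import reference
from .io import DEFAULT_SCHEME, LandmarkScheme, Specimen
from .scalar_measures import polygon_area
from .superimposition import centroid_size

logger = logging.getLogger(__name__)

STAGES = ("larva", "pupa", "adult")
GENOTYPES = ("yw", "shf2", "ds")


# ---------------------------------------------------------------------------
# Stage templates
# ---------------------------------------------------------------------------

def _bezier(p0, p1, p2, ts):
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    return np.array([
        (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2 for t in ts
    ])


def _build_template(fixed, anterior_ctrl, posterior_ctrl) -> np.ndarray:
    """17-point outline: 8 fixed landmarks plus margin semilandmarks sampled
    from quadratic arcs between the margin anchors (1->3 and 5->7)."""
    fixed = np.asarray(fixed, dtype=float)
    anterior = _bezier(fixed[0], anterior_ctrl, fixed[2], [k / 7 for k in range(1, 7)])
    posterior = _bezier(fixed[4], posterior_ctrl, fixed[6], [k / 4 for k in range(1, 4)])
    return np.vstack([fixed, anterior, posterior])


def _polar(r: float, deg: float) -> tuple[float, float]:
    th = np.radians(deg)
    return (r * np.cos(th), r * np.sin(th))


def default_templates() -> dict[str, np.ndarray]:
    """Raw stage templates (arbitrary units; size is set by the area law).

    The larval disc has its margin arc (landmarks 1,3,5,7 plus
    semilandmarks) crossing the compact pouch while the provein tips
    (2,4,6,8) fan out toward the fold; the pupal wing is an elongating
    paddle; the adult is a long narrow blade.  The three shapes are tuned
    so pairwise Procrustes distances fall near 0.46 (larva-pupa), 0.34
    (pupa-adult) and 0.68 (larva-adult), dominating the default
    within-stage noise.
    """
    larva = _build_template(
        [_polar(0.45, 85), _polar(1.05, 120), _polar(0.50, 5), _polar(1.00, 160),
         _polar(0.50, -25), _polar(1.00, 205), _polar(0.45, -85), _polar(1.05, 245)],
        _polar(0.60, 40), _polar(0.60, -55),
    )
    pupa = _build_template(
        [[0.95, 0.65], [0.00, 0.50], [2.05, 0.27], [0.30, 0.18],
         [2.10, -0.05], [0.22, -0.07], [1.20, -0.60], [0.05, -0.44]],
        (1.75, 0.80), (2.00, -0.50),
    )
    adult = _build_template(
        [[1.30, 0.38], [0.00, 0.24], [3.60, 0.24], [0.60, 0.13],
         [3.65, -0.04], [0.55, -0.08], [1.85, -0.42], [0.05, -0.27]],
        (2.80, 0.58), (3.45, -0.38),
    )
    return {"larva": larva, "pupa": pupa, "adult": adult}


# ---------------------------------------------------------------------------
# Genotype effect fields (displacements in shape units, zero-mean columns)
# ---------------------------------------------------------------------------

def _center_columns(d: np.ndarray) -> np.ndarray:
    return d - d.mean(axis=0, keepdims=True)


def _scaled_effect(raw: np.ndarray, norm: float) -> np.ndarray:
    raw = _center_columns(raw)
    length = float(np.linalg.norm(raw))
    if length == 0.0:
        return raw
    return raw * (norm / length)


def _pd_contraction(unit_template: np.ndarray) -> np.ndarray:
    """Pull distal points (large x deviation) inward: proximo-distal shortening."""
    x = unit_template[:, 0] - unit_template[:, 0].mean()
    d = np.zeros_like(unit_template)
    d[:, 0] = -np.maximum(x, 0.0)
    return d


def _ap_broadening(unit_template: np.ndarray) -> np.ndarray:
    """Push points outward along y: anterior-posterior widening."""
    y = unit_template[:, 1] - unit_template[:, 1].mean()
    d = np.zeros_like(unit_template)
    d[:, 1] = y
    return d


def _l3l4_narrowing(unit_template: np.ndarray) -> np.ndarray:
    """Move landmarks 3,4 toward 5,6: narrows the middle (intervein) region."""
    d = np.zeros_like(unit_template)
    d[2] = unit_template[4] - unit_template[2]  # 3 -> toward 5
    d[3] = unit_template[5] - unit_template[3]  # 4 -> toward 6
    return d


def default_genotype_effects(
    templates: dict[str, np.ndarray] | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """ds-like and shf2-like displacement fields per stage (shape units)."""
    templates = templates or default_templates()
    unit = {s: t / centroid_size(t) for s, t in templates.items()}
    effects: dict[str, dict[str, np.ndarray]] = {
        g: {s: np.zeros((17, 2)) for s in STAGES} for g in GENOTYPES
    }
    # ds: distal P-D contraction from the larval stage, A-P broadening at
    # the pupal stage, both carried (plus extra broadening) into the adult.
    effects["ds"]["larva"] = _scaled_effect(_pd_contraction(unit["larva"]), 0.12)
    effects["ds"]["pupa"] = _scaled_effect(
        _pd_contraction(unit["pupa"]), 0.10
    ) + _scaled_effect(_ap_broadening(unit["pupa"]), 0.15)
    effects["ds"]["adult"] = _scaled_effect(
        _pd_contraction(unit["adult"]), 0.08
    ) + _scaled_effect(_ap_broadening(unit["adult"]), 0.10)
    # shf2: middle-region narrowing present from the larval stage onward.
    for s, norm in (("larva", 0.10), ("pupa", 0.10), ("adult", 0.10)):
        effects["shf2"][s] = _scaled_effect(_l3l4_narrowing(unit[s]), norm)
    return effects


DEFAULT_SHAPE_NOISE_SD = {"larva": 0.015, "pupa": 0.025, "adult": 0.005}


@dataclass
class SimulationConfig:
    """Full description of a synthetic dataset (pure function of ``seed``)."""

    templates: dict[str, np.ndarray] = field(default_factory=default_templates)
    genotype_effects: dict[str, dict[str, np.ndarray]] = field(
        default_factory=default_genotype_effects
    )
    shape_noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SHAPE_NOISE_SD)
    )
    area_mean: dict[tuple[str, str], float] = field(default_factory=dict)
    area_cv: dict[tuple[str, str], float] = field(default_factory=dict)
    n_per_group: dict[tuple[str, str], int] = field(default_factory=dict)
    sex_ratio: float = 0.5
    seed: int = 0
    scheme: LandmarkScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        if not self.n_per_group:
            self.n_per_group = {
                (r.stage, r.genotype): int(r.n)
                for r in reference.GROUP_SUMMARY.itertuples()
            }
        if not self.area_mean:
            self.area_mean = {
                (r.stage, r.genotype): float(r.area_total_mean)
                for r in reference.GROUP_SUMMARY.itertuples()
            }
        if not self.area_cv:
            self.area_cv = {
                (r.stage, r.genotype): float(r.area_total_sd / r.area_total_mean)
                for r in reference.GROUP_SUMMARY.itertuples()
            }
        for s, sd in self.shape_noise_sd.items():
            if sd < 0:
                raise ValueError(f"negative shape noise SD for stage {s!r}")
        for key, n in self.n_per_group.items():
            if n < 0:
                raise ValueError(f"negative group size for {key}")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        for s, t in self.templates.items():
            if float(np.linalg.norm(t - t.mean(axis=0))) <= 0:
                raise ValueError(f"degenerate template for stage {s!r}")
        for g, per_stage in self.genotype_effects.items():
            for s, d in per_stage.items():
                if np.abs(np.asarray(d).mean(axis=0)).max() > 1e-9:
                    raise ValueError(
                        f"genotype effect ({g},{s}) is not a pure shape "
                        "effect (non-zero column mean)"
                    )

    @property
    def groups(self) -> list[tuple[str, str]]:
        order = {s: i for i, s in enumerate(STAGES)}
        return sorted(self.n_per_group, key=lambda k: (order.get(k[0], 99), k[1]))


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_dataset(config: SimulationConfig) -> list[Specimen]:
    """Draw the full dataset described by ``config``.

    Per specimen: unit-centroid-size stage template + genotype displacement
    + i.i.d. Gaussian coordinate noise, then a uniform rescaling so the
    total polygon area equals a lognormal draw with the configured
    mean/CV.  Identical seeds give bit-identical datasets.
    """
    specimens: list[Specimen] = []
    stage_index = {s: i for i, s in enumerate(STAGES)}
    for gi, (stage, genotype) in enumerate(config.groups):
        n = config.n_per_group[(stage, genotype)]
        if n == 0:
            continue
        template = np.asarray(config.templates[stage], dtype=float)
        unit = template / centroid_size(template)
        effect = np.asarray(
            config.genotype_effects.get(genotype, {}).get(stage, np.zeros((17, 2))),
            dtype=float,
        )
        sd = config.shape_noise_sd.get(stage, 0.0)
        mu, sigma = _lognormal_params(
            config.area_mean[(stage, genotype)], config.area_cv[(stage, genotype)]
        )
        rng = np.random.default_rng(
            [config.seed, stage_index.get(stage, 99), gi]
        )
        for i in range(n):
            shape = unit + effect + rng.normal(0.0, sd, size=unit.shape)
            target_area = float(np.exp(rng.normal(mu, sigma)))
            current = polygon_area(shape, "total", check_simple=False)
            if current <= 0:
                raise RuntimeError(
                    f"degenerate simulated outline in group ({stage},{genotype})"
                )
            shape = shape * np.sqrt(target_area / current)
            sex = "F" if rng.random() < config.sex_ratio else "M"
            specimens.append(
                Specimen(
                    id=f"{stage}_{genotype}_{i + 1:03d}",
                    stage=stage,
                    genotype=genotype,
                    sex=sex,
                    landmarks=shape,
                    scheme=config.scheme,
                )
            )
    return specimens


def inject_outliers(
    dataset: list[Specimen],
    group: tuple[str, str],
    count: int,
    displacement_sd: float,
    seed: int,
    noise_sd: dict[str, float] | None = None,
) -> tuple[list[Specimen], list[str]]:
    """Displace ``count`` random group members by ``displacement_sd`` noise-SDs.

    The displacement is a random direction in shape space (column-centred,
    so it carries no translation) with norm ``displacement_sd`` times the
    group's per-coordinate noise SD, applied at the specimen's own scale.
    Returns the modified dataset copy and the altered ids (ground truth).
    """
    if displacement_sd < 0:
        raise ValueError("displacement_sd must be >= 0")
    noise_sd = noise_sd or DEFAULT_SHAPE_NOISE_SD
    stage, genotype = group
    members = [i for i, s in enumerate(dataset) if (s.stage, s.genotype) == group]
    if not members:
        raise ValueError(f"group {group} not present in dataset")
    if count > len(members):
        raise ValueError(f"count={count} exceeds group size {len(members)}")
    out = [s.copy() for s in dataset]
    altered: list[str] = []
    if count == 0 or displacement_sd == 0:
        return out, altered
    rng = np.random.default_rng(seed)
    chosen = rng.choice(members, size=count, replace=False)
    sd = noise_sd.get(stage, 0.0)
    for idx in chosen:
        spec = out[idx]
        direction = rng.normal(size=(spec.scheme.n_landmarks, 2))
        direction -= direction.mean(axis=0, keepdims=True)
        direction /= np.linalg.norm(direction)
        cs = centroid_size(spec.landmarks)
        spec.landmarks = spec.landmarks + direction * displacement_sd * sd * cs
        altered.append(spec.id)
    return out, altered
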