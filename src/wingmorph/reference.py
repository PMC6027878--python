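"""Default sampling design and size parameters for the three-stage study system.

These are the per-group sample sizes and dorsal-area summary statistics
(mm^2, mean and SD of the anterior / middle / posterior / total polygon
areas) used as defaults by the simulator: three developmental stages
(larval disc, 5 h pupal wing, adult wing) crossed with a wild-type
(``yw``) and two mutant (``shf2``, ``ds``) genotypes.
"""

from __future__ import annotations

import pandas as pd

#: One row per stage x genotype cell of the reference design.
GROUP_SUMMARY = pd.DataFrame(
    [
        # stage, genotype, n, n_F, n_M, anterior, sd, middle, sd, posterior, sd, total, sd
        ("larva", "yw",   16, 10, 6, 0.0053, 0.0008, 0.0016, 0.0003, 0.0029, 0.0005, 0.0100, 0.0014),
        ("larva", "shf2",  8,  5, 3, 0.0041, 0.0003, 0.0009, 0.0001, 0.0025, 0.0004, 0.0075, 0.0008),
        ("larva", "ds",    8,  1, 7, 0.0056, 0.0016, 0.0014, 0.0004, 0.0031, 0.0008, 0.0101, 0.0027),
        ("pupa",  "yw",   15,  6, 9, 0.0125, 0.0023, 0.0034, 0.0007, 0.0079, 0.0016, 0.0240, 0.0039),
        ("pupa",  "shf2", 15,  6, 9, 0.0107, 0.0030, 0.0014, 0.0004, 0.0055, 0.0015, 0.0177, 0.0047),
        ("pupa",  "ds",   12,  4, 8, 0.0108, 0.0024, 0.0032, 0.0005, 0.0064, 0.0014, 0.0205, 0.0041),
        ("adult", "yw",    6,  2, 4, 0.375,  0.040,  0.142,  0.017,  0.326,  0.036,  0.843,  0.085),
        ("adult", "shf2", 16,  8, 8, 0.383,  0.040,  0.092,  0.011,  0.309,  0.036,  0.784,  0.083),
        ("adult", "ds",   12,  9, 3, 0.486,  0.051,  0.199,  0.019,  0.427,  0.050,  1.112,  0.119),
    ],
    columns=[
        "stage", "genotype", "n", "n_female", "n_male",
        "area_anterior_mean", "area_anterior_sd",
        "area_middle_mean", "area_middle_sd",
        "area_posterior_mean", "area_posterior_sd",
        "area_total_mean", "area_total_sd",
    ],
)

GENOTYPES = ("yw", "shf2", "ds")


def total_area_mean(stage: str, genotype: str) -> float:
    return float(_cell(stage, genotype)["area_total_mean"])


def total_area_sd(stage: str, genotype: str) -> float:
    return float(_cell(stage, genotype)["area_total_sd"])


def sample_size(stage: str, genotype: str) -> int:
    return int(_cell(stage, genotype)["n"])


def total_sample_size() -> int:
    """Total number of specimens across all stage/genotype cells."""
    return int(GROUP_SUMMARY["n"].sum())


def _cell(stage: str, genotype: str) -> pd.Series:
    sel = GROUP_SUMMARY[
        (GROUP_SUMMARY["stage"] == stage) & (GROUP_SUMMARY["genotype"] == genotype)
    ]
    if len(sel) != 1:
        raise KeyError(f"no reference cell for stage={stage!r}, genotype={genotype!r}")
    return sel.iloc[0]
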