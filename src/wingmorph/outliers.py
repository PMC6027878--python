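"""Outlier screening: robust multivariate distances (MCD) and Grubbs' test.

Shape outliers are screened within each genotype x stage group on the
first few principal components of the pooled shape PCA.  Robust location
and scatter come from the Minimum Covariance Determinant estimator; each
specimen's distance from the robust mean is expressed in multivariate
SD units (the square root of the squared robust Mahalanobis distance) and
flagged at 3 and 6 SD.  Flagged specimens are reported, never dropped —
exclusion decisions are external.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet

logger = logging.getLogger(__name__)


@dataclass
class OutlierReport:
    id: str
    group: str
    robust_distance_sd: float
    over3sd: bool
    over6sd: bool
    chi2_flag: bool   # alternative rule: squared distance > chi2_p(0.975)
    decision: str = "keep"

    def __post_init__(self) -> None:
        if self.robust_distance_sd < 0:
            raise ValueError("distances must be non-negative")
        if self.over6sd and not self.over3sd:
            raise ValueError("over6sd implies over3sd")


def default_support_fraction(n: int, p: int) -> float:
    """Maximal-breakdown support: ceil((n + p + 1) / 2) / n."""
    return math.ceil((n + p + 1) / 2) / n


def mcd_screen(
    pc_scores: np.ndarray,
    group_labels: Sequence,
    ids: Sequence[str] | None = None,
    support_fraction: float | None = None,
    seed: int = 0,
    chi2_alpha: float = 0.025,
) -> list[OutlierReport]:
    """Robust within-group outlier screen on shape PC scores.

    Groups with too few members (n <= p + 1) or a singular robust scatter
    are skipped with a logged warning rather than silently flagged.
    ``support_fraction`` in (0.5, 1] overrides the maximal-breakdown
    default.
    """
    X = np.asarray(pc_scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    labels = np.asarray(group_labels)
    if ids is None:
        ids = [f"specimen_{i + 1}" for i in range(n)]
    if support_fraction is not None and not (0.5 < support_fraction <= 1.0):
        raise ValueError("support_fraction must lie in (0.5, 1]")
    chi2_cut = stats.chi2.ppf(1.0 - chi2_alpha, df=p)
    reports: list[OutlierReport] = []
    for group in pd.unique(labels):
        idx = np.flatnonzero(labels == group)
        Xg = X[idx]
        if len(idx) <= p + 1:
            logger.warning(
                "group %r has n=%d <= p+1=%d observations; skipped", group, len(idx), p + 1
            )
            continue
        frac = support_fraction if support_fraction is not None else default_support_fraction(len(idx), p)
        try:
            mcd = MinCovDet(support_fraction=frac, random_state=seed).fit(Xg)
            d2 = mcd.mahalanobis(Xg)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("group %r: MCD failed (%s); skipped", group, exc)
            continue
        if not np.all(np.isfinite(d2)):
            logger.warning("group %r: singular robust scatter; skipped", group)
            continue
        d = np.sqrt(np.maximum(d2, 0.0))
        for local, i in enumerate(idx):
            reports.append(
                OutlierReport(
                    id=str(ids[i]),
                    group=str(group),
                    robust_distance_sd=float(d[local]),
                    over3sd=bool(d[local] > 3.0),
                    over6sd=bool(d[local] > 6.0),
                    chi2_flag=bool(d2[local] > chi2_cut),
                )
            )
    return reports


def reports_to_frame(reports: list[OutlierReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.id, "group": r.group,
                "robust_distance_sd": r.robust_distance_sd,
                "over3sd": r.over3sd, "over6sd": r.over6sd,
                "chi2_flag": r.chi2_flag, "decision": r.decision,
            }
            for r in reports
        ],
        columns=["id", "group", "robust_distance_sd", "over3sd", "over6sd",
                 "chi2_flag", "decision"],
    )


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_screen(values, alpha: float = 0.05) -> int | None:
    """Two-sided Grubbs test; returns the index of the single most extreme
    value if significant at ``alpha``, else None."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs' test needs at least 3 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    s = x.std(ddof=1)
    if s == 0.0:
        raise ValueError("zero variance")
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    G = dev[i] / s
    if G > grubbs_critical_value(x.size, alpha):
        return i
    return None
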