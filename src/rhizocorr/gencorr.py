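"""Broad-sense genetic and environmental correlations between the two
fitness components, per soil environment.

Within one environment the g plant-genotype x rhizobium-mix associations
(g = 12 in the full design) are treated as a single random grouping factor
in a balanced one-way MANOVA with (nodule count, ln fruit) as the joint
response.  With k replicates per association, the between-group (H) and
residual (E) sum-of-cross-products matrices are

    H = k * sum_i (m_i - m)(m_i - m)'        over association means m_i,
    E = sum_i sum_j (y_ij - m_i)(y_ij - m_i)',

and the balanced expected-mean-squares identities give the
method-of-moments components

    Cov_E = E / (g (k - 1)),
    Cov_G = (H / (g - 1) - Cov_E) / k.

Correlations are off-diagonal over the geometric mean of the diagonals.
Cov_G diagonals can come out negative under the moment method; they are
flagged and the correlation reported as undefined, never clamped (clamping
would bias the jackknife SE downward).  Standard errors come from the
delete-one-association jackknife, SE^2 = ((g-1)/g) * sum_i (t_i - t_bar)^2,
recomputing the whole pipeline with each association left out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .anova import ln_fruit
from .errors import (
    DegenerateDesignError,
    DegenerateFitError,
    InsufficientDataError,
    UnbalancedDesignError,
)
from .io import CONTROL_MIX

TRAIT_LABELS = ("nodules", "ln_fruit")


# ---------------------------------------------------------------------------
# group summaries


@dataclass(frozen=True)
class GroupStats:
    """Per-association sufficient statistics for the one-way MANOVA.

    ``means`` is (g, 2): bivariate association means; ``within_sscp`` is
    (g, 2, 2): each association's residual sum-of-cross-products.  Everything
    downstream (full fit and every jackknife replicate) is computed from
    these, so leave-one-out refits cost O(1) per association.
    """

    labels: Tuple[str, ...]
    means: np.ndarray
    within_sscp: np.ndarray
    k: int

    @property
    def g(self) -> int:
        return len(self.labels)


def association_labels(df: pd.DataFrame) -> pd.Series:
    return df["medicago_genotype"].astype(str) + ":" + df["rhizobium_mix"].astype(str)


def group_stats(df: pd.DataFrame, *, offset_policy: str = "plus_one") -> GroupStats:
    """Summarise one environment's records per M x R association.

    Controls are dropped; groups must be balanced (equal k across the g
    associations) or the MoM identities do not hold and the call refuses.
    """
    sub = df[df["rhizobium_mix"] != CONTROL_MIX]
    if len(sub) == 0:
        raise InsufficientDataError("no inoculated records in this environment")
    labels = association_labels(sub)
    y = np.column_stack(
        [
            sub["nodule_count"].to_numpy(float),
            ln_fruit(sub["fruit_count"].to_numpy(), policy=offset_policy),
        ]
    )
    order = np.argsort(labels.to_numpy(), kind="stable")
    labels_sorted = labels.to_numpy()[order]
    y = y[order]

    uniq, starts, counts = np.unique(labels_sorted, return_index=True, return_counts=True)
    if counts.min() != counts.max():
        bad = [
            (lab, int(c)) for lab, c in zip(uniq, counts) if c != np.bincount(counts).argmax()
        ]
        raise UnbalancedDesignError(
            f"unequal replicates across associations: {bad}", offending_cells=bad
        )
    k = int(counts[0])

    g = len(uniq)
    means = np.empty((g, 2))
    within = np.empty((g, 2, 2))
    for i, (s, c) in enumerate(zip(starts, counts)):
        block = y[s : s + c]
        m = block.mean(axis=0)
        dev = block - m
        means[i] = m
        within[i] = dev.T @ dev
    return GroupStats(labels=tuple(uniq), means=means, within_sscp=within, k=k)


# ---------------------------------------------------------------------------
# cross-products and moment components


@dataclass(frozen=True)
class CrossProducts:
    """Between (H) and residual (E) sum-of-cross-products matrices."""

    H: np.ndarray
    E: np.ndarray
    g: int
    k: int
    trait_labels: Tuple[str, str] = TRAIT_LABELS


@dataclass(frozen=True)
class CovEstimates:
    """Method-of-moments Cov_G and Cov_E with negative-variance flags."""

    cov_G: np.ndarray
    cov_E: np.ndarray
    g: int
    k: int
    negative_variance_flags: Tuple[bool, bool] = (False, False)


def crossproducts_from_stats(
    stats: GroupStats, keep: Optional[np.ndarray] = None
) -> CrossProducts:
    means = stats.means if keep is None else stats.means[keep]
    within = stats.within_sscp if keep is None else stats.within_sscp[keep]
    g, k = len(means), stats.k
    if g < 2:
        raise DegenerateDesignError("g < 2 associations: Cov_G inestimable")
    if k < 2:
        raise DegenerateDesignError("k < 2 replicates: Cov_E inestimable")
    grand = means.mean(axis=0)
    dev = means - grand
    H = k * (dev.T @ dev)
    E = within.sum(axis=0)
    return CrossProducts(H=H, E=E, g=g, k=k)


def manova_crossproducts(
    df: pd.DataFrame, *, offset_policy: str = "plus_one"
) -> CrossProducts:
    """One-way MANOVA cross-products over the M x R associations of one
    environment (controls excluded); H + E equals the total corrected
    cross-product matrix by construction."""
    return crossproducts_from_stats(group_stats(df, offset_policy=offset_policy))


def total_crossproducts(df: pd.DataFrame, *, offset_policy: str = "plus_one") -> np.ndarray:
    """Total corrected sum-of-cross-products (independent check of H + E)."""
    sub = df[df["rhizobium_mix"] != CONTROL_MIX]
    y = np.column_stack(
        [
            sub["nodule_count"].to_numpy(float),
            ln_fruit(sub["fruit_count"].to_numpy(), policy=offset_policy),
        ]
    )
    dev = y - y.mean(axis=0)
    return dev.T @ dev


def mom_covariances(cp: CrossProducts) -> CovEstimates:
    """Invert the balanced one-way expected-mean-squares identities."""
    if cp.g < 2 or cp.k < 2:
        raise DegenerateDesignError("need g >= 2 and k >= 2 for moment estimation")
    cov_E = cp.E / (cp.g * (cp.k - 1))
    cov_G = (cp.H / (cp.g - 1) - cov_E) / cp.k
    flags = (bool(cov_G[0, 0] < 0), bool(cov_G[1, 1] < 0))
    return CovEstimates(cov_G=cov_G, cov_E=cov_E, g=cp.g, k=cp.k,
                        negative_variance_flags=flags)


# ---------------------------------------------------------------------------
# correlations


@dataclass(frozen=True)
class Correlation:
    """A correlation that may be undefined (negative moment variance)."""

    value: Optional[float]
    defined: bool
    reason: Optional[str] = None

    @staticmethod
    def of(value: float) -> "Correlation":
        return Correlation(value=float(value), defined=True)

    @staticmethod
    def undefined(reason: str) -> "Correlation":
        return Correlation(value=None, defined=False, reason=reason)


def correlation_from_cov(cov: np.ndarray) -> Correlation:
    """Off-diagonal over sqrt of the diagonal product; tagged undefined
    (never an exception) when a diagonal is nonpositive, so jackknife loops
    can carry on."""
    cov = np.asarray(cov, float)
    bad = [TRAIT_LABELS[i] for i in (0, 1) if cov[i, i] <= 0]
    if bad:
        return Correlation.undefined(
            "nonpositive variance for trait(s): " + ", ".join(bad)
        )
    return Correlation.of(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))


def _statistic_from_stats(stats: GroupStats, which: str,
                          keep: Optional[np.ndarray] = None) -> Correlation:
    cp = crossproducts_from_stats(stats, keep)
    est = mom_covariances(cp)
    if which == "r_G":
        return correlation_from_cov(est.cov_G)
    if which == "r_E":
        return correlation_from_cov(est.cov_E)
    raise ValueError(f"unknown statistic {which!r}; use 'r_G' or 'r_E'")


@dataclass(frozen=True)
class JackknifeResult:
    point: Correlation
    se: Optional[float]
    replicates: Tuple[Optional[float], ...]
    n_dropped: int


def jackknife_se(
    data, statistic: str = "r_G", *, offset_policy: str = "plus_one"
) -> JackknifeResult:
    """Delete-one-association jackknife SE of r_G or r_E.

    ``data`` is either one environment's records or a precomputed
    :class:`GroupStats`.  Each of the g replicates reruns the full pipeline
    (cross-products -> moment components -> correlation) on the remaining
    g - 1 associations.  Undefined replicates are dropped from the SE sum
    with the count recorded in ``n_dropped``; the (m-1)/m jackknife factor
    uses the number m of defined replicates.
    """
    stats = data if isinstance(data, GroupStats) else group_stats(
        data, offset_policy=offset_policy
    )
    g = stats.g
    if g < 3:
        raise DegenerateDesignError("jackknife needs g >= 3 associations")

    point = _statistic_from_stats(stats, statistic)
    replicates: List[Optional[float]] = []
    for i in range(g):
        keep = np.ones(g, dtype=bool)
        keep[i] = False
        rep = _statistic_from_stats(stats, statistic, keep)
        replicates.append(rep.value if rep.defined else None)

    defined = np.array([r for r in replicates if r is not None], float)
    m = len(defined)
    if m < 2:
        se = None
    else:
        se = float(np.sqrt((m - 1) / m * np.sum((defined - defined.mean()) ** 2)))
    return JackknifeResult(
        point=point, se=se, replicates=tuple(replicates), n_dropped=g - m
    )


# ---------------------------------------------------------------------------
# genotypic means and major axis


def genotypic_means(df: pd.DataFrame, *, offset_policy: str = "plus_one") -> pd.DataFrame:
    """Per-association bivariate means (the joint genotypic-value estimates)."""
    stats = group_stats(df, offset_policy=offset_policy)
    return pd.DataFrame(
        {
            "association": list(stats.labels),
            "mean_nodules": stats.means[:, 0],
            "mean_ln_fruit": stats.means[:, 1],
        }
    )


def major_axis_fit(points: np.ndarray) -> Tuple[float, float]:
    """Major-axis (first principal axis) slope and intercept through the
    centroid of bivariate points (x = mean nodules, y = mean ln fruit).

    Raises on identical points, on an exact eigenvalue tie (circularly
    symmetric cloud: the axis is arbitrary) and on a vertical axis.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise DegenerateFitError("need at least two bivariate points")
    centroid = pts.mean(axis=0)
    dev = pts - centroid
    cov = dev.T @ dev / (len(pts) - 1)
    if np.allclose(cov, 0):
        raise DegenerateFitError("all points identical: no axis")
    eigvals, eigvecs = np.linalg.eigh(cov)
    scale = max(abs(eigvals[0]), abs(eigvals[1]))
    if np.isclose(eigvals[0], eigvals[1], rtol=1e-9, atol=1e-12 * scale):
        raise DegenerateFitError("eigenvalue tie: major axis undefined")
    v = eigvecs[:, np.argmax(eigvals)]
    if abs(v[0]) < 1e-12:
        raise DegenerateFitError("vertical major axis: slope undefined")
    slope = float(v[1] / v[0])
    intercept = float(centroid[1] - slope * centroid[0])
    return slope, intercept


# ---------------------------------------------------------------------------
# one-environment composition


@dataclass(frozen=True)
class CorrelationResult:
    """One row of the per-environment correlation table, plus diagnostics."""

    environment: str
    n: int
    r_G: Correlation
    se_rG: Optional[float]
    r_E: Correlation
    se_rE: Optional[float]
    jackknife_replicates: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "environment": self.environment,
            "n": self.n,
            "r_G": self.r_G.value,
            "r_G_defined": self.r_G.defined,
            "r_G_reason": self.r_G.reason,
            "se_rG": self.se_rG,
            "r_E": self.r_E.value,
            "r_E_defined": self.r_E.defined,
            "se_rE": self.se_rE,
            "jackknife_replicates": {
                key: list(val) for key, val in self.jackknife_replicates.items()
            },
            "diagnostics": dict(self.diagnostics),
        }


def estimate_environment(
    df: pd.DataFrame, environment: str, *, offset_policy: str = "plus_one"
) -> CorrelationResult:
    """Full per-environment pipeline: restrict to one soil treatment,
    drop controls, estimate r_G and r_E with jackknife SEs."""
    sub = df[df["soil_treatment"] == environment]
    if len(sub) == 0:
        raise InsufficientDataError(f"no records for environment {environment!r}")
    stats = group_stats(sub, offset_policy=offset_policy)
    est = mom_covariances(crossproducts_from_stats(stats))
    jk_g = jackknife_se(stats, "r_G")
    jk_e = jackknife_se(stats, "r_E")
    return CorrelationResult(
        environment=environment,
        n=stats.g,
        r_G=jk_g.point,
        se_rG=jk_g.se,
        r_E=jk_e.point,
        se_rE=jk_e.se,
        jackknife_replicates={"r_G": jk_g.replicates, "r_E": jk_e.replicates},
        diagnostics={
            "negative_variance_flags": list(est.negative_variance_flags),
            "r_G_replicates_dropped": jk_g.n_dropped,
            "r_E_replicates_dropped": jk_e.n_dropped,
            "k": stats.k,
        },
    )
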