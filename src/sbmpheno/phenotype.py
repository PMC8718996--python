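"""Per-subject uncertainty, continuous vulnerability scores and cluster stats.

A fitted block model gives each subject a discrete community label, but the
posterior samples carry much more: how often each subject visited each
community across the chain.  Two scalar summaries are derived per subject:

* the *uncertainty* ``u(i)`` — the fraction of post-burn-in samples in which
  the subject was assigned to a community other than its MAP community;
* the *vulnerability score* ``v(i)`` — the fraction of samples assigning the
  subject to the community annotated as the vulnerable phenotype, a
  continuous ranking within and across clusters.

Cluster annotation (vulnerable / intermediate / resilient for K = 3) ranks
clusters by a composite of orientation-adjusted mean z-scores.  Descriptive
statistics comparing clusters — one-way ANOVA F tests per measure and the
adjusted Rand index between partitions — round out the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "PhenotypeReport",
    "AmbiguousAnnotationError",
    "occupancy",
    "uncertainty",
    "vulnerability_score",
    "annotate_clusters",
    "flag_subjects",
    "anova_f",
    "anova_table",
    "adjusted_rand_index",
    "connectivity_summary",
    "build_report",
]

CLUSTER_NAMES_K3 = {1: "vulnerable", 2: "intermediate", 3: "resilient"}


class AmbiguousAnnotationError(ValueError):
    """Two clusters tie on the composite score; annotation is undefined."""


def occupancy(samples) -> np.ndarray:
    """n x K matrix of per-subject community occupancy proportions.

    Rows sum to one; entry (i, k) is the fraction of post-burn-in samples
    assigning subject i to community k.
    """
    return samples.occupancy()


def uncertainty(samples, z_map) -> np.ndarray:
    """u(i) = 1 - (1/S) sum_s I(z_i^(s) = z_map_i), in [0, 1].

    Zero for subjects that never leave their MAP community; close to one for
    subjects almost never assigned to it.  Both the samples and z_map must be
    in canonical label form, otherwise label switching makes the indicator
    meaningless.
    """
    z_map = np.asarray(z_map, dtype=int)
    if samples.z.shape[1] != len(z_map):
        raise ValueError("z_map length does not match sample dimension")
    return 1.0 - (samples.z == z_map[None, :]).mean(axis=0)


def vulnerability_score(samples, k_v: int) -> np.ndarray:
    """v(i) = fraction of samples assigning subject i to community k_v."""
    if not 1 <= k_v <= samples.K:
        raise ValueError(f"k_v must be in 1..{samples.K}")
    return (samples.z == k_v).mean(axis=0)


def annotate_clusters(z_map, table, orientation=None):
    """Rank clusters by composite orientation-adjusted mean z-score.

    Parameters
    ----------
    z_map : label vector (1-based)
    table : BehavioralTable (standardized)
    orientation : sequence of +1/-1 per measure, default all +1
        The sign with which each measure loads on the phenotype of interest
        (+1: larger standardized value means more vulnerable).

    Returns
    -------
    annotations : dict cluster -> name (K = 3) or ordinal rank string
    k_v : int
        The top-ranked (vulnerable) cluster.
    composites : dict cluster -> composite score
    """
    z_map = np.asarray(z_map, dtype=int)
    if not table.standardized:
        raise ValueError("annotation requires a standardized table")
    x = table.values
    if len(z_map) != x.shape[0]:
        raise ValueError("label vector length does not match table")
    orientation = (np.ones(table.p) if orientation is None
                   else np.asarray(orientation, dtype=float))
    if orientation.shape != (table.p,) or not np.isin(orientation, (-1, 1)).all():
        raise ValueError("orientation must give +1/-1 per measure")
    clusters = np.unique(z_map)
    composites = {int(k): float((x[z_map == k] * orientation).mean())
                  for k in clusters}
    vals = sorted(composites.values(), reverse=True)
    for a, b in zip(vals, vals[1:]):
        if abs(a - b) <= 1e-9:
            raise AmbiguousAnnotationError(
                "two clusters have indistinguishable composite scores")
    ranked = sorted(composites, key=composites.get, reverse=True)
    if len(clusters) == 3:
        annotations = {k: CLUSTER_NAMES_K3[r + 1] for r, k in enumerate(ranked)}
    else:
        annotations = {k: f"rank {r + 1}" for r, k in enumerate(ranked)}
    return annotations, int(ranked[0]), composites


def flag_subjects(u, v, u_thresh: float = 0.10, v_thresh: float = 0.90,
                  ids=None):
    """Threshold rules for subjects worth individual attention.

    Returns
    -------
    uncertain : ids with u > u_thresh (assignment spent >10% of the chain
        outside its MAP community, by default)
    borderline : ids with u > u_thresh and v < v_thresh (uncertain subjects
        not already firmly in the vulnerable community)
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (0 <= u_thresh <= 1 and 0 <= v_thresh <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    ids = np.arange(len(u)) if ids is None else np.asarray(ids)
    uncertain = ids[u > u_thresh]
    borderline = ids[(u > u_thresh) & (v < v_thresh)]
    return list(uncertain), list(borderline)


def anova_f(values, labels) -> tuple[float, float]:
    """One-way ANOVA global F test of mean differences across clusters.

    Returns (F, p).  Raises if fewer than two groups, if the within-group
    degrees of freedom vanish, or if the within-group sum of squares is zero
    (infinite F).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if sum(len(g) for g in groups) - len(groups) < 1:
        raise ValueError("no within-group degrees of freedom")
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0:
        raise ValueError("within-group sum of squares is zero (infinite F)")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def anova_table(table, z_map, bonferroni: bool = False) -> pd.DataFrame:
    """Per-measure one-way ANOVA of standardized values vs cluster labels."""
    rows = []
    for m in table.measures:
        f, p = anova_f(table.data[m].to_numpy(), z_map)
        rows.append({"measure": m, "F": f, "p": p})
    out = pd.DataFrame(rows)
    if bonferroni:
        out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def adjusted_rand_index(z1, z2) -> float:
    """Chance-corrected agreement between two partitions (1 = identical)."""
    z1 = np.asarray(z1)
    z2 = np.asarray(z2)
    if z1.shape != z2.shape:
        raise ValueError("partitions must have equal length")
    if z1.size < 2:
        raise ValueError("need at least two subjects")
    return float(adjusted_rand_score(z1, z2))


def connectivity_summary(samples):
    """Posterior mean and equal-tailed 95% interval for each theta_rs.

    Quantiles use linear interpolation between order statistics.  Returns
    (mean, low, high), each a symmetric K x K matrix.
    """
    if samples.S < 2:
        raise ValueError("need at least two posterior draws")
    mean = samples.theta.mean(axis=0)
    low = np.quantile(samples.theta, 0.025, axis=0)
    high = np.quantile(samples.theta, 0.975, axis=0)
    return mean, low, high


@dataclass
class PhenotypeReport:
    """Per-subject phenotype scores plus cluster-level summaries."""

    subject_ids: np.ndarray
    z_map: np.ndarray
    u: np.ndarray
    v: np.ndarray
    k_v: int
    annotations: dict
    composites: dict
    flagged_uncertain: list
    flagged_borderline: list
    anova: pd.DataFrame
    theta_mean: np.ndarray
    theta_ci_low: np.ndarray
    theta_ci_high: np.ndarray
    u_thresh: float = 0.10
    v_thresh: float = 0.90

    def to_frame(self) -> pd.DataFrame:
        flag1 = np.isin(self.subject_ids, self.flagged_uncertain)
        flag2 = np.isin(self.subject_ids, self.flagged_borderline)
        return pd.DataFrame({
            "subject_id": self.subject_ids,
            "cluster": self.z_map,
            "annotation": [self.annotations[int(k)] for k in self.z_map],
            "uncertainty": self.u,
            "vulnerability": self.v,
            "flag_uncertain": flag1.astype(int),
            "flag_borderline": flag2.astype(int),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary_dict(self) -> dict:
        return {
            "k_v": self.k_v,
            "annotations": {str(k): v for k, v in self.annotations.items()},
            "composite_scores": {str(k): v for k, v in self.composites.items()},
            "cluster_sizes": {str(int(k)): int(c) for k, c in zip(
                *np.unique(self.z_map, return_counts=True))},
            "thresholds": {"u": self.u_thresh, "v": self.v_thresh},
            "n_flagged_uncertain": len(self.flagged_uncertain),
            "n_flagged_borderline": len(self.flagged_borderline),
            "anova": self.anova.to_dict(orient="records"),
            "theta_mean": self.theta_mean.tolist(),
            "theta_ci_low": self.theta_ci_low.tolist(),
            "theta_ci_high": self.theta_ci_high.tolist(),
            "quantile_rule": "equal-tailed 2.5/97.5% sample quantiles, linear "
                             "interpolation between order statistics",
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary_dict(), fh, indent=2)


def build_report(results, table, orientation=None, u_thresh: float = 0.10,
                 v_thresh: float = 0.90) -> PhenotypeReport:
    """Assemble the full per-subject phenotype report from a fitted model."""
    samples = results.samples
    z_map = results.z_map
    annotations, k_v, composites = annotate_clusters(z_map, table, orientation)
    u = uncertainty(samples, z_map)
    v = vulnerability_score(samples, k_v)
    ids = table.subject_ids
    f1, f2 = flag_subjects(u, v, u_thresh, v_thresh, ids=ids)
    mean, low, high = connectivity_summary(samples)
    return PhenotypeReport(
        subject_ids=ids, z_map=z_map, u=u, v=v, k_v=k_v,
        annotations=annotations, composites=composites,
        flagged_uncertain=f1, flagged_borderline=f2,
        anova=anova_table(table, z_map),
        theta_mean=mean, theta_ci_low=low, theta_ci_high=high,
        u_thresh=u_thresh, v_thresh=v_thresh)
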