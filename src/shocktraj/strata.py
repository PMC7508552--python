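"""Per-cluster outcome/treatment stratification and between-cluster tests.

Given outcome-ordered cluster assignments, this module reproduces the
analysis tables of the trajectory-clustering study: per-cluster size, septic
shock prevalence, mortality, median early warning time, the proportion of
shock patients already treated (adequately fluid-resuscitated / on
vasopressors) by the time of early prediction, the mean offset between first
intervention and threshold crossing, rank-sum feature comparisons one hour
before first intervention, and the per-timepoint symmetrized Kullback-Leibler
divergence between cluster trajectory distributions.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .exceptions import InputError
from .features import FEATURE_NAMES
from .records import HOUR, PatientRecord

logger = logging.getLogger(__name__)

#: Columns expected in the per-patient outcome frame consumed below.
OUTCOME_COLUMNS = ("patient_id", "cluster", "shock", "died", "t_d",
                   "shock_onset", "adequate_resus_time", "vaso_time",
                   "first_intervention_time")


def cluster_outcome_table(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Stratification table: one row per cluster, ordered by cluster index.

    ``outcomes`` carries one row per clustered patient (see
    :data:`OUTCOME_COLUMNS`; times in minutes, NaN = absent). Treatment-by-t_d
    percentages are reported both over shock patients (the table-header
    convention) and over all cluster members; where a cluster has no shock
    patients they are NaN, not 0. Median EWT is computed over patients with
    both t_d and shock onset.
    """
    missing = [c for c in OUTCOME_COLUMNS if c not in outcomes.columns]
    if missing:
        raise InputError(f"outcome frame missing columns: {missing}")
    n_total = len(outcomes)
    rows = []
    for cluster, grp in outcomes.groupby("cluster", sort=True):
        if not len(grp):  # pragma: no cover - groupby never yields empties
            raise InputError(f"empty cluster {cluster}")
        shock = grp["shock"].astype(bool)
        ewt_h = (grp["shock_onset"] - grp["t_d"]).dropna() / HOUR
        sh = grp[shock]
        resus_by_td = (sh["adequate_resus_time"] <= sh["t_d"]) & sh["t_d"].notna()
        vaso_by_td = (sh["vaso_time"] <= sh["t_d"]) & sh["t_d"].notna()
        resus_all = ((grp["adequate_resus_time"] <= grp["t_d"])
                     & grp["t_d"].notna())
        vaso_all = (grp["vaso_time"] <= grp["t_d"]) & grp["t_d"].notna()
        offset_h = ((grp["first_intervention_time"] - grp["t_d"]) / HOUR).dropna()
        rows.append({
            "cluster": cluster,
            "size": len(grp),
            "pct_cohort": 100.0 * len(grp) / n_total,
            "pct_shock": 100.0 * shock.mean(),
            "pct_mortality": 100.0 * grp["died"].astype(bool).mean(),
            "median_ewt_h": float(ewt_h.median()) if len(ewt_h) else np.nan,
            "pct_resus_by_td_shock": (100.0 * resus_by_td.mean()
                                      if len(sh) else np.nan),
            "pct_vaso_by_td_shock": (100.0 * vaso_by_td.mean()
                                     if len(sh) else np.nan),
            "pct_resus_by_td_all": 100.0 * resus_all.mean(),
            "pct_vaso_by_td_all": 100.0 * vaso_all.mean(),
            "mean_intervention_offset_h": (float(offset_h.mean())
                                           if len(offset_h) else np.nan),
        })
    table = pd.DataFrame(rows).set_index("cluster")
    assert int(table["size"].sum()) == n_total
    return table


def compare_features_between_clusters(
        records: Sequence[PatientRecord], assignments: Mapping[str, int],
        cluster_a: int, cluster_b: int, anchor_times: Mapping[str, float],
        lag_h: float = 1.0, alpha: float = 0.01,
        features: Sequence[str] = FEATURE_NAMES) -> pd.DataFrame:
    """Wilcoxon rank-sum feature comparison at ``anchor - lag_h`` hours.

    For every feature, each included patient contributes its LOCF value at
    one hour before the anchor event (e.g. first adequate resuscitation or
    first vasopressor administration); the two clusters are compared with a
    two-sided rank-sum test, Bonferroni-corrected over the tested features at
    the ``alpha`` family level. Features with fewer than two valid values on
    either side are skipped (logged).
    """
    from .risk import locf_featurize

    groups: dict[int, list[np.ndarray]] = {cluster_a: [], cluster_b: []}
    for rec in records:
        cl = assignments.get(rec.patient_id)
        if cl not in groups:
            continue
        anchor = anchor_times.get(rec.patient_id)
        if anchor is None or (isinstance(anchor, float) and np.isnan(anchor)):
            continue
        groups[cl].append(locf_featurize(rec, anchor - lag_h * HOUR, features))
    a = np.vstack(groups[cluster_a]) if groups[cluster_a] else np.empty((0, len(features)))
    b = np.vstack(groups[cluster_b]) if groups[cluster_b] else np.empty((0, len(features)))
    return ranksum_bonferroni(a, b, alpha=alpha, feature_names=features)


def ranksum_bonferroni(values_a: np.ndarray, values_b: np.ndarray,
                       alpha: float = 0.01,
                       feature_names: Sequence[str] | None = None
                       ) -> pd.DataFrame:
    """Per-column two-sided rank-sum tests with Bonferroni correction.

    ``values_a`` and ``values_b`` are samples-by-features matrices (NaN
    entries are dropped per feature). The Bonferroni family is the set of
    features actually tested; columns with fewer than two valid values on
    either side are skipped with a log entry.
    """
    A = np.atleast_2d(np.asarray(values_a, dtype=float))
    B = np.atleast_2d(np.asarray(values_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise InputError("feature matrices have different widths")
    names = (list(feature_names) if feature_names is not None
             else [f"f{j}" for j in range(A.shape[1])])
    rows = []
    for j, name in enumerate(names):
        va, vb = A[:, j], B[:, j]
        va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
        if len(va) < 2 or len(vb) < 2:
            logger.info("skipping %s: fewer than 2 values per side", name)
            continue
        if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
            p = 1.0
        else:
            p = float(mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        rows.append({"feature": name, "mean_a": float(va.mean()),
                     "mean_b": float(vb.mean()), "n_a": len(va), "n_b": len(vb),
                     "p_raw": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = np.minimum(out["p_raw"] * len(out), 1.0)
        out["significant"] = out["p_adj"] < alpha
    return out


def gaussian_symmetric_kl(mu_a: np.ndarray, var_a: np.ndarray,
                          mu_b: np.ndarray, var_b: np.ndarray) -> np.ndarray:
    """Closed-form symmetrized KL between moment-matched Gaussians.

    ``(KL(A||B) + KL(B||A)) / 2`` with
    ``KL(N(m1,s1)||N(m2,s2)) = ln(s2/s1)/... `` - written out directly:
    ``0.25 * ((va/vb + vb/va - 2) + (ma-mb)^2 * (1/va + 1/vb))``.
    """
    d2 = (np.asarray(mu_a) - np.asarray(mu_b)) ** 2
    va, vb = np.asarray(var_a, dtype=float), np.asarray(var_b, dtype=float)
    return 0.25 * (va / vb + vb / va - 2.0 + d2 * (1.0 / va + 1.0 / vb))


def kl_divergence_trajectories(values_a: np.ndarray, values_b: np.ndarray,
                               eps: float = 1e-6) -> np.ndarray:
    """Per-timepoint symmetrized Gaussian KL between two clusters' values.

    Variances below ``eps`` are floored (and the floor logged) so degenerate
    constant clusters do not blow up the divergence.
    """
    A = np.atleast_2d(np.asarray(values_a, dtype=float))
    B = np.atleast_2d(np.asarray(values_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise InputError("cluster value matrices have different time grids")
    if not len(A) or not len(B):
        raise InputError("both clusters must be nonempty")
    var_a, var_b = A.var(axis=0, ddof=0), B.var(axis=0, ddof=0)
    if (var_a < eps).any() or (var_b < eps).any():
        logger.info("flooring near-zero variance at eps=%g", eps)
    return gaussian_symmetric_kl(A.mean(axis=0), np.maximum(var_a, eps),
                                 B.mean(axis=0), np.maximum(var_b, eps))


def intervention_offset_by_cluster(outcomes: pd.DataFrame, alpha: float = 0.01
                                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean (first intervention - t_d) per cluster plus pairwise tests.

    The sign convention is positive when the first intervention follows
    threshold crossing. Pairwise two-sided rank-sum tests are Bonferroni
    corrected over the number of cluster pairs.
    """
    df = outcomes.copy()
    df["offset_h"] = (df["first_intervention_time"] - df["t_d"]) / HOUR
    df = df[df["offset_h"].notna()]
    means = df.groupby("cluster")["offset_h"].agg(["mean", "count"])
    means.columns = ["mean_offset_h", "n"]
    clusters = sorted(df["cluster"].unique())
    pairs = list(itertools.combinations(clusters, 2))
    rows = []
    for a, b in pairs:
        xa = df.loc[df["cluster"] == a, "offset_h"]
        xb = df.loc[df["cluster"] == b, "offset_h"]
        if len(xa) < 2 or len(xb) < 2:
            continue
        p = float(mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        rows.append({"cluster_a": a, "cluster_b": b, "p_raw": p})
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["p_adj"] = np.minimum(tests["p_raw"] * len(pairs), 1.0)
        tests["significant"] = tests["p_adj"] < alpha
    return means, tests
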