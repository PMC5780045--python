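"""Two-level permutation statistics with exceedance-mass cluster correction.

Level 1: pointwise maps are z-scored against a surrogate ensemble built by
sign flips (vs-baseline contrasts) or label permutations (condition
contrasts); p-values come from the normal CDF of the surrogate-standardized
statistic (two-sided, signed z retained).

Level 2: contiguous suprathreshold points (p < 0.05) form clusters,
separately for positive and negative z; the cluster statistic is the sum
of member z-scores; the null is the per-permutation maximum absolute
cluster statistic (positive and negative maxima pooled by absolute value),
giving family-wise control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

log = logging.getLogger(__name__)

__all__ = [
    "StatMap", "Cluster", "ClusterResult", "signflip_test",
    "label_permutation_test", "cluster_correct", "band_cluster_test",
    "per_electrode_tests", "regress_band_vs_trialnum", "rm_anova_trialnum",
]


@dataclass
class StatMap:
    """Pointwise observed/surrogate statistics over an arbitrary-shape grid."""

    observed: np.ndarray
    surr_mean: np.ndarray
    surr_sd: np.ndarray
    z: np.ndarray
    p: np.ndarray
    surrogate_z: np.ndarray       # (n_perm, *shape), standardized surrogates
    n_perm: int


@dataclass
class Cluster:
    indices: np.ndarray           # flat indices into the map
    stat: float                   # sum of member z-scores
    sign: int                     # +1 / -1
    p_corrected: float

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(int(np.prod(shape)), dtype=bool)
        m[self.indices] = True
        return m.reshape(shape)


@dataclass
class ClusterResult:
    clusters: list[Cluster] = field(default_factory=list)
    threshold: float = 0.05
    alpha: float = 0.05
    n_perm: int = 200
    surrogate_max_stats: np.ndarray = field(default_factory=lambda: np.empty(0))
    shape: tuple = ()

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected < self.alpha]

    @property
    def any_significant(self) -> bool:
        return len(self.significant) > 0

    def significant_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for c in self.significant:
            m |= c.mask(self.shape)
        return m

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold, "alpha": self.alpha,
            "n_perm": self.n_perm, "shape": list(self.shape),
            "clusters": [{"stat": c.stat, "sign": c.sign,
                          "p_corrected": c.p_corrected,
                          "size": int(c.indices.size)} for c in self.clusters],
        }


def _finalize(observed: np.ndarray, surr: np.ndarray) -> StatMap:
    """Standardize observed and each surrogate against the surrogate ensemble."""
    mean = surr.mean(axis=0)
    sd = surr.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, np.inf)
    z = (observed - mean) / safe
    surrogate_z = ((surr - mean) / safe).astype(np.float32)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return StatMap(observed=observed, surr_mean=mean, surr_sd=sd, z=z, p=p,
                   surrogate_z=surrogate_z, n_perm=surr.shape[0])


def signflip_test(unit_maps: np.ndarray, n_perm: int = 200,
                  seed: int | None = 0, exact: bool = False) -> StatMap:
    """Sign-flip permutation test of mean(unit_maps) against zero.

    Each surrogate multiplies every unit's map by an independent fair
    Bernoulli +/-1 and re-averages.  ``exact=True`` enumerates all 2**U
    sign patterns instead (U <= 16).
    """
    maps = np.asarray(unit_maps, dtype=float)
    if maps.ndim < 2:
        maps = maps[:, np.newaxis]
    n_units = maps.shape[0]
    if n_units < 2:
        raise ValueError("need at least 2 units")
    if n_perm < 20:
        warnings.warn("n_perm < 20 gives a very coarse surrogate ensemble",
                      stacklevel=2)
    shape = maps.shape[1:]
    flat = maps.reshape(n_units, -1)
    observed = flat.mean(axis=0)
    if exact:
        if n_units > 16:
            raise ValueError("exact enumeration limited to 16 units")
        patterns = ((np.arange(2 ** n_units)[:, None] >> np.arange(n_units)) & 1)
        signs = patterns * 2.0 - 1.0
    else:
        rng = np.random.default_rng(seed)
        signs = rng.integers(0, 2, size=(n_perm, n_units)) * 2.0 - 1.0
    surr = signs @ flat / n_units
    sm = _finalize(observed, surr)
    return StatMap(observed=sm.observed.reshape(shape),
                   surr_mean=sm.surr_mean.reshape(shape),
                   surr_sd=sm.surr_sd.reshape(shape),
                   z=sm.z.reshape(shape), p=sm.p.reshape(shape),
                   surrogate_z=sm.surrogate_z.reshape((-1,) + shape),
                   n_perm=sm.n_perm)


def label_permutation_test(cond_a_maps, cond_b_maps, n_perm: int = 200,
                           seed: int | None = 0, paired: bool = True) -> StatMap:
    """Permutation test of mean(a - b).

    paired=True (session level): surrogates swap the a/b labels of each
    unit independently — equivalent to sign-flipping the per-unit
    difference maps.  paired=False (trial level): surrogates shuffle the
    pooled trial labels; unbalanced designs are allowed.
    """
    a = np.asarray(cond_a_maps, dtype=float)
    b = np.asarray(cond_b_maps, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired design requires matching shapes")
        return signflip_test(a - b, n_perm=n_perm, seed=seed)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("map shapes differ between conditions")
    na, nb = a.shape[0], b.shape[0]
    if na < 1 or nb < 1:
        raise ValueError("each condition needs at least one map")
    shape = a.shape[1:]
    pool = np.concatenate([a.reshape(na, -1), b.reshape(nb, -1)], axis=0)
    n = na + nb
    observed = pool[:na].mean(axis=0) - pool[na:].mean(axis=0)
    rng = np.random.default_rng(seed)
    weights = np.empty((n_perm, n))
    base = np.concatenate([np.full(na, 1.0 / na), np.full(nb, -1.0 / nb)])
    for k in range(n_perm):
        weights[k] = base[rng.permutation(n)]
    surr = weights @ pool
    sm = _finalize(observed, surr)
    return StatMap(observed=sm.observed.reshape(shape),
                   surr_mean=sm.surr_mean.reshape(shape),
                   surr_sd=sm.surr_sd.reshape(shape),
                   z=sm.z.reshape(shape), p=sm.p.reshape(shape),
                   surrogate_z=sm.surrogate_z.reshape((-1,) + shape),
                   n_perm=sm.n_perm)


def _signed_cluster_stats(z: np.ndarray, z_crit: float):
    """Clusters of contiguous suprathreshold points, per sign.

    Returns list of (flat_indices, stat, sign).  Contiguity is
    4-connectivity on 2D grids (axis-adjacent neighbours only).
    """
    out = []
    for sign in (1, -1):
        mask = (sign * z) > z_crit
        if not mask.any():
            continue
        labels, n = ndimage.label(mask)    # default structure = 4-connectivity
        if n == 0:
            continue
        sums = ndimage.sum_labels(z, labels, index=np.arange(1, n + 1))
        flat_labels = labels.ravel()
        order = np.argsort(flat_labels, kind="stable")
        bounds = np.searchsorted(flat_labels[order], np.arange(1, n + 2))
        for i in range(n):
            idx = order[bounds[i]:bounds[i + 1]]
            out.append((idx, float(sums[i]), sign))
    return out


def _max_cluster_stat(z: np.ndarray, z_crit: float) -> float:
    best = 0.0
    for sign in (1, -1):
        mask = (sign * z) > z_crit
        if not mask.any():
            continue
        labels, n = ndimage.label(mask)
        if n:
            sums = ndimage.sum_labels(z, labels, index=np.arange(1, n + 1))
            best = max(best, float(np.max(np.abs(sums))))
    return best


def cluster_correct(stat_map: StatMap, threshold: float = 0.05,
                    alpha: float = 0.05) -> ClusterResult:
    """Exceedance-mass correction of a StatMap.

    Observed and surrogate maps are thresholded identically at pointwise
    p < threshold; corrected p of a cluster is the (+1-smoothed) fraction
    of per-permutation maximum |cluster statistics| at least as large as
    the observed |statistic|.
    """
    z_crit = stats.norm.isf(threshold / 2.0)
    n_perm = stat_map.surrogate_z.shape[0]
    null_max = np.empty(n_perm)
    for k in range(n_perm):
        null_max[k] = _max_cluster_stat(stat_map.surrogate_z[k].astype(float), z_crit)
    clusters = []
    for idx, cstat, sign in _signed_cluster_stats(stat_map.z, z_crit):
        p_corr = (1.0 + np.sum(null_max >= abs(cstat))) / (n_perm + 1.0)
        clusters.append(Cluster(indices=idx, stat=cstat, sign=sign,
                                p_corrected=float(p_corr)))
    clusters.sort(key=lambda c: abs(c.stat), reverse=True)
    return ClusterResult(clusters=clusters, threshold=threshold, alpha=alpha,
                         n_perm=n_perm, surrogate_max_stats=null_max,
                         shape=stat_map.z.shape)


def band_cluster_test(series_a: np.ndarray, series_b: np.ndarray | None = None,
                      n_perm: int = 200, seed: int | None = 0,
                      paired: bool = True, threshold: float = 0.05,
                      alpha: float = 0.05) -> tuple[StatMap, ClusterResult]:
    """1D (time-only) cluster test on band-averaged series.

    With ``series_b`` None this is a vs-baseline sign-flip test of
    ``series_a`` (units x time); otherwise an a-vs-b label permutation.
    """
    if series_b is None:
        sm = signflip_test(np.asarray(series_a), n_perm=n_perm, seed=seed)
    else:
        sm = label_permutation_test(series_a, series_b, n_perm=n_perm,
                                    seed=seed, paired=paired)
    return sm, cluster_correct(sm, threshold=threshold, alpha=alpha)


def per_electrode_tests(contact_maps: dict[str, np.ndarray],
                        conditions: dict[str, np.ndarray] | None = None,
                        n_perm: int = 200, seed: int = 0, min_trials: int = 10,
                        threshold: float = 0.05, alpha: float = 0.05) -> pd.DataFrame:
    """Trial-level tests per electrode contact.

    contact_maps[name] is a trials x ... array of baseline-normalized power
    (each trial's map is its difference from its own baseline, so the
    vs-baseline contrast is a sign-flip across trials).  conditions[name],
    when given, holds the per-trial 'target'/'distractor' labels for the
    pooled-label condition contrast.  Returns one row per contact with
    significance flags and cluster counts; contacts with fewer than
    ``min_trials`` trials are marked untestable.
    """
    rows = []
    for j, (name, maps) in enumerate(contact_maps.items()):
        maps = np.asarray(maps, dtype=float)
        n_trials = maps.shape[0]
        row = {"contact": name, "n_trials": n_trials, "testable": True,
               "sig_baseline": False, "sign_baseline": 0,
               "n_sig_clusters_baseline": 0, "sig_condition": False,
               "n_sig_clusters_condition": 0}
        if n_trials < min_trials:
            row["testable"] = False
            log.info("contact %s untestable: %d trials", name, n_trials)
            rows.append(row)
            continue
        sm = signflip_test(maps, n_perm=n_perm, seed=seed + 7919 * j)
        cr = cluster_correct(sm, threshold=threshold, alpha=alpha)
        row["sig_baseline"] = cr.any_significant
        row["n_sig_clusters_baseline"] = len(cr.significant)
        if cr.any_significant:
            row["sign_baseline"] = int(cr.significant[0].sign)
        if conditions is not None and name in conditions:
            labels = np.asarray(conditions[name])
            is_t = labels == "target"
            if is_t.sum() >= 2 and (~is_t).sum() >= 2:
                sm_c = label_permutation_test(maps[is_t], maps[~is_t],
                                              n_perm=n_perm, paired=False,
                                              seed=seed + 7919 * j + 1)
                cr_c = cluster_correct(sm_c, threshold=threshold, alpha=alpha)
                row["sig_condition"] = cr_c.any_significant
                row["n_sig_clusters_condition"] = len(cr_c.significant)
        rows.append(row)
    return pd.DataFrame(rows)


def regress_band_vs_trialnum(band_means: np.ndarray):
    """Per-session correlation of band power with trial position.

    band_means: sessions x positions (mean band power over the trial
    window per within-block position).  Returns (rho_per_session,
    t_statistic, p_value) where the group test is a one-sample t-test of
    the correlation coefficients against zero.  Sessions with constant
    series are excluded (logged).
    """
    bm = np.asarray(band_means, dtype=float)
    if bm.ndim != 2:
        raise ValueError("band_means must be sessions x positions")
    n_sessions, n_pos = bm.shape
    if n_pos < 3:
        raise ValueError("need at least 3 trial positions")
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    x = np.arange(1, n_pos + 1, dtype=float)
    rhos = []
    for s in range(n_sessions):
        y = bm[s]
        if np.ptp(y) == 0:
            log.info("session %d excluded from regression: constant series", s)
            continue
        rhos.append(stats.pearsonr(x, y).statistic)
    rhos = np.asarray(rhos)
    if rhos.size < 2:
        raise ValueError("fewer than 2 usable sessions")
    t, p = stats.ttest_1samp(rhos, 0.0)
    return rhos, float(t), float(p)


def rm_anova_trialnum(band_means: np.ndarray) -> dict[str, dict]:
    """Repeated-measures ANOVA of band power on trial position.

    band_means is sessions x positions (one-way) or sessions x positions x
    conditions (two-way with interaction).  Returns per-factor
    {'F', 'df_num', 'df_den', 'p'}; a fully degenerate (constant) dataset
    is reported with ``degenerate=True`` flags instead of an F ratio.
    """
    from statsmodels.stats.anova import AnovaRM

    bm = np.asarray(band_means, dtype=float)
    if np.isnan(bm).any():
        raise ValueError("missing cells: the design must be complete")
    if bm.ndim not in (2, 3):
        raise ValueError("band_means must be 2-D or 3-D")
    if bm.shape[0] < 2 or bm.shape[1] < 2 or (bm.ndim == 3 and bm.shape[2] < 2):
        raise ValueError("every factor needs at least 2 levels")
    if np.ptp(bm) == 0:
        keys = ["position"] if bm.ndim == 2 else ["position", "condition",
                                                  "position:condition"]
        return {k: {"F": np.nan, "df_num": np.nan, "df_den": np.nan,
                    "p": np.nan, "degenerate": True} for k in keys}
    records = []
    if bm.ndim == 2:
        for s in range(bm.shape[0]):
            for j in range(bm.shape[1]):
                records.append({"session": s, "position": j + 1, "y": bm[s, j]})
        within = ["position"]
    else:
        for s in range(bm.shape[0]):
            for j in range(bm.shape[1]):
                for c in range(bm.shape[2]):
                    records.append({"session": s, "position": j + 1,
                                    "condition": c, "y": bm[s, j, c]})
        within = ["position", "condition"]
    res = AnovaRM(pd.DataFrame.from_records(records), depvar="y",
                  subject="session", within=within).fit()
    table = res.anova_table
    out = {}
    for name in table.index:
        key = name.lower().replace(" x ", ":")
        out[key] = {"F": float(table.loc[name, "F Value"]),
                    "df_num": float(table.loc[name, "Num DF"]),
                    "df_den": float(table.loc[name, "Den DF"]),
                    "p": float(table.loc[name, "Pr > F"]),
                    "degenerate": False}
    return out
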