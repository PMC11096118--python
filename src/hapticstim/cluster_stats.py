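"""Cluster-based permutation inference on paired contrasts.

Pointwise t statistics over a 1-D (time) or 2-D (frequency x time) domain
are thresholded at the two-tailed Student-t critical value; contiguous
suprathreshold points (4-connectivity in 2-D) form clusters whose mass is
the sum of t values.  The null distribution is built from the maximum
|cluster mass| per permutation — sign flips of participants' contrast maps
for the one-sample (within-group) test, group-label shuffles for the
independent-samples (between-group) test — pooled over both sign classes,
so the familywise error of the two-tailed test is controlled at alpha.
When the full permutation set is no larger than the requested count it is
enumerated exhaustively and the p-values are exact.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import PipelineError


def t_threshold(alpha: float, df: float) -> float:
    """Two-tailed Student-t critical value at 1 - alpha/2."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def truncate_2dp(value: float) -> float:
    """Truncate (not round) to two decimals, the convention used when the
    critical value is quoted in reports (2.1788... -> 2.17)."""
    return math.trunc(value * 100.0) / 100.0


@dataclass
class ClusterResult:
    """Signed clusters with mass statistics and permutation p-values."""

    clusters: list[np.ndarray]  # index arrays into the flattened domain
    mass: np.ndarray  # sum of t within each cluster (signed)
    sign: np.ndarray  # +1 / -1 per cluster
    p_values: np.ndarray
    n_permutations: int
    exact: bool
    threshold: float
    domain_shape: tuple[int, ...] = ()
    t_obs: np.ndarray | None = None

    def significant(self, alpha: float = 0.05) -> list[int]:
        return [i for i, p in enumerate(self.p_values) if p < alpha]


def _connectivity(ndim: int) -> np.ndarray:
    # 4-connectivity in 2-D, simple contiguity in 1-D.
    return ndimage.generate_binary_structure(ndim, 1)


def _cluster_masses(t_map: np.ndarray, threshold: float, structure):
    """Label suprathreshold clusters of each sign; returns (slices, masses, signs)."""
    clusters, masses, signs = [], [], []
    for sign in (1, -1):
        mask = (sign * t_map) > threshold
        labels, n = ndimage.label(mask, structure=structure)
        if n:
            sums = ndimage.sum_labels(t_map, labels, index=np.arange(1, n + 1))
            for k in range(n):
                clusters.append(np.flatnonzero(labels.ravel() == k + 1))
                masses.append(float(sums[k]))
                signs.append(sign)
    return clusters, masses, signs


def _max_masses(t_maps: np.ndarray, threshold: float, structure) -> np.ndarray:
    """Max |cluster mass| per permutation for a stack of t maps.

    The whole stack is labeled in one pass with a connectivity structure
    that never links across the permutation axis, then per-cluster masses
    are aggregated to a per-permutation maximum.
    """
    n_perm = t_maps.shape[0]
    ndim = t_maps.ndim - 1
    big_structure = np.zeros((3,) * (ndim + 1), dtype=bool)
    big_structure[1] = structure
    perm_full = np.broadcast_to(
        np.arange(n_perm).reshape((-1,) + (1,) * ndim), t_maps.shape
    )
    out = np.zeros(n_perm)
    for sign in (1, -1):
        labels, n = ndimage.label((sign * t_maps) > threshold, structure=big_structure)
        if n == 0:
            continue
        idx = np.arange(1, n + 1)
        masses = np.abs(ndimage.sum_labels(t_maps, labels, index=idx))
        perms = ndimage.maximum(perm_full, labels, index=idx).astype(int)
        np.maximum.at(out, perms, masses)
    return out


def _one_sample_t(signed_sums: np.ndarray, sumsq: np.ndarray, n: int) -> np.ndarray:
    """Vectorized one-sample t over sign-flip permutations.

    The per-point sum of squares is invariant under sign flips, so each
    permutation's t map follows from the flipped sum alone.
    """
    mean = signed_sums / n
    var = (sumsq - n * mean**2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return mean / np.sqrt(var / n)


def one_sample_cluster_perm(
    contrasts: np.ndarray,
    threshold: float,
    n_perm: int = 1024,
    seed: int = 0,
    *,
    exact: str | bool = "auto",
) -> ClusterResult:
    """One-sample cluster permutation test against 0 (sign-flip null).

    ``contrasts`` has shape (n_participants, *domain); the domain may be
    1-D (time) or 2-D (frequency x time).  ``exact`` controls enumeration
    of the 2^n sign-flip set: "auto" enumerates whenever 2^n <= n_perm.
    """
    X = np.asarray(contrasts, dtype=float)
    if X.ndim < 2:
        raise ValueError("contrasts must be (participants, *domain)")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two participants")
    domain_shape = X.shape[1:]
    structure = _connectivity(len(domain_shape))
    flat = X.reshape(n, -1)
    sumsq = np.sum(flat**2, axis=0)

    t_obs = _one_sample_t(flat.sum(axis=0), sumsq, n).reshape(domain_shape)
    clusters, masses, signs = _cluster_masses(t_obs, threshold, structure)

    if exact == "auto":
        use_exact = 2**n <= n_perm
    else:
        use_exact = bool(exact)
    if use_exact:
        bits = np.array(
            [[1 if (m >> i) & 1 else -1 for i in range(n)] for m in range(2**n)]
        )
        signs_matrix = bits.astype(float)
        n_used = signs_matrix.shape[0]
    else:
        rng = np.random.default_rng(seed)
        signs_matrix = rng.choice([-1.0, 1.0], size=(n_perm, n))
        n_used = n_perm

    t_perm = _one_sample_t(signs_matrix @ flat, sumsq, n).reshape(
        (n_used,) + domain_shape
    )
    null = _max_masses(t_perm, threshold, structure)
    p = _p_values(masses, null, use_exact)
    return ClusterResult(
        clusters=clusters, mass=np.asarray(masses), sign=np.asarray(signs),
        p_values=p, n_permutations=n_used, exact=use_exact,
        threshold=threshold, domain_shape=domain_shape, t_obs=t_obs,
    )


def _two_sample_t(
    assign: np.ndarray, flat: np.ndarray, flat_sq: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """Pooled-variance independent-samples t for a stack of group assignments
    (rows of ``assign`` are 0/1 indicators of membership in group A)."""
    sum1 = assign @ flat
    sum2 = flat.sum(axis=0)[None, :] - sum1
    ss1 = assign @ flat_sq
    ss2 = flat_sq.sum(axis=0)[None, :] - ss1
    m1, m2 = sum1 / n1, sum2 / n2
    pooled = (ss1 - n1 * m1**2 + ss2 - n2 * m2**2) / (n1 + n2 - 2)
    pooled = np.maximum(pooled, 1e-300)
    return (m1 - m2) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))


def two_sample_cluster_perm(
    group_a: np.ndarray,
    group_b: np.ndarray,
    threshold: float,
    n_perm: int = 1024,
    seed: int = 0,
    *,
    exact: str | bool = "auto",
) -> ClusterResult:
    """Independent-samples cluster permutation test (label-shuffle null)."""
    A = np.asarray(group_a, dtype=float)
    B = np.asarray(group_b, dtype=float)
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("groups must share the domain")
    n1, n2 = A.shape[0], B.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least two members")
    domain_shape = A.shape[1:]
    structure = _connectivity(len(domain_shape))
    flat = np.concatenate([A, B]).reshape(n1 + n2, -1)
    flat_sq = flat**2
    n_total = n1 + n2

    obs_assign = np.zeros((1, n_total))
    obs_assign[0, :n1] = 1.0
    t_obs = _two_sample_t(obs_assign, flat, flat_sq, n1, n2)[0].reshape(domain_shape)
    clusters, masses, signs = _cluster_masses(t_obs, threshold, structure)

    n_partitions = math.comb(n_total, n1)
    if exact == "auto":
        use_exact = n_partitions <= n_perm
    else:
        use_exact = bool(exact)
    if use_exact:
        assign = np.zeros((n_partitions, n_total))
        for r, combo in enumerate(itertools.combinations(range(n_total), n1)):
            assign[r, list(combo)] = 1.0
        n_used = n_partitions
    else:
        rng = np.random.default_rng(seed)
        assign = np.zeros((n_perm, n_total))
        for r in range(n_perm):
            assign[r, rng.choice(n_total, size=n1, replace=False)] = 1.0
        n_used = n_perm

    t_perm = _two_sample_t(assign, flat, flat_sq, n1, n2).reshape(
        (n_used,) + domain_shape
    )
    null = _max_masses(t_perm, threshold, structure)
    p = _p_values(masses, null, use_exact)
    return ClusterResult(
        clusters=clusters, mass=np.asarray(masses), sign=np.asarray(signs),
        p_values=p, n_permutations=n_used, exact=use_exact,
        threshold=threshold, domain_shape=domain_shape, t_obs=t_obs,
    )


def _p_values(masses, null: np.ndarray, exact: bool) -> np.ndarray:
    """Permutation p per cluster.  Random sampling uses the add-one
    convention (1 + #{null >= obs}) / (1 + n_perm), guaranteeing p > 0;
    exact enumeration counts over the full set (which contains the
    identity, so p > 0 there too)."""
    out = np.empty(len(masses))
    for i, m in enumerate(masses):
        count = np.sum(null >= abs(m))
        if exact:
            out[i] = count / null.size
        else:
            out[i] = (1.0 + count) / (1.0 + null.size)
    return out


# --------------------------------------------------------------------------
# Full study contrast grid


@dataclass
class StudyDerived:
    """Per-participant derived metrics feeding the contrast grid.

    ``tfr`` maps (participant_id, phase, trigger) to a frequency x time
    amplitude array; ``gfp_contrast`` and ``gmd`` map
    (participant_id, contrast_phase, trigger) to 1-D time series (GFP of
    the paired-contrast evoked map, and GMD between the phase and the
    pre-intervention evoked maps).  ``groups`` maps participant_id to group.
    """

    groups: dict[str, str]
    tfr: dict[tuple[str, str, str], np.ndarray]
    gfp_contrast: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    gmd: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    tfr_valid: np.ndarray | None = None  # (freqs, times) validity mask
    freqs: np.ndarray | None = None
    times: dict[str, np.ndarray] = field(default_factory=dict)


CONTRASTS = (("intervention", "pre"), ("post", "pre"))


def run_full_contrast_suite(
    study: StudyDerived,
    alpha: float = 0.05,
    n_perm: int = 1024,
    seed: int = 0,
    triggers=("start", "end"),
) -> pd.DataFrame:
    """The full comparison grid of the analysis.

    Within-group: one-sample cluster tests of the intervention-pre and
    post-pre contrasts against zero, per group.  Between-group: two-sample
    cluster tests of the same contrasts, stimulation versus sham, the sham
    group being the reference.  All of TFR, GFP and GMD, for trial-start
    and trial-end epochs.  Returns one tidy row per cluster (or one row
    with no cluster columns if a cell yielded none).
    """
    by_group: dict[str, list[str]] = {"Sham": [], "WH-Stim": []}
    for pid, grp in study.groups.items():
        by_group[grp].append(pid)
    for grp, pids in by_group.items():
        if len(pids) < 2:
            raise PipelineError(f"group {grp} has fewer than 2 participants")

    rows = []
    test_index = 0
    for trigger in triggers:
        for metric in ("TFR", "GFP", "GMD"):
            for phase_a, phase_b in CONTRASTS:
                contrast = f"{'int' if phase_a == 'intervention' else phase_a}-{phase_b}"
                per_group = {}
                for grp, pids in by_group.items():
                    maps = [
                        _contrast_map(study, metric, pid, phase_a, phase_b, trigger)
                        for pid in pids
                    ]
                    per_group[grp] = np.stack(maps)
                    df = len(pids) - 1
                    thr = t_threshold(alpha, df)
                    res = one_sample_cluster_perm(
                        per_group[grp], thr, n_perm=n_perm, seed=seed + test_index
                    )
                    test_index += 1
                    rows.extend(
                        _result_rows(res, study, metric, trigger, f"within:{grp}", contrast)
                    )
                thr = t_threshold(alpha, min(len(p) for p in by_group.values()) - 1)
                res = two_sample_cluster_perm(
                    per_group["WH-Stim"], per_group["Sham"], thr,
                    n_perm=n_perm, seed=seed + test_index,
                )
                test_index += 1
                rows.extend(
                    _result_rows(
                        res, study, metric, trigger, "between:WH-Stim-vs-Sham", contrast
                    )
                )
    return pd.DataFrame(rows)


def _contrast_map(study, metric, pid, phase_a, phase_b, trigger):
    try:
        if metric == "TFR":
            a = study.tfr[(pid, phase_a, trigger)]
            b = study.tfr[(pid, phase_b, trigger)]
            diff = a - b
            if study.tfr_valid is not None:
                diff = diff[:, study.tfr_valid.all(axis=0)]
            return diff
        if metric == "GFP":
            return study.gfp_contrast[(pid, phase_a, trigger)]
        return study.gmd[(pid, phase_a, trigger)]
    except KeyError as exc:
        raise PipelineError(
            f"missing derived {metric} for {(pid, phase_a, trigger)}"
        ) from exc


def _result_rows(res: ClusterResult, study, metric, trigger, comparison, contrast):
    rows = []
    base = {
        "metric": metric,
        "trigger_type": trigger,
        "comparison": comparison,
        "contrast": contrast,
        "n_permutations": res.n_permutations,
        "exact_flag": res.exact,
        "threshold": res.threshold,
    }
    if not res.clusters:
        rows.append({**base, "cluster_id": -1, "sign": 0, "t_mass": 0.0,
                     "p": 1.0, "time_span": 0.0, "freq_span": 0.0})
        return rows
    for cid, (idx, mass, sign, p) in enumerate(
        zip(res.clusters, res.mass, res.sign, res.p_values)
    ):
        coords = np.unravel_index(idx, res.domain_shape)
        if len(res.domain_shape) == 2:
            freq_span = float(np.ptp(coords[0]) + 1)
            time_span = float(np.ptp(coords[1]) + 1)
        else:
            freq_span = 0.0
            time_span = float(np.ptp(coords[0]) + 1)
        rows.append({
            **base, "cluster_id": cid, "sign": int(sign),
            "t_mass": float(mass), "p": float(p),
            "time_span": time_span, "freq_span": freq_span,
        })
    return rows
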