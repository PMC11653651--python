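"""Temporal expression patterns: fuzzy C-means clusters and U/N/D trends.

Two complementary views of the three-week time courses are produced per
stratum (phenotype x recovery status):

* soft clusters of standardized average-RPM profiles by fuzzy C-means (FCM),
  with "signature" miRNAs defined by a membership score strictly above 0.7 in
  their argmax cluster;
* a discrete trend call per consecutive-week interval - U (log2FC > 1 and
  FDR < 0.05), D (log2FC < -1 and FDR < 0.05), otherwise N - whose two calls
  concatenate into one of the nine W0->W2 patterns
  {D,N,U} x {D,N,U} = D-D ... U-U.

FCM minimizes sum_ik u_ik^m d_ik^2 by the classic alternating updates
(centroids as u^m-weighted means; memberships proportional to
d^(-2/(m-1)), normalized per profile). The fuzzifier defaults to the
conventional m = 2 and the cluster count to 9, one per nominal pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .de import nb_wald_test
from .errors import ValidationError
from .expression import rpm_normalize
from .io import WEEKS
from .simulate import PATTERN_CATEGORIES

TREND_CALLS = ("U", "N", "D")


def build_timecourse(rpm: pd.DataFrame, meta: pd.DataFrame, phenotype: str,
                     recovery: str | None = None,
                     weeks=WEEKS) -> pd.DataFrame:
    """Average RPM per (miRNA, week) within one phenotype/recovery stratum."""
    cols = {}
    for w in weeks:
        mask = (meta["phenotype"] == phenotype) & (meta["week"] == w)
        if recovery is not None:
            mask &= meta["recovery"] == recovery
        ids = meta.loc[mask, "sample_id"]
        if len(ids) == 0:
            stratum = phenotype if recovery is None else f"{phenotype}/{recovery}"
            raise ValidationError(f"no samples for {stratum} at week {w}")
        cols[w] = rpm.loc[:, ids].mean(axis=1)
    return pd.DataFrame(cols)


def standardize_profiles(tc: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Z-score each profile across time (population sd); drop flat profiles.

    Returns (standardized matrix, index of excluded zero-variance profiles).
    """
    x = tc.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    z = np.full_like(x, np.nan)
    z[~flat] = (x[~flat] - mean[~flat]) / sd[~flat]
    standardized = pd.DataFrame(z[~flat], index=tc.index[~flat],
                                columns=tc.columns)
    return standardized, tc.index[flat]


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; exact one-hot at d = 0."""
    u = np.zeros_like(d2)
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d2 ** (-1.0 / (m - 1.0))
    u[~any_zero] = w[~any_zero] / w[~any_zero].sum(axis=1, keepdims=True)
    if any_zero.any():
        u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    return u


class FuzzyCMeans:
    """Fuzzy C-means model over profile rows of ``data``.

    Parameters
    ----------
    data : DataFrame or array
        N profiles x T time points (already standardized for Mfuzz-style use).
    n_clusters : int
        Cluster count c (2 <= c < N); default 9.
    m : float
        Fuzzifier, > 1; default 2.0.
    """

    def __init__(self, data, n_clusters: int = 9, m: float = 2.0, *,
                 tol: float = 1e-6, max_iter: int = 1000,
                 seed: int | None = None):
        self.data = data if isinstance(data, pd.DataFrame) else pd.DataFrame(data)
        if m <= 1:
            raise ValidationError("fuzzifier m must be > 1")
        if n_clusters < 2:
            raise ValidationError("need at least 2 clusters")
        if n_clusters >= self.data.shape[0]:
            raise ValidationError(
                f"n_clusters={n_clusters} must be < n_profiles={self.data.shape[0]}")
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, init_memberships: np.ndarray | None = None
            ) -> "FuzzyCMeansResults":
        x = self.data.to_numpy(dtype=float)
        n, c = x.shape[0], self.n_clusters
        if init_memberships is None:
            rng = np.random.default_rng(self.seed)
            u = rng.random((n, c))
            u /= u.sum(axis=1, keepdims=True)
        else:
            u = np.asarray(init_memberships, dtype=float)
            if u.shape != (n, c):
                raise ValidationError(
                    f"init_memberships must have shape {(n, c)}, got {u.shape}")
            u = u / u.sum(axis=1, keepdims=True)

        centroids = None
        objective_path = []
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            um = u ** self.m
            new_centroids = (um.T @ x) / um.sum(axis=0)[:, None]
            d2 = cdist(x, new_centroids, metric="sqeuclidean")
            u = _fcm_memberships(d2, self.m)
            objective_path.append(float(((u ** self.m) * d2).sum()))
            if centroids is not None and np.max(np.abs(new_centroids - centroids)) < self.tol:
                centroids = new_centroids
                break
            centroids = new_centroids

        memberships = pd.DataFrame(u, index=self.data.index,
                                   columns=range(self.n_clusters))
        return FuzzyCMeansResults(
            model=self,
            centroids=pd.DataFrame(centroids, columns=self.data.columns),
            memberships=memberships,
            objective=objective_path[-1],
            objective_path=tuple(objective_path),
            n_iter=n_iter,
        )


@dataclass(frozen=True)
class FuzzyCMeansResults:
    """Converged FCM state: centroids, soft memberships, and the objective."""

    model: FuzzyCMeans
    centroids: pd.DataFrame
    memberships: pd.DataFrame
    objective: float
    objective_path: tuple[float, ...]
    n_iter: int

    def hard_labels(self) -> pd.Series:
        """Argmax cluster per profile; ties broken by lowest cluster index."""
        return pd.Series(
            np.argmax(self.memberships.to_numpy(), axis=1),
            index=self.memberships.index, name="cluster")

    def summary(self) -> str:
        sizes = self.hard_labels().value_counts().sort_index()
        lines = [
            "Fuzzy C-means clustering",
            f"  profiles:   {self.memberships.shape[0]}",
            f"  clusters:   {self.model.n_clusters} (m = {self.model.m})",
            f"  iterations: {self.n_iter}",
            f"  objective:  {self.objective:.6g}",
            "  hard cluster sizes: "
            + ", ".join(f"{k}: {v}" for k, v in sizes.items()),
        ]
        return "\n".join(lines)


def select_signatures(result: FuzzyCMeansResults, threshold: float = 0.7
                      ) -> dict[int, set]:
    """Per-cluster signature sets: argmax membership strictly above threshold."""
    labels = result.hard_labels()
    top = result.memberships.to_numpy().max(axis=1)
    out: dict[int, set] = {k: set() for k in range(result.model.n_clusters)}
    for mirna, cluster, score in zip(result.memberships.index, labels, top):
        if score > threshold:
            out[int(cluster)].add(mirna)
    return out


@dataclass(frozen=True)
class TrendCall:
    """Trend over one consecutive-week interval: U, N, or D."""

    interval: tuple[str, str]
    call: str
    log2fc: float
    fdr: float


def call_trend(log2fc: float, fdr: float, interval: tuple[str, str],
               lfc_threshold: float = 1.0,
               fdr_threshold: float = 0.05) -> TrendCall:
    """U iff log2FC > threshold and FDR significant; D mirrored; else N."""
    if fdr < fdr_threshold and log2fc > lfc_threshold:
        call = "U"
    elif fdr < fdr_threshold and log2fc < -lfc_threshold:
        call = "D"
    else:
        call = "N"
    return TrendCall(interval=tuple(interval), call=call,
                     log2fc=float(log2fc), fdr=float(fdr))


def assign_pattern(t1: TrendCall, t2: TrendCall) -> str:
    """Concatenate two consecutive-interval trends into a W0->W2 pattern."""
    if t1.interval[1] != t2.interval[0]:
        raise ValidationError(
            f"intervals {t1.interval} and {t2.interval} are not consecutive")
    pattern = f"{t1.call}-{t2.call}"
    assert pattern in PATTERN_CATEGORIES
    return pattern


def classify_temporal_patterns(counts: pd.DataFrame, meta: pd.DataFrame,
                               phenotype: str, recovery: str | None = None,
                               lfc_threshold: float = 1.0,
                               fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Per-miRNA U/N/D trend calls per interval and the combined pattern.

    Each interval is tested as an unpaired two-group NB Wald contrast between
    the stratum's samples at the two weeks (animals treated as independent
    per week).
    """
    mask = meta["phenotype"] == phenotype
    if recovery is not None:
        mask &= meta["recovery"] == recovery
    sub_meta = meta.loc[mask]
    calls = {}
    for w0, w1 in zip(WEEKS[:-1], WEEKS[1:]):
        de = nb_wald_test(counts.loc[:, sub_meta["sample_id"]], sub_meta,
                          w0, w1, group_column="week",
                          lfc_threshold=lfc_threshold,
                          fdr_threshold=fdr_threshold)
        calls[(w0, w1)] = de
    common = calls[(WEEKS[0], WEEKS[1])].index.intersection(
        calls[(WEEKS[1], WEEKS[2])].index)
    rows = []
    for mirna in common:
        t1 = call_trend(calls[(WEEKS[0], WEEKS[1])].loc[mirna, "log2FoldChange"],
                        calls[(WEEKS[0], WEEKS[1])].loc[mirna, "padj"],
                        (WEEKS[0], WEEKS[1]), lfc_threshold, fdr_threshold)
        t2 = call_trend(calls[(WEEKS[1], WEEKS[2])].loc[mirna, "log2FoldChange"],
                        calls[(WEEKS[1], WEEKS[2])].loc[mirna, "padj"],
                        (WEEKS[1], WEEKS[2]), lfc_threshold, fdr_threshold)
        rows.append({
            "mirna_id": mirna,
            "trend_W0W1": t1.call,
            "trend_W1W2": t2.call,
            "pattern": assign_pattern(t1, t2),
        })
    return pd.DataFrame(rows, columns=["mirna_id", "trend_W0W1", "trend_W1W2",
                                       "pattern"]).set_index("mirna_id")


def cluster_stratum(counts: pd.DataFrame, meta: pd.DataFrame, phenotype: str,
                    recovery: str, n_clusters: int = 9, m: float = 2.0,
                    membership_threshold: float = 0.7,
                    seed: int | None = None) -> pd.DataFrame:
    """FCM-cluster a stratum's standardized time courses; tabulate signatures."""
    rpm = rpm_normalize(counts)
    tc = build_timecourse(rpm, meta, phenotype, recovery)
    z, _excluded = standardize_profiles(tc)
    model = FuzzyCMeans(z, n_clusters=n_clusters, m=m, seed=seed)
    res = model.fit()
    labels = res.hard_labels()
    top = res.memberships.max(axis=1)
    return pd.DataFrame({
        "cluster": labels,
        "membership": top,
        "is_signature": top > membership_threshold,
    })
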