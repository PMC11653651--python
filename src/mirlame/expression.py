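"""RPM normalization, expression calling, and specificity rules.

A miRNA is *expressed* in a sample when its depth-normalized abundance exceeds
1 RPM (reads per million mapped reads, strict inequality). Group-level rules
build on per-group prevalence of that call:

* expressed in a group: called in >= 60% of the group's samples;
* phenotype-specific: group-expressed in exactly one phenotype and called in
  no sample of any other phenotype (the "other group" ceiling is exposed as
  ``max_other_prevalence``, default 0);
* time-point-specific: group-expressed at exactly one of W0/W1/W2 within a
  phenotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import WEEKS


def rpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million over the per-sample total of the count matrix."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(
            f"samples with zero total counts cannot be RPM-normalized: "
            f"{list(zero.index)}")
    return counts.astype(float).div(totals, axis=1) * 1e6


def call_expressed(rpm: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Boolean expression calls at RPM strictly greater than ``threshold``."""
    if threshold < 0:
        raise ValidationError("expression threshold must be nonnegative")
    return rpm > threshold


def _group_mask(meta: pd.DataFrame, group: str, week: str | None) -> pd.Series:
    mask = meta["phenotype"] == group
    if week is not None:
        mask &= meta["week"] == week
    return mask


def group_prevalence(calls: pd.DataFrame, sample_ids) -> pd.Series:
    """Fraction of the given samples in which each miRNA is called expressed."""
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValidationError("empty sample group")
    return calls.loc[:, sample_ids].mean(axis=1)


def group_expressed_set(calls: pd.DataFrame, meta: pd.DataFrame, group: str,
                        min_prevalence: float = 0.6,
                        week: str | None = None) -> set[str]:
    """miRNAs expressed in >= ``min_prevalence`` of the group's samples."""
    mask = _group_mask(meta, group, week)
    if not mask.any():
        raise ValidationError(
            f"no samples for group {group!r}" + (f" at {week}" if week else ""))
    prev = group_prevalence(calls, meta.loc[mask, "sample_id"])
    return set(prev.index[prev >= min_prevalence])


def detect_phenotype_specific(calls: pd.DataFrame, meta: pd.DataFrame,
                              min_prevalence: float = 0.6,
                              max_other_prevalence: float = 0.0,
                              week: str | None = None
                              ) -> dict[str, set[str]]:
    """Assign each miRNA to at most one phenotype's specific set.

    A miRNA is specific to group G when its prevalence in G is at least
    ``min_prevalence`` and its prevalence in every other group is at most
    ``max_other_prevalence``. With overlapping thresholds a miRNA could
    qualify for several groups; it is then assigned to the group with the
    highest prevalence (ties -> no group), keeping the sets disjoint.
    """
    groups = [g for g in meta["phenotype"].unique()]
    if len(groups) < 2:
        raise ValidationError("phenotype-specific detection needs >= 2 groups")
    prev = pd.DataFrame({
        g: group_prevalence(
            calls, meta.loc[_group_mask(meta, g, week), "sample_id"])
        for g in groups})
    out: dict[str, set[str]] = {g: set() for g in groups}
    for mirna, row in prev.iterrows():
        qualifying = [g for g in groups
                      if row[g] >= min_prevalence
                      and (row.drop(g) <= max_other_prevalence).all()]
        if len(qualifying) == 1:
            out[qualifying[0]].add(mirna)
        elif len(qualifying) > 1:
            best = row[qualifying].sort_values(ascending=False)
            if best.iloc[0] > best.iloc[1]:
                out[best.index[0]].add(mirna)
    return out


def detect_timepoint_specific(calls: pd.DataFrame, meta: pd.DataFrame,
                              phenotype: str, min_prevalence: float = 0.6
                              ) -> dict[str, set[str]]:
    """Per-week sets of miRNAs group-expressed at exactly one time point."""
    weeks = [w for w in WEEKS
             if ((meta["phenotype"] == phenotype) & (meta["week"] == w)).any()]
    if len(weeks) < 2:
        raise ValidationError(
            f"phenotype {phenotype!r} has samples at fewer than 2 weeks")
    expressed = {w: group_expressed_set(calls, meta, phenotype,
                                        min_prevalence, week=w)
                 for w in weeks}
    out: dict[str, set[str]] = {}
    for w in weeks:
        others = set().union(*(expressed[v] for v in weeks if v != w))
        out[w] = expressed[w] - others
    return out


def top_expressed_share(rpm: pd.DataFrame, k: int = 10
                        ) -> tuple[list[str], float]:
    """Top-k miRNAs by mean RPM and their share of total RPM mass."""
    if k > rpm.shape[0]:
        raise ValidationError(f"k={k} exceeds the number of miRNAs {rpm.shape[0]}")
    mean_rpm = rpm.mean(axis=1).sort_values(ascending=False)
    top_ids = list(mean_rpm.index[:k])
    share = float(rpm.loc[top_ids].to_numpy().sum() / rpm.to_numpy().sum())
    return top_ids, share


def specific_mirna_table(rpm: pd.DataFrame, meta: pd.DataFrame,
                         specific: dict[str, set[str]],
                         week: str | None = None) -> pd.DataFrame:
    """Tabulate specific miRNAs with per-group prevalence and mean +/- sd RPM."""
    calls = call_expressed(rpm)
    rows = []
    for group, mirnas in specific.items():
        mask = _group_mask(meta, group, week)
        ids = meta.loc[mask, "sample_id"]
        for m in sorted(mirnas):
            vals = rpm.loc[m, ids]
            rows.append({
                "group": group,
                "mirna_id": m,
                "prevalence": float(calls.loc[m, ids].mean()),
                "mean_rpm": float(vals.mean()),
                "sd_rpm": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            })
    return pd.DataFrame(rows, columns=["group", "mirna_id", "prevalence",
                                       "mean_rpm", "sd_rpm"])
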