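"""ddCt relative quantification and sequencing concordance.

Relative expression of a qPCR target is computed by the standard ddCt method
against two reference assays (internal standards): per sample,
dCt = Ct_target - mean(Ct_ref1, Ct_ref2); ddCt subtracts the mean dCt of a
calibrator (reference) group; fold change = 2^-ddCt, assuming perfect
amplification efficiency. By construction the geometric-mean fold change over
the calibrator group is 1.

Concordance with sequencing calls is judged on direction only: a target is
concordant when the sign of the qPCR group-ratio (log2 of the ratio of
geometric-mean fold changes) matches the sign of the sequencing log2FC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError


def delta_delta_ct(ct: pd.DataFrame, meta: pd.DataFrame, target: str,
                   refs: tuple[str, str], reference_group: str
                   ) -> pd.DataFrame:
    """Per-sample ddCt and fold change for one target assay.

    ``ct`` is tidy (sample_id, assay_id, ct); ``meta`` supplies the sample ->
    phenotype join; ``reference_group`` is the calibrator phenotype.
    """
    if len(refs) != 2:
        raise ValidationError("exactly two reference assay ids are required")
    wide = ct.pivot(index="sample_id", columns="assay_id", values="ct")
    if target not in wide.columns:
        raise ValidationError(f"target assay {target!r} absent from the Ct table")
    for ref in refs:
        if ref not in wide.columns:
            raise ValidationError(f"reference assay {ref!r} absent from the Ct table")
    samples = wide.index[wide[target].notna()]
    for ref in refs:
        missing = [s for s in samples if pd.isna(wide.loc[s, ref])]
        if missing:
            raise ValidationError(
                f"missing reference Ct for assay {ref!r} in samples {missing}")
    groups = meta.set_index("sample_id")["phenotype"]
    dct = wide.loc[samples, target] - wide.loc[samples, list(refs)].mean(axis=1)
    ref_samples = [s for s in samples if groups.get(s) == reference_group]
    if not ref_samples:
        raise ValidationError(
            f"reference group {reference_group!r} has no measured samples")
    ddct = dct - dct.loc[ref_samples].mean()
    out = pd.DataFrame({
        "sample_id": samples,
        "target": target,
        "phenotype": groups.loc[samples].to_numpy(),
        "ddct": ddct.to_numpy(dtype=float),
        "fold_change": np.exp2(-ddct.to_numpy(dtype=float)),
    })
    out.attrs["reference_group"] = reference_group
    return out


def qpcr_group_log2_ratio(rel: pd.DataFrame, group_a: str, group_b: str
                          ) -> float:
    """log2 of the ratio of geometric-mean fold changes, group_b over group_a."""
    ddct_a = rel.loc[rel["phenotype"] == group_a, "ddct"]
    ddct_b = rel.loc[rel["phenotype"] == group_b, "ddct"]
    if len(ddct_a) == 0 or len(ddct_b) == 0:
        raise ValidationError(
            f"groups {group_a!r}/{group_b!r} missing from the qPCR table")
    # geometric mean of 2^-ddct is 2^-mean(ddct)
    return float(ddct_a.mean() - ddct_b.mean())


def concordance(seq_de: pd.DataFrame, qpcr: pd.DataFrame,
                contrast: tuple[str, str]) -> pd.Series:
    """Direction agreement per target between sequencing DE and qPCR.

    ``seq_de`` is a DE table indexed by miRNA id with a log2FoldChange for the
    same (group_a, group_b) contrast; ``qpcr`` is a (possibly concatenated)
    relative-expression table from :func:`delta_delta_ct`.
    """
    group_a, group_b = contrast
    results = {}
    for target, rel in qpcr.groupby("target"):
        if target not in seq_de.index:
            raise ValidationError(
                f"target {target!r} absent from the sequencing DE table")
        seq_sign = np.sign(seq_de.loc[target, "log2FoldChange"])
        qpcr_sign = np.sign(qpcr_group_log2_ratio(rel, group_a, group_b))
        results[target] = "concordant" if seq_sign == qpcr_sign else "discordant"
    if not results:
        raise ValidationError("qPCR table contains no targets")
    return pd.Series(results, name="concordance")
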