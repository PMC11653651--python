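"""Tabular IO for count matrices and sample metadata.

The pipeline's entry point is a miRNA x sample matrix of non-negative integer
read counts plus a per-sample metadata table carrying the lameness phenotype
(HC, DD, FR, TTN, FRDD), sampling week (W0/W1/W2), the 0-3 locomotion gait
score, and the recovery label (RE/UNR/NA).  Both are tab-separated UTF-8 text
with '.' as the decimal mark; a missing gait score is an empty field.

Everything downstream joins through :func:`join_validate`, which refuses to
run when the sample-id sets of the two tables differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

PHENOTYPES = ("HC", "DD", "FR", "TTN", "FRDD")
WEEKS = ("W0", "W1", "W2")
RECOVERY_LABELS = ("RE", "UNR", "NA")

METADATA_COLUMNS = ("sample_id", "animal_id", "phenotype", "week",
                    "gait_score", "recovery")


@dataclass(frozen=True)
class Study:
    """A validated, column-aligned (counts, metadata) pair.

    ``metadata`` rows are reordered so that ``metadata.sample_id`` matches
    ``counts.columns`` position by position.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check CountMatrix invariants; return the frame with int64 counts."""
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate miRNA ids: {dups}")
    if counts.columns.has_duplicates:
        dups = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dups}")
    values = counts.to_numpy()
    if values.size == 0:
        raise ValidationError("empty count matrix")
    numeric = pd.DataFrame(counts).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (numeric.to_numpy() % 1 != 0) | (numeric < 0)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-integer or negative count at miRNA {counts.index[i]!r}, "
            f"sample {counts.columns[j]!r}: {counts.iat[i, j]!r}"
        )
    out = numeric.astype(np.int64)
    if not (out.to_numpy().sum(axis=0) > 0).any():
        raise ValidationError("count matrix has no nonzero column")
    out.index.name = "mirna_id"
    return out


def read_counts(path) -> pd.DataFrame:
    """Read a counts.tsv (header: mirna_id, <sample ids...>)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    seen, dups = set(), []
    for s in samples:
        if s in seen:
            dups.append(s)
        seen.add(s)
    if dups:
        raise FormatError(f"duplicate sample columns in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    return validate_counts(df)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts = validate_counts(counts)
    counts.to_csv(path, sep="\t", index_label="mirna_id")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check SampleMetadata invariants; normalize dtypes."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    meta = meta.loc[:, list(METADATA_COLUMNS)].copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["animal_id"] = meta["animal_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dups}")
    bad_ph = sorted(set(meta["phenotype"]) - set(PHENOTYPES))
    if bad_ph:
        raise ValidationError(f"unknown phenotype labels: {bad_ph}")
    bad_wk = sorted(set(meta["week"]) - set(WEEKS))
    if bad_wk:
        raise ValidationError(f"unknown week labels: {bad_wk}")
    gait = pd.to_numeric(meta["gait_score"], errors="coerce")
    stated = meta["gait_score"].notna() & (meta["gait_score"].astype(str).str.strip() != "")
    if (stated & gait.isna()).any():
        raise ValidationError("non-numeric gait_score")
    present = gait.notna()
    if ((gait[present] % 1 != 0) | (gait[present] < 0) | (gait[present] > 3)).any():
        bad = gait[present][(gait[present] < 0) | (gait[present] > 3) | (gait[present] % 1 != 0)]
        raise ValidationError(f"gait_score outside the 0-3 integer scale: {bad.tolist()}")
    meta["gait_score"] = gait.astype("Int64")
    meta["recovery"] = meta["recovery"].fillna("NA").replace("", "NA")
    bad_rec = sorted(set(meta["recovery"]) - set(RECOVERY_LABELS))
    if bad_rec:
        raise ValidationError(f"unknown recovery labels: {bad_rec}")
    if meta.duplicated(subset=["animal_id", "week"]).any():
        dup = meta.loc[meta.duplicated(subset=["animal_id", "week"]),
                       ["animal_id", "week"]]
        raise ValidationError(
            f"duplicate (animal_id, week) pairs: {dup.to_records(index=False).tolist()}"
        )
    check_recovery_consistency(meta)
    return meta.reset_index(drop=True)


def check_recovery_consistency(meta: pd.DataFrame) -> list[str]:
    """Warn (but keep) recovery labels inconsistent with the gait trajectory.

    Recovery is defined as a decreased gait score between the first and last
    sampled weeks; a stated RE label on a non-decreasing trajectory (or UNR on
    a decreasing one) is logged as a warning and retained verbatim.
    """
    messages: list[str] = []
    week_order = {w: i for i, w in enumerate(WEEKS)}
    for animal, rows in meta.groupby("animal_id"):
        rows = rows.sort_values("week", key=lambda s: s.map(week_order))
        gait = rows["gait_score"].dropna()
        labels = set(rows["recovery"]) - {"NA"}
        if len(gait) < 2 or not labels:
            continue
        decreased = gait.iloc[-1] < gait.iloc[0]
        if "RE" in labels and not decreased:
            messages.append(
                f"animal {animal}: labeled RE but gait did not decrease "
                f"({gait.iloc[0]} -> {gait.iloc[-1]})"
            )
        if "UNR" in labels and decreased:
            messages.append(
                f"animal {animal}: labeled UNR but gait decreased "
                f"({gait.iloc[0]} -> {gait.iloc[-1]})"
            )
    for msg in messages:
        logger.warning("recovery/gait inconsistency: %s", msg)
    return messages


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.replace("", pd.NA)
    return validate_metadata(df)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta = validate_metadata(meta)
    out = meta.copy()
    out["gait_score"] = out["gait_score"].astype(object).where(out["gait_score"].notna(), "")
    out.to_csv(path, sep="\t", index=False)


def join_validate(counts: pd.DataFrame, meta: pd.DataFrame) -> Study:
    """Align metadata rows to count columns; fail loudly on id mismatches."""
    counts = validate_counts(counts)
    meta = validate_metadata(meta)
    count_ids = set(counts.columns)
    meta_ids = set(meta["sample_id"])
    extra_counts = sorted(count_ids - meta_ids)
    extra_meta = sorted(meta_ids - count_ids)
    if extra_counts or extra_meta:
        raise ValidationError(
            "sample id sets differ between counts and metadata; "
            f"counts-only: {extra_counts}; metadata-only: {extra_meta}"
        )
    aligned = meta.set_index("sample_id").loc[list(counts.columns)].reset_index()
    return Study(counts=counts, metadata=aligned)
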