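"""Readers and writers for the pipeline's on-disk formats.

Three plain-text formats are supported:

* **beta matrix** — tab-separated, first column ``probe_id``, remaining
  columns one per patient; cells are methylation beta values in [0, 1]
  ('.' decimal, UTF-8). Empty cells denote missing measurements.
* **probe manifest** — CSV with columns ``probe_id,gene_annotation``; an
  empty annotation means the probe maps to no annotated gene. Multi-gene
  annotations stay a single semicolon-joined string (e.g.
  ``MZF1;LOC100131691``).
* **sample sheet** — CSV in long form, one row per patient x timepoint,
  carrying outcomes, survival times, clinical scores and covariates.

Probes are treated as opaque identifiers with gene-name annotations only;
genomic coordinates play no role in this analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TIMEPOINTS = ("t0", "t2", "tr")

#: sample-sheet columns that are required, in canonical order
SHEET_REQUIRED = [
    "patient_id",
    "timepoint",
    "outcome",
    "early_outcome",
    "time_to_event",
    "event_observed",
    "save_score",
    "apache2",
    "lods",
    "mods",
    "sofa",
]

#: float format used by every writer; wide enough for lossless round trips
FLOAT_FMT = "%.17g"


@dataclass
class BetaMatrix:
    """Probes x samples beta values for one sampling timepoint.

    ``values`` is a DataFrame indexed by probe ID with one column per
    patient; entries lie in [0, 1] or are NaN (missing).
    """

    values: pd.DataFrame
    timepoint: str

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe IDs: {dups[:5]}")
        cols = self.values.columns
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValueError(
                f"beta value {vals[i, j]} outside [0,1] at probe "
                f"{idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        missing = [p for p in probe_ids if p not in self.values.index]
        if missing:
            raise KeyError(f"probes absent from {self.timepoint} matrix: {missing[:5]}")
        return BetaMatrix(self.values.loc[list(probe_ids)], self.timepoint)


@dataclass
class CohortTable:
    """Per-patient outcomes, survival times, clinical scores and covariates."""

    data: pd.DataFrame  # indexed by patient_id
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("duplicate patient IDs in cohort table")
        bad_outcome = ~df["outcome"].isin(["survivor", "non_survivor"])
        if bad_outcome.any():
            raise ValueError(f"invalid outcome values: {df['outcome'][bad_outcome].unique()}")
        bad_early = ~df["early_outcome"].isin(["success", "failure"])
        if bad_early.any():
            raise ValueError(
                f"invalid early_outcome values: {df['early_outcome'][bad_early].unique()}"
            )
        # in-hospital death is the event; discharge alive is censoring
        inconsistent = (df["outcome"] == "survivor") == df["event_observed"].astype(bool)
        if inconsistent.any():
            pids = df.index[inconsistent].tolist()
            raise ValueError(
                f"outcome/event_observed inconsistent (survivor <=> censored) for {pids[:5]}"
            )
        if (df["time_to_event"] <= 0).any():
            raise ValueError("time_to_event must be positive")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_survivors(self) -> int:
        return int((self.data["outcome"] == "survivor").sum())

    @property
    def n_non_survivors(self) -> int:
        return int((self.data["outcome"] == "non_survivor").sum())

    def outcome_vector(self, patient_ids=None) -> np.ndarray:
        """0/1 labels with non_survivor = 1 (the positive class downstream)."""
        df = self.data if patient_ids is None else self.data.loc[list(patient_ids)]
        return (df["outcome"] == "non_survivor").to_numpy(dtype=int)

    def early_outcome_vector(self, patient_ids=None) -> np.ndarray:
        """0/1 labels with failure = 1."""
        df = self.data if patient_ids is None else self.data.loc[list(patient_ids)]
        return (df["early_outcome"] == "failure").to_numpy(dtype=int)


def read_beta_matrix(path, timepoint: str) -> BetaMatrix:
    """Read a tab-separated probe x sample beta matrix.

    Raises a descriptive error naming the offending cell for non-numeric or
    out-of-range entries and for duplicated probe/sample IDs.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col].str.strip()
        numeric = pd.to_numeric(cells.replace("", np.nan), errors="coerce")
        bad = numeric.isna() & (cells != "")
        if bad.any():
            probe = raw.index[bad.to_numpy()][0]
            raise ValueError(
                f"{path}: non-numeric beta {cells[bad].iloc[0]!r} at probe {probe!r}, "
                f"sample {col!r}"
            )
        parsed[col] = numeric
    return BetaMatrix(parsed, timepoint)


def write_beta_matrix(path, matrix: BetaMatrix) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format=FLOAT_FMT)


def read_manifest(path) -> pd.Series:
    """Read the probe annotation manifest; returns probe_id -> annotation.

    Empty annotations are preserved as empty strings (unannotated probe).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"probe_id", "gene_annotation"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}, has {list(df.columns)}")
    if df["probe_id"].duplicated().any():
        dups = df["probe_id"][df["probe_id"].duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated probe_id in manifest: {dups[:5]}")
    return pd.Series(
        df["gene_annotation"].to_numpy(), index=df["probe_id"].to_numpy(), name="gene_annotation"
    )


def write_manifest(path, manifest: pd.Series) -> None:
    pd.DataFrame({"probe_id": manifest.index, "gene_annotation": manifest.to_numpy()}).to_csv(
        path, index=False
    )


def read_sample_sheet(path) -> CohortTable:
    """Read the long-form sample sheet and collapse it to one row per patient.

    Validates the survivor <=> censored consistency rule and that per-patient
    fields agree across that patient's timepoint rows. ``has_tr`` is derived
    from the presence of a ``tr`` row.
    """
    df = pd.read_csv(path)
    missing = [c for c in SHEET_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {missing}")
    bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
    if bad_tp.any():
        raise ValueError(f"{path}: invalid timepoints {df['timepoint'][bad_tp].unique()}")
    if df.duplicated(["patient_id", "timepoint"]).any():
        raise ValueError(f"{path}: duplicated (patient_id, timepoint) rows")

    covariates = [c for c in df.columns if c not in SHEET_REQUIRED]
    per_patient_cols = [c for c in df.columns if c not in ("timepoint",)]
    collapsed = []
    for pid, grp in df.groupby("patient_id", sort=False):
        row = grp.iloc[0][per_patient_cols].copy()
        const = grp[per_patient_cols].nunique(dropna=False) <= 1
        if not const.all():
            varying = const.index[~const].tolist()
            raise ValueError(f"{path}: fields {varying} vary across rows of patient {pid!r}")
        row["has_tr"] = bool((grp["timepoint"] == "tr").any())
        collapsed.append(row)
    out = pd.DataFrame(collapsed).set_index("patient_id")
    out["event_observed"] = out["event_observed"].astype(bool)
    return CohortTable(out, covariates=covariates)


def write_sample_sheet(path, cohort: CohortTable) -> None:
    """Expand the per-patient table back to long form (one row per sample)."""
    rows = []
    for pid, row in cohort.data.iterrows():
        tps = ["t0", "t2"] + (["tr"] if row["has_tr"] else [])
        for tp in tps:
            r = row.drop(labels=["has_tr"]).to_dict()
            r["patient_id"] = pid
            r["timepoint"] = tp
            rows.append(r)
    df = pd.DataFrame(rows)
    ordered = SHEET_REQUIRED + [c for c in df.columns if c not in SHEET_REQUIRED]
    df[ordered].to_csv(path, index=False, float_format=FLOAT_FMT)


def align_samples(matrix: BetaMatrix, cohort: CohortTable) -> list[str]:
    """Patient IDs present in both the matrix and the cohort, in matrix order.

    Fails loudly if the matrix carries samples the cohort does not know, or
    if a patient expected at this timepoint is missing from the matrix.
    """
    known = set(cohort.patient_ids)
    unknown = [s for s in matrix.sample_ids if s not in known]
    if unknown:
        raise ValueError(
            f"samples in {matrix.timepoint} matrix without cohort entry: {unknown[:5]}"
        )
    if matrix.timepoint == "tr":
        expected = set(cohort.data.index[cohort.data["has_tr"]])
    else:
        expected = known
    missing = sorted(expected - set(matrix.sample_ids))
    if missing:
        raise ValueError(
            f"patients missing from {matrix.timepoint} matrix: {missing[:5]}"
        )
    return matrix.sample_ids


def drop_missing_probes(*matrices: BetaMatrix) -> tuple[BetaMatrix, ...]:
    """Drop probes with any missing beta in any of the given matrices."""
    keep = None
    for m in matrices:
        ok = ~m.values.isna().any(axis=1)
        keep = ok if keep is None else (keep & ok)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d probes with missing betas (%d retained)", dropped, int(keep.sum()))
    kept_ids = keep.index[keep]
    return tuple(BetaMatrix(m.values.loc[kept_ids], m.timepoint) for m in matrices)


def write_result_table(path, df: pd.DataFrame, *, meta: dict | None = None) -> None:
    """Write a result table as TSV with a ``#``-comment header of metadata."""
    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
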