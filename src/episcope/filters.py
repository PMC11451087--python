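"""Stage 1 probe filtering: gene annotation, then temporal stability.

The stability filter inverts the usual hypothesis-testing logic: for each
probe a paired Wilcoxon signed-rank test compares methylation at ECMO
initiation (t0) with methylation at ECMO removal (tr) over the patients
sampled at both timepoints, and probes whose p-value exceeds the threshold
(default 0.8, strict inequality) are RETAINED — large p is read as "no
detectable ECMO-driven change", i.e. the probe reflects patient-intrinsic
epigenetic state. No multiple-testing correction is applied; the retention
rule is a heuristic screen, not an inference procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BetaMatrix, CohortTable, align_samples
from .stats import wilcoxon_signed_rank

__all__ = ["StableProbeSet", "annotation_filter", "stability_filter"]


@dataclass
class StableProbeSet:
    """Per-probe stability-test results and retention flags."""

    records: pd.DataFrame  # probe_id, statistic, p_value, n_effective, retained
    n_input: int
    n_annotated: int
    n_retained: int
    p_threshold: float
    paired_patient_ids: list[str] = field(default_factory=list)

    @property
    def retained_ids(self) -> list[str]:
        r = self.records
        return r.loc[r["retained"], "probe_id"].tolist()

    def to_tsv(self, path, *, meta: dict | None = None) -> None:
        from .io import write_result_table

        base = {
            "n_input": self.n_input,
            "n_annotated": self.n_annotated,
            "n_retained": self.n_retained,
            "p_threshold": self.p_threshold,
            "paired_patients": ",".join(self.paired_patient_ids),
        }
        write_result_table(path, self.records, meta={**base, **(meta or {})})

    @classmethod
    def from_tsv(cls, path) -> "StableProbeSet":
        meta = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.startswith("# "):
                    break
                k, v = line[2:].split(":", 1)
                meta[k.strip()] = v.strip()
        records = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            records=records,
            n_input=int(meta["n_input"]),
            n_annotated=int(meta["n_annotated"]),
            n_retained=int(meta["n_retained"]),
            p_threshold=float(meta["p_threshold"]),
            paired_patient_ids=meta["paired_patients"].split(",") if meta["paired_patients"] else [],
        )


def annotation_filter(matrix: BetaMatrix, manifest: pd.Series) -> list[str]:
    """Probes of ``matrix`` with a nonempty gene annotation, in matrix order."""
    missing = [p for p in matrix.probe_ids if p not in manifest.index]
    if missing:
        raise ValueError(f"probes absent from manifest: {missing[:10]}")
    ann = manifest.loc[matrix.probe_ids]
    return [p for p, g in ann.items() if isinstance(g, str) and g != ""]


def stability_filter(
    t0: BetaMatrix,
    tr: BetaMatrix,
    cohort: CohortTable,
    candidate_probes,
    p_threshold: float = 0.8,
    *,
    wilcoxon_method: str = "auto",
) -> StableProbeSet:
    """Retain probes whose paired t0<->tr Wilcoxon p-value exceeds ``p_threshold``.

    Paired differences are computed over exactly the patients present in
    both matrices. ``wilcoxon_method`` is ``"auto"`` (exact null when
    feasible) or ``"approx"`` (always the normal approximation); the
    retained count can differ between the two because the attainable exact
    p-values form a discrete set around the threshold.
    """
    candidate_probes = list(candidate_probes)
    align_samples(t0, cohort)
    align_samples(tr, cohort)
    paired = [s for s in t0.sample_ids if s in set(tr.sample_ids)]
    if len(paired) < 2:
        raise ValueError(f"need >= 2 patients with both t0 and tr samples, have {len(paired)}")

    t0_sub = t0.subset_probes(candidate_probes).values[paired].to_numpy()
    tr_sub = tr.subset_probes(candidate_probes).values[paired].to_numpy()
    diffs = t0_sub - tr_sub

    rows = []
    for probe, d in zip(candidate_probes, diffs):
        res = wilcoxon_signed_rank(d, method=wilcoxon_method)
        rows.append((probe, res.statistic, res.p_two_sided, res.n_effective, res.method))
    records = pd.DataFrame(
        rows, columns=["probe_id", "statistic", "p_value", "n_effective", "method"]
    )
    records["retained"] = records["p_value"] > p_threshold  # strict
    return StableProbeSet(
        records=records,
        n_input=len(t0.probe_ids),
        n_annotated=len(candidate_probes),
        n_retained=int(records["retained"].sum()),
        p_threshold=p_threshold,
        paired_patient_ids=paired,
    )
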