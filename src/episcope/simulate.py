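"""Synthetic ECMO cohort generator.

Emulates the structure of a 450K-style longitudinal methylation study of
cardiogenic-shock patients on ECMO: beta-value matrices at ECMO initiation
(t0), two hours post-installation (t2) and ECMO removal (tr), a probe
manifest with gene annotations, and a per-patient cohort table with
in-hospital outcome, 7-day outcome, survival/censoring times, clinical
scores (SAVE, APACHE II, LODS, MODS, SOFA) and Table-1-style covariates.

Statistical structure planted in the probes:

* **null probes** — patient-intrinsic methylation, stable across t0/t2/tr,
  carrying no outcome information;
* **prognostic probes** — a logit-scale mean shift for non-survivors at all
  timepoints (the signal the pipeline should recover);
* **responsive probes** — a logit-scale shift at tr (half of it at t2) for
  every patient, mimicking an ECMO-driven methylation drift that the
  temporal-stability filter should remove.

Per-probe baseline means follow the bimodal hypo/hyper mixture typical of
450K arrays; per-sample betas are Beta-distributed around those means so the
[0, 1] support is respected. A patient's t0 and tr values of a stable probe
share the same intrinsic draw: the stable component of the epigenome is
modelled as exactly reproducible within a patient, which is what makes the
rank-based stability filter behave as intended (see docs/methods.md for the
discussion of this idealization). The t2 snapshot is drawn fresh around the
same probe-level means and is tied to t0 only through a patient-level
random offset, so the temporal-transfer test probes the persistent
outcome-linked shifts rather than re-identifying training patients by
their probe-level sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    BetaMatrix,
    CohortTable,
    write_beta_matrix,
    write_manifest,
    write_sample_sheet,
)

__all__ = ["SynthConfig", "PlantedTruth", "SimulatedCohort", "generate", "write_cohort"]


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: 34 patients sampled at t0 and t2,
    14 of whom conclude ECMO and contribute a tr sample, 12 survivors vs 22
    in-hospital deaths. Effects are on the logit (log-odds of methylation)
    scale so shifts respect the [0, 1] beta support.
    """

    n_patients: int = 34
    n_survivors: int = 12
    n_tr: int = 14
    n_probes: int = 5000
    frac_annotated: float = 0.75
    n_prognostic: int = 10
    n_responsive: int = 200
    prognostic_effect: float = 1.3  # logit shift, non-survivors, all timepoints
    responsive_effect: float = 1.5  # logit shift at tr (half at t2), all patients
    beta_precision: float = 50.0  # concentration of the Beta noise
    patient_effect_sd: float = 0.3  # sd of the patient-level logit offset at t2
    tr_noise_sd: float = 0.0  # logit-scale technical noise at tr
    survivor_tr_bias: float = 4.0  # sampling weight of survivors for tr inclusion
    hazard_ratio: float = 3.0  # non-survivor vs survivor event-time scale ratio
    event_scale_days: float = 12.0  # Weibull scale before the hazard-ratio division
    weibull_shape: float = 1.2
    discharge_days: tuple[float, float] = (30.0, 60.0)  # survivor censoring window
    score_signal: float = 1.0  # loading of outcome on the latent clinical risk
    seed: int = 0

    def validate(self) -> None:
        if self.n_prognostic + self.n_responsive > self.n_probes:
            raise ValueError("n_prognostic + n_responsive exceeds n_probes")
        if self.n_survivors > self.n_patients:
            raise ValueError("n_survivors exceeds n_patients")
        if self.n_tr > self.n_patients:
            raise ValueError("n_tr exceeds n_patients")
        if not 0 <= self.frac_annotated <= 1:
            raise ValueError("frac_annotated must be in [0, 1]")
        if self.beta_precision <= 2:
            raise ValueError("beta_precision must exceed 2")


#: a paper-scale configuration (full 450K probe count); not used by the tests
PAPER_SCALE = dict(n_probes=485_577, n_responsive=20_000, n_prognostic=50)


@dataclass
class PlantedTruth:
    """Ground-truth probe roles of one simulated cohort (disjoint ID sets)."""

    prognostic_probe_ids: list[str]
    responsive_probe_ids: list[str]
    null_probe_ids: list[str]


@dataclass
class SimulatedCohort:
    t0: BetaMatrix
    t2: BetaMatrix
    tr: BetaMatrix
    manifest: pd.Series
    cohort: CohortTable
    truth: PlantedTruth
    config: SynthConfig = field(repr=False, default=None)


def generate(config: SynthConfig) -> SimulatedCohort:
    """Draw one fully reproducible synthetic cohort from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    P, N = config.n_probes, config.n_patients

    probe_ids = np.array([f"cg{i:08d}" for i in range(P)])
    patient_ids = np.array([f"P{i + 1:03d}" for i in range(N)])

    # probe roles
    roles = rng.permutation(P)
    prog_idx = np.sort(roles[: config.n_prognostic])
    resp_idx = np.sort(roles[config.n_prognostic : config.n_prognostic + config.n_responsive])
    null_idx = np.sort(roles[config.n_prognostic + config.n_responsive :])

    # bimodal baseline means on the logit scale (hypo ~0.1 / hyper ~0.9 with a
    # minor intermediate component)
    comp = rng.choice(3, size=P, p=[0.45, 0.45, 0.10])
    mean_logit = np.where(
        comp == 0,
        rng.normal(_logit(0.1), 0.5, size=P),
        np.where(comp == 1, rng.normal(_logit(0.9), 0.5, size=P), rng.normal(0.0, 1.0, size=P)),
    )

    # outcomes
    outcome = np.array(["non_survivor"] * N)
    surv_pos = rng.choice(N, size=config.n_survivors, replace=False)
    outcome[surv_pos] = "survivor"
    is_ns = outcome == "non_survivor"

    # patient x probe intrinsic methylation (shared by t0 and tr); prognostic
    # shifts point toward the logit midpoint (demethylation at hypermethylated
    # sites, methylation gain at hypomethylated ones) so differential signal
    # is not squashed against the [0, 1] boundaries
    shift = np.zeros((P, N))
    prog_sign = -np.sign(mean_logit[prog_idx])
    prog_sign[prog_sign == 0] = 1.0
    shift[prog_idx[:, None], np.where(is_ns)[0][None, :]] = (
        config.prognostic_effect * prog_sign
    )[:, None]
    mu = _expit(mean_logit[:, None] + shift)
    kappa = config.beta_precision
    intrinsic = rng.beta(mu * kappa, (1.0 - mu) * kappa)
    intrinsic = np.clip(intrinsic, 1e-6, 1.0 - 1e-6)

    def to_beta(logits):
        return np.clip(_expit(logits), 1e-6, 1.0 - 1e-6)

    t0_vals = intrinsic

    # t2: fresh beta draws around the same probe-level means (prognostic shift
    # persists, responsive probes get half their drift), correlated with t0
    # only through a patient-level random offset — per-probe sampling noise is
    # redrawn, so spurious t0 probe-outcome associations do not carry over
    g_patient = rng.normal(0.0, config.patient_effect_sd, size=N)
    t2_mu_logit = mean_logit[:, None] + shift + g_patient[None, :]
    t2_mu_logit[resp_idx, :] += config.responsive_effect / 2.0
    mu_t2 = _expit(t2_mu_logit)
    t2_vals = np.clip(rng.beta(mu_t2 * kappa, (1.0 - mu_t2) * kappa), 1e-6, 1.0 - 1e-6)

    # tr: subset of patients, sampled preferentially from survivors
    w = np.where(is_ns, 1.0, config.survivor_tr_bias)
    tr_pos = np.sort(rng.choice(N, size=config.n_tr, replace=False, p=w / w.sum()))
    # stable probes keep the intrinsic draw untouched (bitwise) so paired
    # t0-tr differences are exactly zero; only responsive probes (and, when
    # technical noise is configured, all probes) pass through the logit map
    tr_vals = intrinsic[:, tr_pos].copy()
    if config.tr_noise_sd > 0:
        tl = _logit(tr_vals) + rng.normal(0.0, config.tr_noise_sd, size=tr_vals.shape)
        tl[resp_idx, :] += config.responsive_effect
        tr_vals = to_beta(tl)
    else:
        tr_vals[resp_idx, :] = to_beta(
            _logit(tr_vals[resp_idx, :]) + config.responsive_effect
        )

    # manifest: planted-signal probes are always annotated so the annotation
    # filter cannot silently discard the structure under study
    annotated = rng.random(P) < config.frac_annotated
    annotated[prog_idx] = True
    annotated[resp_idx] = True
    genes = np.array([""] * P, dtype=object)
    two_symbols = rng.random(P) < 0.05
    for i in np.where(annotated)[0]:
        genes[i] = f"GENE{i:05d};LOC{i:06d}" if two_symbols[i] else f"GENE{i:05d}"
    manifest = pd.Series(genes, index=probe_ids, name="gene_annotation")

    # survival: in-hospital death is the event; survivors censored at discharge
    scale_ns = config.event_scale_days / config.hazard_ratio ** (1.0 / config.weibull_shape)
    times = np.empty(N)
    times[is_ns] = np.maximum(
        0.25, scale_ns * rng.weibull(config.weibull_shape, size=int(is_ns.sum()))
    )
    lo, hi = config.discharge_days
    times[~is_ns] = rng.uniform(lo, hi, size=int((~is_ns).sum()))
    event = is_ns.copy()
    early = np.where(event & (times <= 7.0), "failure", "success")

    # clinical scores from a latent risk correlated with outcome
    risk = config.score_signal * is_ns.astype(float) + rng.normal(0.0, 1.0, size=N)
    apache2 = np.clip(np.round(14 + 6 * risk + rng.normal(0, 3, N)), 0, 71)
    lods = np.clip(np.round(7 + 3 * risk + rng.normal(0, 2, N)), 0, 22)
    mods = np.clip(np.round(8 + 3 * risk + rng.normal(0, 3, N)), 0, 24)
    sofa = np.clip(np.round(9 + 3 * risk + rng.normal(0, 3, N)), 0, 24)
    save = np.clip(np.round(-2 - 4 * risk + rng.normal(0, 3, N)), -35, 17)  # higher = better

    cohort_df = pd.DataFrame(
        {
            "outcome": outcome,
            "early_outcome": early,
            "time_to_event": times,
            "event_observed": event,
            "save_score": save,
            "apache2": apache2,
            "lods": lods,
            "mods": mods,
            "sofa": sofa,
            "age": np.round(rng.normal(52, 10, N), 1),
            "gender": rng.choice(["male", "female"], size=N, p=[0.7, 0.3]),
            "diabetes": (rng.random(N) < np.where(is_ns, 0.6, 0.9)).astype(int),
            "dialysis": (rng.random(N) < np.where(is_ns, 0.8, 0.95)).astype(int),
            "hypertension": (rng.random(N) < 0.55).astype(int),
            "smoking": (rng.random(N) < 0.8).astype(int),
            "has_tr": np.isin(np.arange(N), tr_pos),
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )
    cohort = CohortTable(
        cohort_df,
        covariates=["age", "gender", "diabetes", "dialysis", "hypertension", "smoking"],
    )

    pidx = pd.Index(probe_ids, name="probe_id")
    bundle = SimulatedCohort(
        t0=BetaMatrix(pd.DataFrame(t0_vals, index=pidx, columns=patient_ids), "t0"),
        t2=BetaMatrix(pd.DataFrame(t2_vals, index=pidx, columns=patient_ids), "t2"),
        tr=BetaMatrix(pd.DataFrame(tr_vals, index=pidx, columns=patient_ids[tr_pos]), "tr"),
        manifest=manifest,
        cohort=cohort,
        truth=PlantedTruth(
            prognostic_probe_ids=list(probe_ids[prog_idx]),
            responsive_probe_ids=list(probe_ids[resp_idx]),
            null_probe_ids=list(probe_ids[null_idx]),
        ),
        config=config,
    )
    return bundle


def write_cohort(outdir, sim: SimulatedCohort) -> dict[str, Path]:
    """Write the full bundle in the pipeline's on-disk formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "t0": out / "beta_t0.tsv",
        "t2": out / "beta_t2.tsv",
        "tr": out / "beta_tr.tsv",
        "manifest": out / "manifest.csv",
        "sheet": out / "sample_sheet.csv",
        "truth": out / "planted_truth.csv",
    }
    write_beta_matrix(paths["t0"], sim.t0)
    write_beta_matrix(paths["t2"], sim.t2)
    write_beta_matrix(paths["tr"], sim.tr)
    write_manifest(paths["manifest"], sim.manifest)
    write_sample_sheet(paths["sheet"], sim.cohort)
    truth_rows = (
        [(p, "prognostic") for p in sim.truth.prognostic_probe_ids]
        + [(p, "responsive") for p in sim.truth.responsive_probe_ids]
        + [(p, "null") for p in sim.truth.null_probe_ids]
    )
    pd.DataFrame(truth_rows, columns=["probe_id", "role"]).to_csv(paths["truth"], index=False)
    return paths


def config_to_dict(config: SynthConfig) -> dict:
    d = asdict(config)
    d["discharge_days"] = list(d["discharge_days"])
    return d


def config_from_dict(d: dict) -> SynthConfig:
    d = dict(d)
    if "discharge_days" in d:
        d["discharge_days"] = tuple(d["discharge_days"])
    return SynthConfig(**d)
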