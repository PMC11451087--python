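"""LASSO feature selection over the stable probes of the t0 dataset.

Fits the (2n)^-1 squared-error LASSO across the conventional alpha grid
{0, 1e-5, 0.05, 0.1, 0.2, 0.25} on z-scored beta values, with the 0/1
in-hospital outcome as response (non-survivor = 1). Alpha 0 means "no
selection" (all stable probes kept). The feature table lists each selected
probe's per-alpha coefficient, gene annotation, Mann-Whitney group p-value
and the number of alphas selecting it.
"""

from episcope import SynthConfig, annotation_filter, generate, stability_filter
from episcope.lasso import build_feature_table, fit_lasso_path

sim = generate(SynthConfig(n_probes=2000, seed=7))
annotated = annotation_filter(sim.t0, sim.manifest)
stable = stability_filter(sim.t0, sim.tr, sim.cohort, annotated)

ids = stable.retained_ids
pats = sim.cohort.patient_ids
X = sim.t0.subset_probes(ids).values[pats].to_numpy().T
y = sim.cohort.outcome_vector(pats)

path = fit_lasso_path(X, y, ids, cv_folds=5, seed=1)
print(path.summary().to_string(index=False))

table = build_feature_table(path, X, y, sim.manifest)
print(f"\nfeatures selected at any selective alpha: {len(table)}")
print(table.head(8).to_string(index=False))

planted = set(sim.truth.prognostic_probe_ids)
print(f"\nplanted prognostic probes among them: "
      f"{len(set(table['probe_id']) & planted)}/{len(planted)}")

# n_features shrinks as alpha grows (the soft-threshold removes weakly
# correlated probes first); planted prognostic probes have tiny Mann-Whitney
# p-values and dominate the most-selected rows.
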