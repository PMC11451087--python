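"""Run the full pipeline end-to-end on a synthetic cohort.

Equivalent to `episcope run --config pipeline.yaml --outdir out/`: simulate
-> annotation + stability filter -> LASSO path -> random-forest LOOCV +
temporal transfer (+ EpiSAVE fusion) -> ROC / Kaplan-Meier / log-rank /
cohort table. All outputs land in the chosen directory together with a
manifest of seeds, parameters and row counts for exact reproduction.
"""

import tempfile
from pathlib import Path

from episcope import ForestConfig, PipelineConfig, SynthConfig, run_pipeline

config = PipelineConfig(
    seed=7,
    synth=SynthConfig(n_probes=2000, seed=0),
    alphas=(0.0, 0.00001, 0.05, 0.1, 0.2, 0.25),
    classify_alphas=(0.1,),
    episave=True,
    forest=ForestConfig(n_trees=500),
)

outdir = Path(tempfile.mkdtemp()) / "run"
results = run_pipeline(config, outdir)

counts = results["manifest"]["counts"]
print("probe ledger:", {k: counts[k] for k in
                        ("probes_total", "probes_annotated", "probes_stable")})
print("features per alpha:", counts["features_per_alpha"])

for (alpha, variant), rep in results["reports"].items():
    m = rep.test_metrics
    roc = results["roc"][(alpha, variant)]
    lr = results["logrank"].get((alpha, variant))
    print(f"alpha={alpha:g} [{variant:<11}] transfer accuracy={m['accuracy']:.3f} "
          f"AUC={roc.auc:.3f} log-rank p={lr.p_value:.2e}" if lr else "")

print("outputs written to", outdir)

# The probe ledger shrinks monotonically across the filter stages; rerunning
# with the same config and seed reproduces every table byte for byte.
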