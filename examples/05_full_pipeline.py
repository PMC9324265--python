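"""The whole analysis in one call, with every artefact written to disk.

QC -> association -> risk orientation -> LD pruning -> both score models ->
score-level association -> ROC, plus a run manifest and markdown report.
Equivalent shell command:  mirpgs run --config cfg.yaml --out out/
"""

from mirpgs.pipeline import PipelineConfig, run_pipeline
from mirpgs.simulate import default_config

config = PipelineConfig(sim=default_config(seed=1), seed=1, out_dir="scratch/example_run")
result = run_pipeline(config)

m = result.manifest
print(f"variants: {m['counts']['input']['variants']} in -> "
      f"{m['counts']['qc']['variants']} after QC -> "
      f"{m['counts']['prune']['kept']} after LD pruning")
w = result.pgs_assoc["weighted"]["adjusted"]
print(f"weighted PGS (covariate-adjusted): OR per SD {w.or_per_sd:.2f} "
      f"({w.ci_low:.2f}-{w.ci_high:.2f}); AUC {result.roc['weighted'].auc:.3f}")
print(f"outputs (tables, models, scores, ROC, report.md) in {config.out_dir}/")
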