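"""End-to-end run at reduced scale: phantom data -> patch features ->
NCA/INCA selection -> tenfold 1-NN + benchmark.

Uses 15 images per class at 64 px with 256-dimensional random-projection
features so the whole run takes seconds; the pooled kNN metrics and the
chosen subset size are printed at the end. Scale n_class0/1, image_size
and output_dim up for the full-size experiment.
"""

from pdfe import NCAConfig, PipelineConfig, SynthConfig, generate_dataset, run_pipeline

records, manifest = generate_dataset(
    SynthConfig(n_class0=15, n_class1=15, image_size=64,
                lesion_radius_class0=10, lesion_radius_class1=4,
                effect_size=2.0, noise_sd=0.05, seed=0),
    "scratch_example_run/data",
)
config = PipelineConfig(
    manifest_path=manifest,
    output_dir="scratch_example_run/out",
    extractor="fallback", extractor_seed=0,
    output_dim=256, fallback_input_side=16,
    patch_side=16, resize_side=64,
    nca=NCAConfig(max_iters=15),
    k_min=1, k_max=60, folds=5, seed=1,
)
result = run_pipeline(config, records=records)

sel = result.selection
print(f"fused features: {result.features.n_samples} x {result.features.n_features}")
print(f"selection: chosen_k = {sel.chosen_k}, min CV loss = {sel.losses.min():.3f}")
report = result.knn_report
print(f"kNN pooled: accuracy {report.accuracy:.1f}%  recall {report.recall:.1f}%  "
      f"precision {report.precision:.1f}%  F1 {report.f1:.1f}%")
print("benchmark:", {r.classifier_name: round(r.accuracy, 1) for r in result.reports})
print("artifacts:", sorted(p.name for p in result.artifacts.values()))
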