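"""Gradient-based feature ranking and cross-task overlap.

Fits a small multi-stage model, ranks connectome edges per outcome by the
absolute gradient of each task head, and intersects the top-20 lists.
"""

from mmdtl import PipelineConfig, TrainingConfig, TransferPipeline, overlap_sets, top_k
from mmdtl.synthetic import (
    SyntheticConfig,
    generate_intermediate_cohort,
    generate_source_cohort,
    generate_target_cohort,
)

syn = SyntheticConfig(n_roi=20, n_source=150, n_intermediate=100, n_target=33,
                      n_sites=4, n_planted_common=4, n_planted_per_task=8,
                      seed=0)
cfg = PipelineConfig(
    n_input=syn.n_edges, task_count=3, mode="multi_stage", widths=(32, 16, 8, 6),
    seed=0,
    stage1=TrainingConfig(batch_size=16, max_epochs=10, seed=0),
    stage2=TrainingConfig(batch_size=16, max_epochs=15, seed=0),
    stage3=TrainingConfig(batch_size=4, max_epochs=10, seed=0),
)
pipe = TransferPipeline(cfg)
pipe.pretrain(generate_source_cohort(syn, 0), generate_intermediate_cohort(syn, 0))
target = generate_target_cohort(syn, 0)
model = pipe.fit_stage3(target.records, seed=0)

rankings = pipe.saliency(model, target.records)
tops = {}
for task, ranking in rankings.items():
    tops[task] = top_k(ranking, 20)
    print(f"{task}: top 5 edges {tops[task][:5]}")

overlaps = overlap_sets(tops)
for subset, common in overlaps.items():
    print(f"common to {' & '.join(subset)}: {len(common)} edges")
# Edges named ROIi__ROIj in the fixed vectorization order; the all-task
# intersection is the candidate set of connections relevant to every
# outcome. Rankings fitted on 33 subjects are noisy — see docs/methods.md.
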