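"""Spike-in style detection metrics for one submission.

Treats the synthetic annotation as a set of ground-truth spike-in
transcripts (each gene one known isoform), submits a mix of faithful and
degraded models, and reports sensitivity/precision-type rates.
"""

import json

from isobench import (
    SimConfig, TruthSet, build_reference_index, classify_set,
    evaluate_detection, perturb_submission, simulate_annotation,
)

cfg = SimConfig(
    seed=13, n_genes=30, isoforms_per_gene=1,
    p_drop=0.1, p_truncate=0.2, p_site_shift=0.1,
)
truth_ann = simulate_annotation(cfg)
submission, labels = perturb_submission(truth_ann, cfg)

classified, _ = classify_set(submission, build_reference_index(truth_ann))
perf = evaluate_detection(classified, TruthSet(mode="sirv", transcripts=truth_ann))

print(json.dumps(perf.to_dict(), indent=2))

# TP counts truth transcripts recovered as Reference Matches; PTP those
# recovered only as truncated/non-RM matches; FP counts submitted novel
# models (NIC/NNC/antisense/fusion). Sensitivity = TP / truth size;
# precision = RM models / submission size; redundancy near 1 means one
# model per detected truth transcript.
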