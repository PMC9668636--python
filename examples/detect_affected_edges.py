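"""Detect planted disease-affected connections with edgewise permutation stats.

A single-site cohort (40 controls, 40 patients) carries 20 planted edges with
reduced FA in patients.  Edgewise age/sex-adjusted t-tests with permutation
FDR, gated on Cohen's d > 0.8 and the 15%-density mask, recover the planted
signature.
"""

import numpy as np

import netharm as nh
from netharm.connectome import binarize, group_probability
from netharm.edgestats import edge_data_from_matrices, permutation_fdr, stage_detections
from netharm.evaluation import ReferenceEdgeSet, score_precision
from netharm.thresholding import ThresholdConfig, density_threshold

truth = nh.default_truth(n_nodes=40, n_core=120, n_affected=20, spurious_edge_rate=30.0)
site = nh.SiteSpec(site_id="demo", n_controls=40, n_patients=40, seed=5)
subjects = nh.generate_cohort(site, truth, seed=5)

binaries = [binarize(s.count_matrix) for s in subjects]
data = edge_data_from_matrices(
    [s.fa_matrix for s in subjects],
    binaries,
    np.array([s.is_control for s in subjects]),
    np.array([s.age for s in subjects]),
    np.array([float(s.sex) for s in subjects]),
)
results = permutation_fdr(data, n_perm=1000, seed=5)
mask = density_threshold(group_probability(binaries), ThresholdConfig(density=0.15))
det = stage_detections(results, mask)

print(f"edges tested: {int(results.table['testable'].sum())}")
print(f"large effect (d > 0.8): {len(det.large_effect)}")
print(f"... surviving thresholding: {len(det.surviving_threshold)}")
print(f"... surviving thresholding + FDR: {len(det.surviving_fdr)}")

planted = ReferenceEdgeSet(edges=set(truth.affected_edges), provenance="planted truth")
res = score_precision(det.surviving_fdr, planted)
print(f"against the 20 planted edges: TP={res.TP}, FP={res.FP}, precision={res.formatted()}")
# thresholding strips the spurious large-d edges (low subject counts inflate
# d); what survives FDR is almost exactly the planted signature
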