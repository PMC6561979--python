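"""Filter a feature panel by test-retest repeatability and redundancy.

Builds a parametric feature table with known structure (planted effects,
deliberately non-repeatable features, near-duplicate blocks) and shows the
CCC >= 0.7 filter and the R^2 >= 0.95 redundancy collapse at work.
"""

from pulmorad import generate_feature_table_direct, qc_pipeline

test, retest, y = generate_feature_table_direct(
    n0=150, n1=150, p_noise=20,
    planted=[(1.0, 2)],
    redundancy_blocks=[(3, 0.99), (2, 0.99)],
    retest_ccc_targets={f"noise_{i:03d}": 0.2 for i in range(5)},
    seed=11)

report, grouping, reduced, counts = qc_pipeline(test, retest)
print("feature-count waterfall:", counts)
print("failed repeatability:",
      sorted(report.passed.index[~report.passed]))
print("redundancy groups of size > 1:",
      [g for g in grouping.groups if len(g) > 1])
# The five features rendered with CCC ~0.2 fail the 0.7 threshold; each
# near-duplicate block collapses to its highest-dynamic-range member, so
# the final count is initial - failed - (block sizes - 1).
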