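"""Decision-curve analysis: net benefit of a radiomic model vs baselines.

Calibrates discriminant scores to risks and compares the clinical net
benefit of a strong model against a weak size-like comparator across
threshold probabilities 1-60%.
"""

import numpy as np

from pulmorad import (calibrate_scores, decision_curve,
                      fit_linear_discriminant, generate_feature_table_direct)

table, _, y = generate_feature_table_direct(
    n0=150, n1=150, p_noise=0, planted=[(1.5, 2), (0.3, 1)], seed=9)

strong = fit_linear_discriminant(
    table[["planted_000", "planted_001"]].to_numpy(), y)
weak = fit_linear_discriminant(table[["planted_002"]].to_numpy(), y)
risks = {
    "radiomic": calibrate_scores(
        table[["planted_000", "planted_001"]].to_numpy() @ strong.weights, y),
    "size_like": calibrate_scores(
        table[["planted_002"]].to_numpy() @ weak.weights, y),
}
curve = decision_curve(risks, y)
frame = curve.frame()
print(frame[frame["threshold"].isin([0.1, 0.2, 0.4])].round(3).to_string(
    index=False))
print(f"radiomic model first beats all comparators at "
      f"p_t = {curve.crossing_threshold}")
# Net benefit is in true-positive units per patient: at each threshold
# the radiomic curve above treat-all/treat-none means acting on the model
# finds more cancers per avoidable work-up than either blanket policy.
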