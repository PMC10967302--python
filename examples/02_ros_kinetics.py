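"""Normalize one DCF fluorescence time course to the ROS % scale.

Walks the four-step chain for a single treated well: background
correction against cell-free blanks, start-value normalization, AUC by
the trapezoid rule over the actual read times, and the two-anchor
rescaling (AAPH stress control = 100%, untreated control = 0%).
"""

import numpy as np

from phytoscreen import auc_normalized, background_correct, normalize_two_anchor

times = np.array([0.0, 15.0, 30.0, 60.0, 90.0])  # minutes
raw = np.array([1052.0, 1388.0, 1743.0, 2459.0, 3172.0])  # treated well, RFU
blank = np.array([51.0, 50.0, 52.0, 50.0, 49.0])  # cell-free blank mean, RFU

corrected = background_correct(times, raw, blank)
f_rel, auc = auc_normalized(times, corrected)
print("relative trace:", np.round(f_rel, 3))
print(f"AUC over 0-90 min: {auc:.1f} (dimensionless x min)")

# plate anchors: mean AUCs of the untreated and AAPH stress control wells
auc_untreated, auc_stress = 110.3, 271.8
ros_pct = normalize_two_anchor(auc, auc_untreated, auc_stress)
print(f"normalized ROS level: {ros_pct:.1f} %")

# 0% would mean the well rose no faster than untreated cells and 100%
# means the full AAPH stress response; this well sits in between, i.e.
# the treatment suppressed part of the stress-induced ROS increase.
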