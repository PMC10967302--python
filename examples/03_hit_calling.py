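"""Dunnett hit calling and selectivity classification on one plate family.

Compares each extract's replicate ROS percents against the stress
control with Dunnett's many-to-one test (family-wise error controlled
across the plate), then combines ROS and NO endpoints into a
selectivity class.
"""

from phytoscreen import call_hits, classify_selectivity, dunnett_test

# replicate normalized ROS percents; the stress control scatters around 100
stress_control = [97.4, 103.1, 99.5]
extracts_ros = {
    "EXT0001": [38.2, 41.0, 37.9],   # strong reduction
    "EXT0002": [91.5, 95.2, 93.8],   # weak reduction
    "EXT0003": [101.2, 98.8, 102.5], # inactive
}

p_ros = dunnett_test(stress_control, extracts_ros)
means_ros = {k: sum(v) / len(v) for k, v in extracts_ros.items()}
ros_calls = call_hits(means_ros, p_ros, endpoint="ros", alpha=0.05)
for sid, call in ros_calls.items():
    print(
        f"{sid}: ros {call.mean_pct:6.1f}%  p_adj={call.p_adj:.4f}  "
        f"{call.direction:8s}  >=30% reduction: {call.reduction30}"
    )

# pair with NO results (computed the same way on the RAW264.7 plates)
no_means = {"EXT0001": 35.0, "EXT0002": 95.0, "EXT0003": 99.0}
no_calls = call_hits(no_means, {"EXT0001": 0.0001, "EXT0002": 0.2, "EXT0003": 0.7}, "no")
for sid in extracts_ros:
    cls = classify_selectivity(
        sid, no_means[sid], means_ros[sid], no_calls[sid], ros_calls[sid]
    )
    print(f"{sid}: selectivity = {cls.selectivity}")

# EXT0001 suppresses both endpoints below 60% -> dual. EXT0002 shows how
# literal the rules are: its ROS dip to 93.5% is statistically
# significant (tight replicates) and its NO stays above 90%, so the rule
# set labels it ROS-selective despite the tiny effect size — significance
# and effect size are deliberately separate flags. EXT0003 is
# indistinguishable from the stress control.
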