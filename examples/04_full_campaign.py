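"""Simulate a small screening campaign and run the full pipeline on it.

Generates raw plate files (TPC, FRAP, DCF ROS, Griess NO, viability x2)
for an 84-extract library with known ground truth, then runs
calibrate -> normalize -> gate -> call -> classify -> correlate and
prints the campaign report.
"""

import tempfile

from phytoscreen import RunConfig, SimConfig, run_screen, simulate_campaign

with tempfile.TemporaryDirectory() as tmp:
    config = SimConfig(n_extracts=84, seed=42)
    truth, manifest = simulate_campaign(config, tmp)
    screen = run_screen(RunConfig.from_manifest(manifest))

rep = screen.report
print(f"extracts screened: {rep['n_extracts']}")
for endpoint in ("ros", "no"):
    e = rep[endpoint]
    print(
        f"{endpoint:3s}: {e['n_significant_decrease']:3d} significant decreases, "
        f"{e['n_reduction30']:2d} with >=30% reduction, "
        f"{e['n_excluded_cytotoxic']} excluded as cytotoxic"
    )
print("selectivity classes:", dict(sorted(rep["selectivity_counts"].items())))
print(f"quercetin positive control: ROS {rep['positive_control_ros']['mean_pct']:.1f}%, "
      f"NO {rep['positive_control_no']['mean_pct']:.1f}%")
for name, c in rep["correlations"].items():
    print(f"spearman {name:9s} r_s = {c['r_s']:+.3f}  (n = {c['n']})")

# The TPC-FRAP rank correlation is strong (the generator targets 0.857),
# phenolic-rich extracts tend to suppress both cellular endpoints
# (negative TPC-ROS / TPC-NO correlations), and the quercetin wells
# recover the configured positive-control levels (3.6% ROS, 66.5% NO).
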