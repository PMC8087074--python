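"""Choose the SW/CT weighting ratio by fitting annotation similarity.

Builds a pair table whose annotation Jaccard similarity (JS) was planted to
follow the logarithm of the equal-weight blend of normalized SW and CT, then
scans the nine-point weighting-ratio grid.  The logarithmic-model R-squared
should peak at rho = 1 and slope down toward both ends of the grid, and the
integrated score should beat raw SW at explaining the annotations.
"""

import numpy as np
import pandas as pd

from imcc import annotations_matching_js, compare_integrations, scan_rho

rng = np.random.default_rng(7)
n = 24
pairs = [(f"A{i:02d}", f"B{i:02d}") for i in range(n)]
sw = rng.uniform(0.02, 1, n)
ct = rng.uniform(0.02, 1, n)
blend = 0.5 * sw + 0.5 * ct
js_target = np.log(blend)
js_target = (js_target - js_target.min() + 0.05) / (js_target.max() - js_target.min() + 0.1)

table = pd.DataFrame(
    {
        "module_a": [a for a, _ in pairs],
        "module_b": [b for _, b in pairs],
        "sw": sw,
        "ct": ct,
        "sw_norm": sw,
        "ct_norm": ct,
        "sw_valid": True,
        "ct_valid": True,
        "ps_valid": False,
        "imcc2": np.nan,
    }
)
annotations = annotations_matching_js(pairs, js_target, union_size=200)

best_rho, profile = scan_rho(table, annotations)
print("R-squared of the logarithmic JS fit per weighting ratio:")
for _, row in profile.iterrows():
    marker = "  <- best" if row["rho"] == best_rho else ""
    print(f"  rho = {row['rho']:<6g} R2 = {row['r_squared']:.4f}{marker}")

report = compare_integrations(table, annotations, best_rho=best_rho)
print("\nintegration-scheme comparison (same model, same outlier rule):")
for name, r2 in report["r_squared"].items():
    print(f"  {name:6s} R2 = {r2:.4f}" if r2 is not None else f"  {name}: unavailable")
print(f"winner: {report['winner']}")
print(
    "\nThe peak at rho = 1 recovers the planted equal contribution of direct"
    "\n(SW) and shared-partner (CT) connectivity to functional similarity."
)
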