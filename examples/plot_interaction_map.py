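"""Render a linear interaction diagram from an interaction_map.json file.

Residues of the two chains are drawn as two rows of boxes; each map entry
becomes an arc whose line width scales linearly with persistence (10% of
simulation time thinnest, 98% thickest).  Intramolecular interactions are
green, intermolecular magenta.

Usage: python examples/plot_interaction_map.py MAP_JSON [OUT_PNG]
"""

import json
import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import FancyArrowPatch

map_path = sys.argv[1] if len(sys.argv) > 1 else "interaction_map.json"
out_path = sys.argv[2] if len(sys.argv) > 2 else "interaction_map.png"

with open(map_path) as fh:
    doc = json.load(fh)

chains = sorted({e["chain_a"] for e in doc["entries"]}
                | {e["chain_b"] for e in doc["entries"]}) or ["A", "B"]
rows = {c: i for i, c in enumerate(chains)}
n_res = max(
    [e["res_a"] for e in doc["entries"]] + [e["res_b"] for e in doc["entries"]] + [12]
)

fig, ax = plt.subplots(figsize=(10, 4))
for chain, row in rows.items():
    y = -3.0 * row
    for r in range(1, n_res + 1):
        ax.add_patch(plt.Rectangle((r - 0.4, y - 0.3), 0.8, 0.6,
                                   fill=False, lw=0.8))
        ax.text(r, y, str(r), ha="center", va="center", fontsize=7)
    ax.text(0.2, y, chain, ha="right", va="center", fontsize=10)

for e in doc["entries"]:
    y_a, y_b = -3.0 * rows[e["chain_a"]], -3.0 * rows[e["chain_b"]]
    width = 0.5 + 4.0 * e["line_width"]
    color = "magenta" if e["chain_a"] != e["chain_b"] else "green"
    if e["chain_a"] == e["chain_b"]:
        rad = 0.4 if y_a > -1 else -0.4
        arc = FancyArrowPatch((e["res_a"], y_a + (0.3 if rad > 0 else -0.3)),
                              (e["res_b"], y_b + (0.3 if rad > 0 else -0.3)),
                              connectionstyle=f"arc3,rad={rad}",
                              arrowstyle="-", lw=width, color=color, alpha=0.7)
    else:
        arc = FancyArrowPatch((e["res_a"], y_a - 0.3), (e["res_b"], y_b + 0.3),
                              arrowstyle="-", lw=width, color=color, alpha=0.7)
    ax.add_patch(arc)

ax.set_xlim(-0.5, n_res + 0.5)
ax.set_ylim(-3.0 * (len(chains) - 1) - 2, 2)
ax.axis("off")
ax.set_title(
    f"Interaction persistence map (threshold {doc['threshold']:.0%}, "
    f"{doc['n_frames']} frames)"
)
fig.savefig(out_path, dpi=150, bbox_inches="tight")
print(f"wrote {out_path}")
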