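"""Call 3' UTR termination sites from strand asymmetry and classify usage.

Plants three usage patterns — one shared end, per-cell scattered ends, and
a cell-type-specific short/long isoform switch — in synthetic read-start
tracks, calls candidate ends from the smoothed antisense-sense
differential, and classifies each gene from its cross-cell coherence
fractions.
"""

import numpy as np

import scvarcal as sv

spec = sv.SyntheticSpec(seed=29)
gene_ids = ["shared", "scattered", "switch"]
layout = sv.make_gene_layout(gene_ids)
ends = dict(zip(layout.gene_id, layout.annotated_end))
cells = [f"{t}_c{i+1:02d}" for t in ("typeA", "typeB") for i in range(8)]

rng = np.random.default_rng(0)
planted = {
    "shared": {"typeA": [int(ends["shared"])], "typeB": [int(ends["shared"])]},
    "scattered": {},
    "switch": {"typeA": [int(ends["switch"]) - 600],
               "typeB": [int(ends["switch"]) + 300]},
}
slots = np.arange(-960, 760, 240)
per_cell = {"scattered": {
    c: [int(ends["scattered"]) + int(slots[k]) + int(rng.integers(-15, 16))]
    for c, k in zip(cells, rng.permutation(len(slots))[:8].tolist() * 2)}}

data = sv.simulate_read_starts(spec, layout, planted, per_cell_ends=per_cell)
cmap = dict(zip(data.cells.cell_id, data.cells.cell_type))

track = data.tracks[("shared", cells[0])]
called = sv.call_track_ends(track, int(ends["shared"]))
print(f"gene 'shared', cell {cells[0]}: candidate end(s) at {called} "
      f"(planted at {int(ends['shared'])})")

a_ends = sv.call_track_ends(data.tracks[("switch", cells[0])],
                            int(ends["switch"]))
b_ends = sv.call_track_ends(data.tracks[("switch", cells[8])],
                            int(ends["switch"]))
d = sv.pairwise_overlap(a_ends, b_ends)
print(f"gene 'switch': typeA cell ends {a_ends} vs typeB cell ends "
      f"{b_ends}, overlap d(A,B) = {d}")

for g in gene_ids:
    tracks = {c: data.tracks[(g, c)] for c in cells}
    profile = sv.end_profile(g, tracks, cmap, int(ends[g]))
    label = sv.classify_utr_gene(profile)
    fr = profile.fractions.round(2)
    print(f"gene {g!r}: class = {label}; coherence fractions:")
    print(fr.to_string())
print("an end with fraction >= 0.8 in every type is shared usage; all "
      "fractions < 0.6 is cell-to-cell variable usage; coherent in one "
      "type but not another is cell-type-specific.")
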