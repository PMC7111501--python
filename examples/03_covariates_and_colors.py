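"""Covariate bars: parsing, classification, default coloring.

Parses a discrete (tumor stage) and a continuous (age) covariate file
against a matrix's sample labels, assigns default colors from the
colorblind-safe palette, and shows the value->color mapping the heat
map will use.
"""

import tempfile

from chmforge import default_colors, map_color, parse_covariate
from chmforge.fixtures import covariate_file

labels = [f"sample_{i}" for i in range(1, 9)]

with tempfile.TemporaryDirectory() as tmp:
    stage_path = covariate_file(f"{tmp}/stage.txt", labels, kind="discrete",
                                categories=("I", "II", "III"), seed=3)
    age_path = covariate_file(f"{tmp}/age.txt", labels[:-1], kind="continuous",
                              value_range=(40, 80), seed=4)

    stage = default_colors(parse_covariate(stage_path, "col", "discrete", labels))
    age = default_colors(parse_covariate(age_path, "col", "continuous", labels))

print("stage categories ->", {c: stage.colors[c] for c in stage.categories()})
print("missing samples drawn in", stage.colors["missing"])

print(f"age colormap spans {age.colors.breakpoints[0]:.1f}..{age.colors.breakpoints[1]:.1f}")
for lab in labels:
    v = age.values[lab]
    print(f"  {lab}: {v if v == v else 'missing':>8} -> {map_color(age.colors, v)}")
# sample_8 has no entry in the age file, so it renders in the missing color.
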