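"""A complete build: transforms, clustering, covariates, formatting,
then the .ngchm archive, the 3-page PDF and the creation log.
"""

import tempfile
import zipfile

from chmforge import Builder, OrderSpec, build_raster
from chmforge.fixtures import covariate_file, expression_matrix

with tempfile.TemporaryDirectory() as tmp:
    fx = expression_matrix(n_rows=300, n_cols=40, duplicate_col_labels=1, seed=5)
    matrix_path = fx.write(f"{tmp}/expression.txt")
    stage_path = covariate_file(f"{tmp}/stage.txt", fx.col_labels, kind="discrete",
                                categories=("I", "II", "III"), seed=6)

    b = Builder(name="Demo map", description="expression demo")
    b.import_matrix(matrix_path)
    b.transform("dedupe", axis="col", mode="rename")
    b.transform("threshold_na", cutoff=0.00001)
    b.transform("log", base=10)
    b.transform("mean_center_row")
    b.transform("filter_sd_row", keep_n=100)
    b.set_order("row", OrderSpec(mode="cluster", linkage="ward", distance="euclidean"))
    b.set_order("col", OrderSpec(mode="cluster", linkage="average", distance="correlation"))
    b.add_top_branch_covariate("col", 3)
    b.add_covariate(stage_path, "col", "discrete", name="stage")
    b.set_format(row_label_type="gene symbol", col_label_type="sample id",
                 col_gaps=[10], top_items=[b.session.working.row_labels[0]])

    paths = b.write(f"{tmp}/out")
    build = b.build()

    print("outputs:", {k: p.split("/")[-1] for k, p in paths.items()})
    print("archive members:", zipfile.ZipFile(paths["ngchm"]).namelist())

raster = build_raster(build)
print(f"raster: {raster.shape[0]} x {raster.shape[1]} display cells "
      f"(matrix {build.matrix.n_rows} x {build.matrix.n_cols} + gap strips)")
print(f"creation log: {len(build.log.events)} events; "
      f"colormap breakpoints {['%.2f' % x for x in build.spec.colormap.breakpoints]}")
# The breakpoints default to the 5th/50th/95th percentiles of the working
# matrix under a blue-white-red scale; the PDF's last page shows legends.
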