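import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chmforge import Builder, LabeledMatrix, OrderSpec
from chmforge.fixtures import covariate_file, expression_matrix

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_matrix() -> LabeledMatrix:
    return LabeledMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [5.0, np.nan, 7.0, 9.0],
                [0.5, 0.5, 0.5, 0.5],
            ]
        ),
    )


def random_labeled_matrix(rng: np.random.Generator, n_rows=8, n_cols=6, missing_frac=0.0):
    values = rng.normal(size=(n_rows, n_cols))
    if missing_frac:
        values[rng.random(values.shape) < missing_frac] = np.nan
    return LabeledMatrix(
        [f"r{i}" for i in range(n_rows)],
        [f"c{j}" for j in range(n_cols)],
        values,
    )


def make_full_builder(tmp_path, seed: int = 0, random_col_order: bool = False) -> Builder:
    """A complete builder over a small generated matrix: transforms,
    clustering on both axes (or a seeded random column order), two
    covariates, a top-branch covariate and formatting options."""
    fx = expression_matrix(
        n_rows=60, n_cols=24, duplicate_col_labels=1, missing_frac=0.02,
        invalid_frac=0.01, seed=seed,
    )
    mat = fx.write(str(tmp_path / f"input_{seed}.txt"))
    age = covariate_file(
        str(tmp_path / f"age_{seed}.txt"), fx.col_labels, kind="continuous", seed=seed + 1
    )
    stage = covariate_file(
        str(tmp_path / f"stage_{seed}.txt"),
        fx.col_labels,
        kind="discrete",
        categories=("I", "II", "III"),
        seed=seed + 2,
    )
    b = Builder(name=f"Build {seed}", description="generated")
    b.import_matrix(mat)
    b.transform("dedupe", axis="col", mode="rename")
    b.transform("threshold_na", cutoff=0.00001)
    b.transform("log", base=10)
    b.transform("mean_center_row")
    b.set_order("row", OrderSpec(mode="cluster", linkage="ward", distance="euclidean"))
    if random_col_order:
        b.set_order("col", OrderSpec(mode="random", seed=seed + 100))
    else:
        b.set_order("col", OrderSpec(mode="cluster", linkage="average", distance="correlation"))
        b.add_top_branch_covariate("col", 3)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        b.add_covariate(age, "col", "continuous", name="age")
        b.add_covariate(stage, "col", "discrete", name="stage")
    b.set_format(
        row_label_type="gene symbol",
        col_label_type="sample id",
        col_gaps=[5, 11],
        top_items=[b.session.working.row_labels[0], "not-a-label"],
    )
    return b
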