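"""Import a matrix and run the classic six-step cleanup recipe.

Generates an expression-like 2000x100 matrix (log-normal values, a few
duplicate sample labels, injected missing/invalid cells), parses it,
and applies: dedupe column labels, threshold tiny values to missing,
log10, mean-center rows, drop rows over 50% missing, keep the 500
highest-SD rows.
"""

import tempfile

from chmforge import MatrixSession, TransformStep, parse_matrix, summarize
from chmforge.fixtures import expression_matrix, use_case_steps

with tempfile.TemporaryDirectory() as tmp:
    fx = expression_matrix(n_rows=2000, n_cols=100, duplicate_col_labels=2, seed=1)
    m = parse_matrix(fx.write(f"{tmp}/expression.txt"))

stats = summarize(m)
print(f"imported: {stats.n_rows} rows x {stats.n_cols} cols, "
      f"{stats.n_missing} missing, {stats.n_invalid} invalid cells")
for flag in stats.flags:
    print(f"  flag: {flag}")

session = MatrixSession(original=m)
for action, params in use_case_steps():
    session.apply_step(TransformStep(action, params))
    print(f"after {action:<18} -> {session.working.n_rows} x {session.working.n_cols}")

# Undo works by replaying a history prefix against the preserved original:
session.undo_to(3)
print(f"undo to step 3        -> {session.working.n_rows} x {session.working.n_cols} "
      f"(history now {len(session.history)} steps)")

# The final working matrix after the full recipe has exactly 500 rows: the
# survivors of the missing-data filter, ranked by standard deviation.
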