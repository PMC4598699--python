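"""CSV readers/writers for datasets and fitted models.

Tables travel as plain CSV with the column names produced by the scheme
builders (no index column).  A fitted model is stored as a CSV of labeled
coefficients preceded by ``#key=value`` header lines carrying the spec and
the class levels seen in training, so a reloaded model predicts exactly
like the in-memory one.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .modelfit import FittedModel, ModelSpec, Term, _Column

__all__ = ["write_table", "read_table", "save_model", "load_model"]


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    # round_trip parsing keeps write->read->write byte-identical
    return pd.read_csv(path, float_precision="round_trip")


def save_model(fm: FittedModel, path) -> Path:
    """Serialize a fitted model: spec headers plus a coefficient table."""
    if fm.spec is None:
        raise ValueError("model has no spec attached; fit via fit(records, spec)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spec = fm.spec
    head = {
        "trait": spec.trait,
        "session": spec.session,
        "terms": [{"covariates": list(t.covariates), "classes": list(t.classes)}
                  for t in spec.terms],
        "class_levels": {k: sorted(int(v) for v in vs)
                         for k, vs in fm.class_levels.items()},
        "n": fm.n,
        "p": fm.p,
        "sse": fm.sse,
        "dropped": fm.dropped,
    }
    rows = []
    for col, beta in zip(fm.columns, fm.coefficients):
        rows.append({
            "term_index": col.term_index,
            "cell": "" if col.cell is None else "|".join(str(v) for v in col.cell),
            "label": col.label,
            "coefficient": repr(float(beta)),
        })
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(head) + "\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
    return path


def load_model(path) -> FittedModel:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path} is not a saved model (missing header line)")
        head = json.loads(first[1:])
        table = pd.read_csv(fh, dtype={"cell": str}, keep_default_na=False)
    spec = ModelSpec(
        trait=head["trait"],
        session=head["session"],
        terms=tuple(
            Term(covariates=tuple(t["covariates"]), classes=tuple(t["classes"]))
            for t in head["terms"]
        ),
    )
    columns, coefs = [], []
    for _, row in table.iterrows():
        cell = (None if row["cell"] == ""
                else tuple(int(v) for v in row["cell"].split("|")))
        columns.append(_Column(int(row["term_index"]), cell, row["label"]))
        coefs.append(float(row["coefficient"]))
    return FittedModel(
        spec=spec,
        columns=columns,
        coefficients=np.asarray(coefs, dtype=float),
        dropped=list(head.get("dropped", [])),
        n=int(head["n"]),
        p=int(head["p"]),
        sse=float(head["sse"]),
        class_levels={k: set(vs) for k, vs in head["class_levels"].items()},
    )
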