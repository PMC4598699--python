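"""Class-nested regression models for daily-yield prediction.

The prediction equations regress a trait's daily yield on information from
a single milking.  Model terms are products of continuous covariates
(session milk yield ``milk``, session trait content ``q``) *nested in*
crosses of class factors (30-day days-in-milk classes, parity class,
calendar month).  A term like ``q x milk x DIM`` therefore estimates a
separate regression coefficient of ``q*milk`` inside every DIM class —
the classic way milk-recording factors accommodate heterogeneous means
and variances across lactation stage, parity and season.

Fitting is plain least squares with reference-cell handling of aliasing:
columns are screened in construction order and any column linearly
dependent on the ones already kept is dropped, so refits are reproducible
and the dropped reference cells are deterministic.

``stepwise_select`` performs forward selection from a candidate term pool.
Each step adds the term that most reduces the root-mean-square error of
daily-yield prediction on a held-out TEST dataset; a second held-out VAL
dataset is never consulted during selection and only appears in the final
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Term", "ModelSpec", "FittedModel",
    "dim_class", "build_design", "fit_model", "fit",
    "predict_daily", "stepwise_select", "default_candidate_pool",
    "response_column",
]

COVARIATES = ("q", "milk")
CLASS_FACTORS = ("dim", "parity", "month")

#: rank tolerance of the aliasing screen (relative to column norm)
_RANK_TOL = 1e-8

N_DIM_CLASSES = 11


def dim_class(dim) -> np.ndarray:
    """30-day days-in-milk classes: 1..10 up to DIM 300, 11 beyond."""
    d = np.asarray(dim, dtype=int)
    if (d < 1).any():
        raise ValueError("DIM must be >= 1")
    return np.minimum((d - 1) // 30, N_DIM_CLASSES - 1) + 1


def _parity_class(parity) -> np.ndarray:
    p = np.asarray(parity, dtype=int)
    if (p < 1).any():
        raise ValueError("parity must be >= 1")
    return np.minimum(p, 3)


@dataclass(frozen=True)
class Term:
    """One model term: a covariate product nested in a class cross.

    ``covariates`` is a subset of ``("q", "milk")`` (``q`` = session
    content of the modelled trait); ``classes`` a subset of
    ``("dim", "parity", "month")``.  Both empty is the intercept, which is
    handled separately and not expressed as a Term.
    """

    covariates: tuple[str, ...] = ()
    classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.covariates and not self.classes:
            raise ValueError("a term needs at least one covariate or class factor")
        for c in self.covariates:
            if c not in COVARIATES:
                raise KeyError(f"unknown covariate {c!r}; expected one of {COVARIATES}")
        for c in self.classes:
            if c not in CLASS_FACTORS:
                raise KeyError(f"unknown class factor {c!r}; expected one of {CLASS_FACTORS}")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariate in term")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class factor in term")
        # canonical order makes Term hashing/equality order-insensitive
        object.__setattr__(
            self, "covariates",
            tuple(sorted(self.covariates, key=COVARIATES.index)),
        )
        object.__setattr__(
            self, "classes",
            tuple(sorted(self.classes, key=CLASS_FACTORS.index)),
        )

    def label(self, trait: str, session: str) -> str:
        parts = []
        for c in self.covariates:
            if c == "q":
                parts.append(f"q{trait.upper()}_{session.upper()}")
            else:
                parts.append(f"milk_{session.upper()}")
        for c in self.classes:
            parts.append({"dim": "DIM", "parity": "parity", "month": "month of test"}[c])
        return " x ".join(parts)


@dataclass(frozen=True)
class ModelSpec:
    """A response (trait daily yield), a milking session, and model terms."""

    trait: str
    session: str
    terms: tuple[Term, ...] = ()

    def __post_init__(self) -> None:
        if self.session not in ("am", "pm"):
            raise ValueError(f"session must be 'am' or 'pm', got {self.session!r}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in model spec")
        object.__setattr__(self, "terms", tuple(self.terms))

    def with_term(self, term: Term) -> "ModelSpec":
        return ModelSpec(self.trait, self.session, self.terms + (term,))


@dataclass(frozen=True)
class _Column:
    """Structural description of one design column (for refitting/prediction)."""

    term_index: int  # -1 = intercept
    cell: tuple | None  # class-level tuple in the term's class order
    label: str


def response_column(trait: str) -> str:
    return "milk_daily" if trait == "milk" else f"yield_daily_{trait}"


def _covariate_values(records: pd.DataFrame, name: str, trait: str, session: str):
    if name == "milk":
        col = f"milk_{session}"
    elif name == "q":
        col = f"content_{session}_{trait}"
    else:
        raise KeyError(f"unknown covariate {name!r}")
    if col not in records.columns:
        raise KeyError(f"records lack required column {col!r}")
    return records[col].to_numpy(dtype=float)


def _class_values(records: pd.DataFrame, name: str) -> np.ndarray:
    if name == "dim":
        return dim_class(records["dim"])
    if name == "parity":
        return _parity_class(records["parity"])
    if name == "month":
        m = records["month"].to_numpy(dtype=int)
        if ((m < 1) | (m > 12)).any():
            raise ValueError("month must lie in 1..12")
        return m
    raise KeyError(f"unknown class factor {name!r}")


def build_design(
    records: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[_Column]]:
    """Design matrix for a spec: intercept first, then one block per term.

    Within a term with class factors, one column is emitted per occupied
    subclass cell (sorted by cell value), equal to the covariate product
    inside the cell and zero outside; empty cells produce no column.  A
    purely continuous term yields a single column; a purely categorical
    term yields indicator columns.  No aliasing is resolved here — that is
    ``fit_model``'s job.
    """
    n = len(records)
    cols: list[np.ndarray] = [np.ones(n)]
    info: list[_Column] = [_Column(-1, None, "intercept")]
    for ti, term in enumerate(spec.terms):
        v = np.ones(n)
        for cov in term.covariates:
            v = v * _covariate_values(records, cov, spec.trait, spec.session)
        base = term.label(spec.trait, spec.session)
        if not term.classes:
            cols.append(v)
            info.append(_Column(ti, None, base))
            continue
        class_vals = np.column_stack(
            [_class_values(records, c) for c in term.classes]
        )
        cells = sorted({tuple(row) for row in class_vals.tolist()})
        for cell in cells:
            mask = (class_vals == np.array(cell)).all(axis=1)
            cols.append(np.where(mask, v, 0.0))
            cell_lab = ",".join(
                f"{c}={lv}" for c, lv in zip(term.classes, cell)
            )
            info.append(_Column(ti, tuple(cell), f"{base}[{cell_lab}]"))
    return np.column_stack(cols), info


def _independent_columns(X: np.ndarray, tol: float = _RANK_TOL) -> list[int]:
    """Greedy first-come screen: keep columns that extend the column span."""
    n, p = X.shape
    Q = np.empty((n, min(n, p)))
    k = 0
    keep: list[int] = []
    for j in range(p):
        c = X[:, j]
        nc = np.linalg.norm(c)
        if nc == 0:
            continue
        r = c - Q[:, :k] @ (Q[:, :k].T @ c)
        r = r - Q[:, :k] @ (Q[:, :k].T @ r)  # reorthogonalize for stability
        nr = np.linalg.norm(r)
        if nr > tol * nc:
            keep.append(j)
            Q[:, k] = r / nr
            k += 1
            if k == Q.shape[1]:
                break
    return keep


@dataclass
class FittedModel:
    """A least-squares fit: kept columns, their coefficients, bookkeeping."""

    spec: ModelSpec
    columns: list[_Column]
    coefficients: np.ndarray
    dropped: list[str]
    n: int
    p: int
    sse: float
    #: class levels observed in training, per class factor used by the spec
    class_levels: dict[str, set] = field(default_factory=dict)

    @property
    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"column": [c.label for c in self.columns],
             "coefficient": self.coefficients}
        )


def fit_model(
    design: np.ndarray,
    response: np.ndarray,
    info: list[_Column] | None = None,
) -> FittedModel:
    """Least squares on a design matrix with deterministic aliasing.

    Columns linearly dependent on earlier columns are dropped (first-come
    kept), then coefficients solve the reduced system.  ``p`` counts kept
    columns, including the intercept.
    """
    y = np.asarray(response, dtype=float)
    if design.shape[0] == 0:
        raise ValueError("no usable rows")
    if design.shape[0] != len(y):
        raise ValueError("design and response length mismatch")
    if info is None:
        info = [_Column(i, None, f"x{i}") for i in range(design.shape[1])]
    keep = _independent_columns(design)
    if design.shape[0] < len(keep):
        raise ValueError(
            f"more parameters ({len(keep)}) than rows ({design.shape[0]})"
        )
    Xk = design[:, keep]
    coef, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ coef
    dropped = [info[j].label for j in range(design.shape[1]) if j not in set(keep)]
    return FittedModel(
        spec=None,  # filled by the records-level entry point
        columns=[info[j] for j in keep],
        coefficients=coef,
        dropped=dropped,
        n=design.shape[0],
        p=len(keep),
        sse=float(resid @ resid),
    )


def fit(records: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Build the design for ``spec`` on ``records`` and fit it."""
    y = records[response_column(spec.trait)].to_numpy(dtype=float)
    X, info = build_design(records, spec)
    fm = fit_model(X, y, info)
    fm.spec = spec
    used = {c for t in spec.terms for c in t.classes}
    fm.class_levels = {
        c: set(np.unique(_class_values(records, c)).tolist()) for c in used
    }
    return fm


def predict_daily(fitted: FittedModel, records: pd.DataFrame) -> np.ndarray:
    """Evaluate the fitted linear predictor on single-milking records.

    Records must carry the session milk and content columns of the fitted
    spec.  A class level never seen in training raises (no silent
    extrapolation); a level combination whose cell was empty in training
    contributes nothing, as in training.
    """
    spec = fitted.spec
    if spec is None:
        raise ValueError("fitted model lacks a spec; fit via fit(records, spec)")
    for cname, seen in fitted.class_levels.items():
        new_levels = set(np.unique(_class_values(records, cname)).tolist())
        unseen = new_levels - seen
        if unseen:
            raise ValueError(
                f"class factor {cname!r} has level(s) {sorted(unseen)} "
                "not present in the training data"
            )
    n = len(records)
    pred = np.zeros(n)
    # cache covariate products and class values per term
    term_cov: dict[int, np.ndarray] = {}
    term_cls: dict[int, np.ndarray] = {}
    for col, beta in zip(fitted.columns, fitted.coefficients):
        if col.term_index == -1:
            pred += beta
            continue
        term = spec.terms[col.term_index]
        if col.term_index not in term_cov:
            v = np.ones(n)
            for cov in term.covariates:
                v = v * _covariate_values(records, cov, spec.trait, spec.session)
            term_cov[col.term_index] = v
            if term.classes:
                term_cls[col.term_index] = np.column_stack(
                    [_class_values(records, c) for c in term.classes]
                )
        v = term_cov[col.term_index]
        if col.cell is None:
            pred += beta * v
        else:
            mask = (term_cls[col.term_index] == np.array(col.cell)).all(axis=1)
            pred += beta * np.where(mask, v, 0.0)
    return pred


def default_candidate_pool(preset_terms: tuple[Term, ...] = ()) -> tuple[Term, ...]:
    """All single-factor and two-way terms, plus any supplied preset terms."""
    base = [
        Term(covariates=("milk",)),
        Term(covariates=("q",)),
        Term(classes=("dim",)),
        Term(classes=("parity",)),
        Term(classes=("month",)),
    ]
    pool: list[Term] = list(base)
    # two-way combinations of the five base factors
    factors = [("cov", "milk"), ("cov", "q"),
               ("cls", "dim"), ("cls", "parity"), ("cls", "month")]
    for i in range(len(factors)):
        for j in range(i + 1, len(factors)):
            covs = tuple(n for k, n in (factors[i], factors[j]) if k == "cov")
            clss = tuple(n for k, n in (factors[i], factors[j]) if k == "cls")
            pool.append(Term(covariates=covs, classes=clss))
    for t in preset_terms:
        if t not in pool:
            pool.append(t)
    seen: list[Term] = []
    for t in pool:
        if t not in seen:
            seen.append(t)
    return tuple(seen)


def stepwise_select(
    candidates,
    calib: pd.DataFrame,
    test: pd.DataFrame,
    val: pd.DataFrame,
    trait: str,
    session: str,
    rel_tol: float = 1e-3,
):
    """Forward stepwise selection on TEST-set RMSE.

    Starting from the intercept-only model, each step fits every remaining
    candidate term added to the current model on the calibration data and
    evaluates the root-mean-square error of daily-yield prediction on the
    TEST dataset (denominator ``n - p`` with ``p`` the fitted parameter
    count).  The best candidate enters if it improves TEST RMSE by more
    than ``rel_tol`` relatively; otherwise selection stops.  The VAL
    dataset plays no role in selection and is only evaluated at the end.

    Returns ``(spec, trace, stats)`` where ``trace`` is a list of step
    records and ``stats`` holds final RMSE on all three datasets.
    """
    from .evaluate import rmse  # local import to avoid a cycle

    candidates = tuple(candidates)
    if not candidates:
        raise ValueError("candidate pool is empty")
    y_test = test[response_column(trait)].to_numpy(dtype=float)

    def test_rmse(fm: FittedModel) -> float:
        pred = predict_daily(fm, test)
        return rmse(y_test, pred, fm.p)

    spec = ModelSpec(trait, session, ())
    current = fit(calib, spec)
    best_rmse = test_rmse(current)
    trace = [{"step": 0, "term": "intercept", "test_rmse": best_rmse,
              "p": current.p}]
    remaining = list(candidates)
    step = 0
    while remaining:
        step += 1
        scored = []
        for term in remaining:
            cand_spec = spec.with_term(term)
            try:
                fm = fit(calib, cand_spec)
            except ValueError:
                continue  # rank collapse / too few rows: skip
            if fm.p <= current.p:
                continue  # adds nothing estimable
            scored.append((test_rmse(fm), term, fm))
        if not scored:
            break
        scored.sort(key=lambda s: s[0])
        new_rmse, term, fm = scored[0]
        if not np.isfinite(new_rmse):
            break
        if (best_rmse - new_rmse) <= rel_tol * best_rmse:
            break
        spec = spec.with_term(term)
        current = fm
        best_rmse = new_rmse
        remaining.remove(term)
        trace.append({"step": step, "term": term.label(trait, session),
                      "test_rmse": new_rmse, "p": fm.p})

    y_val = val[response_column(trait)].to_numpy(dtype=float)
    y_cal = calib[response_column(trait)].to_numpy(dtype=float)
    stats = {
        "calib_rmse": rmse(y_cal, predict_daily(current, calib), current.p),
        "test_rmse": best_rmse,
        "val_rmse": rmse(y_val, predict_daily(current, val), current.p),
        "n_terms": len(spec.terms),
        "p": current.p,
    }
    return spec, trace, stats
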