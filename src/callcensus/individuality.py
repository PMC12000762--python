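"""Vocal individuality: CV, PIC, variable selection, and DFA classification.

A variable is useful for telling individuals apart when it varies more
among individuals than within one.  The potential individual coding of a
variable is

    PIC = CVa / CVw

where CVw is the mean of the per-individual coefficients of variation and
CVa the coefficient of variation of the per-individual means.  Variables
with PIC > 1 are retained (peak frequencies are excluded by default even
when PIC sits near 1: in the field the harmonic balance, and hence the
peak, is scrambled by distance-dependent attenuation).

Classification uses discriminant function analysis: each class is its mean
vector under a pooled within-class covariance; a call is assigned to the
class at the smallest Mahalanobis distance, which with equal priors is the
maximum-posterior rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measure import VARIABLE_NAMES, CallMeasurements

DEFAULT_EXCLUDED = ("Fpeak1", "Fpeak2", "Fpeak3", "Fpeak4")


def compute_cv(values) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean)


def _measurements_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        return measurements
    rows = []
    for m in measurements:
        d = m.as_dict()
        d["individual_id"] = m.individual_id
        d["call_id"] = m.call_id
        rows.append(d)
    return pd.DataFrame(rows)


def compute_pic(
    measurements,
    variables=VARIABLE_NAMES,
    excluded: tuple[str, ...] = DEFAULT_EXCLUDED,
) -> pd.DataFrame:
    """Per-variable CVw, CVa, PIC and selection flag.

    ``measurements`` is a list of :class:`CallMeasurements` with
    ``individual_id`` set, or an equivalent DataFrame.  Individuals with a
    single call cannot contribute a within-CV and are excluded from CVw
    with a warning.  ``selected`` is True iff PIC > 1 and the variable is
    not in the configured exclusion set.
    """
    df = _measurements_frame(measurements)
    groups = df.groupby("individual_id")
    if groups.ngroups < 2:
        raise ValueError("need at least 2 individuals")
    singletons = [k for k, g in groups if len(g) < 2]
    if singletons:
        warnings.warn(
            f"{len(singletons)} individual(s) with a single call excluded from CVw"
        )
    rows = []
    for var in variables:
        per_ind_cv = [
            compute_cv(g[var]) for k, g in groups if len(g) >= 2
        ]
        cvw = float(np.mean(per_ind_cv))
        means = groups[var].mean()
        cva = compute_cv(means)
        pic = np.inf if cvw == 0 else cva / cvw
        rows.append(
            {
                "variable": var,
                "cv_within": cvw,
                "cv_among": cva,
                "pic": pic,
                "selected": bool(pic > 1) and var not in excluded,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def select_variables(pic_table: pd.DataFrame) -> list[str]:
    """Variables retained for identification, in table order."""
    chosen = [v for v in pic_table.index if pic_table.loc[v, "selected"]]
    if not chosen:
        raise ValueError("no variable has PIC > 1; nothing to analyse")
    return chosen


@dataclass
class DFAModel:
    variables: list[str]
    classes: list[str]
    class_means: np.ndarray  # (n_classes, p)
    pooled_cov_inv: np.ndarray  # (p, p)
    priors: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.priors is None:
            self.priors = np.full(len(self.classes), 1.0 / len(self.classes))


def _design(measurements, variables) -> tuple[np.ndarray, np.ndarray]:
    df = _measurements_frame(measurements)
    X = df[list(variables)].to_numpy(dtype=float)
    y = df["individual_id"].to_numpy()
    return X, y


def train_dfa(
    training,
    variables,
    ridge: float = 1e-6,
) -> DFAModel:
    """Fit a linear discriminant model (equal priors).

    The pooled within-class covariance is regularised by adding
    ``ridge * trace(S)/p`` to the diagonal, which keeps duplicated or
    collinear variables from making S singular (a warning is emitted when
    that regularisation is doing real work).
    """
    X, y = _design(training, variables)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    p = X.shape[1]
    means = np.zeros((len(classes), p))
    scatter = np.zeros((p, p))
    n_total = 0
    for c_idx, c in enumerate(classes):
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training calls")
        means[c_idx] = Xc.mean(axis=0)
        centred = Xc - means[c_idx]
        scatter += centred.T @ centred
        n_total += Xc.shape[0]
    if n_total - len(classes) <= p:
        warnings.warn(
            f"only {n_total} training calls for {p} variables; "
            "covariance estimate may be unstable"
        )
    cov = scatter / (n_total - len(classes))
    if np.linalg.matrix_rank(cov) < p:
        warnings.warn(
            "pooled covariance is rank-deficient (duplicated or collinear "
            "variables); ridge regularisation carries the fit"
        )
    reg = ridge * np.trace(cov) / p
    cov_reg = cov + reg * np.eye(p)
    try:
        cov_inv = np.linalg.inv(cov_reg)
    except np.linalg.LinAlgError as exc:
        raise ValueError("pooled covariance singular after regularisation") from exc
    return DFAModel(
        variables=list(variables),
        classes=classes,
        class_means=means,
        pooled_cov_inv=cov_inv,
    )


def classify_dfa(
    model: DFAModel, measurement: CallMeasurements | np.ndarray
) -> tuple[str, float]:
    """Assign one call to the nearest class mean (Mahalanobis distance).

    Returns (label, posterior); with equal priors the posterior is
    softmax(-d^2/2) over classes.
    """
    if isinstance(measurement, CallMeasurements):
        x = measurement.vector(model.variables)
    else:
        x = np.asarray(measurement, dtype=float)
        if x.size != len(model.variables):
            raise ValueError("measurement has wrong number of variables")
    diff = model.class_means - x
    d2 = np.einsum("ij,jk,ik->i", diff, model.pooled_cov_inv, diff)
    log_post = -0.5 * d2 + np.log(model.priors)
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    k = int(np.argmax(post))
    return model.classes[k], float(post[k])


def dfa_accuracy(model: DFAModel, test_set) -> tuple[int, float]:
    """(correct count, correct rate) of DFA assignments on labelled calls."""
    df = _measurements_frame(test_set)
    if df.empty:
        raise ValueError("empty test set")
    correct = 0
    for _, row in df.iterrows():
        label, _ = classify_dfa(model, row[model.variables].to_numpy(dtype=float))
        correct += label == row["individual_id"]
    return correct, correct / len(df)


def correct_rate(correct: int, total: int) -> float:
    """Identification rate = correct / total."""
    if total <= 0:
        raise ValueError("total must be positive")
    return correct / total
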