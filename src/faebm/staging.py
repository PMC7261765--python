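"""Subject-level staging along an inferred event ordering.

Given the event ordering S and the per-region mixtures, each subject is
assigned the maximum-likelihood stage k in {0..N}: the number of events
assumed to have occurred, chosen to maximize

    prod_{i<=k} P(x_{s(i)} | event) * prod_{i>k} P(x_{s(i)} | no event).

Controls are staged with the same rule as patients.  A stage threshold
turns staging into a classifier: subjects at or above the cut-off are
called diseased, which yields sensitivity (patients so called) and
specificity (controls below the cut-off).
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import BiomarkerTable
from .exceptions import ValidationError
from .mixtures import MixtureFit
from .ordering import EventOrdering, log_density_matrices


def _stage_log_posteriors(
    log_e: np.ndarray, log_n: np.ndarray, seq: np.ndarray
) -> np.ndarray:
    a = log_e[:, seq]
    b = log_n[:, seq]
    n = a.shape[0]
    zeros = np.zeros((n, 1))
    ca = np.concatenate([zeros, np.cumsum(a, axis=1)], axis=1)
    cb = np.concatenate([zeros, np.cumsum(b, axis=1)], axis=1)
    return ca + (cb[:, -1:] - cb)  # (n, N+1) unnormalized stage log-liks


def stage_table(
    table: BiomarkerTable,
    S: EventOrdering | Sequence[int],
    fits: Mapping[str, MixtureFit],
) -> pd.DataFrame:
    """Maximum-likelihood stage for every subject (patients and controls).

    Returns a DataFrame with subject_id, group, stage and the normalized
    posterior probability of the assigned stage.  Ties in the argmax go
    to the lowest stage (conservative toward healthy).
    """
    seq = np.asarray(tuple(S), dtype=int)
    log_e, log_n = log_density_matrices(table, fits, allow_controls=True)
    terms = _stage_log_posteriors(log_e, log_n, seq)
    stages = terms.argmax(axis=1)  # argmax returns the lowest tied index
    m = terms.max(axis=1, keepdims=True)
    post = np.exp(terms - m)
    post /= post.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        {
            "subject_id": table.subjects["subject_id"].to_numpy(),
            "group": table.subjects["group"].to_numpy(),
            "stage": stages,
            "stage_posterior": post[np.arange(len(stages)), stages],
        }
    )


def ml_stage(
    x: Sequence[float] | np.ndarray,
    S: EventOrdering | Sequence[int],
    fits: Sequence[MixtureFit] | Mapping[str, MixtureFit],
    labels: Sequence[str] | None = None,
) -> tuple[int, np.ndarray]:
    """Stage one subject: returns (stage, normalized stage posterior)."""
    seq = np.asarray(tuple(S), dtype=int)
    values = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("subject has missing or non-finite region values")
    log_e, log_n = log_density_matrices(values[None, :], fits, labels=labels)
    terms = _stage_log_posteriors(log_e, log_n, seq)[0]
    post = np.exp(terms - terms.max())
    post /= post.sum()
    return int(terms.argmax()), post


def stage_proportions(assignments: pd.DataFrame, n_stages: int) -> pd.DataFrame:
    """Per-group proportion of subjects at each stage 0..n_stages.

    ``assignments`` is a stage table from :func:`stage_table`; rows of
    the result are groups, columns stages, each row summing to 1.
    """
    if assignments.empty:
        raise ValidationError("no staged subjects")
    out = {}
    for group, sub in assignments.groupby("group"):
        counts = np.bincount(sub["stage"].to_numpy(), minlength=n_stages + 1)
        out[group] = counts / counts.sum()
    return pd.DataFrame(out, index=pd.RangeIndex(n_stages + 1, name="stage")).T


def classify_by_stage(
    assignments: pd.DataFrame, cutoff: int = 1
) -> tuple[float, float]:
    """Sensitivity and specificity of the stage >= cutoff classifier.

    Subjects with stage >= cutoff are predicted diseased.  Sensitivity
    is the fraction of patients so predicted; specificity the fraction
    of controls predicted healthy.
    """
    if cutoff < 1:
        raise ValidationError("cutoff must be >= 1")
    groups = set(assignments["group"])
    if not {"patient", "control"} <= groups:
        raise ValidationError("classification needs both patients and controls")
    pat = assignments.loc[assignments["group"] == "patient", "stage"]
    con = assignments.loc[assignments["group"] == "control", "stage"]
    sensitivity = float((pat >= cutoff).mean())
    specificity = float((con < cutoff).mean())
    return sensitivity, specificity
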