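"""Event-ordering inference: likelihood, greedy search, MCMC, PVDs, CV.

The model treats disease progression as a fixed sequence S of biomarker
events.  A subject at stage k has experienced the first k events of S.
With a uniform prior over stages, the likelihood of one patient's
measurements x under ordering S is

    P(x | S) = 1/(N+1) * sum_{k=0}^{N} prod_{i<=k} P(x_{s(i)} | event) *
                                        prod_{i>k}  P(x_{s(i)} | no event)

and the data likelihood is the product over patients.  All computation
is in the natural-log domain via log-sum-exp; per-component log
densities are floored at the log of the smallest positive normal float
so a single extreme outlier cannot produce -inf.

The posterior over orderings (uniform prior over permutations) is
sampled with a Metropolis chain whose proposal swaps two positions
chosen uniformly at random; the chain is initialized from a greedy
pairwise-swap ascent.  Positional variance diagrams summarize the
posterior as a doubly stochastic event-by-position confidence matrix.

Bootstrap cross-validation re-estimates the mixtures (one direct fit
per replicate, under weak constraints) and the most likely ordering on
resampled cohorts; its PVD deliberately overstates ordering uncertainty
relative to the MCMC PVD, giving a conservative picture.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import BiomarkerTable
from .exceptions import (
    EstimationFailureError,
    FaebmError,
    SchemaError,
    ValidationError,
)
from .mixtures import (
    ConstraintConfig,
    MixtureFit,
    event_densities,
    fit_constrained_mixture,
    fit_control_gaussian,
)

logger = logging.getLogger(__name__)

_LOG_TINY = float(np.log(np.finfo(float).tiny))


@dataclass(frozen=True)
class EventOrdering:
    """A permutation of region indices: position p holds event sequence[p]."""

    sequence: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(self.sequence) != list(range(len(self.sequence))):
            raise ValidationError("ordering must be a permutation of 0..N-1")

    def __len__(self) -> int:
        return len(self.sequence)

    def __iter__(self):
        return iter(self.sequence)

    def region_labels(self, labels: Sequence[str]) -> tuple[str, ...]:
        return tuple(labels[i] for i in self.sequence)

    @classmethod
    def identity(cls, n: int) -> "EventOrdering":
        return cls(tuple(range(n)))


@dataclass
class OrderingPosterior:
    """Retained MCMC samples over orderings plus the MAP estimate."""

    samples: np.ndarray  # (n_retained, N) int
    log_likelihoods: np.ndarray
    map_ordering: EventOrdering
    map_log_likelihood: float
    burn_in: int
    seed: int
    labels: tuple[str, ...] | None = None
    acceptance_rate: float = float("nan")


@dataclass
class PositionalVariance:
    """Row-stochastic event-by-position posterior confidence matrix.

    Row i corresponds to event ``reference.sequence[i]``; column p to
    sequence position p.  Because every sample is a permutation the
    matrix is doubly stochastic.
    """

    matrix: np.ndarray
    reference: EventOrdering
    labels: tuple[str, ...] | None = None

    @property
    def row_labels(self) -> tuple[str, ...]:
        if self.labels is None:
            return tuple(str(i) for i in self.reference)
        return self.reference.region_labels(self.labels)

    def mean_row_entropy(self) -> float:
        """Mean Shannon entropy (nats) of the rows; larger = more
        positional uncertainty."""
        p = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 0, -p * np.log(p), 0.0)
        return float(h.sum(axis=1).mean())


# ---------------------------------------------------------------------
# Likelihood core
# ---------------------------------------------------------------------

def _patient_matrix(
    X: BiomarkerTable | np.ndarray, allow_controls: bool = False
) -> np.ndarray:
    if isinstance(X, BiomarkerTable):
        if X.n_subjects == 0:
            raise ValidationError("empty subject table")
        if not allow_controls and X.mask("control").any():
            raise ValidationError(
                "ordering inference uses patient data only; "
                "pass table.patients() or set allow_controls=True"
            )
        if not allow_controls and not X.mask("patient").any():
            raise ValidationError("no patients in table")
        return X.value_matrix()
    arr = np.asarray(X, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty data matrix")
    return arr


def log_density_matrices(
    X: BiomarkerTable | np.ndarray,
    fits: Mapping[str, MixtureFit] | Sequence[MixtureFit],
    labels: Sequence[str] | None = None,
    allow_controls: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject, per-region log densities (log p_event, log p_no_event).

    Columns follow the table's region order.  Log densities are floored
    at log(tiny) with a warning, so downstream log-sum-exp stays finite.
    """
    if isinstance(X, BiomarkerTable):
        labels = list(X.region_labels)
    values = _patient_matrix(X, allow_controls)
    if isinstance(fits, Mapping):
        if labels is None:
            raise SchemaError("labels required when fits is a mapping")
        missing = [l for l in labels if l not in fits]
        if missing:
            raise SchemaError(f"mixture fits missing for region(s): {missing}")
        fit_list = [fits[l] for l in labels]
    else:
        fit_list = list(fits)
    if len(fit_list) != values.shape[1]:
        raise SchemaError(
            f"{len(fit_list)} fits for {values.shape[1]} region columns"
        )
    log_e = np.empty_like(values)
    log_n = np.empty_like(values)
    for i, fit in enumerate(fit_list):
        le, ln = event_densities(fit, values[:, i], log=True)
        log_e[:, i] = le
        log_n[:, i] = ln
    n_floored = int((log_e < _LOG_TINY).sum() + (log_n < _LOG_TINY).sum())
    if n_floored:
        logger.warning("floored %d log-densities at log(tiny)", n_floored)
    np.maximum(log_e, _LOG_TINY, out=log_e)
    np.maximum(log_n, _LOG_TINY, out=log_n)
    return log_e, log_n


def _seq_log_likelihood(
    log_e: np.ndarray, log_n: np.ndarray, seq: np.ndarray
) -> float:
    """Stage-marginalized log likelihood of one ordering (log domain)."""
    a = log_e[:, seq]
    b = log_n[:, seq]
    n, N = a.shape
    zeros = np.zeros((n, 1))
    ca = np.concatenate([zeros, np.cumsum(a, axis=1)], axis=1)
    cb = np.concatenate([zeros, np.cumsum(b, axis=1)], axis=1)
    # stage-k term: events at positions < k occurred, the rest did not
    terms = ca + (cb[:, -1:] - cb)
    m = terms.max(axis=1)
    ll = m + np.log(np.exp(terms - m[:, None]).sum(axis=1))
    return float(ll.sum() - n * np.log(N + 1))


def ordering_log_likelihood(
    S: EventOrdering | Sequence[int],
    X: BiomarkerTable | np.ndarray,
    fits: Mapping[str, MixtureFit] | Sequence[MixtureFit],
    allow_controls: bool = False,
) -> float:
    """Log likelihood of ordering S given patient data X.

    Marginalizes each patient's stage over 0..N with a uniform prior and
    sums log likelihoods over patients; invariant to patient row order.
    """
    seq = np.asarray(tuple(S), dtype=int)
    log_e, log_n = log_density_matrices(X, fits, allow_controls=allow_controls)
    if seq.size != log_e.shape[1]:
        raise SchemaError("ordering length does not match number of regions")
    return _seq_log_likelihood(log_e, log_n, seq)


# ---------------------------------------------------------------------
# Greedy ascent
# ---------------------------------------------------------------------

def _greedy_from(
    log_e: np.ndarray, log_n: np.ndarray, seq: np.ndarray
) -> tuple[np.ndarray, float]:
    ll = _seq_log_likelihood(log_e, log_n, seq)
    N = seq.size
    improved = True
    while improved:
        improved = False
        best_ll, best_pair = ll, None
        for i in range(N - 1):
            for j in range(i + 1, N):
                seq[i], seq[j] = seq[j], seq[i]
                cand = _seq_log_likelihood(log_e, log_n, seq)
                seq[i], seq[j] = seq[j], seq[i]
                if cand > best_ll:
                    best_ll, best_pair = cand, (i, j)
        if best_pair is not None:
            i, j = best_pair
            seq[i], seq[j] = seq[j], seq[i]
            ll = best_ll
            improved = True
    return seq, ll


def greedy_ascent(
    X: BiomarkerTable | np.ndarray,
    fits: Mapping[str, MixtureFit] | Sequence[MixtureFit],
    restarts: int = 10,
    seed: int | np.random.Generator = 0,
    allow_controls: bool = False,
) -> EventOrdering:
    """Best-improving pairwise-swap hill climb from random starts."""
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    log_e, log_n = log_density_matrices(X, fits, allow_controls=allow_controls)
    N = log_e.shape[1]
    best_seq, best_ll = None, -np.inf
    for _ in range(restarts):
        seq, ll = _greedy_from(log_e, log_n, rng.permutation(N))
        if ll > best_ll:
            best_seq, best_ll = seq.copy(), ll
    return EventOrdering(tuple(int(i) for i in best_seq))


# ---------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------

def mcmc_sample(
    X: BiomarkerTable | np.ndarray,
    fits: Mapping[str, MixtureFit] | Sequence[MixtureFit],
    init: EventOrdering | Sequence[int] | None = None,
    n_iter: int = 100_000,
    burn_in: int = 10_000,
    seed: int = 0,
    labels: Sequence[str] | None = None,
    allow_controls: bool = False,
) -> OrderingPosterior:
    """Metropolis sampling of the ordering posterior on patient data.

    Proposal: swap two distinct positions chosen uniformly; acceptance
    min(1, likelihood ratio) under a uniform prior over orderings.  The
    MAP is the highest-likelihood ordering visited anywhere in the chain
    (burn-in included).
    """
    if not (n_iter > burn_in >= 0):
        raise ValueError("need n_iter > burn_in >= 0")
    if isinstance(X, BiomarkerTable) and labels is None:
        labels = X.region_labels
    rng = np.random.default_rng(seed)
    log_e, log_n = log_density_matrices(X, fits, allow_controls=allow_controls)
    N = log_e.shape[1]
    seq = (
        np.arange(N)
        if init is None
        else np.asarray(tuple(init), dtype=int).copy()
    )
    if seq.size != N:
        raise SchemaError("init ordering length does not match data")
    ll = _seq_log_likelihood(log_e, log_n, seq)
    map_seq, map_ll = seq.copy(), ll

    kept = np.empty((n_iter - burn_in, N), dtype=int)
    kept_ll = np.empty(n_iter - burn_in)
    n_accept = 0
    for t in range(n_iter):
        if N > 1:
            i = rng.integers(N)
            j = rng.integers(N - 1)
            if j >= i:
                j += 1
            seq[i], seq[j] = seq[j], seq[i]
            cand = _seq_log_likelihood(log_e, log_n, seq)
            if np.log(rng.random()) < cand - ll:
                ll = cand
                n_accept += 1
                if ll > map_ll:
                    map_seq, map_ll = seq.copy(), ll
            else:
                seq[i], seq[j] = seq[j], seq[i]
        else:
            n_accept += 1
        if t >= burn_in:
            kept[t - burn_in] = seq
            kept_ll[t - burn_in] = ll
    return OrderingPosterior(
        samples=kept,
        log_likelihoods=kept_ll,
        map_ordering=EventOrdering(tuple(int(i) for i in map_seq)),
        map_log_likelihood=float(map_ll),
        burn_in=burn_in,
        seed=seed,
        labels=tuple(labels) if labels is not None else None,
        acceptance_rate=n_accept / n_iter,
    )


def exhaustive_map(
    X: BiomarkerTable | np.ndarray,
    fits: Mapping[str, MixtureFit] | Sequence[MixtureFit],
    allow_controls: bool = False,
) -> EventOrdering:
    """Brute-force argmax over all N! orderings (small N only)."""
    from itertools import permutations

    log_e, log_n = log_density_matrices(X, fits, allow_controls=allow_controls)
    N = log_e.shape[1]
    if N > 8:
        raise ValueError("exhaustive search is limited to N <= 8")
    best, best_ll = None, -np.inf
    for perm in permutations(range(N)):
        ll = _seq_log_likelihood(log_e, log_n, np.asarray(perm))
        if ll > best_ll:
            best, best_ll = perm, ll
    return EventOrdering(best)


# ---------------------------------------------------------------------
# Positional variance diagrams
# ---------------------------------------------------------------------

def positional_variance(
    samples: OrderingPosterior | Sequence[Sequence[int]] | np.ndarray,
    reference: EventOrdering | Sequence[int] | None = None,
    labels: Sequence[str] | None = None,
) -> PositionalVariance:
    """Event-by-position posterior confidence matrix from ordering samples.

    Row i is the event at position i of ``reference`` (default: the MAP
    ordering for an :class:`OrderingPosterior` input, identity
    otherwise); entry (i, p) is the fraction of samples placing that
    event at position p.
    """
    if isinstance(samples, OrderingPosterior):
        if reference is None:
            reference = samples.map_ordering
        if labels is None:
            labels = samples.labels
        arr = samples.samples
    else:
        arr = np.asarray(samples, dtype=int)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValidationError("need at least one ordering sample")
    m, N = arr.shape
    if np.any(np.sort(arr, axis=1) != np.arange(N)):
        raise SchemaError("every sample must be a permutation of the same regions")
    ref = (
        EventOrdering.identity(N)
        if reference is None
        else EventOrdering(tuple(reference))
    )
    if len(ref) != N:
        raise SchemaError("reference ordering length does not match samples")
    counts = np.zeros((N, N))
    # arr[s, p] = event at position p in sample s
    np.add.at(counts, (arr.ravel(), np.tile(np.arange(N), m)), 1.0)
    V = counts[np.asarray(ref.sequence)] / m
    return PositionalVariance(
        matrix=V,
        reference=ref,
        labels=tuple(labels) if labels is not None else None,
    )


# ---------------------------------------------------------------------
# Bootstrap cross-validation
# ---------------------------------------------------------------------

@dataclass
class CrossValidationResult:
    pvd: PositionalVariance
    orderings: np.ndarray  # (n_ok, N) per-replicate ML orderings
    n_failed: int
    reference: EventOrdering


def _direct_fits(
    control_values: np.ndarray,
    fit_values: np.ndarray,
    labels: Sequence[str],
    constraints: ConstraintConfig,
) -> list[MixtureFit]:
    fits = []
    for i, label in enumerate(labels):
        ctrl = fit_control_gaussian(control_values[:, i])
        fits.append(
            fit_constrained_mixture(fit_values[:, i], ctrl, constraints, label)
        )
    return fits


def cross_validate(
    table: BiomarkerTable,
    constraints: ConstraintConfig | None = None,
    B: int = 10_000,
    seed: int = 0,
    restarts: int = 5,
    pooled: bool = True,
    reference: EventOrdering | Sequence[int] | None = None,
) -> CrossValidationResult:
    """Bootstrap cross-validation of the inferred event ordering.

    Each replicate resamples patients and controls with replacement
    (within group, preserving group sizes), refits the control Gaussians
    and one direct mixture per region under weak constraints, and
    re-estimates the most likely ordering by greedy ascent.  Replicate
    event positions accumulate into a PVD.  Failed replicates are logged
    and skipped; more than 50% failures aborts.
    """
    constraints = constraints or ConstraintConfig.weak()
    rng = np.random.default_rng(seed)
    labels = list(table.region_labels)
    pat = table.patients().value_matrix()
    con = table.controls().value_matrix()
    if pat.shape[0] == 0 or con.shape[0] == 0:
        raise ValidationError("cross-validation needs both patients and controls")

    if reference is None:
        # full-data ML ordering through the same direct-fit path
        full = np.vstack([pat, con]) if pooled else pat
        fits = _direct_fits(con, full, labels, constraints)
        reference = greedy_ascent(pat, fits, restarts=max(restarts, 10), seed=rng)
    reference = EventOrdering(tuple(reference))

    orderings = []
    n_failed = 0
    for b in range(B):
        pi = rng.integers(0, pat.shape[0], size=pat.shape[0])
        ci = rng.integers(0, con.shape[0], size=con.shape[0])
        rpat, rcon = pat[pi], con[ci]
        try:
            fit_values = np.vstack([rpat, rcon]) if pooled else rpat
            fits = _direct_fits(rcon, fit_values, labels, constraints)
            order = greedy_ascent(rpat, fits, restarts=restarts, seed=rng)
        except FaebmError as exc:
            n_failed += 1
            logger.warning("cross-validation replicate %d failed: %s", b, exc)
            continue
        orderings.append(order.sequence)
    if n_failed > B / 2:
        raise EstimationFailureError(
            f"{n_failed}/{B} cross-validation replicates failed"
        )
    arr = np.asarray(orderings, dtype=int)
    pvd = positional_variance(arr, reference=reference, labels=labels)
    return CrossValidationResult(
        pvd=pvd, orderings=arr, n_failed=n_failed, reference=reference
    )
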