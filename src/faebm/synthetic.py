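"""Synthetic cohort generation with a known ground-truth event ordering.

The generator realizes the event-based model's generative process
directly: each control draws every region from its healthy Gaussian;
each patient draws a latent stage k from a stage distribution, draws the
regions at the first k positions of the true ordering from their
diseased Gaussians, and the rest from the healthy ones.  Optional linear
age effects and additive site offsets can be layered on top to exercise
the residualization step and external harmonizers.

Because no per-tract effect sizes are published for this disease, the
default mixture parameters below are plausible stand-ins on the FA
scale, not measured values; treat recovery results on them as checks of
the inference machinery, not of any real cohort.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import BiomarkerTable, RegionSet
from .exceptions import ValidationError

# Healthy mean FA per tract family: corticospinal and callosal tracts sit
# higher on the FA scale than long association fibers.  Disease shifts
# the mean downward by 3 healthy SDs by default (FA decreases with
# white-matter damage) and inflates the SD slightly.
_HEALTHY_MEANS = {
    "CST_inf": 0.58, "CST_mid": 0.56, "CST_sup": 0.54,
    "CC_genu": 0.65, "CC_body": 0.60, "CC_splenium": 0.68,
    "Cingulum": 0.50, "SLF": 0.45, "ILF": 0.48, "IFOF": 0.50, "UF": 0.42,
}
_SIGMA_HEALTHY = 0.025
_SIGMA_DISEASED = 0.030
_EFFECT_SDS = 3.0  # |mu_H - mu_D| in units of sigma_H


def _base_label(label: str) -> str:
    for suffix in ("_L", "_R"):
        if label.endswith(suffix):
            return label[: -len(suffix)]
    return label


def default_fa_params(
    region_set: RegionSet, effect_sds: float = _EFFECT_SDS
) -> pd.DataFrame:
    """Default per-region mixture parameters on the FA scale.

    Returns a DataFrame indexed by region label with columns
    ``mu_healthy``, ``sigma_healthy``, ``mu_diseased``, ``sigma_diseased``.
    Guarantees mu_diseased < mu_healthy for every region.
    """
    rows = []
    for label in region_set.labels:
        mu_h = _HEALTHY_MEANS.get(_base_label(label), 0.50)
        rows.append(
            {
                "mu_healthy": mu_h,
                "sigma_healthy": _SIGMA_HEALTHY,
                "mu_diseased": mu_h - effect_sds * _SIGMA_HEALTHY,
                "sigma_diseased": _SIGMA_DISEASED,
            }
        )
    return pd.DataFrame(rows, index=list(region_set.labels))


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort.

    ``true_ordering`` is a permutation of region indices (position ->
    region); ``stage_distribution`` is a probability vector over stages
    0..N (default uniform, matching the model's staging prior);
    ``params`` holds the per-region healthy/diseased Gaussians.
    ``age_slopes`` (FA/year, per region) and site offsets are off by
    default.
    """

    region_set: RegionSet
    true_ordering: Sequence[int]
    n_patients: int = 150
    n_controls: int = 130
    stage_distribution: np.ndarray | None = None
    params: pd.DataFrame | None = None
    age_range: tuple[float, float] = (45.0, 75.0)
    age_slopes: np.ndarray | None = None
    site_labels: Sequence[str] | None = None
    site_offsets: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.region_set)
        order = np.asarray(self.true_ordering, dtype=int)
        if sorted(order.tolist()) != list(range(n)):
            raise ValidationError("true_ordering must be a permutation of region indices")
        self.true_ordering = order
        if self.params is None:
            self.params = default_fa_params(self.region_set)
        if self.stage_distribution is None:
            self.stage_distribution = np.full(n + 1, 1.0 / (n + 1))
        dist = np.asarray(self.stage_distribution, dtype=float)
        if dist.shape != (n + 1,) or np.any(dist < 0) or not np.isclose(dist.sum(), 1.0):
            raise ValidationError(
                "stage_distribution must be a probability vector over stages 0..N"
            )
        self.stage_distribution = dist
        p = self.params
        if np.any(p["sigma_healthy"] <= 0) or np.any(p["sigma_diseased"] <= 0):
            raise ValidationError("sigmas must be positive")
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValidationError("cohort sizes must be non-negative")


def generate_cohort(
    config: SimulationConfig,
) -> tuple[BiomarkerTable, dict]:
    """Draw one cohort; returns the biomarker table and the latent truth.

    The truth dict carries ``true_ordering`` (region indices and labels)
    and per-patient latent ``stages``; it is meant to be written to a
    sidecar file, never into the table, so the inference path cannot see
    it.  Fully reproducible from ``config.seed``: a single RNG stream is
    consumed subject-by-subject, region-by-region (controls first).
    """
    rng = np.random.default_rng(config.seed)
    rs = config.region_set
    n_regions = len(rs)
    p = config.params
    mu_h = p["mu_healthy"].to_numpy()
    sd_h = p["sigma_healthy"].to_numpy()
    mu_d = p["mu_diseased"].to_numpy()
    sd_d = p["sigma_diseased"].to_numpy()

    rows, meta = [], []
    for c in range(config.n_controls):
        rows.append(rng.normal(mu_h, sd_h))
        meta.append({"subject_id": f"C{c:04d}", "group": "control"})

    stages = np.empty(config.n_patients, dtype=int)
    # event_rank[r] = 1-based position of region r in the true ordering
    event_rank = np.empty(n_regions, dtype=int)
    event_rank[config.true_ordering] = np.arange(1, n_regions + 1)
    for j in range(config.n_patients):
        k = int(rng.choice(n_regions + 1, p=config.stage_distribution))
        stages[j] = k
        diseased = event_rank <= k
        mu = np.where(diseased, mu_d, mu_h)
        sd = np.where(diseased, sd_d, sd_h)
        rows.append(rng.normal(mu, sd))
        meta.append({"subject_id": f"P{j:04d}", "group": "patient"})

    values = pd.DataFrame(np.asarray(rows), columns=list(rs.labels))
    subjects = pd.DataFrame(meta)

    ages = rng.uniform(*config.age_range, size=len(subjects))
    subjects["age"] = np.round(ages, 1)
    if config.age_slopes is not None:
        slopes = np.asarray(config.age_slopes, dtype=float)
        mid_age = 0.5 * (config.age_range[0] + config.age_range[1])
        values = values + np.outer(subjects["age"] - mid_age, slopes)

    if config.site_labels is not None:
        labels = list(config.site_labels)
        offsets = np.asarray(config.site_offsets, dtype=float)
        idx = rng.integers(0, len(labels), size=len(subjects))
        subjects["site"] = [labels[i] for i in idx]
        values = values + offsets[idx][:, None]

    table = BiomarkerTable(subjects=subjects, values=values, region_set=rs)
    truth = {
        "true_ordering": config.true_ordering.tolist(),
        "true_ordering_labels": [rs.labels[i] for i in config.true_ordering],
        "stages": {
            sid: int(k)
            for sid, k in zip(
                subjects.loc[subjects["group"] == "patient", "subject_id"], stages
            )
        },
        "seed": config.seed,
    }
    return table, truth
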