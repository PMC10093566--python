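"""Synthetic cohort generator calibrated to the clinical class distributions.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage is testable without patient data:

* two-class (benign/malignant) SUVmax distributions as truncated log-normals
  matching the published per-class medians and ranges;
* node-level malignancy prevalence of 28.7%, with malignant nodes clustered
  in node-positive (N+) patients the way nodal metastases cluster in
  practice;
* 1-6 nodes per patient with median 3;
* patient covariates inside the clinical inclusion windows (glucose <= 8.3
  mmol/L, uptake time 45-70 min, injected activity 226-245 MBq);
* patient-level reference-organ uptakes chosen so the per-node ratio
  features (node SUVmax / reference SUVmax) recover the published per-class
  ratio medians.

Reference consistency.  Ratios are *recomputed* downstream as node SUVmax
divided by the patient's reference uptake, so the generator cannot draw
SUVmax, references and ratios independently.  It instead derives each
reference organ's median as (class SUVmax median) / (class ratio median),
conditions the reference draw on the patient's N-status, and
rejection-samples the node SUVmax until all four implied ratios fall inside
the published per-class ratio ranges.  Malignant ratio medians are then
exact by construction; benign medians are mildly biased (a few percent)
because benign nodes inside N+ patients see N+-calibrated references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .cohort import (
    CohortTable,
    NodeRecord,
    PatientRecord,
    ReferenceUptake,
    reference_data,
)

__all__ = [
    "TruncatedLogNormal",
    "ClassDistribution",
    "CohortSpec",
    "GeneratedCohort",
    "calibrate",
    "reference_class_distributions",
    "synthesize",
]

#: Central probability mass whose pre-truncation interval is mapped onto the
#: target range when calibrating the log-normal scale.
_CAL_COVERAGE = 0.995
_CAL_Z = float(stats.norm.ppf(0.5 + _CAL_COVERAGE / 2.0))  # ~2.807

FEATURES = ("suvmax", "ratio_primary", "ratio_liver", "ratio_brainstem", "ratio_lung")

#: Fixture conventions for the derived SUV statistics (not clinically
#: calibrated): SUVmean and SUVpeak as random fractions of SUVmax with
#: plausible partial-volume orderings.
SUVMEAN_FRACTION = (0.55, 0.85)
SUVPEAK_FRACTION = (0.80, 0.98)


@dataclass(frozen=True)
class TruncatedLogNormal:
    """Log-normal calibrated to a median and range, truncated to that range.

    ``mu = log(median)``; ``sigma`` maps the central 99.5% pre-truncation
    interval onto ``log(range)``; sampling rejects draws outside the range.
    """

    mu: float
    sigma: float
    low: float
    high: float

    @property
    def median(self) -> float:
        """Median of the *untruncated* parent (the calibration target)."""
        return math.exp(self.mu)

    @property
    def truncated_median(self) -> float:
        """Exact median after truncation (closed form via normal quantiles)."""
        a = (math.log(self.low) - self.mu) / self.sigma
        b = (math.log(self.high) - self.mu) / self.sigma
        p = (stats.norm.cdf(a) + stats.norm.cdf(b)) / 2.0
        return float(math.exp(self.mu + self.sigma * stats.norm.ppf(p)))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Rejection-sample ``size`` values inside [low, high]."""
        out = np.empty(size)
        filled = 0
        while filled < size:
            draw = np.exp(self.mu + self.sigma * rng.standard_normal(size - filled))
            ok = draw[(draw >= self.low) & (draw <= self.high)]
            out[filled:filled + ok.size] = ok
            filled += ok.size
        return out

    def sample_one(self, rng: np.random.Generator) -> float:
        return float(self.sample(rng, 1)[0])


def calibrate(target_median: float, target_range: tuple[float, float]) -> TruncatedLogNormal:
    """Fit a truncated log-normal to a median and a (low, high) range.

    The location is the log median; the scale spreads the central 99.5% of
    the parent distribution over the range; truncation bounds equal the
    range.  Raises if the median does not lie strictly inside the range.
    """
    low, high = float(target_range[0]), float(target_range[1])
    if not (0 < low < target_median < high):
        raise ValueError(
            f"infeasible calibration target: need 0 < low < median < high, "
            f"got median={target_median}, range=({low}, {high})"
        )
    mu = math.log(target_median)
    sigma = (math.log(high) - math.log(low)) / (2.0 * _CAL_Z)
    return TruncatedLogNormal(mu=mu, sigma=sigma, low=low, high=high)


@dataclass(frozen=True)
class ClassDistribution:
    """Per-feature calibrated distributions for one histology class."""

    features: Mapping[str, TruncatedLogNormal]

    def __post_init__(self) -> None:
        missing = [f for f in FEATURES if f not in self.features]
        if missing:
            raise ValueError(f"class distribution missing features: {missing}")

    def __getitem__(self, feature: str) -> TruncatedLogNormal:
        return self.features[feature]


def reference_class_distributions() -> dict[str, ClassDistribution]:
    """Benign/malignant distributions calibrated to the published summaries."""
    raw = reference_data()["class_distributions"]
    return {
        cls: ClassDistribution({
            feat: calibrate(d["median"], tuple(d["range"]))
            for feat, d in feats.items()
        })
        for cls, feats in raw.items()
    }


def _default_distributions():
    return reference_class_distributions()


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the clinical study conditions: 28.7% node-level
    malignancy prevalence, nodes clustered in N+ patients (75% of an N+
    patient's nodes malignant on average), 1-6 nodes per patient with median
    3 and mean ~2.8, and covariates uniform in the protocol inclusion
    windows.
    """

    n_patients: int = 37
    seed: int = 0
    malignancy_prevalence: float = 0.287
    #: P(node malignant | patient N+); P(patient N+) is prevalence / this.
    node_malignancy_given_npos: float = 0.75
    #: P(nodes per patient = 1..6); median 3.
    nodes_per_patient_probs: tuple[float, ...] = (0.19, 0.27, 0.26, 0.14, 0.09, 0.05)
    glucose_range_mmol_per_l: tuple[float, float] = (4.2, 8.3)
    uptake_time_range_min: tuple[float, float] = (46.0, 68.0)
    activity_range_mbq: tuple[float, float] = (226.0, 245.0)
    body_weight_mean_sd_kg: tuple[float, float] = (78.0, 13.0)
    age_range_years: tuple[int, int] = (52, 83)
    male_fraction: float = 24 / 37
    #: Log-scale SD of the patient-level reference-organ uptake draws.
    reference_sigma: float = 0.18
    benign_dist: ClassDistribution = field(default_factory=lambda: _default_distributions()["benign"])
    malignant_dist: ClassDistribution = field(default_factory=lambda: _default_distributions()["malignant"])

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0.0 < self.malignancy_prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if not (0.0 < self.node_malignancy_given_npos <= 1.0):
            raise ValueError("node_malignancy_given_npos must be in (0, 1]")
        if self.malignancy_prevalence > self.node_malignancy_given_npos:
            raise ValueError("prevalence cannot exceed P(malignant | N+)")
        p = np.asarray(self.nodes_per_patient_probs)
        if p.size != 6 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("nodes_per_patient_probs must be 6 probabilities summing to 1")
        if not (0.0 < self.glucose_range_mmol_per_l[1] <= 8.3):
            raise ValueError("glucose range must respect the <= 8.3 mmol/L inclusion limit")
        if not (45.0 <= self.uptake_time_range_min[0] <= self.uptake_time_range_min[1] <= 70.0):
            raise ValueError("uptake-time range must lie within the 45-70 min inclusion window")
        if self.reference_sigma <= 0:
            raise ValueError("reference_sigma must be > 0")


@dataclass(frozen=True)
class GeneratedCohort:
    """A synthetic cohort plus its provenance (spec, seed, latent classes)."""

    cohort: CohortTable
    spec: CohortSpec
    seed: int
    node_classes: tuple[str, ...]  # latent per-node class draws, in node order

    @property
    def malignant_fraction(self) -> float:
        return sum(c == "malignant" for c in self.node_classes) / len(self.node_classes)


_STATION_NAMES = (2, 4, 5, 6, 7, 10, 11, 12)
_SUBTYPES = ("AC", "SCC", "SCLC", "NSCLC_NOS")
_SUBTYPE_COUNTS = (19, 16, 1, 1)

#: Short-axis size fixture (mm): log-normal medians per class, chosen so the
#: cohort mean diameter lands near the clinical ~13.7 +/- 10 mm.
_SIZE_MEDIAN = {"benign": 10.0, "malignant": 15.0}
_SIZE_SIGMA = 0.55

_MAX_NODE_TRIES = 1000


def _reference_medians(spec: CohortSpec, status_class: str) -> dict[str, float]:
    """Implied reference-organ medians for a patient of the given class.

    reference median = truncated SUVmax median / class ratio median, so that
    median(node SUVmax / reference) hits the class ratio median.
    """
    dist = spec.malignant_dist if status_class == "malignant" else spec.benign_dist
    suv_med = dist["suvmax"].truncated_median
    return {
        "primary": suv_med / dist["ratio_primary"].median,
        "liver": suv_med / dist["ratio_liver"].median,
        "brainstem": suv_med / dist["ratio_brainstem"].median,
        "lung": suv_med / dist["ratio_lung"].median,
    }


def _cross_class_shrinkage(spec: CohortSpec) -> float:
    """Log-scale factor applied to benign node SUVmax drawn in N+ patients.

    Benign nodes of N+ patients see malignant-implied reference uptakes, so
    their ratios are biased by delta_k = log(rho_benign_k / rho_malignant_k)
    per organ while their SUVmax is unbiased.  A single multiplicative
    shrinkage s on those nodes' SUVmax shifts all four ratio biases by log s
    and the SUVmax bias from 0 to log s; the minimax choice centers the bias
    band: log s = -(max + min)/2 over {delta_k} union {0}.
    """
    rho_b = _reference_medians(spec, "benign")
    rho_m = _reference_medians(spec, "malignant")
    deltas = [math.log(rho_b[k] / rho_m[k]) for k in rho_b] + [0.0]
    return math.exp(-(max(deltas) + min(deltas)) / 2.0)


def _draw_node_suvmax(
    rng: np.random.Generator,
    dist: ClassDistribution,
    refs: ReferenceUptake,
    scale: float = 1.0,
) -> float:
    """Class SUVmax draw (optionally log-shifted by ``scale``), rejected until
    all four implied ratios lie inside the class ratio ranges."""
    bounds = {
        "ratio_primary": refs.primary_suvmax,
        "ratio_liver": refs.liver_suvmax,
        "ratio_brainstem": refs.brainstem_suvmax,
        "ratio_lung": refs.lung_suvmax,
    }
    suv = dist["suvmax"]
    if scale != 1.0:
        suv = TruncatedLogNormal(mu=suv.mu + math.log(scale), sigma=suv.sigma,
                                 low=suv.low, high=suv.high)
    for _ in range(_MAX_NODE_TRIES):
        s = suv.sample_one(rng)
        if all(
            d.low <= s / ref <= d.high
            for name, ref in bounds.items()
            for d in (dist[name],)
        ):
            return s
    raise RuntimeError(
        "could not draw a node SUVmax consistent with the patient's reference "
        "uptakes and the class ratio ranges; references are implausibly extreme"
    )


def synthesize(spec: CohortSpec) -> GeneratedCohort:
    """Generate a cohort; identical spec + seed gives a bit-identical cohort."""
    rng = np.random.default_rng(spec.seed)
    raw = reference_data()
    station_values = np.array(_STATION_NAMES)
    station_counts = raw["station_counts"]
    station_probs = np.array([station_counts[str(s)] for s in _STATION_NAMES], dtype=float)
    station_probs /= station_probs.sum()
    subtype_probs = np.array(_SUBTYPE_COUNTS, dtype=float) / sum(_SUBTYPE_COUNTS)

    # Stratified N-status assignment: a fixed count of N+ patients keeps the
    # realized node-level prevalence tightly around the target despite
    # within-patient clustering.
    p_npos = spec.malignancy_prevalence / spec.node_malignancy_given_npos
    n_pos = int(round(spec.n_patients * p_npos))
    status = np.zeros(spec.n_patients, dtype=bool)
    status[:n_pos] = True
    status = rng.permutation(status)

    patients: list[PatientRecord] = []
    nodes: list[NodeRecord] = []
    classes: list[str] = []
    shrink = _cross_class_shrinkage(spec)

    for i in range(spec.n_patients):
        pid = f"P{i + 1:04d}"
        npos = bool(status[i])
        status_class = "malignant" if npos else "benign"
        ref_medians = _reference_medians(spec, status_class)
        refs = ReferenceUptake(**{
            f"{organ}_suvmax": med * math.exp(spec.reference_sigma * rng.standard_normal())
            for organ, med in ref_medians.items()
        })
        patient = PatientRecord(
            patient_id=pid,
            age_years=int(rng.integers(spec.age_range_years[0], spec.age_range_years[1] + 1)),
            sex="m" if rng.random() < spec.male_fraction else "f",
            glucose_mmol_per_l=float(rng.uniform(*spec.glucose_range_mmol_per_l)),
            uptake_time_min=float(rng.uniform(*spec.uptake_time_range_min)),
            injected_activity_mbq=float(rng.uniform(*spec.activity_range_mbq)),
            body_weight_kg=float(np.clip(
                rng.normal(*spec.body_weight_mean_sd_kg), 48.0, 130.0)),
            histology_subtype=str(rng.choice(_SUBTYPES, p=subtype_probs)),
            reference=refs,
        )
        patients.append(patient)

        n_nodes = int(rng.choice(np.arange(1, 7), p=spec.nodes_per_patient_probs))
        for j in range(n_nodes):
            malignant = npos and (rng.random() < spec.node_malignancy_given_npos)
            cls = "malignant" if malignant else "benign"
            dist = spec.malignant_dist if malignant else spec.benign_dist
            scale = shrink if (npos and not malignant) else 1.0
            suvmax = _draw_node_suvmax(rng, dist, refs, scale)
            suvmean = suvmax * rng.uniform(*SUVMEAN_FRACTION)
            suvpeak = suvmax * rng.uniform(*SUVPEAK_FRACTION)
            size = float(np.clip(
                _SIZE_MEDIAN[cls] * math.exp(_SIZE_SIGMA * rng.standard_normal()),
                2.0, 60.0,
            ))
            nodes.append(NodeRecord(
                patient_id=pid,
                node_id=f"{pid}-N{j + 1}",
                station=int(rng.choice(station_values, p=station_probs)),
                short_axis_mm=size,
                suvmax=float(suvmax),
                suvmean=float(suvmean),
                suvpeak=float(suvpeak),
                histology=cls,
            ))
            classes.append(cls)

    cohort = CohortTable(patients=patients, nodes=nodes)
    return GeneratedCohort(cohort=cohort, spec=spec, seed=spec.seed,
                           node_classes=tuple(classes))
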