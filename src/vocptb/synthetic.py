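"""Synthetic GC-IMS spectra and obstetric cohorts.

The generator targets *statistical* realism, not chemistry: a spectrum
is a positive detector baseline with Gaussian noise, plus a constant
reactant-ion (RIP) column, plus a fixed template of 2D Gaussian analyte
peaks whose amplitudes jitter log-normally per sample.  Raw matrices
are dense, as on the instrument; sparsity appears only after the
background threshold.  A binary class effect multiplies the
amplitudes of designated peaks — the simplest mechanism the
crop/threshold/cell-intensity pipeline can detect.

The cohort generator emulates the study population: a high-risk
antenatal clinic with ~20% spontaneous preterm delivery, ~12% bacterial
vaginosis (BV), strong BV→preterm enrichment (~59%), a small iatrogenic
and unknown-outcome fraction, 2-3 swabs per patient sampled in weeks
10-29, and one spectrum per swab.  All randomness flows from one seed
through named sub-streams, so regeneration is byte-stable.

Default grid is 300 × 200 — a desk-scale stand-in for the instrument's
millions of cells that preserves the sparsity structure the reduction
steps rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._util import sub_rng, subseed
from .cohort import GestationalAge, Patient, Swab
from .gcims import IMSSpectrum
from .preprocess import FeatureMatrix

__all__ = [
    "SpectrumSimParams",
    "CohortSimParams",
    "generate_spectrum",
    "generate_labelled_spectra",
    "generate_null_feature_matrix",
    "generate_cohort",
]


@dataclass(frozen=True)
class SpectrumSimParams:
    """Template for one instrument configuration's synthetic output.

    Peak positions/widths are in grid-index units; amplitudes in the
    same arbitrary intensity units as the noise (sd 1 by default, so a
    threshold of 5 sits at five noise sigmas).
    """

    n_retention: int = 300
    n_drift: int = 200
    retention_span: tuple[float, float] = (0.0, 600.0)  # s, a 10-min GC run
    drift_span: tuple[float, float] = (5.0, 15.0)  # ms
    rip_drift_index: int = 30
    rip_intensity: float = 400.0
    baseline_level: float = 2.0  # positive detector baseline; raw matrices are dense
    peak_positions: tuple[tuple[float, float], ...] = ()
    peak_amplitudes: tuple[float, ...] = ()
    sigma_retention: float = 4.0
    sigma_drift: float = 2.5
    baseline_noise_sd: float = 1.0
    amplitude_jitter: float = 0.35  # log-normal sigma of per-sample amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_retention < 8 or self.n_drift < 8:
            raise ValueError("grid dimensions must be >= 8")
        if not (0 <= self.rip_drift_index < self.n_drift):
            raise ValueError("rip_drift_index outside drift axis")
        if self.sigma_retention <= 0 or self.sigma_drift <= 0:
            raise ValueError("peak sigmas must be positive")
        if self.baseline_noise_sd < 0 or self.amplitude_jitter < 0 or self.baseline_level < 0:
            raise ValueError("noise parameters must be non-negative")
        if len(self.peak_positions) != len(self.peak_amplitudes):
            raise ValueError("peak positions and amplitudes must align")
        if any(a <= 0 for a in self.peak_amplitudes):
            raise ValueError("peak amplitudes must be positive")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_positions)

    @classmethod
    def with_random_peaks(cls, n_peaks: int = 20, seed: int = 0, **kwargs) -> "SpectrumSimParams":
        """Template with peaks placed uniformly in the central region.

        Peaks stay at least 10% away from each edge and off the RIP
        column; amplitudes are log-uniform in [30, 300].
        """
        base = cls(seed=seed, **kwargs)
        rng = sub_rng(seed, "peak-template")
        r_lo, r_hi = 0.1 * base.n_retention, 0.9 * base.n_retention
        d_lo, d_hi = max(0.1 * base.n_drift, base.rip_drift_index + 10), 0.9 * base.n_drift
        positions = tuple(
            (float(rng.uniform(r_lo, r_hi)), float(rng.uniform(d_lo, d_hi)))
            for _ in range(n_peaks)
        )
        amplitudes = tuple(float(a) for a in np.exp(rng.uniform(np.log(30), np.log(300), n_peaks)))
        return replace(base, peak_positions=positions, peak_amplitudes=amplitudes)

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.linspace(*self.retention_span, self.n_retention),
            np.linspace(*self.drift_span, self.n_drift),
        )


def generate_spectrum(
    params: SpectrumSimParams,
    class_label: int = 0,
    effect: tuple[tuple[int, ...], float] | None = None,
    seed: int | None = None,
    sample_id: str = "synthetic",
    amplitude_scale: float = 1.0,
) -> IMSSpectrum:
    """One synthetic spectrum: noise + RIP column + Gaussian peaks.

    For ``class_label == 1`` the amplitudes of the peaks named in
    ``effect = (peak_indices, effect_size)`` are multiplied by
    ``effect_size``.  Negative cells are clipped to zero.  Deterministic
    given the seed (``params.seed`` when none is passed).
    """
    if effect is not None:
        idx, size = effect
        if any(i < 0 or i >= params.n_peaks for i in idx):
            raise ValueError("effect peak index out of range")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    shape = (params.n_retention, params.n_drift)
    m = (
        rng.normal(params.baseline_level, params.baseline_noise_sd, shape)
        if params.baseline_noise_sd > 0
        else np.full(shape, params.baseline_level)
    )
    m[:, params.rip_drift_index] += params.rip_intensity
    rows = np.arange(params.n_retention, dtype=float)
    cols = np.arange(params.n_drift, dtype=float)
    for i, ((r0, d0), amp) in enumerate(zip(params.peak_positions, params.peak_amplitudes)):
        a = amp * amplitude_scale
        if params.amplitude_jitter > 0:
            a *= np.exp(rng.normal(0.0, params.amplitude_jitter))
        if effect is not None and class_label == 1 and i in effect[0]:
            a *= effect[1]
        prof_r = np.exp(-0.5 * ((rows - r0) / params.sigma_retention) ** 2)
        prof_d = np.exp(-0.5 * ((cols - d0) / params.sigma_drift) ** 2)
        m += a * np.outer(prof_r, prof_d)
    np.clip(m, 0.0, None, out=m)
    retention, drift = params.axes()
    return IMSSpectrum(sample_id, retention, drift, m)


def generate_labelled_spectra(
    params: SpectrumSimParams,
    n_per_class: int,
    effect_peaks: tuple[int, ...],
    effect_size: float,
    seed: int,
) -> tuple[list[IMSSpectrum], np.ndarray]:
    """A balanced labelled sample collection for pipeline experiments.

    ``effect_size = 1`` is the null construction: classes are then
    statistically identical by design.
    """
    spectra: list[IMSSpectrum] = []
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    for i, y in enumerate(labels):
        spectra.append(
            generate_spectrum(
                params,
                class_label=int(y),
                effect=(effect_peaks, effect_size),
                seed=subseed(seed, "sample", i),
                sample_id=f"SYN{i:04d}",
            )
        )
    return spectra, labels


def generate_null_feature_matrix(
    n_samples: int = 60, n_features: int = 2500, seed: int = 0
) -> FeatureMatrix:
    """Label-independent feature table for leakage demonstrations.

    Non-negative (exponential) intensities with balanced labels carrying
    no signal whatsoever; many features, few samples — the regime where
    selection leakage bites hardest.
    """
    rng = np.random.default_rng(seed)
    values = rng.exponential(1.0, (n_samples, n_features))
    labels = np.zeros(n_samples, dtype=int)
    labels[n_samples // 2 :] = 1
    return FeatureMatrix(
        sample_ids=[f"NULL{i:03d}" for i in range(n_samples)],
        feature_index=[(0, j) for j in range(n_features)],
        values=values,
        labels=labels,
    )


@dataclass(frozen=True)
class CohortSimParams:
    """Joint law of the simulated clinic population.

    Prevalences default to the study cohort: BV 12%, spontaneous preterm
    20% with 59% among BV-positive women, ~5% iatrogenic deliveries and
    ~4% unknown outcomes.  Preterm deliveries fall into the clinical
    categories with weights 2 : 6 : 10 : 21 (midtrimester : extreme :
    very : late); term deliveries are a discretised normal centred at
    39 + 3 (sd 9 days) truncated at 37 + 0.  ``effect_endpoint`` decides
    which patients' spectra carry the VOC class effect ("bv",
    "preterm" or "both").
    """

    n_patients: int = 216
    preterm_prevalence: float = 0.20
    bv_prevalence: float = 0.12
    p_preterm_given_bv: float = 0.59
    p_iatrogenic: float = 0.05
    p_unknown_delivery: float = 0.04
    effect_peaks: tuple[int, ...] = tuple(range(10))
    effect_size: float = 2.5
    effect_endpoint: str = "bv"
    swabs_per_patient: tuple[int, int] = (2, 3)
    sampling_window_days: tuple[int, int] = (70, 203)  # weeks 10 to 29+0
    preterm_category_weights: tuple[float, float, float, float] = (2, 6, 10, 21)
    term_mean_days: float = 276.0  # 39 + 3
    term_sd_days: float = 9.0
    patient_effect_sd: float = 0.0  # optional per-patient amplitude random effect
    spectrum: SpectrumSimParams = field(
        default_factory=lambda: SpectrumSimParams.with_random_peaks()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.preterm_prevalence,
            self.bv_prevalence,
            self.p_preterm_given_bv,
            self.p_iatrogenic,
            self.p_unknown_delivery,
        ):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.effect_endpoint not in ("bv", "preterm", "both"):
            raise ValueError(f"invalid effect_endpoint {self.effect_endpoint!r}")
        if not (0 <= self.p_preterm_given_no_bv <= 1):
            raise ValueError(
                "infeasible joint law: implied P(preterm | BV-) = "
                f"{self.p_preterm_given_no_bv:.3f} outside [0, 1]"
            )

    @property
    def p_preterm_given_no_bv(self) -> float:
        """Implied by the marginal preterm rate and the BV-conditional one."""
        if self.bv_prevalence >= 1:
            return 0.0
        return (
            self.preterm_prevalence - self.bv_prevalence * self.p_preterm_given_bv
        ) / (1 - self.bv_prevalence)


_CATEGORY_DAY_RANGES = (
    (112, 167),  # midtrimester miscarriage: 16+0 to 23+6
    (168, 195),  # extreme preterm
    (196, 223),  # very preterm
    (224, 258),  # late preterm
)


def _draw_delivery(rng: np.random.Generator, params: CohortSimParams, preterm: bool) -> int:
    if preterm:
        w = np.asarray(params.preterm_category_weights, dtype=float)
        cat = rng.choice(4, p=w / w.sum())
        lo, hi = _CATEGORY_DAY_RANGES[cat]
        return int(rng.integers(lo, hi + 1))
    while True:
        d = int(round(rng.normal(params.term_mean_days, params.term_sd_days)))
        if d >= 259:
            return d


def generate_cohort(
    params: CohortSimParams, with_spectra: bool = True
) -> tuple[list[Patient], dict[str, IMSSpectrum]]:
    """Simulate the clinic cohort with one spectrum per swab.

    Returns the patient records and a dict mapping each swab's
    sample_id to its spectrum.  Deterministic given ``params.seed``
    (named sub-streams per patient and per spectrum), so repeated calls
    and serialised outputs are byte-identical.  ``with_spectra=False``
    skips spectrum synthesis (cohort-only studies at large n).
    """
    patients: list[Patient] = []
    spectra: dict[str, IMSSpectrum] = {}
    seed = params.seed
    for i in range(params.n_patients):
        rng = sub_rng(seed, "patient", i)
        pid = f"P{i:04d}"
        bv = rng.random() < params.bv_prevalence
        u = rng.random()
        if u < params.p_iatrogenic:
            outcome = "iatrogenic"
        elif u < params.p_iatrogenic + params.p_unknown_delivery:
            outcome = "unknown"
        else:
            outcome = "spontaneous"
        p_preterm = params.p_preterm_given_bv if bv else params.p_preterm_given_no_bv
        preterm = rng.random() < p_preterm
        delivery: GestationalAge | None = None
        if outcome == "spontaneous":
            delivery = GestationalAge(_draw_delivery(rng, params, preterm))
        elif outcome == "iatrogenic":
            delivery = GestationalAge(int(rng.integers(196, 259)))  # medically indicated preterm
        lo, hi = params.sampling_window_days
        if delivery is not None:
            hi = min(hi, delivery.days - 7)
        hi = max(hi, lo + 1)
        n_swabs = int(rng.integers(params.swabs_per_patient[0], params.swabs_per_patient[1] + 1))
        days = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_swabs, replace=False))
        bv_swab = rng.integers(0, n_swabs) if bv else -1
        effect_on = (
            (params.effect_endpoint in ("bv", "both") and bv)
            or (params.effect_endpoint in ("preterm", "both") and preterm and outcome == "spontaneous")
        )
        amp_scale = (
            float(np.exp(rng.normal(0.0, params.patient_effect_sd)))
            if params.patient_effect_sd > 0
            else 1.0
        )
        swabs = []
        for j, d in enumerate(days):
            sample_id = f"{pid}S{j}"
            swabs.append(
                Swab(
                    patient_id=pid,
                    sample_id=sample_id,
                    gestation_at_sampling=GestationalAge(int(d)),
                    bv_status="positive" if j == bv_swab else "negative",
                )
            )
            if with_spectra:
                spectra[sample_id] = generate_spectrum(
                    params.spectrum,
                    class_label=int(effect_on),
                    effect=(params.effect_peaks, params.effect_size),
                    seed=subseed(seed, "spectrum", i, j),
                    sample_id=sample_id,
                    amplitude_scale=amp_scale,
                )
        patients.append(
            Patient(
                patient_id=pid,
                swabs=swabs,
                age_years=float(np.round(rng.normal(31.0, 4.9), 1)),
                bmi=float(np.round(rng.normal(26.5, 5.0), 1)),
                smoking="yes" if rng.random() < 0.12 else "no",
                indication=rng.choice(
                    ["previous_preterm", "midtrimester_loss", "cervical_surgery"]
                ),
                gestation_at_delivery=delivery,
                outcome=outcome,
            )
        )
    return patients, spectra
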