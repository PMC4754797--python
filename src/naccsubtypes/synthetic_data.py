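"""Synthetic cohort, response-pattern, BOLD and symptom-score generators.

No subject-level data from the original study are available, so this module
is the data source for the whole pipeline.  It emulates the statistical
structure the downstream analysis assumes:

* a cohort of healthy-control (HC) and depressed (MDD) subjects with age and
  gender;
* latent response subtypes (hyperactive / intermediate / suppressed /
  deactivated profiles) with 4-dimensional mean contrast vectors per phase,
  assigned independently of diagnosis;
* per-subject response patterns = subtype mean + i.i.d. Gaussian noise;
* ROI BOLD time series built with the same forward model the GLM inverts;
* 59 item-level ordinal symptom scores (21 HAM-D + 14 HAM-A + 10 MADRS +
  14 SHAPS) from a clipped, rounded latent Gaussian whose mean is a
  diagnosis baseline plus an optional (item, subtype) shift.

Everything is driven by explicit integer seeds; identical configuration and
seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Subject",
    "SubtypeSpec",
    "GeneratorConfig",
    "SCALE_ITEMS",
    "ALL_ITEMS",
    "ITEM_RANGES",
    "SCALE_OF_ITEM",
    "CONDITIONS",
    "DEFAULT_RIGHT_SPECS",
    "DEFAULT_LEFT_SPECS",
    "generate_cohort",
    "assign_subtypes",
    "generate_response_patterns",
    "generate_symptom_scores",
    "generate_bold",
    "patterns_to_matrix",
    "cohort_to_frame",
]

#: monetary conditions contrasted with $0, in fixed feature order
CONDITIONS = ("-$1.0", "-$0.25", "+$0.25", "+$1.0")

# ---------------------------------------------------------------------------
# Symptom scale registry: (item name, min score, max score) per scale.
# HAM-D items use their scale-defined 0-2 or 0-4 ranges, HAM-A items 0-4,
# MADRS items 0-6, SHAPS items scored 1-4 (not the original 0-1 scoring).
# ---------------------------------------------------------------------------
SCALE_ITEMS: dict[str, list[tuple[str, int, int]]] = {
    "HAM-D": [
        ("Depressed Mood (HAM-D)", 0, 4),
        ("Feelings of Guilt (HAM-D)", 0, 4),
        ("Suicidal ideation (HAM-D)", 0, 4),
        ("Insomnia Early (Sleep Onset Insomnia) (HAM-D)", 0, 2),
        ("Insomnia Middle (HAM-D)", 0, 2),
        ("Insomnia Late (Early Awakening) (HAM-D)", 0, 2),
        ("Work and Activities (HAM-D)", 0, 4),
        ("Retardation (HAM-D)", 0, 4),
        ("Agitation (HAM-D)", 0, 4),
        ("Anxiety Psychic (HAM-D)", 0, 4),
        ("Anxiety Somatic (HAM-D)", 0, 4),
        ("Somatic Symptoms Gastrointestinal (HAM-D)", 0, 2),
        ("Somatic Symptoms General (HAM-D)", 0, 2),
        ("Genital Symptoms (HAM-D)", 0, 2),
        ("Hypochondriasis (HAM-D)", 0, 4),
        ("Loss of Weight (HAM-D)", 0, 2),
        ("Insight (HAM-D)", 0, 2),
        ("Severity of diurnal variation (HAM-D)", 0, 2),
        ("Depersonalization and Derealization (HAM-D)", 0, 4),
        ("Paranoid Symptoms (HAM-D)", 0, 4),
        ("Obsessional and Compulsive Symptoms (HAM-D)", 0, 2),
    ],
    "HAM-A": [
        ("Anxious mood (HAM-A)", 0, 4),
        ("Tension (HAM-A)", 0, 4),
        ("Fears (HAM-A)", 0, 4),
        ("Insomnia (HAM-A)", 0, 4),
        ("Intellectual (HAM-A)", 0, 4),
        ("Depressed mood (HAM-A)", 0, 4),
        ("Somatic (Muscular) (HAM-A)", 0, 4),
        ("Somatic (Sensory) (HAM-A)", 0, 4),
        ("Cardiovascular Symptoms (HAM-A)", 0, 4),
        ("Respiratory Symptoms (HAM-A)", 0, 4),
        ("Gastrointestinal Symptoms (HAM-A)", 0, 4),
        ("Genitourinary Symptoms (HAM-A)", 0, 4),
        ("Autonomic Symptoms (HAM-A)", 0, 4),
        ("Behavior at Interview (HAM-A)", 0, 4),
    ],
    "MADRS": [
        ("Apparent Sadness (MADRS)", 0, 6),
        ("Reported Sadness (MADRS)", 0, 6),
        ("Inner tension (MADRS)", 0, 6),
        ("Reduced sleep (MADRS)", 0, 6),
        ("Reduced appetite (MADRS)", 0, 6),
        ("Concentration difficulties (MADRS)", 0, 6),
        ("Lassitude (MADRS)", 0, 6),
        ("Inability to feel (MADRS)", 0, 6),
        ("Pessimistic thoughts (MADRS)", 0, 6),
        ("Suicidal thoughts (MADRS)", 0, 6),
    ],
    "SHAPS": [
        ("I would enjoy my favourite television or radio programme (SHAPS)", 1, 4),
        ("I would enjoy being with my family or close friends (SHAPS)", 1, 4),
        ("I would find pleasure in my hobbies or pastimes (SHAPS)", 1, 4),
        ("I would be able to enjoy my favourite meal (SHAPS)", 1, 4),
        ("I would enjoy a warm bath or refreshing shower (SHAPS)", 1, 4),
        ("I would find pleasure in the scent of flowers (SHAPS)", 1, 4),
        ("I would enjoy seeing other people's smiling faces (SHAPS)", 1, 4),
        ("I would enjoy looking smart when I have made an effort with my appearance (SHAPS)", 1, 4),
        ("I would enjoy reading a book, magazine or newspaper (SHAPS)", 1, 4),
        ("I would enjoy a cup of tea or coffee or my favourite drink (SHAPS)", 1, 4),
        ("I would find pleasure in small things (SHAPS)", 1, 4),
        ("I would be able to appreciate a beautiful landscape or view (SHAPS)", 1, 4),
        ("I would get pleasure from helping others (SHAPS)", 1, 4),
        ("I would feel pleasure when I receive praise from other people (SHAPS)", 1, 4),
    ],
}

ALL_ITEMS: list[str] = [name for items in SCALE_ITEMS.values() for name, _, _ in items]
ITEM_RANGES: dict[str, tuple[int, int]] = {
    name: (lo, hi) for items in SCALE_ITEMS.values() for name, lo, hi in items
}
SCALE_OF_ITEM: dict[str, str] = {
    name: scale for scale, items in SCALE_ITEMS.items() for name, _, _ in items
}
assert len(ALL_ITEMS) == 59


@dataclass
class Subject:
    id: str
    diagnosis: str  # "HC" or "MDD"
    age: float
    gender: str  # "male" or "female"
    latent_subtype: str | None = None


@dataclass
class SubtypeSpec:
    """Latent subtype: mean 4-vectors (condition order ``CONDITIONS``) for the
    anticipation and outcome phases, and the mixing proportion."""

    label: str
    anticipation_means: tuple[float, float, float, float]
    outcome_means: tuple[float, float, float, float]
    mixing_proportion: float

    def __post_init__(self):
        if len(self.anticipation_means) != 4 or len(self.outcome_means) != 4:
            raise ValueError("subtype mean vectors must have length 4")


# Default subtype profiles.  The shapes follow the qualitative patterns the
# analysis is designed to recover (hyperactive to both gain and loss
# anticipation; intermediate with gain > loss; suppressed below the neutral
# condition; a fourth deactivated profile for the left ROI); the magnitudes
# are calibrated choices in percent-signal-change beta units.
DEFAULT_RIGHT_SPECS: tuple[SubtypeSpec, ...] = (
    SubtypeSpec("hyperactive", (0.25, 0.25, 0.30, 0.35), (-0.20, -0.10, 0.05, 0.05), 0.30),
    SubtypeSpec("intermediate", (0.00, 0.00, 0.10, 0.15), (-0.12, -0.05, 0.03, 0.08), 0.45),
    SubtypeSpec("suppressed", (-0.20, -0.20, -0.15, -0.15), (-0.02, -0.01, 0.01, 0.02), 0.25),
)

DEFAULT_LEFT_SPECS: tuple[SubtypeSpec, ...] = (
    SubtypeSpec("hyperactive", (0.25, 0.25, 0.30, 0.35), (-0.22, -0.10, 0.05, 0.06), 0.30),
    SubtypeSpec("intermediate", (0.00, 0.00, 0.10, 0.15), (-0.12, -0.05, 0.03, 0.08), 0.35),
    SubtypeSpec("suppressed", (-0.20, -0.20, -0.15, -0.15), (-0.02, -0.01, 0.01, 0.02), 0.20),
    SubtypeSpec("deactivated", (-0.15, -0.12, -0.10, 0.00), (-0.03, -0.01, 0.00, 0.02), 0.15),
)


@dataclass
class GeneratorConfig:
    n_hc: int = 45
    n_mdd: int = 44
    subtype_specs: tuple[SubtypeSpec, ...] = DEFAULT_RIGHT_SPECS
    response_noise_sd: float = 0.08
    symptom_effects: dict = field(default_factory=dict)
    bold_noise_sd: float = 0.1
    female_proportion: float = 0.73
    age_range: tuple[float, float] = (20.0, 55.0)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_hc < 0 or self.n_mdd < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.response_noise_sd < 0 or self.bold_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def _check_proportions(specs):
    if not specs:
        raise ValueError("at least one subtype spec is required")
    total = sum(s.mixing_proportion for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixing proportions must sum to 1 (got {total})")


def generate_cohort(
    n_hc: int,
    n_mdd: int,
    seed: int,
    female_proportion: float = 0.73,
    age_range: tuple[float, float] = (20.0, 55.0),
) -> list[Subject]:
    """Draw a cohort of HC and MDD subjects with age and gender.

    Genders are Bernoulli draws with the given female proportion (the default
    mirrors the roughly three-quarters-female composition of the study
    cohort), ages uniform on ``age_range``.
    """
    if n_hc < 0 or n_mdd < 0:
        raise ValueError("cohort sizes must be non-negative")
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_hc + n_mdd):
        diagnosis = "HC" if i < n_hc else "MDD"
        age = float(rng.uniform(*age_range))
        gender = "female" if rng.random() < female_proportion else "male"
        subjects.append(Subject(id=f"S{i + 1:03d}", diagnosis=diagnosis, age=age, gender=gender))
    return subjects


def cohort_to_frame(cohort: list[Subject]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.id, s.diagnosis, s.age, s.gender, s.latent_subtype) for s in cohort],
        columns=["subject", "diagnosis", "age", "gender", "latent_subtype"],
    )


def assign_subtypes(
    cohort: list[Subject], specs: tuple[SubtypeSpec, ...], seed: int
) -> list[Subject]:
    """Assign a latent subtype to every subject, independently of diagnosis."""
    _check_proportions(specs)
    rng = np.random.default_rng(seed)
    labels = [s.label for s in specs]
    probs = np.array([s.mixing_proportion for s in specs])
    probs = probs / probs.sum()
    draws = rng.choice(len(labels), size=len(cohort), p=probs)
    return [replace(subj, latent_subtype=labels[d]) for subj, d in zip(cohort, draws)]


def generate_response_patterns(
    cohort: list[Subject],
    specs: tuple[SubtypeSpec, ...],
    noise_sd: float,
    seed: int,
    roi: str = "right",
) -> pd.DataFrame:
    """Per-subject contrast 4-vectors for both phases, long format.

    Returns a DataFrame with columns ``subject, roi, phase, condition, beta``;
    each subject's vector is its subtype's phase mean plus i.i.d. Gaussian
    noise, the two phases drawn independently.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    by_label = {s.label: s for s in specs}
    for subj in cohort:
        if subj.latent_subtype is None:
            raise ValueError(f"subject {subj.id} has no latent subtype")
        if subj.latent_subtype not in by_label:
            raise ValueError(f"subject {subj.id} has unknown subtype {subj.latent_subtype!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for subj in cohort:
        spec = by_label[subj.latent_subtype]
        for phase, means in (
            ("anticipation", spec.anticipation_means),
            ("outcome", spec.outcome_means),
        ):
            vec = np.asarray(means, dtype=float) + rng.normal(0.0, noise_sd, size=4)
            for cond, beta in zip(CONDITIONS, vec):
                rows.append((subj.id, roi, phase, cond, float(beta)))
    return pd.DataFrame(rows, columns=["subject", "roi", "phase", "condition", "beta"])


def patterns_to_matrix(
    patterns: pd.DataFrame, phase: str = "anticipation", roi: str | None = None
) -> tuple[np.ndarray, list[str]]:
    """Pivot long-format patterns into an n-subject x 4 matrix (condition
    order ``CONDITIONS``) plus the subject id list."""
    df = patterns[patterns["phase"] == phase]
    if roi is not None:
        df = df[df["roi"] == roi]
    wide = df.pivot_table(index="subject", columns="condition", values="beta", sort=False)
    wide = wide[list(CONDITIONS)]
    if wide.isna().any().any():
        raise ValueError("missing condition betas for some subjects")
    return wide.to_numpy(), list(wide.index)


def generate_symptom_scores(
    cohort: list[Subject],
    effects: dict[tuple[str, str], float] | None,
    seed: int,
    latent_sd_frac: float = 0.25,
    hc_baseline_frac: float = 0.10,
    mdd_baseline_frac: float = 0.40,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """59 item-level ordinal scores per subject.

    Each score is a latent Gaussian, rounded and clipped to the item's scale
    range.  The latent mean is a diagnosis baseline (a fraction of the scale
    span above the minimum; MDD above HC) plus the ``(item, subtype)`` shift
    from ``effects`` in raw score units.  ``missing_rate`` > 0 blanks scores
    at random (off by default; downstream analyses reject missing rows).
    """
    effects = effects or {}
    for item, _subtype in effects:
        if item not in ITEM_RANGES:
            raise ValueError(f"unknown symptom item {item!r}")
    rng = np.random.default_rng(seed)
    records = []
    for subj in cohort:
        base_frac = mdd_baseline_frac if subj.diagnosis == "MDD" else hc_baseline_frac
        rec = {"subject": subj.id}
        for item in ALL_ITEMS:
            lo, hi = ITEM_RANGES[item]
            span = hi - lo
            mean = lo + base_frac * span + effects.get((item, subj.latent_subtype), 0.0)
            latent = rng.normal(mean, latent_sd_frac * span)
            score = int(np.clip(np.rint(latent), lo, hi))
            if missing_rate > 0 and rng.random() < missing_rate:
                rec[item] = np.nan
            else:
                rec[item] = score
        records.append(rec)
    return pd.DataFrame.from_records(records)


def generate_bold(
    events,
    true_betas: dict[str, float],
    tr: float,
    n_vols: int,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """ROI BOLD series from the forward model the GLM inverts.

    ``events`` is a list of :class:`~naccsubtypes.task_design.Trial`; the
    series is the task design matrix times ``true_betas`` (keyed by regressor
    name, absent names = 0) plus white noise in percent-signal units.
    """
    from . import roi_glm

    design = roi_glm.build_design_matrix(events, tr=tr, n_vols=n_vols)
    unknown = set(true_betas) - set(design.columns)
    if unknown:
        raise ValueError(f"unknown regressor names: {sorted(unknown)}")
    beta = np.array([true_betas.get(c, 0.0) for c in design.columns])
    rng = np.random.default_rng(seed)
    return design.values @ beta + rng.normal(0.0, noise_sd, size=n_vols)
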