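"""Desk-scale synthetic cohorts for end-to-end experiments.

Builders that wire the synthetic generator, preprocessing and feature
extraction into per-subject ``SubjectData`` ready for LOOCV.  Two kinds
of ground truth are supported:

* the per-minute reference index produced by the patient generator
  (state-driven, the analogue of a clinical reference monitor); or
* a fixed smooth map from the four features to a 0–100 index plus
  Gaussian noise, used for model-recovery experiments where the target
  must be exactly learnable from the inputs.
"""

from __future__ import annotations

import numpy as np

from .evaluate import SubjectData
from .preprocess import Epoch, PreprocessConfig, preprocess_pipeline
from .spectral import extract_features
from .synthetic import StateSpec, default_state_specs, generate_patient, inject_artifacts

__all__ = [
    "feature_reference_map",
    "standard_profile",
    "extract_subject_features",
    "build_cohort",
    "build_map_cohort",
    "build_feature_space_cohort",
]

#: Feature scales used by the smooth reference map: (center, half-range)
#: spanning roughly deep → awake on the default synthetic states.
_MAP_SCALES = {
    "pe": (0.959, 0.020),
    "br": (-0.400, 0.150),
    "sef95": (30.0, 9.0),
    "sfs": (1.150, 0.320),
}
_MAP_WEIGHTS = np.array([0.35, 0.20, 0.30, 0.15])
_MAP_GAIN = 1.8


def feature_reference_map(X: np.ndarray) -> np.ndarray:
    """Fixed smooth map (features → 0–100 index), increasing with arousal.

    Each feature is centered and scaled to its typical deep→awake span,
    SFS enters with a negative sign (it grows with depth), and a logistic
    squashes the weighted sum onto (0, 100).
    """
    X = np.atleast_2d(np.asarray(X, float))
    z = np.column_stack(
        [
            (X[:, 0] - _MAP_SCALES["pe"][0]) / _MAP_SCALES["pe"][1],
            (X[:, 1] - _MAP_SCALES["br"][0]) / _MAP_SCALES["br"][1],
            (X[:, 2] - _MAP_SCALES["sef95"][0]) / _MAP_SCALES["sef95"][1],
            -(X[:, 3] - _MAP_SCALES["sfs"][0]) / _MAP_SCALES["sfs"][1],
        ]
    )
    s = z @ _MAP_WEIGHTS
    return 100.0 / (1.0 + np.exp(-_MAP_GAIN * s))


def standard_profile(
    specs: dict[str, StateSpec] | None = None, minutes: tuple[int, int, int, int] = (4, 4, 6, 4)
) -> list[tuple[StateSpec, int]]:
    """An induction→maintenance→emergence profile touching all four states."""
    specs = specs or default_state_specs()
    m_aw, m_li, m_ge, m_de = minutes
    return [
        (specs["awake"], m_aw),
        (specs["light"], m_li),
        (specs["general"], m_ge),
        (specs["deep"], m_de),
        (specs["general"], max(m_ge // 2, 1)),
        (specs["light"], max(m_li // 2, 1)),
        (specs["awake"], max(m_aw // 2, 1)),
    ]


def extract_subject_features(epochs: list[Epoch]) -> np.ndarray:
    return np.array([extract_features(ep).as_array() for ep in epochs])


def build_cohort(
    n_subjects: int,
    seed: int,
    fs: float = 128.0,
    minutes: tuple[int, int, int, int] = (4, 4, 6, 4),
    with_artifacts: bool = True,
    preprocess: bool = True,
) -> list[SubjectData]:
    """Generate subjects end to end: EEG → (artifacts) → pipeline → features.

    Targets are each subject's generated reference-index minutes, aligned
    to the epochs that survive preprocessing.
    """
    rng = np.random.default_rng(seed)
    specs = default_state_specs()
    cohort: list[SubjectData] = []
    for i in range(n_subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        patient = generate_patient(standard_profile(specs, minutes), fs, sub_seed)
        record = patient.record
        if with_artifacts:
            record, _ = inject_artifacts(
                record, eog_rate=1.0, emg_rate=0.5, outlier_rate=0.5, seed=sub_seed + 1
            )
        if preprocess:
            epochs, _ = preprocess_pipeline(record, PreprocessConfig())
        else:
            from .preprocess import epoch_record, resample

            epochs, _ = epoch_record(resample(record, 100.0))
        feats = extract_subject_features(epochs)
        targets = patient.ref_index.values[[ep.minute_index for ep in epochs]]
        cohort.append(SubjectData(feats, targets, subject_id=f"subj{i + 1:02d}"))
    return cohort


def build_map_cohort(
    n_subjects: int,
    seed: int,
    noise_sd: float = 3.0,
    fs: float = 128.0,
    minutes: tuple[int, int, int, int] = (4, 4, 6, 4),
) -> list[SubjectData]:
    """Cohort whose targets are ``feature_reference_map(features) + noise``.

    The reference index is, by construction, a fixed smooth function of
    the four extracted features plus Gaussian noise (SD ``noise_sd``
    index units), so a well-behaved fusion model can recover it up to the
    noise floor.
    """
    rng = np.random.default_rng(seed)
    base = build_cohort(
        n_subjects, seed=int(rng.integers(0, 2**31 - 1)), fs=fs, minutes=minutes,
        with_artifacts=False, preprocess=False,
    )
    out = []
    for s in base:
        y = feature_reference_map(s.features) + rng.normal(0.0, noise_sd, s.targets.size)
        out.append(SubjectData(s.features, np.clip(y, 0, 100), subject_id=s.subject_id))
    return out


def _z_to_features(z: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [
            _MAP_SCALES["pe"][0] + z[:, 0] * _MAP_SCALES["pe"][1],
            _MAP_SCALES["br"][0] + z[:, 1] * _MAP_SCALES["br"][1],
            _MAP_SCALES["sef95"][0] + z[:, 2] * _MAP_SCALES["sef95"][1],
            _MAP_SCALES["sfs"][0] - z[:, 3] * _MAP_SCALES["sfs"][1],
        ]
    )


def build_feature_space_cohort(
    n_subjects: int,
    minutes_per_subject: int,
    seed: int,
    noise_sd: float = 2.0,
    weights: np.ndarray | None = None,
    gain: float = 2.2,
) -> list[SubjectData]:
    """Cohort drawn directly in feature space with independent features.

    Used by ablation experiments: the four standardized features are
    independent and, with the default equal weights, each carries the
    same share of the information about the target, so removing any
    input must cost predictive skill.  Targets are a logistic map of the
    weighted features plus Gaussian noise, clipped to [0, 100].
    """
    rng = np.random.default_rng(seed)
    w = np.full(4, 0.25) if weights is None else np.asarray(weights, float)
    cohort = []
    for i in range(n_subjects):
        z = rng.uniform(-1.8, 1.8, size=(minutes_per_subject, 4))
        s = z @ w
        y = 100.0 / (1.0 + np.exp(-gain * s)) + rng.normal(0, noise_sd, minutes_per_subject)
        cohort.append(
            SubjectData(_z_to_features(z), np.clip(y, 0, 100), subject_id=f"fsubj{i + 1:02d}")
        )
    return cohort


def build_balanced_cohort(
    n_subjects: int,
    minutes_per_subject: int,
    seed: int,
    noise_sd: float = 2.0,
    gain: float = 1.8,
) -> list[SubjectData]:
    """Cohort whose reference-index minutes are balanced across the four
    anesthesia-state bands (¼ each).

    The target is drawn state-uniform (then uniform within the state's
    index band) and the feature vector is constructed to be consistent
    with it through the logistic map, plus directions orthogonal to the
    map's weights filled with independent noise.  Balanced band priors
    make the chance hit rate of any target-independent predictor exactly
    the class-prior rate Σ pᵢ² = 0.25, which permutation-null experiments
    rely on.
    """
    rng = np.random.default_rng(seed)
    bands = [(2.0, 38.0), (41.0, 59.0), (61.0, 79.0), (81.0, 98.0)]
    w = np.full(4, 0.25)
    ww = w / (w @ w)
    cohort = []
    for i in range(n_subjects):
        m = minutes_per_subject
        band_idx = rng.integers(0, 4, size=m)
        lo = np.array([bands[b][0] for b in band_idx])
        hi = np.array([bands[b][1] for b in band_idx])
        y = rng.uniform(lo, hi)
        s = np.log(y / (100.0 - y)) / gain
        z = np.outer(s, ww) + rng.uniform(-0.8, 0.8, size=(m, 4)) @ _ortho_complement(w).T @ _ortho_complement(w)
        y_obs = np.clip(y + rng.normal(0, noise_sd, m), 0, 100)
        cohort.append(SubjectData(_z_to_features(z), y_obs, subject_id=f"bsubj{i + 1:02d}"))
    return cohort


def _ortho_complement(w: np.ndarray) -> np.ndarray:
    """Rows spanning the subspace orthogonal to ``w``."""
    q, _ = np.linalg.qr(np.column_stack([w, np.eye(w.size)]))
    return q[:, 1 : w.size].T
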