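"""Synthetic multimodal cohorts and delimited-text dataset I/O.

The generator emulates a small case-control neuroimaging cohort in which a
handful of clinical questionnaire scores separate the groups strongly while
the two imaging modalities (EEG spectral power, PET regional glucose uptake)
carry only weak, diffuse per-feature signal.  Clinical features are drawn
per group from Gaussians parameterised by published-style group summaries;
EEG and PET features are correlated Gaussians (exchangeable correlation
within a modality) with a small group mean shift expressed as Cohen's d.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalFeature",
    "CohortSpec",
    "MultimodalDataset",
    "REFERENCE_CLINICAL_SUMMARIES",
    "null_clinical_features",
    "generate_cohort",
    "load_dataset",
    "save_dataset",
]

POSITIVE_LABEL = +1  # cases (IGD)
NEGATIVE_LABEL = -1  # healthy controls


@dataclass(frozen=True)
class ClinicalFeature:
    """Group-level summary for one questionnaire score."""

    name: str
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float


#: Default clinical feature summaries: group means/SDs of the demographic and
#: questionnaire battery for a 28-case / 24-control internet-gaming-disorder
#: cohort (age; Young's Internet Addiction Test; depression BDI; anxiety BAI;
#: behavioural inhibition/activation BIS/BAS; aggression AQ; impulsiveness
#: BIS-11; stress PWI; emotional control ECQ; resilience CD-RISC; quality of
#: life WHOQOL-BREF).
REFERENCE_CLINICAL_SUMMARIES: tuple[ClinicalFeature, ...] = (
    ClinicalFeature("Age", 24.21, 5.01, 24.25, 2.72),
    ClinicalFeature("Y-IAT", 63.21, 17.00, 31.70, 9.38),
    ClinicalFeature("BDI", 16.69, 11.16, 3.88, 4.03),
    ClinicalFeature("BAI", 13.40, 12.24, 5.01, 6.02),
    ClinicalFeature("BIS", 21.47, 3.75, 16.97, 4.42),
    ClinicalFeature("BAS", 35.16, 7.43, 31.90, 6.74),
    ClinicalFeature("AQ", 73.43, 18.22, 56.17, 13.82),
    ClinicalFeature("BIS-11", 66.50, 11.12, 54.88, 7.69),
    ClinicalFeature("PWI", 64.42, 26.90, 29.95, 15.73),
    ClinicalFeature("ECQ", 10.64, 3.87, 10.33, 2.77),
    ClinicalFeature("CD-RISC", 49.58, 17.32, 72.26, 9.29),
    ClinicalFeature("WHOQOL-BREF", 48.85, 9.35, 59.87, 7.09),
)

#: Age shows no group difference and Y-IAT is quasi-definitional for the case
#: label, so both are generated but kept out of the default classifier block.
DEFAULT_EXCLUDED_CLINICAL = ("Age", "Y-IAT")


def null_clinical_features(
    base: Sequence["ClinicalFeature"] = None,
) -> tuple["ClinicalFeature", ...]:
    """Clinical summaries with the group difference removed.

    Both groups draw from the control-group distribution of each feature;
    useful for cohorts whose signal should live in the imaging modalities
    only (e.g. kernel-weight recovery experiments).
    """
    feats = REFERENCE_CLINICAL_SUMMARIES if base is None else tuple(base)
    return tuple(
        ClinicalFeature(f.name, f.control_mean, f.control_sd,
                        f.control_mean, f.control_sd)
        for f in feats
    )

EEG_CHANNELS = (
    "FP1", "F3", "F7", "Fz", "FP2", "F4", "F8", "T3", "C3", "Cz",
    "T4", "C4", "T5", "P3", "O1", "Pz", "T6", "P4", "O2",
)
EEG_BANDS = ("delta", "theta", "alpha", "beta", "highbeta", "gamma", "highgamma")
EEG_POWER_TYPES = ("abs", "rel")


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-group multimodal cohort.

    Parameters
    ----------
    n_case, n_control
        Group sizes (defaults 28 cases / 24 controls).
    clinical_features
        Per-feature group summaries used for the clinical block.
    eeg_shape
        (channels, bands, power types); the EEG block has their product
        as feature count (19 x 7 x 2 = 266 by default).
    n_pet_rois
        Number of PET regions of interest (90 AAL regions by default).
    weak_effect_size
        Cohen's d of the group shift for ordinary EEG/PET features.
    strong_fraction, strong_effect_size
        A small fraction of EEG/PET features receives a larger shift.
    within_modality_correlation
        Exchangeable (compound-symmetric) correlation rho within each of
        the EEG and PET blocks.
    clip_non_negative
        Clip negative clinical draws at 0 (questionnaire scales are
        bounded below); recorded in provenance when active.
    exclude_from_features
        Clinical columns generated but left out of the classifier block
        (kept in ``covariates``).
    seed
        Base seed; generation is bit-reproducible given (spec, seed).
    """

    n_case: int = 28
    n_control: int = 24
    clinical_features: Sequence[ClinicalFeature] = REFERENCE_CLINICAL_SUMMARIES
    eeg_shape: tuple[int, int, int] = (19, 7, 2)
    n_pet_rois: int = 90
    weak_effect_size: float = 0.1
    strong_fraction: float = 0.05
    strong_effect_size: float = 0.4
    eeg_effect_size: float | None = None  # override weak_effect_size for EEG
    pet_effect_size: float | None = None  # override weak_effect_size for PET
    effect_direction: str = "coherent"    # "coherent" or "random" shift signs
    within_modality_correlation: float = 0.3
    clip_non_negative: bool = True
    exclude_from_features: Sequence[str] = DEFAULT_EXCLUDED_CLINICAL
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 2:
            raise ValueError(f"n_case must be >= 2, got {self.n_case}")
        if self.n_control < 2:
            raise ValueError(f"n_control must be >= 2, got {self.n_control}")
        for f in self.clinical_features:
            if f.case_sd <= 0 or f.control_sd <= 0:
                raise ValueError(f"clinical_features: SD must be > 0 for {f.name!r}")
        if self.weak_effect_size < 0:
            raise ValueError(f"weak_effect_size must be >= 0, got {self.weak_effect_size}")
        for name in ("eeg_effect_size", "pet_effect_size"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.effect_direction not in ("coherent", "random"):
            raise ValueError(
                f"effect_direction must be 'coherent' or 'random', "
                f"got {self.effect_direction!r}"
            )
        if self.strong_effect_size < 0:
            raise ValueError(f"strong_effect_size must be >= 0, got {self.strong_effect_size}")
        if not 0.0 <= self.strong_fraction <= 1.0:
            raise ValueError(f"strong_fraction must be in [0, 1], got {self.strong_fraction}")
        rho = self.within_modality_correlation
        if not 0.0 <= rho < 1.0:
            raise ValueError(f"within_modality_correlation must be in [0, 1), got {rho}")
        if any(n <= 0 for n in self.eeg_shape) or self.n_pet_rois <= 0:
            raise ValueError("eeg_shape entries and n_pet_rois must be positive")


@dataclass
class MultimodalDataset:
    """Aligned per-subject feature blocks for several modalities.

    ``y`` uses +1 for cases (the positive class) and -1 for controls.  All
    blocks share row count and row order; missing values are rejected.
    """

    subject_ids: tuple[str, ...]
    y: np.ndarray
    blocks: dict[str, pd.DataFrame]
    covariates: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.subject_ids)
        if self.y.shape != (n,):
            raise ValueError(f"labels have shape {self.y.shape}, expected ({n},)")
        if not np.all(np.isin(self.y, [POSITIVE_LABEL, NEGATIVE_LABEL])):
            raise ValueError("labels must be +1 (case) or -1 (control)")
        if (self.y == POSITIVE_LABEL).sum() < 1 or (self.y == NEGATIVE_LABEL).sum() < 1:
            raise ValueError("need at least one subject per class")
        for name, block in self.blocks.items():
            if len(block) != n:
                raise ValueError(f"block {name!r} has {len(block)} rows, expected {n}")
            if list(block.index) != list(self.subject_ids):
                raise ValueError(f"block {name!r} row order does not match subject_ids")
            if block.isna().any().any():
                raise ValueError(f"block {name!r} contains missing values")

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.blocks)

    def stacked(self, modalities: Sequence[str] | None = None) -> pd.DataFrame:
        """Concatenate feature blocks column-wise into one wide matrix."""
        names = list(modalities) if modalities is not None else list(self.blocks)
        parts = []
        for m in names:
            block = self.blocks[m]
            parts.append(block.add_prefix(f"{m}:"))
        return pd.concat(parts, axis=1)


def _feature_names_eeg(shape: tuple[int, int, int]) -> list[str]:
    n_ch, n_bands, n_types = shape
    chans = list(EEG_CHANNELS[:n_ch])
    if len(chans) < n_ch:
        chans += [f"CH{i}" for i in range(len(chans), n_ch)]
    bands = list(EEG_BANDS[:n_bands])
    if len(bands) < n_bands:
        bands += [f"band{i}" for i in range(len(bands), n_bands)]
    types = list(EEG_POWER_TYPES[:n_types])
    if len(types) < n_types:
        types += [f"type{i}" for i in range(len(types), n_types)]
    return [f"{c}_{b}_{t}" for t in types for b in bands for c in chans]


def _correlated_block(
    rng: np.random.Generator, n: int, p: int, rho: float
) -> np.ndarray:
    # Exchangeable correlation via a single shared factor per subject:
    # x_j = sqrt(rho) * g + sqrt(1-rho) * e_j gives corr(x_j, x_k) = rho.
    shared = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, p))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise


def _weak_block(
    rng: np.random.Generator,
    n_case: int,
    n_control: int,
    p: int,
    rho: float,
    weak_d: float,
    strong_fraction: float,
    strong_d: float,
    direction: str = "coherent",
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated unit-variance block with a per-feature group mean shift.

    With ``direction="coherent"`` all features of the block shift the same
    way (the pattern of global band-power or metabolism differences), which
    keeps the multivariate signal weak: the shift direction coincides with
    the shared-factor noise axis.  ``"random"`` draws an independent sign
    per feature, which makes the aggregate far easier to classify than each
    feature's effect size suggests.

    Returns the (n, p) matrix (cases first) and the per-feature shifts.
    """
    n = n_case + n_control
    x = _correlated_block(rng, n, p, rho)
    d = np.full(p, weak_d)
    n_strong = int(round(strong_fraction * p))
    if n_strong > 0:
        strong_idx = rng.choice(p, size=n_strong, replace=False)
        d[strong_idx] = strong_d
    if direction == "coherent":
        signs = np.ones(p)
    else:
        signs = rng.choice([-1.0, 1.0], size=p)
    shift = signs * d  # group difference in SD units (total sd is 1)
    x[:n_case] += shift
    return x, shift


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> MultimodalDataset:
    """Draw a synthetic multimodal cohort from ``spec``.

    Cases come first in the subject order, then controls.  The draw is
    bit-reproducible given (spec, seed); ``seed`` overrides ``spec.seed``
    when given.
    """
    spec.validate()
    base_seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    rng_clin, rng_eeg, rng_pet = (np.random.default_rng(s) for s in ss.spawn(3))

    n_case, n_control = spec.n_case, spec.n_control
    n = n_case + n_control
    subject_ids = tuple(f"S{i + 1:03d}" for i in range(n))
    y = np.concatenate(
        [np.full(n_case, POSITIVE_LABEL, float), np.full(n_control, NEGATIVE_LABEL, float)]
    )

    clipped_any = False
    clin_cols: dict[str, np.ndarray] = {}
    for f in spec.clinical_features:
        case = rng_clin.normal(f.case_mean, f.case_sd, size=n_case)
        ctrl = rng_clin.normal(f.control_mean, f.control_sd, size=n_control)
        col = np.concatenate([case, ctrl])
        if spec.clip_non_negative:
            if (col < 0).any():
                clipped_any = True
            col = np.clip(col, 0.0, None)
        clin_cols[f.name] = col
    clinical = pd.DataFrame(clin_cols, index=list(subject_ids))

    excluded = [c for c in spec.exclude_from_features if c in clinical.columns]
    covariates = clinical[excluded].copy() if excluded else None
    clinical_block = clinical.drop(columns=excluded)

    eeg_d = spec.weak_effect_size if spec.eeg_effect_size is None else spec.eeg_effect_size
    pet_d = spec.weak_effect_size if spec.pet_effect_size is None else spec.pet_effect_size
    p_eeg = int(np.prod(spec.eeg_shape))
    eeg_values, eeg_shift = _weak_block(
        rng_eeg, n_case, n_control, p_eeg, spec.within_modality_correlation,
        eeg_d, spec.strong_fraction, spec.strong_effect_size,
        direction=spec.effect_direction,
    )
    eeg = pd.DataFrame(eeg_values, index=list(subject_ids),
                       columns=_feature_names_eeg(spec.eeg_shape))

    pet_values, pet_shift = _weak_block(
        rng_pet, n_case, n_control, spec.n_pet_rois, spec.within_modality_correlation,
        pet_d, spec.strong_fraction, spec.strong_effect_size,
        direction=spec.effect_direction,
    )
    pet = pd.DataFrame(pet_values, index=list(subject_ids),
                       columns=[f"ROI_{i + 1:03d}" for i in range(spec.n_pet_rois)])

    provenance = {
        "source": "synthetic",
        "seed": int(base_seed),
        "n_case": n_case,
        "n_control": n_control,
        "clipped_clinical_draws": bool(spec.clip_non_negative and clipped_any),
        "excluded_clinical": excluded,
        "eeg_mean_shift_sd_units": eeg_shift.tolist(),
        "pet_mean_shift_sd_units": pet_shift.tolist(),
    }
    return MultimodalDataset(
        subject_ids=subject_ids,
        y=y,
        blocks={"clinical": clinical_block, "eeg": eeg, "pet": pet},
        covariates=covariates,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O


def _read_feature_table(path: Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{path.name}: non-numeric value in column {col!r}, "
                    f"row {bad[0]!r}"
                )
            df[col] = coerced
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"{path.name}: missing values in rows {rows}")
    return df


def load_dataset(manifest: str | Path | Mapping, base_dir: str | Path | None = None) -> MultimodalDataset:
    """Load an aligned multimodal dataset from delimited-text files.

    ``manifest`` is a JSON file (or mapping) with keys ``modalities``
    (modality name -> file), ``labels`` (file with a subject-id column and a
    label column), ``label_column``, ``positive_class`` and
    ``negative_class``; optional ``sep`` (default ``,``).  Subject order is
    taken from the label file; every modality file must cover all of its
    subjects.
    """
    if isinstance(manifest, (str, Path)):
        manifest_path = Path(manifest)
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        if base_dir is None:
            base_dir = manifest_path.parent
    base = Path(base_dir) if base_dir is not None else Path(".")
    sep = manifest.get("sep", ",")

    labels_df = pd.read_csv(base / manifest["labels"], sep=sep, index_col=0)
    labels_df.index = labels_df.index.astype(str)
    label_col = manifest["label_column"]
    if label_col not in labels_df.columns:
        raise ValueError(f"label column {label_col!r} not found in {manifest['labels']}")
    pos = str(manifest["positive_class"])
    neg = str(manifest["negative_class"])
    raw = labels_df[label_col].astype(str)
    unknown = sorted(set(raw) - {pos, neg})
    if unknown:
        raise ValueError(
            f"label values {unknown} are outside the declared classes "
            f"({pos!r}, {neg!r})"
        )
    subject_ids = tuple(labels_df.index)
    y = np.where(raw.to_numpy() == pos, POSITIVE_LABEL, NEGATIVE_LABEL).astype(float)

    blocks: dict[str, pd.DataFrame] = {}
    for modality, fname in manifest["modalities"].items():
        df = _read_feature_table(base / fname, sep)
        missing = [s for s in subject_ids if s not in df.index]
        if missing:
            raise ValueError(
                f"modality {modality!r} ({fname}) is missing subjects: {missing}"
            )
        extra = sorted(set(df.index) - set(subject_ids))
        if extra:
            warnings.warn(
                f"modality {modality!r} has {len(extra)} subjects absent from the "
                "label file; they are dropped", stacklevel=2,
            )
        blocks[modality] = df.loc[list(subject_ids)]

    provenance = {"source": "files", "manifest": {k: str(v) for k, v in manifest.items()
                                                  if k != "modalities"},
                  "files": {m: str(f) for m, f in manifest["modalities"].items()}}
    return MultimodalDataset(subject_ids=subject_ids, y=y, blocks=blocks,
                             provenance=provenance)


def save_dataset(dataset: MultimodalDataset, out_dir: str | Path,
                 positive_class: str = "IGD", negative_class: str = "HC",
                 sep: str = ",") -> Path:
    """Write one delimited file per modality plus labels and a manifest.

    Returns the manifest path; ``load_dataset`` on it round-trips the data.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "modalities": {},
        "labels": "labels.csv",
        "label_column": "group",
        "positive_class": positive_class,
        "negative_class": negative_class,
        "sep": sep,
    }
    for modality, block in dataset.blocks.items():
        fname = f"{modality}.csv"
        block.to_csv(out / fname, sep=sep, index_label="subject_id")
        manifest["modalities"][modality] = fname
    labels = pd.DataFrame(
        {"group": np.where(dataset.y > 0, positive_class, negative_class)},
        index=list(dataset.subject_ids),
    )
    labels.to_csv(out / "labels.csv", sep=sep, index_label="subject_id")
    if dataset.covariates is not None:
        dataset.covariates.to_csv(out / "covariates.csv", sep=sep,
                                  index_label="subject_id")
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path
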