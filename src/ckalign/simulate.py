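"""Synthetic morphometric-style feature tables.

Emulates the statistical structure the metric-learning method assumes,
so every stage is testable without access to a clinical cohort:

* three diagnostic classes whose subject counts default to a 231:379:286
  ratio, with several scans per subject (within-subject repeats are
  correlated, making subject-grouped cross-validation meaningful);
* a low-dimensional discriminative signal subspace embedded among many
  nuisance dimensions;
* feature blocks on heterogeneous scales mimicking FreeSurfer output
  (region volumes in mm^3, surface areas in mm^2, cortical thickness
  statistics in mm) — 310 features at the default full scale;
* the middle class placed between the outer two in signal space
  (``intermediate_mix``), mimicking mild cognitive impairment as an
  intermediate stage between healthy controls and Alzheimer's disease;
* optional non-linear class geometry (XOR or annulus) for exercising the
  multi-layer pretraining path.

Class-conditional Gaussians with shared covariance in signal space are the
default generative model; ground-truth metadata (true signal columns,
class means) is returned for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FeatureMatrix
from .exceptions import ParameterError

__all__ = ["GeneratorSpec", "generate", "make_fixture", "FIXTURE_NAMES"]

#: FreeSurfer-like feature blocks: (name, count, typical location, scale).
#: Volumes are TIV-normalized fractions (dimensionless, small), areas mm^2,
#: thicknesses mm. The cortical-volume block is 6 short of its nominal 69
#: regions so that with the default 6 signal columns the table has exactly
#: 310 features (69+37+68+68+68 region measures in total).
DEFAULT_BLOCKS = (
    ("cortical_volume", 63, 4e-3, 8e-4),
    ("subcortical_volume", 37, 2e-3, 4e-4),
    ("surface_area", 68, 2.5e3, 4e2),
    ("thickness_avg", 68, 2.5, 0.25),
    ("thickness_std", 68, 0.6, 0.1),
)


@dataclass
class GeneratorSpec:
    """Conditions for one synthetic cohort.

    Defaults mirror the intended application scale: subject counts
    231/379/286 across the three classes, scans per subject drawn uniformly
    from {2, ..., 5} (mean ≈ 3.7, N ≈ 3300), 310 features of which
    ``p_signal`` carry the class signal. ``class_separation`` is the
    distance between the outer class means in units of the within-class
    standard deviation; ``intermediate_mix`` places the middle class on the
    segment between them (0.5 = halfway). Between-subject spread adds to
    within-subject scan noise so repeats of one subject correlate.
    """

    n_subjects: tuple[int, ...] = (231, 379, 286)
    scans_per_subject: tuple[int, int] = (2, 5)  # inclusive uniform range
    p_signal: int = 6
    class_separation: float = 3.0
    intermediate_mix: float = 0.5
    between_subject_sd: float = 1.0
    within_subject_sd: float = 0.5
    noise_sd: float = 1.0  # multiplier on each block's native scale
    feature_blocks: tuple = DEFAULT_BLOCKS
    signal_scale: float = 1.0
    class_means: np.ndarray | None = None  # (C, p_signal); default auto
    nonlinearity: str = "none"  # none | xor | annulus
    class_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_subjects):
            raise ParameterError("subject counts must be positive")
        if not 0.0 <= self.intermediate_mix <= 1.0:
            raise ParameterError("intermediate_mix must lie in [0, 1]")
        if self.p_signal <= 0:
            raise ParameterError("p_signal must be positive")
        if self.scans_per_subject[0] < 1 or self.scans_per_subject[1] < self.scans_per_subject[0]:
            raise ParameterError("invalid scans_per_subject range")
        if self.nonlinearity not in ("none", "xor", "annulus"):
            raise ParameterError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.nonlinearity in ("xor", "annulus") and len(self.n_subjects) != 2:
            raise ParameterError("nonlinear families are two-class")

    @property
    def p_noise(self) -> int:
        return sum(b[1] for b in self.feature_blocks)

    @property
    def n_classes(self) -> int:
        return len(self.n_subjects)


def _default_means(spec: GeneratorSpec) -> np.ndarray:
    """Outer classes at ±separation/2 along a diagonal signal direction;
    the middle class (3-class case) interpolated by ``intermediate_mix``."""
    C, p = spec.n_classes, spec.p_signal
    direction = np.ones(p) / np.sqrt(p)
    half = spec.class_separation / 2.0
    if C == 2:
        return np.vstack([-half * direction, half * direction])
    m1 = -half * direction
    m3 = half * direction
    m2 = spec.intermediate_mix * m1 + (1.0 - spec.intermediate_mix) * m3
    means = [m1, m2, m3]
    for c in range(3, C):
        means.append((c - 1) * half * direction)
    return np.vstack(means)


def _subject_signal(spec: GeneratorSpec, c: int, rng: np.random.Generator) -> np.ndarray:
    p = spec.p_signal
    if spec.nonlinearity == "xor":
        # Four clusters at (±s, ±s); class = sign of the product.
        s = spec.class_separation / 2.0
        corner = rng.integers(0, 2, size=2) * 2 - 1
        if c == 1:
            center2 = np.array([corner[0], corner[0]]) * s  # same-sign corners
        else:
            center2 = np.array([corner[0], -corner[0]]) * s
        center = np.zeros(p)
        center[:2] = center2
        return center + rng.normal(scale=spec.between_subject_sd, size=p)
    if spec.nonlinearity == "annulus":
        s = spec.class_separation
        radius = 0.0 if c == 0 else s
        angle = rng.uniform(0, 2 * np.pi)
        center = np.zeros(p)
        center[:2] = radius * np.array([np.cos(angle), np.sin(angle)])
        return center + rng.normal(scale=spec.between_subject_sd, size=p)
    means = spec.class_means if spec.class_means is not None else _default_means(spec)
    return means[c] + rng.normal(scale=spec.between_subject_sd, size=p)


def generate(spec: GeneratorSpec) -> tuple[FeatureMatrix, dict]:
    """Draw one cohort; returns the table and ground-truth metadata.

    Each subject gets a class-conditional signal-space mean and a noise
    offset per nuisance feature; each scan adds within-subject noise to
    both. Signal columns come first (scaled by ``signal_scale``), then the
    nuisance blocks at their native locations/scales. Metadata records the
    signal column indices, the class means, and the spec itself.
    """
    rng = np.random.default_rng(spec.seed)
    C = spec.n_classes
    names = spec.class_names or tuple(f"class{c}" for c in range(C))
    if len(names) != C:
        raise ParameterError("class_names length must match class count")
    rows, labels, subjects = [], [], []
    sid = 0
    for c in range(C):
        for _ in range(spec.n_subjects[c]):
            center = _subject_signal(spec, c, rng)
            noise_center = np.concatenate(
                [
                    loc + rng.normal(scale=spec.noise_sd * scale, size=cnt)
                    for _, cnt, loc, scale in spec.feature_blocks
                ]
            ) if spec.feature_blocks else np.empty(0)
            n_scans = int(rng.integers(spec.scans_per_subject[0], spec.scans_per_subject[1] + 1))
            for _ in range(n_scans):
                sig = center + rng.normal(scale=spec.within_subject_sd, size=spec.p_signal)
                noise = noise_center + np.concatenate(
                    [
                        rng.normal(scale=spec.within_subject_sd * spec.noise_sd * scale, size=cnt)
                        for _, cnt, loc, scale in spec.feature_blocks
                    ]
                ) if spec.feature_blocks else np.empty(0)
                rows.append(np.concatenate([spec.signal_scale * sig, noise]))
                labels.append(names[c])
                subjects.append(f"subj{sid:05d}")
            sid += 1
    feature_names = [f"signal{j}" for j in range(spec.p_signal)]
    for bname, cnt, _, _ in spec.feature_blocks:
        feature_names += [f"{bname}{j}" for j in range(cnt)]
    data = FeatureMatrix(
        np.vstack(rows), np.array(labels), feature_names, np.array(subjects)
    )
    meta = {
        "signal_columns": list(range(spec.p_signal)),
        "class_means": (
            spec.class_means if spec.class_means is not None else _default_means(spec)
        ),
        "spec": spec,
    }
    return data, meta


# ---------------------------------------------------------------------------
# Pinned fixtures used across the test suite.

def _tiny3class() -> GeneratorSpec:
    return GeneratorSpec(
        n_subjects=(5, 5, 5),
        scans_per_subject=(2, 2),
        p_signal=2,
        class_separation=4.0,
        between_subject_sd=0.5,
        within_subject_sd=0.3,
        feature_blocks=(("noise", 4, 0.0, 1.0),),
        class_names=("HC", "MCI", "AD"),
        seed=20170726,
    )


def _xor2class() -> GeneratorSpec:
    return GeneratorSpec(
        n_subjects=(20, 20),
        scans_per_subject=(2, 2),
        p_signal=2,
        class_separation=4.0,
        between_subject_sd=0.45,
        within_subject_sd=0.25,
        feature_blocks=(("noise", 2, 0.0, 1.0),),
        nonlinearity="xor",
        class_names=("neg", "pos"),
        seed=20170726,
    )


def _scale_confounded() -> GeneratorSpec:
    # One unit-scale discriminative feature drowned by nine high-variance
    # nuisance features: unstandardized distances are noise-dominated.
    return GeneratorSpec(
        n_subjects=(20, 20, 20),
        scans_per_subject=(2, 2),
        p_signal=1,
        class_separation=6.0,
        between_subject_sd=0.4,
        within_subject_sd=0.25,
        feature_blocks=(("nuisance", 9, 0.0, 100.0),),
        class_names=("HC", "MCI", "AD"),
        seed=20170726,
    )


_FIXTURES = {
    "tiny3class": _tiny3class,
    "xor2class": _xor2class,
    "scale-confounded": _scale_confounded,
}

FIXTURE_NAMES = tuple(_FIXTURES)


def make_fixture(name: str, seed: int | None = None) -> tuple[FeatureMatrix, dict]:
    """Canned instances used across the test suite.

    Deterministic: regeneration is byte-identical for a given (name, seed).
    ``seed`` overrides the pinned default to draw a fresh replicate of the
    same family.
    """
    if name not in _FIXTURES:
        raise ParameterError(f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}")
    spec = _FIXTURES[name]()
    if seed is not None:
        spec.seed = int(seed)
    return generate(spec)
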