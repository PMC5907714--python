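"""Synthetic landmark datasets with the statistical structure the analyses
assume.

The generator builds a bilaterally symmetric mean shape (midline landmarks on
the symmetry plane, paired landmarks mirrored across it), adds per-group mean
offsets, and draws per-specimen shape deviations with a block correlation
structure: deviations of landmarks in the same module share a module factor
(within-module correlation ``rho_within``) on top of a global factor
(between-module correlation ``rho_between``), with compound symmetry inside
each block.  Symmetric deviations are generated on the midline-plus-left
landmarks and mirrored, so they are exactly symmetric; independent noise of
scale ``asymmetry_sd`` then breaks the symmetry.  Everything is deterministic
given the seed.

The ``equid`` preset mirrors the study conditions of the cranial sample:
62 landmarks in 3D with the bundled bilateral pairing, four groups of sizes
133 (domesticated horses), 47 (zebras), 31 (donkeys) and 5 (Przewalski's
horses, a small offset from the domestic horses), and six correlated
modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Dataset, LandmarkConfiguration
from .modularity import ModuleHypothesis, load_bundled_hypotheses
from .superimposition import CRANIUM_PAIRING, PairingScheme

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "TwoViewData",
    "generate_dataset",
    "generate_two_view",
    "equid_preset",
]


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n: int
    offset: float  # Frobenius norm of the group's mean-shape offset


@dataclass
class SimulationConfig:
    k: int
    m: int
    pairing: PairingScheme | None
    groups: list[GroupSpec]
    module_map: dict[int, str] | None
    rho_within: float = 0.6
    rho_between: float = 0.2
    noise_sd: float = 1.5
    asymmetry_sd: float = 0.3
    base_scale: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pairing is not None and self.pairing.k != self.k:
            raise ValueError(
                f"pairing covers {self.pairing.k} landmarks, config has k={self.k}"
            )
        if not (0 <= self.rho_between <= self.rho_within < 1):
            raise ValueError("need 0 <= rho_between <= rho_within < 1")
        if any(g.n < 1 for g in self.groups):
            raise ValueError("group sizes must be >= 1")
        if self.module_map is not None and set(self.module_map) != set(range(self.k)):
            raise ValueError("module_map must assign every landmark")

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)


def _base_shape(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Random mean shape, mirror-symmetric about the first-axis plane."""
    k, m, s = config.k, config.m, config.base_scale
    shape = rng.uniform(-s, s, size=(k, m))
    if config.pairing is not None:
        for i in config.pairing.midline:
            shape[i, 0] = 0.0
        for left, right in config.pairing.paired:
            shape[left, 0] = abs(shape[left, 0]) + 0.1 * s  # keep sides apart
            shape[right] = shape[left]
            shape[right, 0] = -shape[left, 0]
    return shape


def _symmetric_field(
    config: SimulationConfig, n: int, rng: np.random.Generator, scale: float
) -> np.ndarray:
    """n x k x m mirror-symmetric deviations with block correlation.

    Deviations are drawn for the 'independent' landmarks (midline plus one
    member of each pair) as scale * (sqrt(rho_b) * global factor +
    sqrt(rho_w - rho_b) * module factor + sqrt(1 - rho_w) * landmark noise),
    independently per axis, then mirrored onto the other side.  Midline
    landmarks get no deviation along the mirrored axis (that displacement
    would be asymmetric by construction).
    """
    k, m = config.k, config.m
    if config.pairing is None:
        independent = list(range(k))
        partners: list[tuple[int, int]] = []
        midline: list[int] = []
    else:
        independent = list(config.pairing.midline) + [
            left for left, _ in config.pairing.paired
        ]
        partners = list(config.pairing.paired)
        midline = list(config.pairing.midline)

    if config.module_map is None:
        modules = {i: "all" for i in range(k)}
    else:
        modules = config.module_map
    module_names = sorted(set(modules[i] for i in independent))
    mod_index = {name: j for j, name in enumerate(module_names)}

    rho_w, rho_b = config.rho_within, config.rho_between
    a = np.sqrt(rho_b)
    b = np.sqrt(rho_w - rho_b)
    c = np.sqrt(1 - rho_w)

    dev = np.zeros((n, k, m))
    g = rng.standard_normal((n, 1, m))
    f = rng.standard_normal((n, len(module_names), m))
    e = rng.standard_normal((n, len(independent), m))
    for col, lm in enumerate(independent):
        dev[:, lm, :] = scale * (
            a * g[:, 0, :] + b * f[:, mod_index[modules[lm]], :] + c * e[:, col, :]
        )
    for i in midline:
        dev[:, i, 0] = 0.0
    for left, right in partners:
        dev[:, right, :] = dev[:, left, :]
        dev[:, right, 0] = -dev[:, left, 0]
    return dev


def _symmetric_direction(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Unit-norm symmetric k x m displacement direction."""
    d = _symmetric_field(config, 1, rng, scale=1.0)[0]
    norm = np.linalg.norm(d)
    return d / norm


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Simulate a landmark dataset under the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    base = _base_shape(config, rng)
    offsets = {
        g.label: g.offset * _symmetric_direction(config, rng) for g in config.groups
    }
    configs: list[LandmarkConfiguration] = []
    labels: list[str] = []
    for g in config.groups:
        dev = _symmetric_field(config, g.n, rng, scale=config.noise_sd)
        asym = (
            config.asymmetry_sd * rng.standard_normal((g.n, config.k, config.m))
            if config.asymmetry_sd > 0
            else np.zeros((g.n, config.k, config.m))
        )
        coords = base + offsets[g.label] + dev + asym
        for i in range(g.n):
            configs.append(
                LandmarkConfiguration(f"{g.label}-{i + 1:03d}", coords[i])
            )
            labels.append(g.label)
    return Dataset(configs, metadata=None, group_labels=np.array(labels))


@dataclass
class TwoViewData:
    """Two digitising views per specimen plus the ground truth for testing."""

    full: Dataset
    dorsal: list[LandmarkConfiguration]
    ventral: list[LandmarkConfiguration]
    transforms: list[tuple[np.ndarray, np.ndarray]]  # applied (R, t) per specimen
    dorsal_ref: list[int]  # positions of reference landmarks within the dorsal view
    ventral_ref: list[int]  # positions within the ventral view


def generate_two_view(
    config: SimulationConfig,
    dorsal_landmarks: list[int] | None = None,
    ref_landmarks: list[int] | None = None,
    translation_scale: float = 25.0,
) -> TwoViewData:
    """Split each simulated configuration into two overlapping views.

    The dorsal view keeps ``dorsal_landmarks`` (default: the first half); the
    ventral view holds the reference landmarks followed by the remaining
    landmarks, moved by a random rigid transform.  Reference landmarks
    (default: the first two plus the last of the dorsal view) appear in both
    views, so merging reproduces the full configuration in original order.
    """
    full = generate_dataset(config)
    rng = np.random.default_rng(config.seed + 1)
    k = config.k
    if dorsal_landmarks is None:
        dorsal_landmarks = list(range(k // 2))
    if ref_landmarks is None:
        if len(dorsal_landmarks) < 3:
            raise ValueError("dorsal view needs at least 3 landmarks")
        ref_landmarks = [dorsal_landmarks[0], dorsal_landmarks[1], dorsal_landmarks[-1]]
    if len(set(ref_landmarks)) < 3:
        raise ValueError("need at least 3 distinct shared reference landmarks")
    if not set(ref_landmarks) <= set(dorsal_landmarks):
        raise ValueError("reference landmarks must belong to the dorsal view")
    rest = [i for i in range(k) if i not in dorsal_landmarks]
    ventral_landmarks = list(ref_landmarks) + rest

    dorsal_list, ventral_list, transforms = [], [], []
    for conf in full.configurations:
        dorsal_list.append(
            LandmarkConfiguration(
                conf.specimen_id, conf.coords[dorsal_landmarks], view_tag="dorsal"
            )
        )
        # random proper rotation via QR, then a translation
        q, r = np.linalg.qr(rng.standard_normal((config.m, config.m)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        t = rng.uniform(-translation_scale, translation_scale, size=config.m)
        ventral_list.append(
            LandmarkConfiguration(
                conf.specimen_id,
                conf.coords[ventral_landmarks] @ q + t,
                view_tag="ventral",
            )
        )
        transforms.append((q, t))
    return TwoViewData(
        full=full,
        dorsal=dorsal_list,
        ventral=ventral_list,
        transforms=transforms,
        dorsal_ref=[dorsal_landmarks.index(i) for i in ref_landmarks],
        ventral_ref=list(range(len(ref_landmarks))),
    )


def equid_preset(
    seed: int = 0,
    rho_within: float = 0.6,
    rho_between: float = 0.2,
    hypothesis: ModuleHypothesis | None = None,
) -> SimulationConfig:
    """Study-condition preset: 62 landmarks, 3D, four unbalanced groups.

    Group sizes follow the cranial sample (H 133, Z 47, D 31, P 5).  Offsets
    place zebras and donkeys far from horses (distinct wild lineages) and the
    Przewalski's horses as a small displacement from the domestic horses.
    The six-module assignment drives the block correlation of shape
    deviations.
    """
    if hypothesis is None:
        hypothesis = load_bundled_hypotheses()["mammalian_six"]
    return SimulationConfig(
        k=62,
        m=3,
        pairing=CRANIUM_PAIRING,
        groups=[
            GroupSpec("H", 133, 0.0),
            GroupSpec("Z", 47, 22.0),
            GroupSpec("D", 31, 18.0),
            GroupSpec("P", 5, 4.0),
        ],
        module_map=dict(hypothesis.assignment),
        rho_within=rho_within,
        rho_between=rho_between,
        noise_sd=1.5,
        asymmetry_sd=0.3,
        seed=seed,
    )
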