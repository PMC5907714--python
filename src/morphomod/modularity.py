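"""Likelihood-based comparison of cranial modularity hypotheses.

A modularity hypothesis assigns every landmark to a module.  Each hypothesis
is evaluated in four variants of increasing complexity — (a) one within- and
one between-module correlation, (b) one within, separate between per module
pair, (c) separate within per module, one between, (d) separate within and
separate between — against a no-modularity null, on a landmark correlation
matrix built from Procrustes-aligned coordinates (absolute congruence
coefficients).  Each correlation set's parameter rho is the maximum-likelihood
value under a Gaussian model of the Fisher-z-transformed correlations with
standard deviation 1/sqrt(n_specimens - 3); models are ranked by
small-sample-corrected AIC with sample size equal to the number of unique
correlations.

Per-module integration is quantified by relative eigenvalue standard
deviation (eigenvalue dispersion) of the module's coordinate correlation
matrix after module-wise superimposition, and per-module disparity by the
maximum and mean Procrustes distance of specimens to the module consensus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .superimposition import gpa

__all__ = [
    "ModuleHypothesis",
    "ModelSpec",
    "CorrelationMatrix",
    "ModelFit",
    "IntegrationReport",
    "landmark_correlation_matrix",
    "build_model_set",
    "emmli_fit",
    "eigenvalue_dispersion",
    "eigenvalue_dispersion_from_corr",
    "module_disparity",
    "compare_wild_domestic",
    "read_hypothesis_file",
    "load_bundled_hypotheses",
]

VARIANTS = ("a", "b", "c", "d")


@dataclass(frozen=True)
class ModuleHypothesis:
    """Assignment of every landmark (0-based index) to a named module."""

    name: str
    assignment: dict[int, str]

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("empty hypothesis")

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def landmarks_of(self, module: str) -> list[int]:
        return sorted(i for i, mod in self.assignment.items() if mod == module)

    def validate(self, k: int) -> None:
        if set(self.assignment) != set(range(k)):
            raise ValueError(
                f"hypothesis {self.name!r} does not assign all {k} landmarks"
            )


@dataclass(frozen=True)
class ModelSpec:
    """One modularity model: a hypothesis with a variant, or the null."""

    hypothesis: ModuleHypothesis | None
    variant: str | None  # 'a'..'d', or None for the no-modularity null

    @property
    def name(self) -> str:
        if self.hypothesis is None:
            return "null"
        return f"{self.hypothesis.name}.{self.variant}"


@dataclass
class CorrelationMatrix:
    values: np.ndarray  # k x k, |r|, diagonal 1
    sample_size: int  # number of specimens behind each correlation

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def n_corr(self) -> int:
        return self.k * (self.k - 1) // 2


@dataclass
class ModelFit:
    model: ModelSpec
    K: int
    logL: float
    AICc: float
    dAICc: float
    rho_hat: dict[str, float]


@dataclass
class IntegrationReport:
    """Per-module integration (eigenvalue dispersion) and disparity."""

    per_module: pd.DataFrame  # index module; psi, disparity_max, disparity_mean, k
    average_psi: float
    median_psi: float


def landmark_correlation_matrix(aligned_coords: np.ndarray) -> CorrelationMatrix:
    """Absolute congruence coefficients between landmark deviation patterns.

    For each landmark the deviations of its coordinates from the mean
    landmark position, across specimens and axes, form a vector; the
    congruence coefficient of two landmarks is the inner product of their
    deviation vectors normalised by the product of norms.  Absolute values
    are taken and the diagonal set to 1.
    """
    coords = np.asarray(aligned_coords, float)
    if coords.ndim != 3:
        raise ValueError("expected an n x k x m coordinate array")
    n, k, m = coords.shape
    if n < 4:
        raise ValueError("need at least 4 specimens for a correlation matrix")
    dev = coords - coords.mean(axis=0)  # n x k x m
    flat = dev.transpose(1, 0, 2).reshape(k, n * m)  # per-landmark deviation vectors
    norms = np.linalg.norm(flat, axis=1)
    if np.any(norms == 0):
        bad = int(np.argmin(norms))
        raise ValueError(f"landmark {bad} has zero variance across specimens")
    r = (flat @ flat.T) / np.outer(norms, norms)
    r = np.abs(r)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(values=r, sample_size=n)


def _correlation_sets(
    model: ModelSpec, k: int
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Map set label -> (i_indices, j_indices) of the correlations it owns."""
    iu, ju = np.triu_indices(k, 1)
    if model.hypothesis is None:
        return {"all": (iu, ju)}
    hyp = model.hypothesis
    hyp.validate(k)
    module_of = np.array([hyp.assignment[i] for i in range(k)])
    mi, mj = module_of[iu], module_of[ju]
    within = mi == mj
    sets: dict[str, np.ndarray] = {}
    if model.variant in ("a", "b"):
        sets["within"] = within
    else:  # separate within per module
        for mod in hyp.modules:
            sets[f"within.{mod}"] = within & (mi == mod)
    if model.variant in ("a", "c"):
        sets["between"] = ~within
    else:  # separate between per module pair
        for ma, mb in itertools.combinations(hyp.modules, 2):
            mask = ((mi == ma) & (mj == mb)) | ((mi == mb) & (mj == ma))
            sets[f"between.{ma}-{mb}"] = mask
    return {
        label: (iu[mask], ju[mask]) for label, mask in sets.items() if mask.any()
    }


_RHO_GRID = np.arange(0.0, 0.9951, 0.001)
_Z_GRID = np.arctanh(_RHO_GRID)


def _fit_set(z: np.ndarray, sd: float) -> tuple[float, float]:
    """Grid-search MLE of rho for one correlation set; returns (rho, logL)."""
    n = len(z)
    # sum of squared deviations from each candidate mean, expanded form
    ss = np.sum(z**2) - 2 * _Z_GRID * np.sum(z) + n * _Z_GRID**2
    loglik = -ss / (2 * sd**2) - n * np.log(sd * np.sqrt(2 * np.pi))
    best = int(np.argmax(loglik))
    return float(_RHO_GRID[best]), float(loglik[best])


def build_model_set(hypotheses: list[ModuleHypothesis]) -> list[ModelSpec]:
    """All hypothesis x variant combinations plus the no-modularity null."""
    models = [ModelSpec(hypothesis=None, variant=None)]
    for hyp in hypotheses:
        for v in VARIANTS:
            models.append(ModelSpec(hypothesis=hyp, variant=v))
    return models


def emmli_fit(
    corr: CorrelationMatrix, models: list[ModelSpec]
) -> list[ModelFit]:
    """Maximum-likelihood comparison of modularity models on one matrix.

    Returns fits sorted by AICc (best first); dAICc is relative to the
    minimum.  K counts the distinct rho parameters plus one.
    """
    k = corr.k
    if corr.sample_size < 4:
        raise ValueError("sample size must exceed 3 for the Fisher-z likelihood")
    sd = 1.0 / np.sqrt(corr.sample_size - 3)
    z_all = np.arctanh(np.clip(corr.values, 0.0, 0.999999))
    fits = []
    for model in models:
        sets = _correlation_sets(model, k)
        K = len(sets) + 1
        if K >= corr.n_corr - 1:
            raise ValueError(
                f"model {model.name}: K={K} too large for {corr.n_corr} correlations"
            )
        logL = 0.0
        rho_hat = {}
        for label, (ii, jj) in sets.items():
            rho, ll = _fit_set(z_all[ii, jj], sd)
            rho_hat[label] = rho
            logL += ll
        aicc = -2 * logL + 2 * K + 2 * K * (K + 1) / (corr.n_corr - K - 1)
        fits.append(ModelFit(model, K, logL, aicc, 0.0, rho_hat))
    best = min(f.AICc for f in fits)
    for f in fits:
        f.dAICc = f.AICc - best
    return sorted(fits, key=lambda f: f.AICc)


def fits_table(fits: list[ModelFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [f.model.name for f in fits],
            "K": [f.K for f in fits],
            "logL": [f.logL for f in fits],
            "AICc": [f.AICc for f in fits],
            "dAICc": [f.dAICc for f in fits],
        }
    )


def eigenvalue_dispersion_from_corr(corr: np.ndarray) -> float:
    """Relative eigenvalue standard deviation of a correlation matrix.

    psi = sqrt(sum (lambda_i - mean)^2 / p) / (mean * sqrt(p - 1)); 0 when
    all eigenvalues are equal (no integration), 1 when a single dimension
    carries all variation (complete integration).
    """
    corr = np.asarray(corr, float)
    p = corr.shape[0]
    if p < 2:
        raise ValueError("need at least 2 variables")
    lam = np.linalg.eigvalsh(corr)
    mean = lam.mean()
    return float(np.sqrt(np.sum((lam - mean) ** 2) / p) / (mean * np.sqrt(p - 1)))


def eigenvalue_dispersion(module_coords: np.ndarray) -> float:
    """Eigenvalue dispersion of a module's coordinate correlation matrix.

    ``module_coords`` is an n x k_mod x m stack of module-wise superimposed
    coordinates; the correlation matrix is across the k_mod*m coordinate
    variables.
    """
    coords = np.asarray(module_coords, float)
    flat = coords.reshape(coords.shape[0], -1)
    if flat.shape[0] < 3:
        raise ValueError("need at least 3 specimens")
    sd = flat.std(axis=0)
    keep = sd > 1e-12 * max(1.0, float(sd.max()))
    if keep.sum() < 2:
        raise ValueError("fewer than 2 variables with nonzero variance")
    corr = np.corrcoef(flat[:, keep], rowvar=False)
    return eigenvalue_dispersion_from_corr(corr)


def module_disparity(module_coords: np.ndarray) -> tuple[float, float]:
    """(max, mean) Procrustes distance of specimens to the module consensus."""
    coords = np.asarray(module_coords, float)
    flat = coords.reshape(coords.shape[0], -1)
    consensus = flat.mean(axis=0)
    d = np.linalg.norm(flat - consensus, axis=1)
    return float(d.max()), float(d.mean())


def _module_gpa(raw_coords: np.ndarray, landmarks: list[int]) -> np.ndarray:
    """Module-wise superimposition of a landmark subset."""
    if len(landmarks) < 3:
        raise ValueError("module needs at least 3 landmarks for superimposition")
    return gpa(raw_coords[:, landmarks, :]).aligned


def integration_report(
    coords: np.ndarray, hypothesis: ModuleHypothesis
) -> IntegrationReport:
    """Module-wise superimposition, then psi and disparity per module."""
    coords = np.asarray(coords, float)
    hypothesis.validate(coords.shape[1])
    rows = []
    for mod in hypothesis.modules:
        lms = hypothesis.landmarks_of(mod)
        aligned = _module_gpa(coords, lms)
        psi = eigenvalue_dispersion(aligned)
        d_max, d_mean = module_disparity(aligned)
        rows.append((mod, psi, d_max, d_mean, len(lms)))
    table = pd.DataFrame(
        rows, columns=["module", "psi", "disparity_max", "disparity_mean", "k"]
    ).set_index("module")
    return IntegrationReport(
        per_module=table,
        average_psi=float(table["psi"].mean()),
        median_psi=float(table["psi"].median()),
    )


def compare_wild_domestic(
    coords: np.ndarray,
    groups: np.ndarray,
    hypothesis: ModuleHypothesis,
    wild_groups: tuple[str, ...] = ("D", "Z", "P"),
    domestic_groups: tuple[str, ...] = ("H",),
) -> dict[str, IntegrationReport]:
    """Integration and disparity per module for wild vs domesticated subsets.

    Each subset's landmarks are re-superimposed module by module before
    computing eigenvalue dispersion and disparity.
    """
    coords = np.asarray(coords, float)
    groups = np.asarray(groups)
    out = {}
    for label, members in [("domestic", domestic_groups), ("wild", wild_groups)]:
        mask = np.isin(groups, members)
        if mask.sum() < 3:
            raise ValueError(f"{label} subset has fewer than 3 specimens")
        out[label] = integration_report(coords[mask], hypothesis)
    return out


def read_hypothesis_file(path: str | Path, name: str | None = None) -> ModuleHypothesis:
    """Read a two-column (1-based landmark id, module label) hypothesis file."""
    path = Path(path)
    assignment: dict[int, str] = {}
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"bad hypothesis line {line!r}")
        idx = int(fields[0]) - 1
        if idx in assignment:
            raise ValueError(f"landmark {idx + 1} assigned twice")
        assignment[idx] = fields[1]
    return ModuleHypothesis(name or path.stem, assignment)


def load_bundled_hypotheses() -> dict[str, ModuleHypothesis]:
    """The four bundled cranial modularity hypotheses.

    These are synthetic stand-ins: the landmark-to-module assignments were
    constructed from the anatomical positions of the 62 cranial landmarks
    (tissue origin, mammalian six-module, functional six-module, and a
    horse-specific face/braincase split), not taken from a published
    assignment table.
    """
    out = {}
    pkg = resources.files("morphomod").joinpath("data")
    for stem, name in [
        ("hypothesis_tissue_origin_synthetic", "tissue_origin"),
        ("hypothesis_mammalian_six_synthetic", "mammalian_six"),
        ("hypothesis_functional_synthetic", "functional"),
        ("hypothesis_horse_specific_synthetic", "horse_specific"),
    ]:
        with resources.as_file(pkg.joinpath(stem + ".txt")) as p:
            out[name] = read_hypothesis_file(p, name)
    return out
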