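"""End-to-end study workflow over one skeletal structure.

``run_pipeline`` executes the full sequence — load (or simulate) landmarks,
superimpose, extract the symmetric component (bilateral structures only),
ordinate, select the PC dimensionality, test group differences, classify,
predict excluded specimens, partition disparity, and compare modularity
models — writing per-stage CSV/JSON outputs plus a machine-readable run
manifest, all driven by one declarative config.  Every stochastic stage is
seeded from the config seed, so a rerun with the same config reproduces the
bundle bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .disparity import partial_disparity
from .io import Dataset, read_landmark_table, read_tps, write_landmark_table
from .modularity import (
    ModuleHypothesis,
    build_model_set,
    compare_wild_domestic,
    emmli_fit,
    fits_table,
    landmark_correlation_matrix,
    load_bundled_hypotheses,
    read_hypothesis_file,
)
from .ordination import (
    cva_classify,
    pca,
    predict_excluded,
    procrustes_anova,
    select_dimensions,
)
from .simulate import equid_preset, generate_dataset
from .superimposition import (
    CRANIUM_PAIRING,
    MANDIBLE_PAIRING,
    PairingScheme,
    gpa,
    read_pairing_file,
    symmetric_component,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("morphomod")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    structure: str = "cranium"  # cranium | mandible | tooth
    # input: either a preset name, or a landmark file
    preset: str | None = "equid"
    input_path: str | None = None
    input_format: str = "table"  # table | tps
    dims: int = 3
    pairing_file: str | None = None  # bundled default per structure when None
    hypothesis_files: list[str] = field(default_factory=list)  # bundled when empty
    exclude_below: int = 6  # groups smaller than this are held out of the CVA
    max_N: int = 10
    anova_N: int | None = None  # default: selected N
    cva_N: int | None = None  # default: selected N
    select_resamples: int = 100
    resamples: int = 300
    permutations: int = 999
    seed: int = 0
    wild_groups: tuple[str, ...] = ("D", "Z", "P")
    domestic_groups: tuple[str, ...] = ("H",)
    out_dir: str = "results/run"

    def __post_init__(self) -> None:
        if self.structure not in ("cranium", "mandible", "tooth"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.structure == "tooth" and self.pairing_file is not None:
            raise ValueError("tooth runs must not request symmetrisation")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "wild_groups" in raw:
            raw["wild_groups"] = tuple(raw["wild_groups"])
        if "domestic_groups" in raw:
            raw["domestic_groups"] = tuple(raw["domestic_groups"])
        return cls(**raw)


def _load_dataset(cfg: RunConfig) -> Dataset:
    if cfg.input_path is not None:
        if cfg.input_format == "tps":
            return read_tps(cfg.input_path, parse_metadata=True)
        return read_landmark_table(cfg.input_path, dims=cfg.dims)
    if cfg.preset == "equid":
        return generate_dataset(equid_preset(seed=cfg.seed))
    raise ValueError("config needs either input_path or a known preset")


def _pairing(cfg: RunConfig, k: int) -> PairingScheme | None:
    if cfg.structure == "tooth":
        return None
    if cfg.pairing_file is not None:
        scheme = read_pairing_file(cfg.pairing_file)
    else:
        scheme = CRANIUM_PAIRING if cfg.structure == "cranium" else MANDIBLE_PAIRING
    scheme.validate(k)
    return scheme


def _hypotheses(cfg: RunConfig) -> dict[str, ModuleHypothesis]:
    if cfg.hypothesis_files:
        return {
            Path(p).stem: read_hypothesis_file(p) for p in cfg.hypothesis_files
        }
    return load_bundled_hypotheses()


def _stage(name: str, **info) -> None:
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every applicable stage in order; returns the result bundle.

    Writes per-stage tables (CSV) and reports (JSON) under ``cfg.out_dir``
    together with ``manifest.json`` recording version, parameters and seeds.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    dataset = _load_dataset(cfg)
    groups = dataset.groups
    _stage("load", n=len(dataset), k=dataset.k, m=dataset.m)
    write_landmark_table(dataset, out / "landmarks_raw.csv")
    pd.DataFrame({"specimen_id": dataset.ids, "group": groups}).to_csv(
        out / "groups.csv", index=False
    )

    result = gpa(dataset)
    _stage("gpa", iterations=result.iterations, converged=result.converged)

    pairing = _pairing(cfg, dataset.k)
    if pairing is not None:
        decomp = symmetric_component(result, pairing)
        shape_coords = decomp.symmetric
        _stage(
            "symmetrise",
            asym_rms=float(np.sqrt(np.mean(decomp.asymmetric**2))),
        )
    else:
        shape_coords = result.aligned
        _stage("symmetrise", skipped="tooth structure")
    flat = shape_coords.reshape(len(dataset), -1)
    pd.DataFrame(flat).assign(specimen_id=dataset.ids).to_csv(
        out / "shape_coords.csv", index=False
    )

    space = pca(shape_coords)
    _stage("pca", components=len(space.eigenvalues))
    pd.DataFrame(
        {
            "eigenvalue": space.eigenvalues,
            "variance_fraction": space.variance_fractions,
        }
    ).to_csv(out / "pca_eigenvalues.csv", index=False)
    bundle["pca_top3_fraction"] = float(space.variance_fractions[:3].sum())

    selection = select_dimensions(
        space.scores,
        groups,
        max_N=cfg.max_N,
        resamples=cfg.select_resamples,
        seed=cfg.seed + 1,
    )
    _stage("select_n", chosen_N=selection.chosen_N)
    selection.accuracy_by_N.to_csv(out / "dimension_selection.csv", index=False)
    bundle["chosen_N"] = selection.chosen_N

    anova_N = cfg.anova_N or selection.chosen_N
    anova = procrustes_anova(
        space.scores, groups, N=anova_N, permutations=cfg.permutations,
        seed=cfg.seed + 2,
    )
    _stage("anova", F=round(anova.F, 3), p=anova.p, N=anova_N)
    bundle["anova"] = {"F": anova.F, "p": anova.p, "N": anova_N}

    cva_N = cfg.cva_N or selection.chosen_N
    labels, counts = np.unique(groups, return_counts=True)
    small = set(labels[counts < cfg.exclude_below])
    train_mask = ~np.isin(groups, list(small))
    report_all, dist_all = cva_classify(
        space.scores, groups, N=cva_N, resamples=cfg.resamples, seed=cfg.seed + 3
    )
    bundle["cva_all_groups"] = {
        "accuracy": report_all.overall_accuracy,
        "ci": [report_all.ci_low, report_all.ci_high],
        "N": cva_N,
    }
    dist_all.frame().to_csv(out / "mahalanobis_all.csv")
    report_all.confusion.to_csv(out / "confusion_all.csv")
    _stage("classify_all", accuracy=round(report_all.overall_accuracy, 1))

    if small and train_mask.sum() > 0:
        report_tr, dist_tr = cva_classify(
            space.scores[train_mask],
            groups[train_mask],
            N=cva_N,
            resamples=cfg.resamples,
            seed=cfg.seed + 4,
        )
        bundle["cva_excluding_small"] = {
            "excluded": sorted(small),
            "accuracy": report_tr.overall_accuracy,
            "ci": [report_tr.ci_low, report_tr.ci_high],
            "per_group": report_tr.per_group_accuracy,
        }
        dist_tr.frame().to_csv(out / "mahalanobis_train.csv")
        report_tr.confusion.to_csv(out / "confusion_train.csv")
        _stage("classify_excluding_small", accuracy=round(report_tr.overall_accuracy, 1))
        posts = predict_excluded(
            space.scores[train_mask],
            groups[train_mask],
            space.scores[~train_mask],
            N=cva_N,
            resamples=cfg.resamples,
            seed=cfg.seed + 5,
        )
        posts.insert(0, "specimen_id", np.array(dataset.ids)[~train_mask])
        posts.to_csv(out / "predicted_excluded.csv", index=False)
        bundle["predicted_excluded"] = posts.to_dict(orient="records")
        _stage("predict_excluded", n=int((~train_mask).sum()))

    disp = partial_disparity(shape_coords, groups)
    disp.partial.to_csv(out / "partial_disparity.csv")
    bundle["total_procrustes_variance"] = disp.total_variance
    bundle["partial_disparity_percent"] = disp.partial["PD_percent"].to_dict()
    _stage("disparity", total=round(disp.total_variance, 6))

    if cfg.structure == "cranium":
        corr = landmark_correlation_matrix(shape_coords)
        hyps = _hypotheses(cfg)
        fits = emmli_fit(corr, build_model_set(list(hyps.values())))
        table = fits_table(fits)
        table.to_csv(out / "modularity_models.csv", index=False)
        best = fits[0]
        bundle["modularity"] = {
            "best_model": best.model.name,
            "K": best.K,
            "logL": best.logL,
            "AICc": best.AICc,
        }
        _stage("modularity", best=best.model.name, AICc=round(best.AICc, 2))
        if best.model.hypothesis is not None:
            reports = compare_wild_domestic(
                shape_coords,
                groups,
                best.model.hypothesis,
                wild_groups=cfg.wild_groups,
                domestic_groups=cfg.domestic_groups,
            )
            rows = []
            for subset, rep in reports.items():
                for mod, row in rep.per_module.iterrows():
                    rows.append(
                        {
                            "subset": subset,
                            "module": mod,
                            "psi": row["psi"],
                            "disparity_max": row["disparity_max"],
                            "disparity_mean": row["disparity_mean"],
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "module_integration.csv", index=False)
            bundle["integration"] = {
                subset: {
                    "average_psi": rep.average_psi,
                    "median_psi": rep.median_psi,
                }
                for subset, rep in reports.items()
            }
            _stage(
                "integration",
                **{s: round(r.average_psi, 3) for s, r in reports.items()},
            )

    manifest = {
        "morphomod_version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
        },
        "n": len(dataset),
        "k": dataset.k,
        "m": dataset.m,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "report.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    return bundle
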