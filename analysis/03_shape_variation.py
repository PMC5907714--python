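#!/usr/bin/env python
"""Ordination and group classification of the symmetric shape data.

PCA of the symmetric shapes, cross-validated choice of how many PCs to carry
forward, permutation ANOVA of shape on group, leave-one-out discriminant
classification with and without the small Przewalski sample, Mahalanobis
distances, and predictive identification of the excluded Przewalski
specimens.  Tables land under results/tables/.
"""

from pathlib import Path

import pandas as pd

from morphomod.io import read_landmark_table
from morphomod.ordination import (
    cva_classify,
    pca,
    predict_excluded,
    procrustes_anova,
    select_dimensions,
)
from morphomod.plots import pca_scatter

SHAPE = Path("results/shape/symmetric_coords.csv")
GROUPS = Path("results/data/groups.csv")
OUT = Path("results/tables")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dataset = read_landmark_table(SHAPE, dims=3, parse_metadata=False)
    groups = (
        pd.read_csv(GROUPS).set_index("specimen_id")["group"].loc[dataset.ids].to_numpy()
    )

    space = pca(dataset.coords)
    top3 = 100 * space.variance_fractions[:3].sum()
    print(f"first three PCs carry {top3:.1f}% of symmetric shape variation")
    pd.DataFrame(
        {"eigenvalue": space.eigenvalues, "variance_fraction": space.variance_fractions}
    ).to_csv(OUT / "pca_eigenvalues.csv", index=False)
    Path("results/figures").mkdir(parents=True, exist_ok=True)
    pca_scatter(
        space.scores, groups, space.variance_fractions,
        "results/figures/pca_scatter.png",
    )

    sel = select_dimensions(space.scores, groups, max_N=10, resamples=50, seed=SEED)
    sel.accuracy_by_N.to_csv(OUT / "dimension_selection.csv", index=False)
    print(f"cross-validation selects the first {sel.chosen_N} PCs")

    anova = procrustes_anova(
        space.scores, groups, N=sel.chosen_N, permutations=999, seed=SEED + 1
    )
    print(f"Procrustes ANOVA: F = {anova.F:.3f}, p = {anova.p:.3g}")

    rep4, dist4 = cva_classify(
        space.scores, groups, N=sel.chosen_N, resamples=200, seed=SEED + 2
    )
    print(
        f"4-group classification: {rep4.overall_accuracy:.1f}% "
        f"(CI {rep4.ci_low:.0f}-{rep4.ci_high:.0f}%)"
    )
    rep4.confusion.to_csv(OUT / "confusion_4group.csv")
    dist4.frame().to_csv(OUT / "mahalanobis_4group.csv")

    mask = groups != "P"
    rep3, dist3 = cva_classify(
        space.scores[mask], groups[mask], N=sel.chosen_N, resamples=200, seed=SEED + 3
    )
    print(
        f"3-group classification (P excluded): {rep3.overall_accuracy:.1f}% "
        f"(CI {rep3.ci_low:.0f}-{rep3.ci_high:.0f}%)"
    )
    rep3.confusion.to_csv(OUT / "confusion_3group.csv")
    dist3.frame().to_csv(OUT / "mahalanobis_3group.csv")

    posts = predict_excluded(
        space.scores[mask], groups[mask], space.scores[~mask],
        N=sel.chosen_N, resamples=200, seed=SEED + 4,
    )
    posts.insert(0, "specimen_id", pd.Index(dataset.ids)[~mask])
    posts.to_csv(OUT / "przewalski_identification.csv", index=False)
    print(
        "Przewalski specimens identified as horses with mean probability "
        f"{100 * posts['H'].mean():.0f}%"
    )


if __name__ == "__main__":
    main()
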