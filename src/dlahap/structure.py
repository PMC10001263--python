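"""Breed population structure from haplotype frequencies.

Breeds are summarised as rows of a breed x haplotype frequency matrix,
with haplotype labels collapsed to field-1 resolution (alleles that
differ only past field-1 encode near-identical peptide-binding regions,
so collapsing them reduces the column count without losing the
immunogenetic signal).  A covariance PCA of the centered matrix places
breeds in a low-dimensional space where shared high-frequency
haplotypes pull breeds together; the Pearson correlation of per-allele
carrier proportions compares the same breed across cohorts (for
example, countries).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA

from .diversity import round_half_up
from .phasing import PhasingResult

__all__ = [
    "PCAResult",
    "breed_frequency_matrix",
    "pca",
    "carrier_correlation",
    "plot_pca",
]


def breed_frequency_matrix(
    result: PhasingResult,
    breeds: list[str] | None = None,
    level: str = "field1",
) -> pd.DataFrame:
    """Within-breed haplotype frequencies, breeds as rows.

    ``level="field1"`` collapses haplotype labels to field-1 resolution
    before counting (merging haplotypes that differ only in deeper
    fields); ``level="full"`` keeps full names.  Each row sums to 1 over
    2 x (breed's assigned dogs) chromosomes.  Breeds without resolved
    dogs are dropped with a warning.
    """
    if level not in ("field1", "full"):
        raise ValueError(f"unknown level {level!r}")
    if breeds is None:
        breeds = result.breeds
    counts: dict[str, dict] = {}
    for r in result.resolved_records:
        if r.breed not in breeds:
            continue
        row = counts.setdefault(r.breed, {})
        for h in r.diplotype.haplotypes:
            if level == "field1":
                h = h.collapse_field1()
            row[h] = row.get(h, 0) + 1
    missing = [b for b in breeds if b not in counts]
    if missing:
        warnings.warn(
            f"breeds without resolved dogs excluded: {', '.join(missing)}",
            stacklevel=2,
        )
    kept = [b for b in breeds if b in counts]
    columns = sorted({h for row in counts.values() for h in row}, key=lambda h: h.sort_key)
    mat = np.zeros((len(kept), len(columns)))
    col_index = {h: j for j, h in enumerate(columns)}
    for i, b in enumerate(kept):
        total = sum(counts[b].values())
        for h, c in counts[b].items():
            mat[i, col_index[h]] = c / total
    return pd.DataFrame(mat, index=kept, columns=[h.label() for h in columns])


@dataclass
class PCAResult:
    """Principal components of a breed frequency matrix.

    ``coordinates`` holds per-breed scores on PC1..PCk; eigenvalues are
    of the column covariance matrix, and ``contribution_ratios`` sum to
    one over all components.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    contribution_ratios: np.ndarray
    loadings: pd.DataFrame

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def pca(
    matrix: pd.DataFrame,
    drop_breeds: list[str] | None = None,
    standardize: bool = False,
) -> PCAResult:
    """Covariance PCA of a breed x haplotype frequency matrix.

    Columns are centered (and optionally scaled to unit variance with
    ``standardize=True``; the default keeps raw frequencies since they
    already share a scale).  The sign of each component is fixed so its
    largest-magnitude loading is positive, making outputs deterministic.
    Dropping named breeds (e.g. outliers) re-fits on the remainder.
    """
    if drop_breeds:
        matrix = matrix.drop(index=list(drop_breeds))
    n = matrix.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least three breeds")
    X = matrix.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    k = min(n - 1, X.shape[1])
    model = _SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    comps = model.components_
    # deterministic sign: largest-|loading| positive per component
    for c in range(k):
        jmax = int(np.argmax(np.abs(comps[c])))
        if comps[c, jmax] < 0:
            comps[c] *= -1
            scores[:, c] *= -1
    pcs = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        coordinates=pd.DataFrame(scores, index=matrix.index, columns=pcs),
        eigenvalues=model.explained_variance_.copy(),
        contribution_ratios=model.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(comps, index=pcs, columns=matrix.columns),
    )


def carrier_correlation(
    propsA: Mapping[str, float],
    propsB: Mapping[str, float],
    allele_union: list[str] | None = None,
) -> float:
    """Pearson r between two cohorts' per-allele carrier proportions.

    Computed over the union of alleles observed in either cohort
    (absent alleles count as 0), so private alleles reduce the
    correlation rather than being ignored.  Returns NaN when either
    vector has zero variance.
    """
    keys = (
        list(allele_union)
        if allele_union is not None
        else sorted(set(propsA) | set(propsB))
    )
    if len(keys) < 3:
        raise ValueError("need at least three alleles in the union")
    x = np.array([propsA.get(k, 0.0) for k in keys], dtype=float)
    y = np.array([propsB.get(k, 0.0) for k in keys], dtype=float)
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


def plot_pca(result: PCAResult, path=None, title: str | None = None):
    """Scatter of breeds on PC1/PC2 with contribution ratios on the axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    xs = result.coordinates["PC1"]
    ys = (
        result.coordinates["PC2"]
        if "PC2" in result.coordinates
        else np.zeros(len(xs))
    )
    ax.scatter(xs, ys, s=18, color="tab:blue")
    for breed, x, y in zip(result.coordinates.index, xs, ys, strict=True):
        ax.annotate(breed, (x, y), fontsize=7, xytext=(2, 2), textcoords="offset points")
    r = [round_half_up(100 * v, 1) for v in result.contribution_ratios[:2]]
    ax.set_xlabel(f"PC1 ({r[0]}%)")
    if len(r) > 1:
        ax.set_ylabel(f"PC2 ({r[1]}%)")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
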