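"""Ancestry inference: reference-panel PCA, projection, nearest-centroid labels.

The PC space is fitted on a labelled reference panel only.  Each variant is
centered by its reference mean dosage and scaled by ``sqrt(2 p (1-p))`` with
``p`` the reference alt-allele frequency (the standard genotype
standardization); loadings come from the SVD of the standardized matrix.
Study samples are *projected*: standardized with the reference means/scales —
never re-fit — and multiplied by the loadings, so study data cannot rotate
the basis.  Ancestry is the nearest reference-population centroid in the
first K components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeSet

__all__ = ["PCModel", "fit_reference_pca", "project_samples", "assign_ancestry"]


@dataclass
class PCModel:
    """A fitted reference PC space.

    ``loadings`` has one column per component, orthonormal; ``means`` and
    ``scales`` are the per-variant standardization constants;
    ``component_variances`` are non-increasing; ``centroids`` maps population
    label -> mean reference score vector.
    """

    variant_ids: np.ndarray
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray
    component_variances: np.ndarray
    reference_scores: pd.DataFrame = field(repr=False)
    centroids: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def save(self, path) -> None:
        """Serialize as a tab-delimited loadings table with a metadata header.

        Header lines (``#``-prefixed) carry K, the component variances and
        the population centroids; the body has one row per variant with its
        standardization constants and loadings.
        """
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\n")
            fh.write(
                "#component_variances="
                + ",".join(f"{v:.12g}" for v in self.component_variances)
                + "\n"
            )
            for label in sorted(self.centroids):
                fh.write(
                    f"#centroid:{label}="
                    + ",".join(f"{v:.12g}" for v in self.centroids[label])
                    + "\n"
                )
            cols = ["variant_id", "mean", "scale"] + [
                f"loading{j + 1}" for j in range(self.k)
            ]
            fh.write("\t".join(cols) + "\n")
            for i, vid in enumerate(self.variant_ids):
                vals = [self.means[i], self.scales[i], *self.loadings[i]]
                fh.write(
                    str(vid) + "\t" + "\t".join(f"{v:.12g}" for v in vals) + "\n"
                )

    @classmethod
    def load(cls, path) -> "PCModel":
        meta: dict[str, str] = {}
        centroids: dict[str, np.ndarray] = {}
        n_header = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                n_header += 1
                key, _, val = line[1:].strip().partition("=")
                if key.startswith("centroid:"):
                    centroids[key.split(":", 1)[1]] = np.array(
                        [float(x) for x in val.split(",")]
                    )
                else:
                    meta[key] = val
        body = pd.read_csv(path, sep="\t", skiprows=n_header)
        k = int(meta["k"])
        return cls(
            variant_ids=body["variant_id"].to_numpy(),
            means=body["mean"].to_numpy(),
            scales=body["scale"].to_numpy(),
            loadings=body[[f"loading{j + 1}" for j in range(k)]].to_numpy(),
            component_variances=np.array(
                [float(x) for x in meta["component_variances"].split(",")]
            ),
            reference_scores=pd.DataFrame(),
            centroids=centroids,
        )


def fit_reference_pca(reference: GenotypeSet, k: int = 4) -> PCModel:
    """Fit a K-component PC space on a reference panel.

    Monomorphic variants carry no information and are dropped before the
    decomposition.  Requires at least ``k + 1`` samples and ``k`` informative
    variants.  Missing dosages are mean-imputed (zero after centering).
    """
    if reference.n_samples < k + 1:
        raise ValueError(f"need >= {k + 1} reference samples for K={k}")
    d = reference.dosages
    means = np.nanmean(d, axis=0)
    p = means / 2.0
    informative = (p > 0) & (p < 1)
    if informative.sum() < k:
        raise ValueError(
            f"only {int(informative.sum())} informative variants for K={k}"
        )
    d = d[:, informative]
    means = means[informative]
    scales = np.sqrt(2.0 * p[informative] * (1.0 - p[informative]))
    x = (d - means) / scales
    x = np.where(np.isnan(x), 0.0, x)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    loadings = vt[:k].T
    # pin component signs: largest-|loading| entry positive
    for j in range(loadings.shape[1]):
        idx = np.argmax(np.abs(loadings[:, j]))
        if loadings[idx, j] < 0:
            loadings[:, j] *= -1.0
    scores = x @ loadings
    variances = (s[:k] ** 2) / reference.n_samples
    ref_scores = pd.DataFrame(
        scores, columns=[f"pc{j + 1}" for j in range(k)]
    )
    ref_scores.insert(0, "sample_id", reference.samples)
    centroids: dict[str, np.ndarray] = {}
    if reference.populations is not None:
        ref_scores["population"] = reference.populations
        for label in np.unique(reference.populations):
            centroids[str(label)] = scores[reference.populations == label].mean(axis=0)
    return PCModel(
        variant_ids=reference.variants["variant_id"].to_numpy()[informative],
        means=means,
        scales=scales,
        loadings=loadings,
        component_variances=variances,
        reference_scores=ref_scores,
        centroids=centroids,
    )


def project_samples(model: PCModel, study: GenotypeSet) -> pd.DataFrame:
    """Project study samples into the reference PC space.

    Study dosages are standardized with the *reference* means and scales.
    Model variants absent from the study (and missing genotypes) contribute
    zero after centering.  Requires at least K overlapping variants.
    """
    pos = {v: i for i, v in enumerate(model.variant_ids)}
    study_ids = study.variants["variant_id"].to_numpy()
    overlap = [(j, pos[v]) for j, v in enumerate(study_ids) if v in pos]
    if len(overlap) < model.k:
        raise ValueError(
            f"only {len(overlap)} study variants overlap the model "
            f"(need >= {model.k})"
        )
    x = np.zeros((study.n_samples, len(model.variant_ids)))
    for j_study, j_model in overlap:
        col = (study.dosages[:, j_study] - model.means[j_model]) / model.scales[j_model]
        x[:, j_model] = np.where(np.isnan(col), 0.0, col)
    scores = x @ model.loadings
    out = pd.DataFrame(scores, columns=[f"pc{j + 1}" for j in range(model.k)])
    out.insert(0, "sample_id", study.samples)
    return out


def assign_ancestry(
    coordinates: pd.DataFrame, model: PCModel
) -> pd.DataFrame:
    """Nearest-centroid population label per sample.

    Euclidean distance over the first K components; exact ties break to the
    lexicographically first label and are flagged in the ``tie`` column.
    """
    if not model.centroids:
        raise ValueError("model has no population centroids")
    labels = sorted(model.centroids)
    pcs = coordinates[[f"pc{j + 1}" for j in range(model.k)]].to_numpy()
    cent = np.stack([model.centroids[l] for l in labels])
    dists = np.linalg.norm(pcs[:, None, :] - cent[None, :, :], axis=2)
    best = np.argmin(dists, axis=1)
    dist_best = dists[np.arange(len(best)), best]
    ties = (dists == dist_best[:, None]).sum(axis=1) > 1
    return pd.DataFrame(
        {
            "sample_id": coordinates["sample_id"].to_numpy(),
            "ancestry": [labels[i] for i in best],
            "distance": dist_best,
            "tie": ties,
        }
    )
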