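"""Per-cell quantification: compartment masks and intensities, C/N ratio,
grain density, a two-component naive-Bayes PVI classifier on log grain
density, and extreme-pair selection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .measures import subject_means

__all__ = [
    "QuantificationError",
    "ClassifierFitError",
    "CompartmentMasks",
    "GrainDensity",
    "PviClassifier",
    "compartment_intensity",
    "cn_ratio",
    "grain_density",
    "fit_pvi_classifier",
    "classify_cells",
    "select_extreme_pairs",
    "load_mask",
]


class QuantificationError(ValueError):
    """Per-cell quantification failure (cell should be excluded, not imputed)."""


class ClassifierFitError(RuntimeError):
    """Mixture fit did not converge or collapsed."""


@dataclass
class CompartmentMasks:
    """Cell body / nucleus boolean masks; the cytoplasm is their difference."""

    body_mask: np.ndarray
    nucleus_mask: np.ndarray

    def __post_init__(self) -> None:
        self.body_mask = np.asarray(self.body_mask, dtype=bool)
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        if self.body_mask.ndim != 2 or self.body_mask.shape != self.nucleus_mask.shape:
            raise QuantificationError("masks must be 2-D and share a shape")
        if np.any(self.nucleus_mask & ~self.body_mask):
            raise QuantificationError("nucleus mask extends outside the cell body")

    @property
    def cytoplasm_mask(self) -> np.ndarray:
        return self.body_mask & ~self.nucleus_mask


@dataclass(frozen=True)
class GrainDensity:
    count: int
    area: float

    @property
    def density(self) -> float:
        if self.area <= 0:
            raise QuantificationError("grain density needs a positive area")
        return self.count / self.area


def compartment_intensity(image: np.ndarray, masks: CompartmentMasks
                          ) -> tuple[float, float, float]:
    """Mean image intensity over the body, nuclear and cytoplasmic masks."""
    image = np.asarray(image, dtype=float)
    if image.shape != masks.body_mask.shape:
        raise QuantificationError("image and masks must share a shape")
    cyto = masks.cytoplasm_mask
    if not cyto.any():
        raise QuantificationError("empty cytoplasm mask (nucleus fills the body)")
    if not masks.nucleus_mask.any():
        raise QuantificationError("empty nucleus mask")
    return (
        float(image[masks.body_mask].mean()),
        float(image[masks.nucleus_mask].mean()),
        float(image[cyto].mean()),
    )


def cn_ratio(cytoplasmic_mean: float, nuclear_mean: float) -> float:
    """Cytoplasmic-to-nuclear intensity ratio."""
    if nuclear_mean <= 0:
        raise QuantificationError("C/N ratio undefined for nuclear mean <= 0")
    return cytoplasmic_mean / nuclear_mean


def grain_density(count: int, area: float) -> float:
    return GrainDensity(count=count, area=area).density


@dataclass
class PviClassifier:
    """Two-component Gaussian model on log grain density.

    Component with the larger location is the PVI class. Decision rule:
    posterior(PVI) > 0.5 -> PVI; ties go to nonPV.
    """

    weights: np.ndarray  # class priors, sum to 1
    locations: np.ndarray  # on log(density + eps) scale; locations[1] > locations[0]
    scales: np.ndarray
    epsilon: float
    n_iter: int
    log_likelihood: float

    @property
    def prior_pvi(self) -> float:
        return float(self.weights[1])

    def posterior_pvi(self, densities: np.ndarray) -> np.ndarray:
        x = np.log(np.asarray(densities, dtype=float) + self.epsilon)
        log_p = np.stack([
            np.log(self.weights[k]) + norm.logpdf(x, self.locations[k], self.scales[k])
            for k in (0, 1)
        ])
        log_p -= log_p.max(axis=0, keepdims=True)
        p = np.exp(log_p)
        return p[1] / p.sum(axis=0)


def _log_transform(densities: np.ndarray, epsilon: float | None) -> tuple[np.ndarray, float]:
    densities = np.asarray(densities, dtype=float)
    if np.any(densities < 0):
        raise ValueError("densities must be >= 0")
    if epsilon is None:
        if (densities == 0).any():
            nonzero = densities[densities > 0]
            # half the smallest nonzero density keeps zero-count cells finite
            epsilon = 0.5 * nonzero.min() if nonzero.size else 1.0
        else:
            epsilon = 0.0
    return np.log(densities + epsilon), float(epsilon)


def fit_pvi_classifier(densities: np.ndarray, epsilon: float | None = None,
                       max_iter: int = 500, tol: float = 1e-8) -> PviClassifier:
    """EM fit of a two-component Gaussian mixture on log(density + eps).

    Deterministic initialization: split at the median log density. Raises
    :class:`ClassifierFitError` on non-convergence or variance collapse.
    """
    x, epsilon = _log_transform(densities, epsilon)
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 cells to fit the classifier")
    if np.ptp(x) == 0:
        raise ClassifierFitError("all densities identical: zero-variance fit")

    # deterministic 2-means initialization (robust to unequal weights)
    centers = np.percentile(x, [10.0, 90.0])
    for _ in range(25):
        assign = np.abs(x[:, None] - centers[None, :]).argmin(axis=1)
        if assign.all() or not assign.any():
            break
        new = np.array([x[assign == 0].mean(), x[assign == 1].mean()])
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    lo, hi = x[assign == 0], x[assign == 1]
    if lo.size == 0 or hi.size == 0:  # degenerate split, fall back to median
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
    w = np.array([lo.size / n, hi.size / n])
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.array([max(lo.std(), 1e-3), max(hi.std(), 1e-3)])

    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        log_p = np.stack([
            np.log(w[k]) + norm.logpdf(x, mu[k], sd[k]) for k in (0, 1)
        ])
        mx = log_p.max(axis=0)
        lse = mx + np.log(np.exp(log_p - mx).sum(axis=0))
        ll = float(lse.sum())
        resp = np.exp(log_p - lse)  # responsibilities, shape (2, n)

        nk = resp.sum(axis=1)
        if np.any(nk < 1e-10):
            raise ClassifierFitError("a mixture component emptied during EM")
        w = nk / n
        mu = (resp @ x) / nk
        var = np.array([(resp[k] @ (x - mu[k]) ** 2) / nk[k] for k in (0, 1)])
        if np.any(var < 1e-12):
            raise ClassifierFitError(
                f"component variance collapsed at iteration {it}: var={var}")
        sd = np.sqrt(var)

        if ll - prev_ll < tol and it > 1:
            break
        prev_ll = ll
    else:
        raise ClassifierFitError(
            f"EM did not converge in {max_iter} iterations (last dll="
            f"{ll - prev_ll:.3g})")

    order = np.argsort(mu)  # component 1 = larger location = PVI
    return PviClassifier(weights=w[order], locations=mu[order], scales=sd[order],
                         epsilon=epsilon, n_iter=it, log_likelihood=ll)


def classify_cells(classifier: PviClassifier, densities: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Label cells as PVI / nonPV by posterior; ties (0.5) go to nonPV."""
    post = classifier.posterior_pvi(densities)
    labels = np.where(post > 0.5, "PVI", "nonPV")
    return labels, post


def select_extreme_pairs(dataset, measure: str, k: int) -> list[int]:
    """Pair ids of the ``k`` pairs with the greatest within-pair difference
    (comparison subject mean minus schizophrenia subject mean), descending.

    Deterministic tie-break: smaller pair_id first.
    """
    subjects = dataset.subjects
    n_pairs = subjects.pair_id.nunique()
    if k > n_pairs:
        raise ValueError(f"k={k} exceeds the {n_pairs} available pairs")
    means = subject_means(dataset.cells, measure)
    diffs = []
    for pair_id, grp in subjects.groupby("pair_id"):
        comp = grp[grp.diagnosis == "comparison"].subject_id.iloc[0]
        sz = grp[grp.diagnosis == "schizophrenia"].subject_id.iloc[0]
        diffs.append((float(means[comp] - means[sz]), int(pair_id)))
    diffs.sort(key=lambda t: (-t[0], t[1]))
    return [pair_id for _, pair_id in diffs[:k]]


def load_mask(path) -> np.ndarray:
    """Read a boolean mask from .npy or a bilevel image file."""
    path = str(path)
    if path.endswith(".npy"):
        return np.load(path).astype(bool)
    from PIL import Image

    return (np.asarray(Image.open(path).convert("L")) > 0)
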