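"""Range-shift detection: Gaussian Naive Bayes over RL samples and AUROC.

Bootstrapped range-landmark values from a "no shift" and a "shift" scenario
are treated as two labelled classes.  A single-feature Gaussian Naive
Bayes classifier (class-conditional normal likelihoods, empirical priors,
MAP decision) is fit on random 80/20 train/test splits; the posterior
probability of the "shift" class scores the test samples and the area
under the ROC curve is computed with the rank-sum estimator.  Repeating
over many random splits yields a mean AUROC and its spread; detectability
thresholds are read off where the mean AUROC crosses 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

NO_SHIFT = "no_shift"
SHIFT = "shift"
VARIANCE_FLOOR = 1e-12  # mm^2


@dataclass(frozen=True)
class GNBModel:
    """Per-class mean, variance (floored) and prior of the RL feature."""

    means: np.ndarray  # [no_shift, shift]
    variances: np.ndarray
    priors: np.ndarray

    def log_likelihoods(self, rl: np.ndarray) -> np.ndarray:
        """(n, 2) class-conditional Gaussian log-densities."""
        rl = np.atleast_1d(np.asarray(rl, dtype=float))
        diff = rl[:, None] - self.means[None, :]
        return (-0.5 * np.log(2.0 * np.pi * self.variances)[None, :]
                - 0.5 * diff * diff / self.variances[None, :])

    def posterior_shift(self, rl: np.ndarray) -> np.ndarray:
        """Posterior probability of the "shift" class, computed in log space."""
        log_post = self.log_likelihoods(rl) + np.log(self.priors)[None, :]
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        post /= post.sum(axis=1, keepdims=True)
        return post[:, 1]


@dataclass(frozen=True)
class DetectionSummary:
    """Mean AUROC with uncertainty for one (species, shift, intensity) cell."""

    species: str
    shift_mm: float
    intensity: float
    auroc_mean: float
    auroc_sd: float
    n_repeats: int


def fit_gnb(values: np.ndarray, labels: np.ndarray) -> GNBModel:
    """Maximum-likelihood GNB fit; labels are 0 (no shift) / 1 (shift)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    means, variances, priors = np.empty(2), np.empty(2), np.empty(2)
    for j in (0, 1):
        cls = values[labels == j]
        if cls.size == 0:
            raise ValueError("both classes must be present in training data")
        means[j] = cls.mean()
        variances[j] = max(cls.var(ddof=0), VARIANCE_FLOOR)
        priors[j] = cls.size / values.size
    return GNBModel(means=means, variances=variances, priors=priors)


def classify_posterior(model: GNBModel, rl: float) -> tuple[float, str]:
    """Posterior P(shift | RL) and the MAP class; ties go to "no shift"."""
    p = float(model.posterior_shift(np.array([rl]))[0])
    return p, (SHIFT if p > 0.5 else NO_SHIFT)


def repeated_auroc(rl_no_shift: np.ndarray, rl_shift: np.ndarray,
                   n_repeats: int = 1000, test_frac: float = 0.2,
                   rng_seed: int | np.random.SeedSequence = 0,
                   ) -> tuple[float, float]:
    """Mean and standard deviation of the AUROC over repeated random splits.

    Each repeat draws an unstratified random 80/20 split of the pooled
    labelled samples, fits the GNB on the training part and scores the test
    part with the shift-class posterior; the AUROC uses the rank-sum
    (Mann-Whitney) estimator with tie correction.  Splits that lose a class
    from either side are redrawn (counted internally).
    """
    x0 = np.asarray(rl_no_shift, dtype=float)
    x1 = np.asarray(rl_shift, dtype=float)
    if x0.size < 10 or x1.size < 10:
        raise ValueError("need at least 10 samples per class")
    values = np.concatenate([x0, x1])
    labels = np.concatenate([np.zeros(x0.size, dtype=int),
                             np.ones(x1.size, dtype=int)])
    n = values.size
    n_test = max(1, int(round(test_frac * n)))
    rng = np.random.default_rng(rng_seed)
    aurocs = np.empty(n_repeats)
    for k in range(n_repeats):
        for _attempt in range(100):
            perm = rng.permutation(n)
            test, train = perm[:n_test], perm[n_test:]
            y_train, y_test = labels[train], labels[test]
            if (y_train.min() == 0 and y_train.max() == 1
                    and y_test.min() == 0 and y_test.max() == 1):
                break
        else:
            raise ValueError("could not draw a split containing both classes")
        model = fit_gnb(values[train], y_train)
        scores = model.posterior_shift(values[test])
        aurocs[k] = roc_auc_score(y_test, scores)
    return float(aurocs.mean()), float(aurocs.std(ddof=1))


def min_intensity_at_threshold(intensities, auroc_means, auroc_sds=None,
                               threshold: float = 0.9, log_interp: bool = True,
                               ):
    """Smallest intensity where the interpolated mean AUROC reaches the threshold.

    Interpolation is piecewise linear in log10(intensity) by default
    (switchable to linear).  Returns ``(intensity, (lo, hi))`` where the
    bounds come from interpolating the mean +- sd curves, or ``(None, None)``
    if the threshold is never reached.
    """
    x = np.asarray(intensities, dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("intensities must be strictly increasing")
    y = np.asarray(auroc_means, dtype=float)
    xi = np.log10(x) if log_interp else x

    def crossing(yy):
        if yy[0] >= threshold:
            return x[0]
        for i in range(1, len(yy)):
            if yy[i] >= threshold:
                f = (threshold - yy[i - 1]) / (yy[i] - yy[i - 1])
                xc = xi[i - 1] + f * (xi[i] - xi[i - 1])
                return float(10 ** xc) if log_interp else float(xc)
        return None

    best = crossing(y)
    if best is None:
        return None, None
    if auroc_sds is None:
        return best, None
    sd = np.asarray(auroc_sds, dtype=float)
    lo = crossing(y + sd)  # optimistic curve crosses earlier
    hi = crossing(y - sd)
    return best, (lo, hi)


def min_detectable_shift(shifts, auroc_means, threshold: float = 0.9):
    """Smallest |shift| whose mean AUROC reaches the threshold, or None."""
    shifts = np.asarray(shifts, dtype=float)
    y = np.asarray(auroc_means, dtype=float)
    order = np.argsort(np.abs(shifts))
    for i in order:
        if y[i] >= threshold:
            return float(shifts[i])
    return None
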