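"""FRET-efficiency distributions: KDE plus ≤2-component Gaussian fits."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

__all__ = ["EfretDistribution", "fit_efret_samples"]


@dataclass
class EfretDistribution:
    """Samples of FRET efficiency with a fitted Gaussian-mixture summary.

    ``components`` is a list of (mean, sd, weight), sorted by mean; weights
    sum to 1.  ``kde`` evaluates the Silverman-bandwidth kernel density.
    """

    samples: np.ndarray
    components: list[tuple[float, float, float]]
    n_components: int
    bic: dict[int, float] = field(default_factory=dict)
    _kde: gaussian_kde | None = None

    def kde(self, grid: np.ndarray) -> np.ndarray:
        if self._kde is None:
            self._kde = gaussian_kde(self.samples, bw_method="silverman")
        return self._kde(np.asarray(grid))

    @property
    def modes(self) -> list[float]:
        return [m for m, _, _ in self.components]

    def histogram(self, bins: int = 50, range_: tuple[float, float] = (0.0, 1.0)):
        return np.histogram(self.samples, bins=bins, range=range_, density=True)


def fit_efret_samples(
    samples: np.ndarray,
    max_components: int = 2,
    force: int | None = None,
    seed: int = 0,
) -> EfretDistribution:
    """Fit 1..max_components Gaussians by maximum likelihood; pick by BIC.

    ``force`` pins the component count.  Needs more samples than mixture
    parameters (3 per component).
    """
    samples = np.asarray(samples, dtype=float).ravel()
    samples = samples[np.isfinite(samples)]
    if force is not None and not (1 <= force <= max_components):
        raise ValueError("forced component count out of range")
    n_needed = 3 * (force or max_components)
    if len(samples) <= n_needed:
        raise ValueError(f"need more than {n_needed} samples, got {len(samples)}")
    x = samples.reshape(-1, 1)
    bic = {}
    fits = {}
    candidates = [force] if force else list(range(1, max_components + 1))
    for k in candidates:
        gm = GaussianMixture(n_components=k, n_init=3, random_state=seed)
        gm.fit(x)
        bic[k] = float(gm.bic(x))
        fits[k] = gm
    best_k = min(bic, key=bic.get)
    gm = fits[best_k]
    comp = sorted(
        zip(gm.means_.ravel(), np.sqrt(gm.covariances_.ravel()), gm.weights_),
        key=lambda t: t[0],
    )
    return EfretDistribution(
        samples=samples,
        components=[(float(m), float(s), float(w)) for m, s, w in comp],
        n_components=best_k,
        bic=bic,
    )
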