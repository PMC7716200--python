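"""Downsampling and genotype likelihoods for low-coverage read counts.

Downsampling is binomial thinning of the per-site counts, which matches
random read sampling in distribution under the counts representation.
Likelihoods use the standard biallelic read model: each read reports the
true allele with probability 1 - eps.  Everything is computed in log space
with a floor at -745 natural-log units to dodge underflow at high depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .types import ReadPileup

LOG_FLOOR = -745.0
DEFAULT_BASE_ERROR = 0.01


@dataclass
class SiteLikelihood:
    """Unnormalized genotype likelihoods at one site, scaled to max = 1."""

    l_rr: float
    l_ra: float
    l_aa: float
    depth: int

    def as_array(self) -> np.ndarray:
        return np.array([self.l_rr, self.l_ra, self.l_aa])


def downsample_reads(
    pileup: ReadPileup,
    fraction: float | None = None,
    target_mean_depth: float | None = None,
    seed: int = 0,
) -> ReadPileup:
    """Binomial thinning: each read kept independently with the implied probability.

    Give either ``fraction`` directly, or ``target_mean_depth`` from which
    the fraction is derived as target / current mean depth (capped at 1).
    """
    if (fraction is None) == (target_mean_depth is None):
        raise ConfigurationError("fraction", "give exactly one of fraction / target_mean_depth")
    if fraction is None:
        if target_mean_depth < 0:
            raise ConfigurationError("target_mean_depth", "must be non-negative")
        current = pileup.mean_depth()
        fraction = 1.0 if current == 0 else min(1.0, target_mean_depth / current)
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("fraction", "must be in [0, 1]")
    if fraction == 1.0:
        return ReadPileup(
            pileup.ref_counts.copy(), pileup.alt_counts.copy(),
            pileup.animal_ids, pileup.variants,
        )
    rng = np.random.default_rng([int(seed), 505])
    ref = rng.binomial(pileup.ref_counts, fraction)
    alt = rng.binomial(pileup.alt_counts, fraction)
    return ReadPileup(ref, alt, pileup.animal_ids, pileup.variants)


def likelihood_matrix(ref_counts, alt_counts, base_error: float = DEFAULT_BASE_ERROR) -> np.ndarray:
    """Vectorized genotype likelihoods; returns (..., 3) normalized to max = 1.

    l_rr = (1-eps)^ref * eps^alt, l_ra = 0.5^(ref+alt),
    l_aa = eps^ref * (1-eps)^alt; order RR, RA, AA.
    """
    if not 0.0 < base_error < 0.5:
        raise ConfigurationError("base_error", "must be in (0, 0.5)")
    ref = np.asarray(ref_counts, dtype=float)
    alt = np.asarray(alt_counts, dtype=float)
    if (ref < 0).any() or (alt < 0).any():
        raise ConfigurationError("counts", "read counts must be non-negative")
    log_e = np.log(base_error)
    log_1e = np.log1p(-base_error)
    ll = np.stack(
        [
            ref * log_1e + alt * log_e,
            (ref + alt) * np.log(0.5),
            ref * log_e + alt * log_1e,
        ],
        axis=-1,
    )
    ll -= ll.max(axis=-1, keepdims=True)
    return np.exp(np.maximum(ll, LOG_FLOOR))


def genotype_likelihood(ref_count: int, alt_count: int, base_error: float = DEFAULT_BASE_ERROR) -> SiteLikelihood:
    """Scalar convenience wrapper around :func:`likelihood_matrix`."""
    l = likelihood_matrix(ref_count, alt_count, base_error)
    return SiteLikelihood(float(l[0]), float(l[1]), float(l[2]), int(ref_count + alt_count))


def to_phred_gl(likelihoods: np.ndarray) -> np.ndarray:
    """Phred-scaled likelihoods (PL convention, order RR,RA,AA), min set to 0."""
    l = np.maximum(np.asarray(likelihoods, dtype=float), np.exp(LOG_FLOOR))
    pl = -10.0 * np.log10(l)
    return pl - pl.min(axis=-1, keepdims=True)
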