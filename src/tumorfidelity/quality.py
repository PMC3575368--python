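"""Alternate-allele base-quality filtering.

Low-confidence variant calls tend to carry systematically lower mean
alternate-allele base qualities, producing a bimodal quality distribution at
novel sites (known polymorphisms stay unimodal). A 1-D Gaussian mixture is
fit by EM over three candidate families — one component, two components with
a shared variance, two components with free variances — the best model is
selected by BIC, and when two components win, sites assigned to the
lower-mean component are flagged for removal.

Also provides call-set QC summaries: transition/transversion ratio and the
fraction of calls present in a known-variant database.
"""
from __future__ import annotations

import warnings

import numpy as np

from .types import (
    InsufficientDataError,
    MixtureFit,
    SiteObservation,
    ValidationError,
)

MIN_FIT_SIZE = 50
_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def _loglik(x: np.ndarray, means, variances, weights) -> tuple[float, np.ndarray]:
    """Total log-likelihood and per-point responsibilities."""
    means = np.asarray(means)[None, :]
    variances = np.asarray(variances)[None, :]
    weights = np.asarray(weights)[None, :]
    log_comp = (np.log(weights) - 0.5 * np.log(2 * np.pi * variances)
                - (x[:, None] - means) ** 2 / (2 * variances))
    m = log_comp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
    resp = np.exp(log_comp - lse[:, None])
    return float(lse.sum()), resp


def _em_fit(x: np.ndarray, k: int, equal_var: bool, rng: np.random.Generator,
            n_restarts: int = 10, tol: float = 1e-8, max_iter: int = 500):
    """EM for a 1-D Gaussian mixture; returns the best restart.

    The per-iteration log-likelihood trace is retained so callers can verify
    EM monotonicity.
    """
    n = x.size
    best = None
    for r in range(n_restarts):
        if k == 1:
            means = np.array([x.mean()])
        else:
            # quantile-split start, jittered across restarts
            qs = np.linspace(0, 100, k + 2)[1:-1] + rng.uniform(-5, 5, size=k)
            means = np.percentile(x, np.clip(qs, 1, 99))
            means = np.sort(means)
        variances = np.full(k, max(x.var(), 1e-6))
        weights = np.full(k, 1.0 / k)
        trace = []
        ll_prev = -np.inf
        for _ in range(max_iter):
            ll, resp = _loglik(x, means, variances, weights)
            trace.append(ll)
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-12)
            weights = nk / n
            means = (resp * x[:, None]).sum(axis=0) / nk
            sq = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0)
            if equal_var:
                variances = np.full(k, max(sq.sum() / n, 1e-6))
            else:
                variances = np.maximum(sq / nk, 1e-6)
            if ll - ll_prev < tol * max(abs(ll), 1.0) and np.isfinite(ll_prev):
                break
            ll_prev = ll
        ll, resp = _loglik(x, means, variances, weights)
        trace.append(ll)
        if best is None or ll > best[0]:
            best = (ll, means.copy(), variances.copy(), weights.copy(),
                    resp.copy(), tuple(trace))
    return best


def fit_quality_mixture(qualities, seed: int = 0) -> MixtureFit:
    """Fit 1- and 2-component Gaussian mixtures to mean alt-allele base
    qualities and select by BIC.

    Parameters
    ----------
    qualities : array-like of float
        Mean alternate-allele base quality per variant; at least 50 values.
    seed : int
        Seeds the EM restarts; the fit is deterministic for a fixed seed.

    Returns
    -------
    MixtureFit
        With ``discard_component`` set to the lower-mean component index
        when a 2-component model is selected, else ``None``.
    """
    x = np.asarray(qualities, dtype=float)
    if x.size < MIN_FIT_SIZE:
        raise InsufficientDataError(
            f"mixture fitting needs >= {MIN_FIT_SIZE} quality values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("quality values must be finite")
    rng = np.random.default_rng(seed)
    n = x.size

    candidates = []  # (bic, k, means, variances, weights, resp, trace)
    for k, equal_var, n_params in ((1, True, 2), (2, True, 4), (2, False, 5)):
        ll, means, variances, weights, resp, trace = _em_fit(x, k, equal_var, rng)
        bic = n_params * np.log(n) - 2.0 * ll
        candidates.append((bic, k, means, variances, weights, resp, trace))
    bic, k, means, variances, weights, resp, trace = min(candidates, key=lambda c: c[0])

    order = np.argsort(means)
    means = means[order]
    variances = variances[order]
    weights = weights[order]
    resp = resp[:, order]
    assignments = tuple(int(a) for a in resp.argmax(axis=1))
    return MixtureFit(
        n_components=k,
        means=tuple(float(m) for m in means),
        variances=tuple(float(v) for v in variances),
        weights=tuple(float(w) for w in weights),
        assignments=assignments,
        model_score=float(bic),
        discard_component=0 if k == 2 else None,
        loglik_trace=trace,
    )


def filter_variants_by_quality(sites: list[SiteObservation], fit: MixtureFit,
                               exempt_known: bool = True
                               ) -> tuple[list[SiteObservation], list[SiteObservation]]:
    """Partition sites into (kept, discarded) using a quality-mixture fit.

    ``fit.assignments`` must align 1:1 with ``sites``. Known variants are
    exempt from removal by default: the bimodality arises at novel calls,
    while database-known sites show a single high-quality mode.
    """
    if len(sites) != len(fit.assignments):
        raise ValidationError(
            f"fit covers {len(fit.assignments)} sites but {len(sites)} were given")
    if fit.discard_component is None:
        return list(sites), []
    kept, discarded = [], []
    for site, a in zip(sites, fit.assignments):
        if a == fit.discard_component and not (exempt_known and site.known):
            discarded.append(site)
        else:
            kept.append(site)
    return kept, discarded


def titv_ratio(sites: list[SiteObservation]) -> float:
    """Transition/transversion ratio over SNV sites.

    Transitions are A<->G and C<->T; all other substitutions are
    transversions. With zero transversions the ratio is undefined and
    returned as infinity with a warning.
    """
    ts = tv = 0
    for s in sites:
        if s.variant_type != "snv":
            continue
        ref, alt = s.ref.upper(), s.alt.upper()
        if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
            raise ValidationError(f"invalid SNV alleles {ref}>{alt} at {s.chrom}:{s.pos}")
        if (ref, alt) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if ts + tv == 0:
        raise InsufficientDataError("no SNV sites to compute Ts/Tv")
    if tv == 0:
        warnings.warn("no transversions observed; Ts/Tv is undefined (reporting inf)")
        return float("inf")
    return ts / tv


def known_fraction(sites: list[SiteObservation]) -> float:
    """Fraction of sites flagged as present in a known-variant database."""
    if not sites:
        raise InsufficientDataError("known_fraction of an empty call set is undefined")
    return sum(1 for s in sites if s.known) / len(sites)
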