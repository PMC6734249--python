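"""Bimodal bound/unbound mixture model over strand-specific cut matrices.

Each motif site contributes a count vector ``X`` over ``S = 2W`` model
positions (forward window columns followed by reverse window columns) with
total ``R``.  Bound sites spread cuts according to a shared per-position
probability vector ``lambda``; unbound sites cut uniformly (``1/S``).  Read
totals follow per-component negative binomials.  Fitting is plain EM on the
two-component mixture; per-site binding evidence is reported as a posterior
log-odds.

The multinomial coefficient ``R!/prod(X_s!)`` is identical under both
components and is never materialized: every likelihood ratio reduces to
``sum_s X_s * (log lambda_s - log(1/S))``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import expit, gammaln, logsumexp

from .cutmatrix import CutMatrix

__all__ = [
    "FootprintModel",
    "SiteScore",
    "multinomial_log_ratio",
    "fit_footprint_model",
    "score_sites",
    "write_scores_tsv",
]

LAMBDA_PSEUDOCOUNT = 1.0
PROB_FLOOR = 1e-8
PI_CLAMP = 1e-4
NB_SIZE_FLOOR = 0.05
LOG_ODDS_CLIP = 700.0


@dataclass
class FootprintModel:
    """Fitted two-component mixture.

    ``nb_bound`` / ``nb_null`` are (mean, size) pairs; ``size = inf`` marks
    a Poisson fallback (used when the weighted variance does not exceed the
    mean).  ``loglik_trace`` records the EM objective per iteration: the
    observed-data log-likelihood plus the Dirichlet pseudocount regularizer
    on lambda, which is the quantity EM provably does not decrease.
    """

    S: int
    lam: np.ndarray
    nb_bound: tuple[float, float]
    nb_null: tuple[float, float]
    pi: float
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True

    def to_json(self, path: Union[str, Path]) -> None:
        def enc(pair: tuple[float, float]) -> list:
            mean, size = pair
            return [mean, None if math.isinf(size) else size]

        payload = {
            "S": self.S,
            "lambda": self.lam.tolist(),
            "nb_bound": enc(self.nb_bound),
            "nb_null": enc(self.nb_null),
            "pi": self.pi,
            "loglik_trace": self.loglik_trace,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FootprintModel":
        with open(path) as fh:
            d = json.load(fh)

        def dec(pair: list) -> tuple[float, float]:
            mean, size = pair
            return (float(mean), math.inf if size is None else float(size))

        return cls(
            S=int(d["S"]),
            lam=np.asarray(d["lambda"], dtype=float),
            nb_bound=dec(d["nb_bound"]),
            nb_null=dec(d["nb_null"]),
            pi=float(d["pi"]),
            loglik_trace=list(d["loglik_trace"]),
            converged=bool(d["converged"]),
        )

    def oriented_profile(self) -> np.ndarray:
        """Strand-combined per-position cut probability over W oriented columns."""
        w = self.S // 2
        prof = self.lam[:w] + self.lam[w:]
        return prof / prof.sum()


@dataclass
class SiteScore:
    site_id: str
    R: int
    log_odds: float
    posterior: float


def multinomial_log_ratio(X: np.ndarray, lam: np.ndarray) -> float:
    """Log likelihood ratio of the bound vs. uniform multinomial for counts X.

    Equals ``sum_s X_s * (log lambda_s - log(1/S))``; the shared factorial
    terms cancel and are never computed.
    """
    X = np.asarray(X)
    lam = np.asarray(lam, dtype=float)
    if X.shape[-1] != lam.shape[0]:
        raise ValueError(f"length mismatch: X has {X.shape[-1]}, lambda {lam.shape[0]}")
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    if np.any(lam <= 0):
        raise ValueError("lambda must be strictly positive (apply a pseudocount)")
    s = lam.shape[0]
    return float(np.dot(X, np.log(lam) - math.log(1.0 / s)))


def _count_logpmf(r: np.ndarray, mean: float, size: float) -> np.ndarray:
    """Log pmf of the read-total component: NB(mean, size) or Poisson(mean)."""
    r = np.asarray(r, dtype=float)
    mean = max(mean, 1e-8)
    if math.isinf(size):
        return r * math.log(mean) - mean - gammaln(r + 1.0)
    p = size / (size + mean)
    return (
        gammaln(r + size)
        - gammaln(size)
        - gammaln(r + 1.0)
        + size * math.log(p)
        + r * math.log1p(-p)
    )


def _fit_count_component(
    r: np.ndarray, weights: np.ndarray, previous: tuple[float, float]
) -> tuple[float, float]:
    """Responsibility-weighted method-of-moments (mean, size) update.

    Falls back to Poisson when the weighted variance does not exceed the
    mean, and keeps the previous parameters whenever the candidate does not
    improve the weighted log-likelihood (a generalized-EM guard that keeps
    the EM objective monotone).
    """
    wsum = weights.sum()
    if wsum <= 0:
        return previous
    mean = float(np.dot(weights, r) / wsum)
    var = float(np.dot(weights, (r - mean) ** 2) / wsum)
    if mean <= 0:
        return previous
    if var <= mean:
        candidate = (mean, math.inf)
    else:
        candidate = (mean, max(mean * mean / (var - mean), NB_SIZE_FLOOR))
    cand_ll = float(np.dot(weights, _count_logpmf(r, *candidate)))
    prev_ll = float(np.dot(weights, _count_logpmf(r, *previous)))
    return candidate if cand_ll >= prev_ll else previous


def fit_footprint_model(
    m: CutMatrix,
    max_iter: int = 200,
    tol: float = 1e-6,
    pseudocount: float = LAMBDA_PSEUDOCOUNT,
    min_informative_sites: int = 20,
) -> FootprintModel:
    """Fit the two-component mixture by EM on a strand-specific cut matrix.

    Forward and reverse count rows are concatenated (S = 2W).  The fit is
    deterministic: lambda is initialized from the aggregate profile of the
    top half of sites by read total, pi starts at 0.1, and both count
    components start from global moments.
    """
    X = np.hstack([m.forward_counts, m.reverse_counts]).astype(float)
    n, S = X.shape
    R = X.sum(axis=1)
    if X.sum() == 0:
        raise ValueError("cut matrix is all zeros; nothing to fit")
    n_informative = int((R > 0).sum())
    if n_informative < min_informative_sites:
        raise ValueError(
            f"need >= {min_informative_sites} sites with reads, got {n_informative}"
        )

    # deterministic initialization
    order = np.argsort(R, kind="stable")[::-1]
    top = order[: max(n // 2, 1)]
    lam = X[top].sum(axis=0) + pseudocount
    lam = np.maximum(lam / lam.sum(), PROB_FLOOR)
    lam /= lam.sum()
    pi = 0.1
    mean0 = float(R.mean())
    var0 = float(R.var())
    if var0 > mean0 > 0:
        nb = (mean0, max(mean0 * mean0 / (var0 - mean0), NB_SIZE_FLOOR))
    else:
        nb = (max(mean0, 1e-8), math.inf)
    nb_bound = nb
    nb_null = nb

    log_unif = -math.log(S)
    log_lam_term = X @ (np.log(lam) - log_unif)  # per-site multinomial log ratio

    trace: list[float] = []
    prev_obj = -math.inf
    converged = False
    for _ in range(max_iter):
        # E-step
        log_b = math.log(pi) + _count_logpmf(R, *nb_bound) + log_lam_term
        log_0 = math.log1p(-pi) + _count_logpmf(R, *nb_null)
        norm = logsumexp(np.stack([log_b, log_0]), axis=0)
        z = np.exp(log_b - norm)
        # EM objective: observed loglik (minus the constant multinomial
        # coefficient and the constant R * log(1/S) term) + Dirichlet reg.
        obj = float(norm.sum()) + pseudocount * float(np.log(lam).sum())
        trace.append(obj)
        if abs(obj - prev_obj) < tol:
            converged = True
            break
        prev_obj = obj

        # M-step
        pi = float(np.clip(z.mean(), PI_CLAMP, 1.0 - PI_CLAMP))
        lam = (z @ X + pseudocount) / (float(z @ R) + S * pseudocount)
        lam = np.maximum(lam, PROB_FLOOR)
        lam /= lam.sum()
        log_lam_term = X @ (np.log(lam) - log_unif)
        nb_bound = _fit_count_component(R, z, nb_bound)
        nb_null = _fit_count_component(R, 1.0 - z, nb_null)

    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations "
            f"(last delta {trace[-1] - trace[-2]:.3g})",
            RuntimeWarning,
        )
    return FootprintModel(
        S=S,
        lam=lam,
        nb_bound=nb_bound,
        nb_null=nb_null,
        pi=pi,
        loglik_trace=trace,
        converged=converged,
    )


def score_sites(model: FootprintModel, m: CutMatrix) -> list[SiteScore]:
    """Per-site posterior binding log-odds and probability.

    ``log_odds = logit(pi) + log NB ratio + multinomial log ratio``, clipped
    to +-700 before the logistic transform.
    """
    X = np.hstack([m.forward_counts, m.reverse_counts]).astype(float)
    if X.shape[1] != model.S:
        raise ValueError(f"matrix has {X.shape[1]} columns, model expects {model.S}")
    R = X.sum(axis=1)
    log_prior = math.log(model.pi) - math.log1p(-model.pi)
    nb_ratio = _count_logpmf(R, *model.nb_bound) - _count_logpmf(R, *model.nb_null)
    mult_ratio = X @ (np.log(model.lam) + math.log(model.S))
    log_odds = np.clip(log_prior + nb_ratio + mult_ratio, -LOG_ODDS_CLIP, LOG_ODDS_CLIP)
    posterior = expit(log_odds)
    return [
        SiteScore(
            site_id=site.site_id,
            R=int(R[i]),
            log_odds=float(log_odds[i]),
            posterior=float(posterior[i]),
        )
        for i, site in enumerate(m.sites)
    ]


def write_scores_tsv(
    scores: Sequence[SiteScore], m: CutMatrix, path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tchrom\tstart\tend\tstrand\tR\tlog_odds\tposterior\n")
        for site, sc in zip(m.sites, scores):
            fh.write(
                f"{sc.site_id}\t{site.chrom}\t{site.start}\t{site.end}\t"
                f"{site.strand}\t{sc.R}\t{sc.log_odds:.6g}\t{sc.posterior:.6g}\n"
            )
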