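"""Per-tumor RP transcript deregulation against a normal-tissue reference.

The statistic set:

* per-transcript two-sided tail probability under the normal reference,
  P = 2 * (1 - Phi(|x_t - mu_n| / sigma_n)), where x_t is the transcript's
  percent-of-pool value in the tumor and (mu_n, sigma_n) summarize the
  normal samples;
* the per-tumor count of transcripts with P < alpha;
* a cohort-level upper-tail Binomial(n_genes, alpha) test on the floored
  average count, controlling the discovery rate of the whole screen;
* a total deregulation score per tumor: the sum over genes of the absolute
  difference, in percentage points, between the tumor's relative expression
  and the normal mean;
* quartile labels on the score, feeding survival stratification.

`DeregulationModel` wraps the whole set in a fit()/results interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, ndtr

from .relexp import NormalReference, RelativeExpressionMatrix

__all__ = [
    "DeregulationProfile",
    "CohortTestResult",
    "transcript_pvalue",
    "count_deregulated",
    "cohort_binomial_test",
    "deregulation_score",
    "quartile_groups",
    "DeregulationModel",
    "DeregulationResults",
]


@dataclass(frozen=True)
class DeregulationProfile:
    """One tumor's deviation vector, P-values, significant count and score."""

    sample_id: str
    deviation: pd.Series  # rel - mu, percentage points
    pvalue: pd.Series
    n_sig: int
    score: float
    degenerate: pd.Series  # True where sigma = 0 forced the P-value


@dataclass(frozen=True)
class CohortTestResult:
    """Upper-tail binomial test on the cohort's floored mean significant count."""

    n_genes: int
    alpha: float
    mean_count: float
    k: int
    p_binomial: float
    log10_p: float

    def __str__(self) -> str:
        return (
            f"mean significant transcripts/tumor = {self.mean_count:.4g} "
            f"(k = {self.k}); upper-tail B({self.n_genes}, {self.alpha}) "
            f"P = {self.p_binomial:.3g}"
        )


def transcript_pvalue(x_t, mu, sigma):
    """Two-sided normal tail probability of a relative-expression value.

    P = 2 * (1 - Phi(|x_t - mu| / sigma)).  Vectorized; returns
    (pvalue, degenerate) where ``degenerate`` flags sigma = 0 positions
    (there P is 1 if x_t equals mu exactly, else 0).
    """
    x_t = np.asarray(x_t, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if (sigma < 0).any():
        raise ValueError("sigma must be nonnegative")
    degenerate = np.broadcast_to(sigma == 0, np.broadcast_shapes(x_t.shape, mu.shape, sigma.shape))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(x_t - mu) / sigma
    # 2 * (1 - Phi(z)) evaluated as 2 * Phi(-z) so deep tails keep precision
    p = np.where(degenerate, np.where(x_t == mu, 1.0, 0.0), 2.0 * ndtr(-z))
    if p.ndim == 0:
        return float(p), bool(degenerate)
    return p, np.asarray(degenerate)


def count_deregulated(pvalues, alpha: float) -> int:
    """Strict count of P-values below alpha."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("P-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return int((p < alpha).sum())


def _log_binom_sf(k: int, n: int, alpha: float) -> float:
    """log of the upper tail sum_{j=k}^{n} C(n,j) alpha^j (1-alpha)^(n-j)."""
    if k <= 0:
        return 0.0
    j = np.arange(k, n + 1)
    log_pmf = (
        gammaln(n + 1)
        - gammaln(j + 1)
        - gammaln(n - j + 1)
        + j * math.log(alpha)
        + (n - j) * math.log1p(-alpha)
    )
    return float(logsumexp(log_pmf))


def cohort_binomial_test(counts, n_genes: int, alpha: float = 0.05) -> CohortTestResult:
    """Cohort-level false-discovery control for the per-tumor counts.

    Under the null every transcript independently reaches P < alpha with
    probability alpha, so the per-tumor count is Binomial(n_genes, alpha).
    The observed mean count is floored and the one-sided (upper tail)
    probability of a count at least that large is reported.  Computed in log
    space so tails far below double underflow still come back exact.
    """
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if ((counts < 0) | (counts > n_genes)).any():
        raise ValueError(f"counts must lie in [0, {n_genes}]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    mean_count = float(counts.mean())
    k = math.floor(mean_count)
    log_p = _log_binom_sf(k, n_genes, alpha)
    return CohortTestResult(
        n_genes=n_genes,
        alpha=alpha,
        mean_count=mean_count,
        k=k,
        p_binomial=math.exp(log_p),
        log10_p=log_p / math.log(10.0),
    )


def deregulation_score(rel_tumor: pd.Series, reference: NormalReference, alpha: float = 0.05):
    """Build one tumor's DeregulationProfile against the normal reference."""
    if len(rel_tumor) != len(reference.mu):
        raise ValueError("tumor vector and reference have different lengths")
    if isinstance(rel_tumor, pd.Series):
        if list(rel_tumor.index) != list(reference.mu.index):
            raise ValueError("tumor vector genes do not match the reference gene set")
        values = rel_tumor.to_numpy(dtype=float)
        name = str(rel_tumor.name) if rel_tumor.name is not None else ""
    else:
        values = np.asarray(rel_tumor, dtype=float)
        name = ""
    deviation = values - reference.mu.to_numpy()
    p, degenerate = transcript_pvalue(values, reference.mu.to_numpy(), reference.sigma.to_numpy())
    index = reference.mu.index
    return DeregulationProfile(
        sample_id=name,
        deviation=pd.Series(deviation, index=index),
        pvalue=pd.Series(np.atleast_1d(p), index=index),
        n_sig=count_deregulated(np.atleast_1d(p), alpha),
        score=float(np.abs(deviation).sum()),
        degenerate=pd.Series(np.atleast_1d(degenerate), index=index),
    )


def quartile_groups(scores) -> dict[str, str]:
    """Label the top and bottom score quartiles of a cohort.

    Samples are ranked by score descending; the top ceil(N/4) get "upper",
    the bottom ceil(N/4) "lower", the rest "middle".  Boundary ties break by
    ascending sample ID, so the assignment is deterministic.
    """
    scores = dict(scores)
    n = len(scores)
    if n < 4:
        raise ValueError(f"need >= 4 samples for quartile groups, got {n}")
    ranked = sorted(scores, key=lambda s: (-scores[s], s))
    q = math.ceil(n / 4)
    labels = {s: "middle" for s in ranked}
    for s in ranked[:q]:
        labels[s] = "upper"
    for s in ranked[-q:]:
        labels[s] = "lower"
    return labels


class DeregulationModel:
    """Cohort deregulation analysis: tumors scored against a normal reference.

    Parameters
    ----------
    tumors : RelativeExpressionMatrix
        Percent-of-pool values for the tumor samples.
    reference : NormalReference
        Per-gene (mu, sigma) from normal tissue.
    alpha : float
        Per-transcript significance threshold (default 0.05).

    Examples
    --------
    >>> model = DeregulationModel.from_expression(matrix)   # doctest: +SKIP
    >>> results = model.fit()                               # doctest: +SKIP
    >>> print(results.summary())                            # doctest: +SKIP
    """

    def __init__(
        self,
        tumors: RelativeExpressionMatrix,
        reference: NormalReference,
        alpha: float = 0.05,
    ) -> None:
        if tumors.gene_set.genes != reference.gene_set.genes:
            raise ValueError("tumor matrix and reference gene sets differ")
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.tumors = tumors
        self.reference = reference
        self.alpha = alpha

    @classmethod
    def from_expression(
        cls,
        matrix,
        normal_group: str = "normal",
        tumor_group: str = "tumor",
        alpha: float = 0.05,
    ) -> "DeregulationModel":
        """Build from a raw ExpressionMatrix holding both normals and tumors."""
        from .relexp import normal_reference, relative_percent

        rel = relative_percent(matrix)
        normals = rel.subset_samples(rel.samples_in_group(normal_group))
        tumors = rel.subset_samples(rel.samples_in_group(tumor_group))
        if not tumors.samples:
            raise ValueError(f"no samples in tumor group {tumor_group!r}")
        return cls(tumors, normal_reference(normals), alpha=alpha)

    def fit(self) -> "DeregulationResults":
        mu = self.reference.mu.to_numpy()[:, None]
        sigma = self.reference.sigma.to_numpy()[:, None]
        values = self.tumors.values
        p, degenerate = transcript_pvalue(values, mu, sigma)
        deviations = values - mu
        genes = self.reference.mu.index
        samples = self.tumors.samples
        pvalues = pd.DataFrame(p, index=genes, columns=samples)
        dev = pd.DataFrame(deviations, index=genes, columns=samples)
        n_sig = pd.Series((p < self.alpha).sum(axis=0).astype(int), index=samples, name="n_sig")
        scores = pd.Series(np.abs(deviations).sum(axis=0), index=samples, name="score")
        cohort = cohort_binomial_test(n_sig.to_numpy(), len(genes), self.alpha)
        quartiles = pd.Series(quartile_groups(scores)) if len(samples) >= 4 else None
        return DeregulationResults(
            model=self,
            deviations=dev,
            pvalues=pvalues,
            degenerate=pd.DataFrame(np.broadcast_to(degenerate, p.shape), index=genes, columns=samples),
            n_sig=n_sig,
            scores=scores,
            cohort_test=cohort,
            quartiles=quartiles,
        )


class DeregulationResults:
    """Fitted cohort deregulation: per-tumor profiles plus the cohort test."""

    def __init__(self, model, deviations, pvalues, degenerate, n_sig, scores, cohort_test, quartiles):
        self.model = model
        self.deviations = deviations
        self.pvalues = pvalues
        self.degenerate = degenerate
        self.n_sig = n_sig
        self.scores = scores
        self.cohort_test = cohort_test
        self.quartiles = quartiles

    @property
    def profiles(self) -> list[DeregulationProfile]:
        """Per-tumor profiles (one object per sample, in cohort order)."""
        return [
            DeregulationProfile(
                sample_id=s,
                deviation=self.deviations[s],
                pvalue=self.pvalues[s],
                n_sig=int(self.n_sig[s]),
                score=float(self.scores[s]),
                degenerate=self.degenerate[s],
            )
            for s in self.scores.index
        ]

    def to_frame(self) -> pd.DataFrame:
        """One row per tumor: n_sig, score, quartile label."""
        frame = pd.DataFrame({"n_sig": self.n_sig, "score": self.scores})
        frame.index.name = "sample_id"
        if self.quartiles is not None:
            frame["quartile"] = self.quartiles
        return frame

    def summary(self) -> str:
        lines = [
            "Cohort RP transcript deregulation",
            "=" * 48,
            f"genes               : {self.deviations.shape[0]}",
            f"tumors              : {self.deviations.shape[1]}",
            f"normals in reference: {self.model.reference.n_normals}",
            f"alpha               : {self.model.alpha}",
            "-" * 48,
            f"mean sig. transcripts/tumor : {self.cohort_test.mean_count:.2f}",
            f"floored mean (k)            : {self.cohort_test.k}",
            f"cohort binomial P           : {self.cohort_test.p_binomial:.3g}",
            f"mean deregulation score     : {self.scores.mean():.2f} pct points",
            f"score quartile cut (upper)  : "
            f"{self.scores.sort_values(ascending=False).iloc[max(0, math.ceil(len(self.scores)/4)-1)]:.2f}"
            if len(self.scores) >= 4
            else "score quartiles             : n/a (< 4 tumors)",
            "=" * 48,
        ]
        return "\n".join(lines)
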