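"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates what the analysis needs from real data and nothing
more: per-gene baseline abundances spread over orders of magnitude (so the
lowest-abundance transcripts show far larger relative-expression
variability, as in real normal tissue), negative-binomial count noise,
tumors with a planted subset of fold-perturbed genes, and exponential
survival whose log-hazard rises with the true (planted) deregulation
score, under independent uniform censoring.

Negative-binomial noise is chosen deliberately: its CV^2 = 1/mean + 1/size
makes relative-expression variability rise at low abundance without any
hand-tuned heteroscedasticity.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GeneSet, SurvivalRecord
from .relexp import NormalReference, RelativeExpressionMatrix

__all__ = ["SimulationParams", "SimulatedCohort", "simulate_cohort", "simulate_null_tumors"]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the cohort generator.

    Defaults mirror a liver-cancer-sized study: 77 RP genes, 50 normal
    samples, 373 tumors, baselines log-uniform over three orders of
    magnitude, a fifth of the genes perturbed per tumor by 1.5-4 fold, and
    ~30% censoring.
    """

    n_genes: int = 77
    n_normals: int = 50
    n_tumors: int = 373
    #: per-gene baseline mean counts drawn log10-uniform over this range
    baseline_logmean_range: tuple[float, float] = (0.0, 3.0)
    #: negative-binomial size parameter (var = m + m^2/dispersion)
    dispersion: float = 100.0
    frac_deregulated: float = 0.2
    #: multiplicative fold range for perturbed genes (inverted half the time)
    effect_size_range: tuple[float, float] = (1.5, 4.0)
    #: log-hazard slope on the standardized true deregulation score
    hazard_coef: float = 0.5
    #: events per time unit for a tumor with average deregulation
    baseline_hazard: float = 1e-3
    censor_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_normals < 0 or self.n_tumors < 0:
            raise ValueError("sample counts must be nonnegative")
        if not 0 <= self.frac_deregulated <= 1:
            raise ValueError("frac_deregulated must lie in [0, 1]")
        if not 0 <= self.censor_frac < 1:
            raise ValueError("censor_frac must lie in [0, 1)")
        lo, hi = self.effect_size_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("effect sizes must be positive with lo <= hi")
        if self.dispersion <= 0 or self.baseline_hazard <= 0:
            raise ValueError("dispersion and baseline_hazard must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulatedCohort:
    """Expression + clinical tables plus the planted ground truth."""

    expression: ExpressionMatrix
    #: per-tumor truth: true_score (percentage points), n_perturbed
    truth: pd.DataFrame
    #: long table of planted perturbations: sample_id, gene, fold
    perturbations: pd.DataFrame
    clinical: list[SurvivalRecord]
    params: SimulationParams


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial draws with the given means (NB2 parameterization)."""
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p).astype(float)


def _tune_uniform_censoring(times: np.ndarray, censor_frac: float) -> float:
    """Upper bound c of U(0, c) censoring hitting the target censored fraction.

    With C ~ U(0, c), P(censored | T = t) = min(t, c) / c; the expectation
    over the drawn times is monotone decreasing in c, so bisection finds c.
    """

    def frac(c: float) -> float:
        return float(np.minimum(times, c).mean() / c)

    lo = float(times.min()) * 1e-6 + 1e-12
    hi = float(times.max()) * 2 + 1e-9
    while frac(hi) > censor_frac:
        hi *= 2
        if hi > 1e18:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > censor_frac:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(params: SimulationParams | None = None, **overrides) -> SimulatedCohort:
    """Draw one cohort: normals, tumors with planted deregulation, survival.

    The same seed always yields a bit-identical cohort; baselines, count
    noise, perturbation choices, survival and censoring each use an
    independent substream of the seed.
    """
    if params is None:
        params = SimulationParams(**overrides)
    elif overrides:
        params = SimulationParams(**{**params.to_dict(), **overrides})
    streams = np.random.SeedSequence(params.seed).spawn(5)
    rng_base = np.random.default_rng(streams[0])
    rng_counts = np.random.default_rng(streams[1])
    rng_perturb = np.random.default_rng(streams[2])
    rng_surv = np.random.default_rng(streams[3])
    rng_cens = np.random.default_rng(streams[4])

    g = params.n_genes
    lo, hi = params.baseline_logmean_range
    baselines = 10.0 ** rng_base.uniform(lo, hi, size=g)
    gene_set = GeneSet("simulated_rp", tuple(f"RPG{i+1:03d}" for i in range(g)))
    baseline_rel = 100.0 * baselines / baselines.sum()

    normal_ids = [f"N{i+1:04d}" for i in range(params.n_normals)]
    tumor_ids = [f"T{i+1:04d}" for i in range(params.n_tumors)]

    normal_counts = _nb_draw(
        rng_counts, np.repeat(baselines[:, None], params.n_normals, axis=1), params.dispersion
    ) if params.n_normals else np.empty((g, 0))

    n_perturbed = round(params.frac_deregulated * g)
    flo, fhi = params.effect_size_range
    tumor_means = np.repeat(baselines[:, None], params.n_tumors, axis=1)
    perturb_rows = []
    true_scores = np.zeros(params.n_tumors)
    for j, tid in enumerate(tumor_ids):
        idx = rng_perturb.choice(g, size=n_perturbed, replace=False)
        folds = rng_perturb.uniform(flo, fhi, size=n_perturbed)
        invert = rng_perturb.random(n_perturbed) < 0.5
        folds = np.where(invert, 1.0 / folds, folds)
        tumor_means[idx, j] *= folds
        # planted truth is compositional: the recoverable target is the
        # post-renormalization shift of expected relative expression
        true_rel = 100.0 * tumor_means[:, j] / tumor_means[:, j].sum()
        true_scores[j] = np.abs(true_rel - baseline_rel).sum()
        for i, f in zip(idx, folds):
            perturb_rows.append((tid, gene_set.genes[i], float(f)))
    tumor_counts = (
        _nb_draw(rng_counts, tumor_means, params.dispersion)
        if params.n_tumors
        else np.empty((g, 0))
    )

    data = pd.DataFrame(
        np.concatenate([normal_counts, tumor_counts], axis=1),
        index=gene_set.index(),
        columns=normal_ids + tumor_ids,
    )
    # a sample whose every gene drew 0 cannot be normalized; nudge the most
    # abundant gene to 1 (vanishingly rare outside extreme parameter choices)
    zero_cols = data.sum(axis=0) == 0
    if zero_cols.any():
        data.loc[data.index[int(np.argmax(baselines))], zero_cols[zero_cols].index] = 1.0
    groups = {s: "normal" for s in normal_ids} | {s: "tumor" for s in tumor_ids}
    expression = ExpressionMatrix(gene_set, data, groups)

    clinical: list[SurvivalRecord] = []
    if params.n_tumors:
        z = (true_scores - true_scores.mean()) / (true_scores.std() or 1.0)
        hazard = params.baseline_hazard * np.exp(params.hazard_coef * z)
        event_times = rng_surv.exponential(1.0 / hazard)
        if params.censor_frac > 0:
            c = _tune_uniform_censoring(event_times, params.censor_frac)
            censor_times = rng_cens.uniform(0.0, c, size=params.n_tumors)
            observed = np.minimum(event_times, censor_times)
            events = event_times <= censor_times
        else:
            observed, events = event_times, np.ones(params.n_tumors, dtype=bool)
        if not events.any():
            raise ValueError("censor_frac left zero observed events; lower it")
        clinical = [
            SurvivalRecord(tid, float(t), bool(e))
            for tid, t, e in zip(tumor_ids, observed, events)
        ]

    truth = pd.DataFrame(
        {"true_score": true_scores, "n_perturbed": n_perturbed},
        index=pd.Index(tumor_ids, name="sample_id"),
    )
    perturbations = pd.DataFrame(perturb_rows, columns=["sample_id", "gene", "fold"])
    return SimulatedCohort(
        expression=expression,
        truth=truth,
        perturbations=perturbations,
        clinical=clinical,
        params=params,
    )


def simulate_null_tumors(reference: NormalReference, n: int, seed: int) -> RelativeExpressionMatrix:
    """Tumors indistinguishable from the normals that built ``reference``.

    Gene-wise Normal(mu, sigma) draws, clipped at zero and renormalized to
    sum 100.  Used to calibrate the per-transcript tail test: against a
    reference built the same way, ~alpha of the resulting P-values fall
    below alpha.
    """
    if (reference.sigma.to_numpy() <= 0).any():
        raise ValueError("all reference sigmas must be positive")
    rng = np.random.default_rng(seed)
    gene_set = reference.gene_set
    cols = [f"NT{i+1:05d}" for i in range(n)]
    if n == 0:
        rel = pd.DataFrame(index=gene_set.index(), columns=cols, dtype=float)
        return RelativeExpressionMatrix(gene_set, rel, {})
    draws = rng.normal(
        reference.mu.to_numpy()[:, None], reference.sigma.to_numpy()[:, None], size=(len(gene_set), n)
    )
    draws = np.clip(draws, 0.0, None)
    rel = pd.DataFrame(
        100.0 * draws / draws.sum(axis=0), index=gene_set.index(), columns=cols
    )
    return RelativeExpressionMatrix(gene_set, rel, {c: "null_tumor" for c in cols})
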