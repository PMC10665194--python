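"""Cell-composition testing by beta-binomial regression, plus power simulation.

For each cell type, per-embryo counts (k out of n total cells, size-factor
normalized and rounded) are modelled as beta-binomial with a logit-linear
mean, ``logit(mu) = intercept + coef x genotype``, and a shared
overdispersion ``rho`` in [0, 1): given mean mu, the per-embryo proportion is
Beta(mu(1-rho)/rho, (1-mu)(1-rho)/rho), so the variance of k/n is inflated by
a factor 1 + (n-1)rho over binomial. ``rho -> 0`` recovers binomial logistic
regression. The genotype effect is tested by a Wald z-test from the observed
information (likelihood-ratio fallback when the Hessian is degenerate).

Mutant genotypes are tested within their background strain against a pooled
reference of all other same-background embryos (wild type plus other
mutants). Cell types with a normalized mean below ``min_mean_cells`` per
embryo are reported untested; significance is at an uncorrected alpha and
flagged as nominal. Effect summaries are log2 proportion ratios on merged
counts, clipped for display at +/- ``log2_display_clip``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betaln, expit, gammaln, logit
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess

from .config import PipelineConfig
from .datasets import CellDataset, CompositionTable
from .qc import compute_size_factors

__all__ = [
    "BetaBinomFit", "BetaBinomialGLM", "fit_beta_binomial",
    "build_count_matrix", "test_composition_all", "log2_proportion_ratio",
    "simulate_power",
]

log = logging.getLogger("phenoscape.composition")

_RHO_EPS = 1e-8


@dataclass
class BetaBinomFit:
    """Maximum-likelihood beta-binomial regression fit."""

    coef_intercept: float
    coef_genotype: float
    rho: float
    loglik: float
    se_genotype: float
    p_value: float
    converged: bool
    test: str = "wald"     # or "lr" when the Hessian was degenerate
    se_rho: float = float("nan")   # delta method from the logit-rho scale


def betabinom_loglik(params: np.ndarray, k: np.ndarray, n: np.ndarray,
                     x: np.ndarray) -> float:
    """Beta-binomial log-likelihood at (intercept, coef, logit(rho))."""
    b0, b1, zrho = params
    mu = expit(b0 + b1 * x)
    rho = min(max(expit(zrho), _RHO_EPS), 1 - _RHO_EPS)
    s = (1.0 - rho) / rho
    a = mu * s
    b = (1.0 - mu) * s
    ll = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
          + betaln(k + a, n - k + b) - betaln(a, b))
    return float(ll.sum())


def _binomial_loglik(params: np.ndarray, k, n, x) -> float:
    b0, b1 = params
    mu = expit(b0 + b1 * x)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    ll = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
          + k * np.log(mu) + (n - k) * np.log1p(-mu))
    return float(ll.sum())


def _binomial_start(k, n, x) -> tuple[float, float]:
    # two-group binomial MLE is the pooled empirical logit of each group
    p1 = (k[x == 1].sum() + 0.5) / (n[x == 1].sum() + 1.0)
    p0 = (k[x == 0].sum() + 0.5) / (n[x == 0].sum() + 1.0)
    return float(logit(p0)), float(logit(p1) - logit(p0))


class BetaBinomialGLM(BaseEstimator):
    """Beta-binomial regression of per-embryo counts on a binary covariate.

    Attributes (after :meth:`fit`): ``intercept_``, ``coef_`` (genotype
    effect, logit scale), ``rho_``, ``loglik_``, ``se_``, ``pvalue_``,
    ``converged_``, ``test_``.
    """

    def __init__(self, rho_starts: tuple[float, ...] = (0.001, 0.01, 0.1)):
        self.rho_starts = rho_starts

    def fit(self, genotype, successes, totals) -> "BetaBinomialGLM":
        x = np.asarray(genotype, dtype=float)
        k = np.asarray(successes, dtype=float)
        n = np.asarray(totals, dtype=float)
        if (k > n).any():
            raise ValueError("successes exceed totals")
        if (k < 0).any() or (n <= 0).any():
            raise ValueError("need n > 0 and k >= 0")
        groups = np.unique(x)
        if len(groups) != 2:
            raise ValueError("genotype must be binary with both levels present")
        x = (x == groups.max()).astype(float)
        if (x == 1).sum() < 2 or (x == 0).sum() < 2:
            raise ValueError("need at least 2 embryos per genotype group")

        import warnings as _warnings

        def _guard(fun):
            def wrapped(p):
                v = fun(p)
                return v if np.isfinite(v) else 1e12
            return wrapped

        b0, b1 = _binomial_start(k, n, x)
        nll = _guard(lambda p: -betabinom_loglik(p, k, n, x))
        bin_nll = _guard(lambda p: -_binomial_loglik(p, k, n, x))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            binom = optimize.minimize(
                bin_nll, np.array([b0, b1]), method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11})
            best = None
            for rho0 in self.rho_starts:
                start = np.array([b0, b1, logit(rho0)])
                res = optimize.minimize(nll, start, method="L-BFGS-B")
                if best is None or res.fun < best.fun:
                    best = res
            self.converged_ = bool(best.success)
            if not self.converged_:
                # one Nelder-Mead rescue from the best point so far
                res = optimize.minimize(
                    nll, best.x, method="Nelder-Mead",
                    options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
                if res.fun <= best.fun:
                    best = res
                self.converged_ = bool(best.success)

        # rho -> 0 boundary: the supremum is the binomial fit; take it when
        # it beats the interior optimum (the zrho axis is flat there)
        boundary = np.array([binom.x[0], binom.x[1], logit(_RHO_EPS)])
        at_boundary = nll(boundary) <= best.fun
        if at_boundary:
            params = boundary
            self.loglik_ = -float(binom.fun)
            self.converged_ = True
        else:
            params = best.x
            self.loglik_ = -float(best.fun)
        self.intercept_, self.coef_ = float(params[0]), float(params[1])
        self.rho_ = float(np.clip(expit(params[2]), _RHO_EPS, 1 - _RHO_EPS))
        self._wald_or_lr(params, k, n, x, nll, binomial=at_boundary)
        return self

    @staticmethod
    def _hess(params, fun):
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            return approx_hess(params, fun)

    def _wald_or_lr(self, params, k, n, x, nll, binomial: bool = False) -> None:
        self.test_ = "wald"
        try:
            if binomial:
                # rho on the boundary: profile information over (b0, b1)
                H = self._hess(params[:2],
                               lambda p: -_binomial_loglik(p, k, n, x))
                cov = np.linalg.inv(H)
                self.se_rho_ = float("nan")
            else:
                H = self._hess(params, nll)
                cov = np.linalg.inv(H)
                var_z = cov[2, 2]
                self.se_rho_ = float(
                    np.sqrt(var_z) * self.rho_ * (1 - self.rho_)
                ) if var_z > 0 else float("nan")
            var = cov[1, 1]
            if not np.isfinite(var) or var <= 0:
                raise np.linalg.LinAlgError("non-positive variance")
            self.se_ = float(np.sqrt(var))
            z = self.coef_ / self.se_
            self.pvalue_ = float(2 * stats.norm.sf(abs(z)))
        except np.linalg.LinAlgError:
            # near-singular observed information: likelihood-ratio fallback
            self.test_ = "lr"
            self.se_ = float("nan")
            self.se_rho_ = float("nan")
            null_nll = lambda p: -betabinom_loglik(
                np.array([p[0], 0.0, p[1]]), k, n, x)
            starts = [np.array([params[0], params[2]])]
            best = None
            for s in starts:
                res = optimize.minimize(null_nll, s, method="Nelder-Mead")
                if best is None or res.fun < best.fun:
                    best = res
            lr = 2 * (self.loglik_ + best.fun)
            self.pvalue_ = float(stats.chi2.sf(max(lr, 0.0), df=1))
        if not self.converged_:
            self.pvalue_ = float("nan")

    def result(self) -> BetaBinomFit:
        return BetaBinomFit(
            coef_intercept=self.intercept_, coef_genotype=self.coef_,
            rho=self.rho_, loglik=self.loglik_, se_genotype=self.se_,
            p_value=self.pvalue_, converged=self.converged_, test=self.test_,
            se_rho=self.se_rho_)


def fit_beta_binomial(k, n, genotype) -> BetaBinomFit:
    """ML beta-binomial fit of per-embryo successes/totals on genotype."""
    return BetaBinomialGLM().fit(genotype, k, n).result()


def build_count_matrix(dataset: CellDataset,
                       level: str = "sub") -> CompositionTable:
    """Cross-tabulate cells by embryo x trajectory annotation."""
    col = {"major": "major_trajectory", "sub": "sub_trajectory"}[level]
    annot = dataset.cells[col].astype(str)
    keep = (annot != "") & (annot != "nan")
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("build_count_matrix: excluding %d unannotated cells", n_dropped)
    if not keep.any():
        raise ValueError(f"no cells carry a {col} annotation")
    cells = dataset.cells.loc[keep]
    counts = pd.crosstab(cells["embryo_id"], annot[keep])
    counts = counts.loc[list(dict.fromkeys(cells["embryo_id"]))]  # input order
    counts.index.name = "embryo_id"
    counts.columns.name = None
    meta = (cells[["embryo_id", "genotype", "background"]]
            .drop_duplicates("embryo_id").set_index("embryo_id")
            .loc[counts.index].reset_index())
    sf = compute_size_factors(counts.sum(axis=1))
    return CompositionTable(counts=counts, embryo_meta=meta, size_factors=sf)


def log2_proportion_ratio(n_mut: float, total_mut: float, n_ref: float,
                          total_ref: float, pseudocount: float = 0.5) -> float:
    """log2 of mutant vs reference cell-type proportion, zero-guarded."""
    if total_mut <= 0 or total_ref <= 0:
        raise ValueError("totals must be positive")
    p_mut = (n_mut + pseudocount) / (total_mut + pseudocount)
    p_ref = (n_ref + pseudocount) / (total_ref + pseudocount)
    return float(np.log2(p_mut / p_ref))


def test_composition_all(table: CompositionTable,
                         config: PipelineConfig,
                         normalize_totals: bool = True) -> pd.DataFrame:
    """Test every (mutant genotype, cell type) against its pooled reference.

    Counts are size-factor normalized then rounded to integers before
    regression (``normalize_totals=False`` regresses on the raw counts
    instead). Returns one row per genotype x type with the log2 proportion
    ratio (raw and display-clipped), the nominal p-value, and a ``tested``
    flag (false when the normalized mean count is below ``min_mean_cells``).
    """
    meta = table.embryo_meta.set_index("embryo_id")
    if normalize_totals:
        norm = np.rint(
            table.counts.div(table.size_factors, axis=0)).astype(np.int64)
    else:
        norm = table.counts.astype(np.int64)
    results = []
    for background, bg_meta in meta.groupby("background", sort=True):
        genotypes = bg_meta["genotype"].unique()
        if len(genotypes) < 2:
            log.warning("background %r has a single genotype; skipped",
                        background)
            continue
        bg_counts = norm.loc[bg_meta.index]
        n_total = bg_counts.sum(axis=1)
        mean_counts = bg_counts.mean(axis=0)
        for genotype in sorted(g for g in genotypes if g != "wt"):
            is_mut = (bg_meta["genotype"] == genotype).to_numpy()
            raw_mut = table.counts.loc[bg_meta.index[is_mut]].sum(axis=0)
            raw_ref = table.counts.loc[bg_meta.index[~is_mut]].sum(axis=0)
            for ct in bg_counts.columns:
                tested = bool(mean_counts[ct] >= config.min_mean_cells)
                ratio = log2_proportion_ratio(
                    raw_mut[ct], raw_mut.sum(), raw_ref[ct], raw_ref.sum())
                clip = config.log2_display_clip
                row = {
                    "background": background, "genotype": genotype,
                    "cell_type": ct,
                    "n_mut_cells": int(raw_mut[ct]),
                    "n_ref_cells": int(raw_ref[ct]),
                    "log2_ratio": ratio,
                    "log2_ratio_display": float(np.clip(ratio, -clip, clip)),
                    "tested": tested, "p_value": np.nan,
                    "significant_nominal": False,
                }
                if tested:
                    try:
                        fit = fit_beta_binomial(
                            bg_counts[ct].to_numpy(), n_total.to_numpy(),
                            is_mut.astype(int))
                        row["p_value"] = fit.p_value
                        row["significant_nominal"] = bool(
                            np.isfinite(fit.p_value)
                            and fit.p_value < config.alpha)
                    except (ValueError, RuntimeError) as exc:
                        log.warning("fit failed for %s/%s: %s", genotype, ct,
                                    exc)
                        row["tested"] = False
                results.append(row)
    out = pd.DataFrame(results)
    if len(out):
        out = out.sort_values(
            ["background", "genotype", "cell_type"]).reset_index(drop=True)
    return out


def simulate_power(
    base_proportions,
    effect_sizes,
    n_replicates,
    config: PipelineConfig,
    type_indices=None,
    cells_per_embryo_mean: float = 15_000.0,
    cells_per_embryo_sd: float = 3_000.0,
    dirichlet_concentration: float = 2e4,
    seed: int | None = None,
) -> pd.DataFrame:
    """Power of the composition test over effect sizes, replicate counts and types.

    For each grid point, ``config.n_power_sims`` cohorts are simulated with
    the shift applied to that cell type alone; power is the fraction of
    simulations reaching ``p < alpha`` for the shifted type.
    """
    from .synthetic import CohortDesign, simulate_composition_cohort

    base = np.asarray(base_proportions, dtype=float)
    if type_indices is None:
        type_indices = list(range(len(base)))
    seed = config.seed if seed is None else seed
    rows = []
    for t in type_indices:
        for effect in effect_sizes:
            for n_rep in n_replicates:
                hits = 0
                n_ok = 0
                for s in range(config.n_power_sims):
                    sub_seed = (hash((seed, t, round(effect * 1e6), n_rep, s))
                                % (2**31 - 1))
                    design = CohortDesign(
                        base_proportions=base,
                        dirichlet_concentration=dirichlet_concentration,
                        n_wt_embryos=n_rep, n_mut_embryos=n_rep,
                        cells_per_embryo_mean=cells_per_embryo_mean,
                        cells_per_embryo_sd=cells_per_embryo_sd,
                        effect_sizes={t: effect}, seed=sub_seed)
                    cohort = simulate_composition_cohort(design)
                    norm = np.rint(cohort.counts.div(
                        cohort.size_factors, axis=0)).astype(np.int64)
                    is_mut = (cohort.embryo_meta["genotype"] == "mut"
                              ).to_numpy().astype(int)
                    fit = fit_beta_binomial(
                        norm.iloc[:, t].to_numpy(),
                        norm.sum(axis=1).to_numpy(), is_mut)
                    if np.isfinite(fit.p_value):
                        n_ok += 1
                        hits += fit.p_value < config.alpha
                rows.append({
                    "type_index": t, "abundance": base[t], "effect": effect,
                    "n_replicates": n_rep,
                    "power": hits / max(n_ok, 1), "n_sims": n_ok,
                    "alpha": config.alpha,
                })
    return pd.DataFrame(rows)
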