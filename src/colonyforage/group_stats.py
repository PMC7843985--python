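"""Inferential layer: rank tests, mixed models, PCA, diet models.

Everything here wraps a standard routine (scipy.stats, statsmodels)
behind a uniform :class:`TestResult` so pipeline output is one flat
table of named tests.  The substantive choices:

* group comparisons of skewed trip metrics use Kruskal–Wallis followed
  by pairwise Mann–Whitney (Wilcoxon rank-sum) tests with Bonferroni
  correction;
* repeated trips by the same bird are pseudo-replicates, so species
  effects on log-metrics are also fit with a random intercept per bird;
* the seven trip metrics are summarised by PCA on the correlation
  matrix, retaining components with eigenvalue > 1 (Kaiser rule);
* diet composition differences use Pearson χ² after dropping prey
  species observed fewer than five times; prey counts per load use a
  quasi-Poisson (overdispersed log-link) model; prey size vs number is
  ordinary least squares.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    adjusted_p: float | None = None
    groups: tuple = ()
    n_per_group: tuple = ()
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "adjusted_p": self.adjusted_p,
            "groups": list(self.groups),
            "n_per_group": list(self.n_per_group),
        }
        d.update(self.extra)
        return d


@dataclass
class PcaResult:
    loadings: pd.DataFrame  # metric × component
    eigenvalues: np.ndarray
    scores: pd.DataFrame  # trip × component
    retained: int


def _split_groups(values, groups) -> dict:
    s = pd.Series(np.asarray(values, dtype=float), index=np.asarray(groups))
    return {g: s.loc[[g]].to_numpy() for g in pd.unique(s.index)}


def kruskal_by_group(values, groups) -> TestResult:
    """Tie-corrected Kruskal–Wallis H test across ≥2 groups."""
    by = _split_groups(values, groups)
    if len(by) < 2:
        raise ValueError("need at least two groups")
    samples = list(by.values())
    if np.ptp(np.concatenate(samples)) == 0:
        # all values identical: H is 0 by definition, scipy raises instead
        return TestResult("kruskal", 0.0, 1.0, df=len(by) - 1,
                          groups=tuple(by), n_per_group=tuple(len(v) for v in samples))
    h, p = stats.kruskal(*samples)
    return TestResult(
        "kruskal", float(h), float(p), df=len(by) - 1,
        groups=tuple(by), n_per_group=tuple(len(v) for v in samples),
    )


def pairwise_wilcoxon(values, groups, correction: str = "bonferroni") -> list[TestResult]:
    """Two-sided Mann–Whitney rank-sum tests for every group pair.

    Exact p-values when the combined sample is small (≤25) and tie-free,
    a continuity-corrected normal approximation otherwise.  Bonferroni
    multiplies each p by the number of pairs (capped at 1).
    """
    by = _split_groups(values, groups)
    if len(by) < 2:
        raise ValueError("need at least two groups")
    pairs = list(itertools.combinations(by, 2))
    results = []
    for g1, g2 in pairs:
        a, b = by[g1], by[g2]
        pooled = np.concatenate([a, b])
        ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(pooled) <= 25 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
        p = float(res.pvalue)
        adj = min(1.0, p * len(pairs)) if correction == "bonferroni" else p
        results.append(
            TestResult(
                "wilcoxon_rank_sum", float(res.statistic), p, adjusted_p=adj,
                groups=(g1, g2), n_per_group=(len(a), len(b)),
                extra={"method": method, "n_comparisons": len(pairs)},
            )
        )
    return results


def lmm_species_effect(values, species, bird_id, log_transform: bool = True) -> TestResult:
    """Species fixed effect on a (log) trip metric with a bird random intercept.

    Fits log(metric) ~ species + (1 | bird) via restricted maximum
    likelihood and reports a Wald F test of the species terms, with
    denominator df approximated as n − rank − (n_birds − 1) (recorded in
    the output as ``df_method``).  When every bird contributed exactly
    one trip the random intercept is unidentifiable and the model
    reduces to a one-way fixed-effects ANOVA on the (log) values; the
    result is flagged accordingly.
    """
    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "species": np.asarray(species).astype(str),
        "bird": np.asarray(bird_id).astype(str),
    })
    if df["species"].nunique() < 2:
        raise ValueError("need more than one species")
    if log_transform:
        if (df["y"] <= 0).any():
            raise ValueError("log transform requires positive values")
        df["y"] = np.log(df["y"])
    k = df["species"].nunique()
    n_birds = df["bird"].nunique()
    singleton_birds = (df.groupby("bird").size() == 1).all()

    if singleton_birds:
        ols = smf.ols("y ~ C(species)", data=df).fit()
        fres = ols.f_test(np.eye(len(ols.params))[1:])
        return TestResult(
            "lmm_species_effect", float(fres.fvalue), float(fres.pvalue),
            df=(k - 1, float(ols.df_resid)),
            groups=tuple(sorted(df["species"].unique())),
            n_per_group=tuple(df.groupby("species").size()),
            extra={"flag": "degenerate_random_effect_ols_fallback", "df_method": "residual"},
        )

    model = smf.mixedlm("y ~ C(species)", data=df, groups=df["bird"])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    terms = [name for name in fit.fe_params.index if name != "Intercept"]
    contrast = np.zeros((len(terms), len(fit.params)))
    names = list(fit.params.index)
    for i, t in enumerate(terms):
        contrast[i, names.index(t)] = 1.0
    wald = fit.wald_test(contrast, scalar=True)
    chi2 = float(np.squeeze(wald.statistic))
    q = len(terms)
    f_stat = chi2 / q
    df_den = max(1.0, len(df) - (q + 1) - (n_birds - 1))
    p = float(stats.f.sf(f_stat, q, df_den))
    flag = "singular_fit" if (fit.cov_re.values <= 1e-10).all() else None
    return TestResult(
        "lmm_species_effect", f_stat, p, df=(q, df_den),
        groups=tuple(sorted(df["species"].unique())),
        n_per_group=tuple(df.groupby("species").size()),
        extra={"flag": flag, "df_method": "residual-approximation",
               "re_variance": float(fit.cov_re.values[0, 0])},
    )


def pca_metrics(metrics: pd.DataFrame, columns: list[str] | None = None) -> PcaResult:
    """PCA of the trip metrics on the correlation matrix.

    Columns are standardized (zero mean, unit variance); components with
    eigenvalue > 1 are retained.  Eigenvalues sum to the number of
    metrics.  Raises on constant columns, naming them.
    """
    cols = columns if columns is not None else list(metrics.columns)
    x = metrics[cols].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least three complete trips")
    sd = x.std(axis=0, ddof=1)
    constant = [c for c, s in zip(cols, sd) if s == 0 or not np.isfinite(s)]
    if constant:
        raise ValueError(f"constant or degenerate columns: {constant}")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    retained = int(np.sum(eigval > 1.0))
    comp_names = [f"PC{i + 1}" for i in range(len(cols))]
    loadings = pd.DataFrame(eigvec, index=cols, columns=comp_names)
    scores = pd.DataFrame(z @ eigvec, columns=comp_names, index=metrics.index)
    return PcaResult(loadings=loadings, eigenvalues=eigval, scores=scores, retained=retained)


def diet_chisq(records: pd.DataFrame, min_observations: int = 5) -> TestResult:
    """Pearson χ² of bird species × prey species after rarity filtering.

    Prey species with fewer than ``min_observations`` total observations
    (FO across all bird species) are dropped before testing.
    """
    table = pd.crosstab(records["bird_species"], records["prey_species"])
    keep = table.sum(axis=0) >= min_observations
    table = table.loc[:, keep]
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 1:
        raise ValueError("contingency table empty after rarity filtering")
    if table.shape[1] == 1:
        raise ValueError("only one prey species remains; chi-square undefined")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(
        "diet_chisq", float(chi2), float(p), df=int(dof),
        groups=tuple(table.index), n_per_group=tuple(table.sum(axis=1)),
        extra={"prey_species": list(table.columns)},
    )


def prey_count_glm(counts, bird_species) -> TestResult:
    """Quasi-Poisson model of load size on bird species.

    Log-link Poisson regression with the dispersion estimated from the
    Pearson χ² (statsmodels ``scale="X2"``); reports the species
    contrast t statistic, its p-value and the dispersion.
    """
    df = pd.DataFrame({
        "count": np.asarray(counts, dtype=float),
        "species": np.asarray(bird_species).astype(str),
    })
    if df["species"].nunique() < 2:
        raise ValueError("need at least two bird species")
    model = smf.glm("count ~ C(species)", data=df, family=sm.families.Poisson())
    fit = model.fit(scale="X2")
    term = [n for n in fit.params.index if n != "Intercept"][0]
    return TestResult(
        "prey_count_quasipoisson", float(fit.tvalues[term]), float(fit.pvalues[term]),
        df=float(fit.df_resid),
        groups=tuple(sorted(df["species"].unique())),
        n_per_group=tuple(df.groupby("species").size()),
        extra={"estimate": float(fit.params[term]), "dispersion": float(fit.scale)},
    )


def size_vs_number_regression(sizes, numbers) -> TestResult:
    """OLS of prey size (mm) on prey number per load: slope, F and p."""
    x = np.asarray(numbers, dtype=float)
    y = np.asarray(sizes, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0:
        raise ValueError("prey number is constant; regression undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return TestResult(
        "size_vs_number_ols", float(fit.fvalue), float(fit.f_pvalue),
        df=(float(fit.df_model), float(fit.df_resid)),
        extra={"slope": float(fit.params[1]), "intercept": float(fit.params[0]),
               "r_squared": float(fit.rsquared)},
    )
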