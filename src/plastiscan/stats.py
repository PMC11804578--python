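"""Significance machinery: randomization test for direction-matched shared
DE genes, one-proportion chi-square, permutation chance expectations, and
P_ST vs F_ST adaptive-divergence screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class RandomizationResult:
    observed_overlap: int
    expected_overlap: float
    p_value: float
    n_permutations: int


def _calls_series(calls) -> pd.Series:
    if isinstance(calls, pd.DataFrame):
        return calls.set_index("gene_id")["call"]
    return calls


def overlap_randomization(
    calls_a,
    calls_b,
    universe,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> RandomizationResult:
    """Randomization test for the direction-matched shared-gene count.

    Observed: genes where both call sets agree on up or down. Null: B's
    up- and down-calls are reassigned to uniformly random distinct genes of
    the universe (A held fixed) and the matched count recomputed.
    p = (1 + #{perm >= observed}) / (n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    universe = pd.Index(universe)
    b_raw = _calls_series(calls_b)
    if int(b_raw.isin(["up", "down"]).sum()) > len(universe):
        raise ValueError("universe smaller than B's significant set")
    a = _calls_series(calls_a).reindex(universe).fillna("ns")
    b = b_raw.reindex(universe).fillna("ns")
    n_up = int((b == "up").sum())
    n_down = int((b == "down").sum())
    observed = int(((a == b) & a.isin(["up", "down"])).sum())

    a_num = np.where(a == "up", 1, np.where(a == "down", -1, 0))
    rng = np.random.default_rng(seed)
    n_sig = n_up + n_down
    counts = np.empty(n_permutations, dtype=np.int64)
    for k in range(n_permutations):
        idx = rng.choice(len(universe), size=n_sig, replace=False)
        counts[k] = int(np.sum(a_num[idx[:n_up]] == 1)) + int(
            np.sum(a_num[idx[n_up:]] == -1)
        )
    p = (1 + int(np.sum(counts >= observed))) / (n_permutations + 1)
    return RandomizationResult(
        observed_overlap=observed,
        expected_overlap=float(counts.mean()),
        p_value=float(p),
        n_permutations=n_permutations,
    )


@dataclass
class ProportionTestResult:
    x: int
    n: int
    p0: float
    chi2: float
    df: int
    p_value: float


def proportion_chisq(
    x: int, n: int, p0: float, continuity: bool = False
) -> ProportionTestResult:
    """One-sample proportion test: chi2 = (x - n p0)^2 / (n p0 (1 - p0))."""
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be strictly between 0 and 1")
    dev = abs(x - n * p0)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    chi2 = dev**2 / (n * p0 * (1 - p0))
    p = float(sps.chi2.sf(chi2, df=1))
    return ProportionTestResult(x=x, n=n, p0=p0, chi2=float(chi2), df=1, p_value=p)


def chance_proportion(
    call_frame: pd.DataFrame,
    rule,
    n_permutations: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo chance probability of satisfying a category rule.

    Each permutation independently shuffles every call column across genes
    (destroying between-contrast dependence while keeping marginal call
    rates) and evaluates ``rule`` — a function of a calls frame returning a
    boolean mask. Returns (p0, standard error of p0).
    """
    rng = np.random.default_rng(seed)
    fracs = np.empty(n_permutations)
    perm = call_frame.copy()
    for k in range(n_permutations):
        for col in call_frame.columns:
            perm[col] = rng.permutation(call_frame[col].to_numpy())
        fracs[k] = float(np.mean(np.asarray(rule(perm), dtype=bool)))
    p0 = float(fracs.mean())
    se = float(fracs.std(ddof=1) / np.sqrt(n_permutations)) if n_permutations > 1 else float("nan")
    return p0, se


@dataclass
class PstResult:
    sigma2_between: float
    sigma2_within: float
    c_over_h2: float
    pst: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def pst_statistic(values, labels, c_over_h2: float = 1.0) -> PstResult:
    """P_ST of one trait between two populations.

    sigma2_between is the variance of the population means about their grand
    (unweighted) mean; sigma2_within is the pooled within-population
    variance. P_ST = c/h2 * s2B / (c/h2 * s2B + 2 s2W).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pops = np.unique(labels)
    if len(pops) != 2:
        raise ValueError("pst_statistic expects exactly 2 populations")
    groups = [values[labels == p] for p in pops]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each population needs >= 2 samples")
    means = np.array([g.mean() for g in groups])
    s2b = float(np.sum((means - means.mean()) ** 2) / (len(pops) - 1))
    dfs = np.array([len(g) - 1 for g in groups])
    s2w = float(np.sum([d * g.var(ddof=1) for d, g in zip(dfs, groups)]) / dfs.sum())
    denom = c_over_h2 * s2b + 2.0 * s2w
    if denom <= 0:
        warnings.warn("P_ST undefined: zero variance in both components")
        pst = float("nan")
    else:
        pst = float(c_over_h2 * s2b / denom)
    return PstResult(sigma2_between=s2b, sigma2_within=s2w, c_over_h2=c_over_h2, pst=pst)


def pst_bootstrap(
    values, labels, c_over_h2: float = 1.0, reps: int = 1000, seed: int = 0
) -> PstResult:
    """Percentile bootstrap CI (2.5/97.5%) by within-population resampling.

    The point estimate itself is included in the bootstrap sample so the
    interval always contains it.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    point = pst_statistic(values, labels, c_over_h2)
    pops = np.unique(labels)
    idx_by_pop = [np.flatnonzero(labels == p) for p in pops]
    if any(len(ix) < 2 for ix in idx_by_pop):
        raise ValueError("each population needs >= 2 samples to bootstrap")
    rng = np.random.default_rng(seed)
    boots = np.empty(reps)
    for k in range(reps):
        resampled = np.concatenate(
            [rng.choice(ix, size=len(ix), replace=True) for ix in idx_by_pop]
        )
        boots[k] = pst_statistic(values[resampled], labels[resampled], c_over_h2).pst
    boots = np.append(boots[np.isfinite(boots)], point.pst)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return PstResult(
        sigma2_between=point.sigma2_between,
        sigma2_within=point.sigma2_within,
        c_over_h2=c_over_h2,
        pst=point.pst,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def fraction_exceeding(pst_values, fst_values, alpha: float = 0.05) -> float:
    """Fraction of P_ST point estimates above the (1 - alpha) F_ST quantile."""
    fst_values = np.asarray(fst_values, dtype=float)
    if fst_values.size == 0:
        raise ValueError("F_ST distribution is empty")
    pst_values = np.asarray(pst_values, dtype=float)
    pst_values = pst_values[np.isfinite(pst_values)]
    if pst_values.size == 0:
        warnings.warn("fraction_exceeding undefined for an empty gene set")
        return float("nan")
    threshold = np.quantile(fst_values, 1.0 - alpha)
    return float(np.mean(pst_values > threshold))


def log_ratio_trait(
    norm_counts: pd.DataFrame,
    sheet: pd.DataFrame,
    population: str,
    cue: str,
) -> pd.DataFrame:
    """Per-individual log2(cue / control) normalized expression per gene.

    This is the variance-stabilized version of the 'fraction of cue over
    control expression' trait used for plastic-gene P_ST; columns are
    individuals of the population.
    """
    sub = sheet[sheet["population"] == population].set_index("sample_id")
    out = {}
    for ind, grp in sub.groupby("individual"):
        cue_s = grp.index[grp["treatment"] == cue]
        ctl_s = grp.index[grp["treatment"] == "control"]
        if len(cue_s) != 1 or len(ctl_s) != 1:
            raise ValueError(f"individual {ind!r} lacks a paired sample")
        out[ind] = np.log2(
            np.maximum(norm_counts[cue_s[0]].to_numpy(), 0.5)
            / np.maximum(norm_counts[ctl_s[0]].to_numpy(), 0.5)
        )
    return pd.DataFrame(out, index=norm_counts.index)


def pst_table(
    traits_by_pop: dict[str, pd.DataFrame],
    c_over_h2: float = 1.0,
) -> pd.DataFrame:
    """Vectorized per-gene P_ST for two populations.

    ``traits_by_pop`` maps each of two population names to a genes x
    replicates trait table on a common gene index.
    """
    if len(traits_by_pop) != 2:
        raise ValueError("pst_table expects exactly 2 populations")
    (na, a), (nb, b) = traits_by_pop.items()
    a_v, b_v = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    means = np.stack([a_v.mean(axis=1), b_v.mean(axis=1)])
    s2b = np.sum((means - means.mean(axis=0)) ** 2, axis=0)  # df = 1
    dfa, dfb = a_v.shape[1] - 1, b_v.shape[1] - 1
    s2w = (dfa * a_v.var(axis=1, ddof=1) + dfb * b_v.var(axis=1, ddof=1)) / (dfa + dfb)
    denom = c_over_h2 * s2b + 2.0 * s2w
    with np.errstate(invalid="ignore", divide="ignore"):
        pst = np.where(denom > 0, c_over_h2 * s2b / denom, np.nan)
    return pd.DataFrame(
        {"sigma2_between": s2b, "sigma2_within": s2w, "pst": pst}, index=a.index
    )
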