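"""Differential expression for two-group RNA-seq counts.

The caller follows the exact negative-binomial (NB) test family of
Robinson & Smyth: libraries are equalized by quantile-adjusting counts to a
common library size, a single dispersion shared by all genes is estimated by
conditional maximum likelihood, and each gene's two group sums are compared
with a conditional exact test.  The NB is parameterized by mean/dispersion,
Var = mu + phi * mu^2, so phi = 0 is the Poisson limit and the exact test
degenerates to the exact binomial split test.

Fold changes are signed: B/A when the case group is higher, -(A/B) when
lower, so |FC| >= 1 and the sign is the direction.  FDR control is
Benjamini-Hochberg.  A ddCt utility for qPCR validation lives here too.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, ValidationError

FOLD_THRESHOLD = 3.0
FDR_THRESHOLD = 0.01
#: sentinel for a zero-vs-positive mean comparison at pseudocount 0
INF_FOLD = np.inf


# ---------------------------------------------------------------------------
# TPM


def compute_tpm(counts: pd.DataFrame, lengths: Mapping[str, int]) -> pd.DataFrame:
    """Length-normalize counts to transcripts-per-million per sample.

    TPM_i = (count_i / length_i) / sum_j(count_j / length_j) * 1e6, so every
    column sums to 1e6.
    """
    missing = [t for t in counts.index if t not in lengths]
    if missing:
        raise ValidationError(f"no length for transcripts: {missing[:5]}")
    lens = np.array([lengths[t] for t in counts.index], dtype=float)
    if (lens <= 0).any():
        raise ValidationError("transcript lengths must be positive")
    rate = counts.to_numpy(dtype=float) / lens[:, None]
    tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# Library scaling


def normalize_libraries(counts: pd.DataFrame, trim: float = 0.3) -> pd.Series:
    """Per-sample scale factors by trimmed mean of log ratios.

    Each sample's log2 ratios to a per-gene geometric-mean pseudo-reference
    (genes expressed in all samples) are trimmed symmetrically by ``trim``
    and averaged; factors are renormalized to geometric mean 1.  Dividing a
    column by its factor removes both depth and composition bias.
    """
    if counts.shape[1] < 2:
        raise ValidationError("need at least two samples to normalize")
    x = counts.to_numpy(dtype=float)
    zero_cols = np.where(x.sum(axis=0) == 0)[0]
    if zero_cols.size:
        raise ValidationError(
            f"all-zero sample(s): {[counts.columns[i] for i in zero_cols]}"
        )
    pos = (x > 0).all(axis=1)
    if not pos.any():
        raise ValidationError("no gene observed in every sample")
    logx = np.log2(x[pos])
    ref = logx.mean(axis=1)  # log2 of per-gene geometric mean
    log_factors = np.array(
        [stats.trim_mean(logx[:, j] - ref, trim) for j in range(x.shape[1])]
    )
    log_factors -= log_factors.mean()  # geometric mean of factors = 1
    return pd.Series(2.0 ** log_factors, index=counts.columns, name="scale_factor")


def effective_library_sizes(counts: pd.DataFrame, trim: float = 0.3) -> pd.Series:
    """Scale factors anchored to the geometric mean of column sums (bp units)."""
    anchor = np.exp(np.log(counts.sum(axis=0).to_numpy(dtype=float)).mean())
    return normalize_libraries(counts, trim=trim) * anchor


# ---------------------------------------------------------------------------
# Quantile adjustment to a common library size


def _q2q_nbinom(x: np.ndarray, mu_in: np.ndarray, mu_out: np.ndarray, phi: float) -> np.ndarray:
    """Map counts between NB distributions of equal shape, different means.

    Average of a normal-approximation and a gamma-approximation quantile
    match; identity when the two means coincide.
    """
    eps = 1e-8
    mu_in = np.maximum(mu_in, eps)
    mu_out = np.maximum(mu_out, eps)
    v_in = mu_in * (1.0 + phi * mu_in)
    v_out = mu_out * (1.0 + phi * mu_out)
    q_norm = mu_out + np.sqrt(v_out / v_in) * (x - mu_in)
    with np.errstate(invalid="ignore"):
        p = stats.gamma.cdf(x, a=mu_in**2 / v_in, scale=v_in / mu_in)
        q_gamma = stats.gamma.ppf(p, a=mu_out**2 / v_out, scale=v_out / mu_out)
    q = 0.5 * (q_norm + np.where(np.isfinite(q_gamma), q_gamma, q_norm))
    return np.maximum(q, 0.0)


def pseudocounts_to_common_size(
    counts: pd.DataFrame, lib_sizes: pd.Series, phi: float = 0.1
) -> tuple[pd.DataFrame, float]:
    """Quantile-adjust every column to the geometric-mean library size."""
    n = lib_sizes.to_numpy(dtype=float)
    common = float(np.exp(np.log(n).mean()))
    x = counts.to_numpy(dtype=float)
    lam = x.sum(axis=1) / n.sum()  # per-gene relative abundance
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = _q2q_nbinom(x[:, j], lam * n[j], lam * common, phi)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns), common


# ---------------------------------------------------------------------------
# Common dispersion (conditional maximum likelihood)


def _split_groups(columns: Sequence[str], groups: Mapping[str, str]) -> tuple[list[int], list[int]]:
    labels = [groups[c] for c in columns]
    lvls = sorted(set(labels))
    if len(lvls) != 2:
        raise ValidationError(f"exactly two groups required, got {lvls}")
    a = [i for i, l in enumerate(labels) if l == lvls[0]]
    b = [i for i, l in enumerate(labels) if l == lvls[1]]
    return a, b


def _cml_loglik(phi: float, mats: list[np.ndarray]) -> float:
    """Conditional log-likelihood of phi given each group's counts (equal libs)."""
    r = 1.0 / phi
    total = 0.0
    for y in mats:  # genes x replicates for one group
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r)) - y.size * gammaln(r)
            + np.sum(gammaln(n * r) - gammaln(z + n * r))
        )
    return total


def estimate_common_dispersion(
    counts: pd.DataFrame, groups: Mapping[str, str], lib_sizes: pd.Series | None = None
) -> float:
    """Shared NB dispersion phi by conditional maximum likelihood.

    Counts are first quantile-adjusted to a common library size so the
    conditional likelihood (which assumes exchangeable replicates) applies.
    """
    ia, ib = _split_groups(counts.columns, groups)
    if lib_sizes is None:
        lib_sizes = effective_library_sizes(counts)
    x = counts.to_numpy(dtype=float)
    keep = x.sum(axis=1) > 0
    if not keep.any():
        warnings.warn("all-zero count matrix; dispersion undefined, returning 0")
        return 0.0
    # one adjustment pass at a moderate prior phi, then CML on the pseudodata
    pseudo, _ = pseudocounts_to_common_size(counts.loc[keep], lib_sizes, phi=0.1)
    y = pseudo.to_numpy(dtype=float)
    mats = [y[:, ia], y[:, ib]]
    res = optimize.minimize_scalar(
        lambda lp: -_cml_loglik(10.0**lp, mats), bounds=(-6.0, 1.0), method="bounded"
    )
    phi = float(10.0 ** res.x)
    return 0.0 if phi < 2e-6 else phi


# ---------------------------------------------------------------------------
# Exact NB test


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    if phi <= 0:
        return stats.poisson.logpmf(k, mean)
    r = 1.0 / phi
    return stats.nbinom.logpmf(k, r, r / (r + mean))


def _exact_tail_p(sa: int, sb: int, na: int, nb: int, phi: float) -> float:
    """Two-sided conditional exact p for group sums sa, sb on equalized libs.

    Conditional on s = sa + sb the split probabilities are
    P(a) propto f_NB(a; na*mu, phi/na) * f_NB(s-a; nb*mu, phi/nb) with
    mu = s / (na + nb); the p-value sums all splits no more likely than the
    observed one (double-tail by likelihood ordering).
    """
    s = sa + sb
    if s == 0:
        return 1.0
    mu = s / (na + nb)
    a = np.arange(s + 1)
    logw = _nb_logpmf(a, na * mu, phi / na) + _nb_logpmf(s - a, nb * mu, phi / nb)
    logw -= logsumexp(logw)
    obs = logw[sa]
    inc = logw <= obs + 1e-12
    return float(min(1.0, np.exp(logsumexp(logw[inc]))))


def exact_nb_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    phi: float,
    lib_sizes: pd.Series | None = None,
) -> pd.Series:
    """Per-gene two-sided exact NB p-values (Robinson-Smyth family).

    Counts are quantile-adjusted to a common library size, group sums are
    rounded to integers, and each gene's split is scored conditionally.
    """
    if phi < 0:
        raise ValidationError("dispersion must be non-negative")
    ia, ib = _split_groups(counts.columns, groups)
    if lib_sizes is None:
        lib_sizes = effective_library_sizes(counts)
    pseudo, _ = pseudocounts_to_common_size(counts, lib_sizes, phi=max(phi, 1e-8))
    y = pseudo.to_numpy(dtype=float)
    sa = np.rint(y[:, ia].sum(axis=1)).astype(int)
    sb = np.rint(y[:, ib].sum(axis=1)).astype(int)
    pvals = np.array(
        [_exact_tail_p(a, b, len(ia), len(ib), phi) for a, b in zip(sa, sb)]
    )
    return pd.Series(pvals, index=counts.index, name="p")


# ---------------------------------------------------------------------------
# Fold change, FDR, calling


def signed_fold_change(mean_a, mean_b, pseudocount: float = 0.0):
    """Signed ratio: +B'/A' if B' >= A', else -A'/B' (X' = X + pseudocount).

    A is the reference/control mean, B the case mean.  With pseudocount 0 a
    zero-vs-positive comparison yields +/-inf, a sentinel that always clears
    any finite fold threshold.  Equal means give +1 by convention.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    a = np.asarray(mean_a, dtype=float) + pseudocount
    b = np.asarray(mean_b, dtype=float) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        up = np.where(b >= a, np.where(a > 0, b / a, np.where(b > 0, np.inf, 1.0)), 0.0)
        down = np.where(b < a, np.where(b > 0, a / b, np.inf), 0.0)
    fc = np.where(b >= a, up, -down)
    return fc if fc.ndim else float(fc)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    results: pd.DataFrame,
    fc_threshold: float = FOLD_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Direction calls at strict fold and FDR cutoffs.

    up iff FC > fc_threshold and FDR < fdr_threshold; down iff
    FC < -fc_threshold and FDR < fdr_threshold; otherwise not-DE.  A fold of
    exactly +/-threshold is not-DE (strict inequality).
    """
    fc = results["fold_change"].to_numpy(dtype=float)
    fdr = results["fdr"].to_numpy(dtype=float)
    call = np.where(
        (fdr < fdr_threshold) & (fc > fc_threshold),
        "up",
        np.where((fdr < fdr_threshold) & (fc < -fc_threshold), "down", "not-DE"),
    )
    out = results.copy()
    out["call"] = call
    return out


def de_analysis(
    expr: ExpressionMatrix,
    case_group: str | None = None,
    fc_threshold: float = FOLD_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    pseudocount: float = 0.0,
    phi: float | None = None,
) -> pd.DataFrame:
    """Full two-group DE pipeline: normalize, dispersion, exact test, call.

    Returns a table with columns id, fold_change, p, fdr, call.  The fold
    change is case/control on depth-normalized means; ``case_group`` defaults
    to the lexicographically later group label.
    """
    if expr.groups is None:
        raise ValidationError("expression matrix carries no group labels")
    counts = expr.values
    lib = effective_library_sizes(counts)
    phi_hat = estimate_common_dispersion(counts, expr.groups, lib) if phi is None else phi
    p = exact_nb_test(counts, expr.groups, phi_hat, lib)

    norm = counts.div(lib / np.exp(np.log(lib.to_numpy()).mean()), axis=1)
    labels = sorted({expr.groups[c] for c in counts.columns})
    if case_group is None:
        case_group = labels[1]
    ctrl_group = labels[0] if case_group == labels[1] else labels[1]
    case_cols = [c for c in counts.columns if expr.groups[c] == case_group]
    ctrl_cols = [c for c in counts.columns if expr.groups[c] == ctrl_group]
    fc = signed_fold_change(
        norm[ctrl_cols].mean(axis=1).to_numpy(),
        norm[case_cols].mean(axis=1).to_numpy(),
        pseudocount=pseudocount,
    )
    table = pd.DataFrame(
        {"id": counts.index, "fold_change": fc, "p": p.to_numpy(), "fdr": bh_fdr(p.to_numpy())}
    ).set_index("id", drop=False)
    table.index.name = None
    return call_de(table, fc_threshold, fdr_threshold)


# ---------------------------------------------------------------------------
# qPCR utilities


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """2^-ddCt with ddCt = (Ct_tgt - Ct_ref)|case - (Ct_tgt - Ct_ref)|ctrl."""
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def rank_sum_test(case_values, ctrl_values) -> float:
    """Two-sided Mann-Whitney U p-value, exact for small replicate counts."""
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(ctrl_values, dtype=float)
    method = "exact" if max(case.size, ctrl.size) <= 8 else "auto"
    return float(stats.mannwhitneyu(case, ctrl, alternative="two-sided", method=method).pvalue)


__all__ = [
    "FDR_THRESHOLD",
    "FOLD_THRESHOLD",
    "bh_fdr",
    "call_de",
    "compute_tpm",
    "ddct_fold_change",
    "de_analysis",
    "effective_library_sizes",
    "estimate_common_dispersion",
    "exact_nb_test",
    "normalize_libraries",
    "pseudocounts_to_common_size",
    "rank_sum_test",
    "signed_fold_change",
]
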