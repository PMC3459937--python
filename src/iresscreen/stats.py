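"""Validation statistics: efficiency-corrected qPCR relative expression with
a randomization test, and the equal-variance two-sample t-test.

The relative-expression estimate follows the efficiency-corrected ratio

    ratio = E_target ** dCt_target / E_ref ** dCt_ref,
    dCt = mean Ct(control) - mean Ct(treated),

so a ratio > 1 means up-regulation in the treated group.  Significance is
assessed by fixed reallocation: treated/control labels of whole samples
(their target and reference Cts jointly) are permuted, the ratio recomputed,
and the two-sided p-value is the fraction of reallocations at least as far
from 1 (on the log scale) as the observed ratio, with the (k+1)/(n+1)
small-sample correction.  The ratio SD is a leave-one-out jackknife spread.
This mirrors the behaviour of relative-expression randomization software
whose exact internals are unpublished; iteration count and seed are exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "ExpressionRatio",
    "TTestResult",
    "pfaffl_ratio",
    "rest_randomization",
    "t_test_equal_var",
    "percent_change",
]


@dataclass(frozen=True)
class ExpressionRatio:
    """Treated-vs-control relative expression (1 = unchanged)."""

    ratio: float
    sd: float
    p_value: float
    n_iterations: int
    seed: int


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    group_means: tuple[float, float]
    zero_variance: bool = False


def _check_efficiency(e: float, name: str) -> None:
    if not 1.0 < e <= 2.0:
        raise ParameterError(
            f"{name} amplification efficiency must be in (1, 2], got {e}"
        )


def pfaffl_ratio(e_target: float, dct_target: float,
                 e_ref: float, dct_ref: float) -> float:
    """Efficiency-corrected relative expression ratio.

    ``dct`` values use the control - treated sign convention.
    """
    _check_efficiency(e_target, "target")
    _check_efficiency(e_ref, "reference")
    return e_target ** dct_target / e_ref ** dct_ref


def _group_arrays(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-sample (target_ct, reference_ct) arrays plus efficiencies."""
    tgt = df[df["role"] == "target"].set_index("sample_id")["ct"]
    ref = df[df["role"] == "reference"].set_index("sample_id")["ct"]
    common = tgt.index.intersection(ref.index)
    if len(common) < 2:
        raise ParameterError(
            "need >= 2 samples with both target and reference Cts per group"
        )
    e_t = float(df.loc[df["role"] == "target", "efficiency"].iloc[0])
    e_r = float(df.loc[df["role"] == "reference", "efficiency"].iloc[0])
    return tgt.loc[common].to_numpy(float), ref.loc[common].to_numpy(float), e_t, e_r


def _log_ratio(lt: float, lr: float,
               t_tgt, t_ref, c_tgt, c_ref) -> float:
    dct_t = np.mean(c_tgt) - np.mean(t_tgt)
    dct_r = np.mean(c_ref) - np.mean(t_ref)
    return lt * dct_t - lr * dct_r


def rest_randomization(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    n_iterations: int = 2000,
    seed: int = 0,
) -> ExpressionRatio:
    """Relative expression with a fixed-reallocation randomization test.

    ``treated`` and ``control`` are qPCR tables with columns
    sample_id, role ('target'/'reference'), ct, efficiency; each sample
    contributes one target and one reference Ct.
    """
    if n_iterations < 1:
        raise ParameterError("n_iterations must be >= 1")
    t_tgt, t_ref, e_t, e_r = _group_arrays(treated)
    c_tgt, c_ref, e_t2, e_r2 = _group_arrays(control)
    _check_efficiency(e_t, "target")
    _check_efficiency(e_r, "reference")
    if not (math.isclose(e_t, e_t2) and math.isclose(e_r, e_r2)):
        raise ParameterError("treated and control efficiencies must agree per gene")
    lt, lr = math.log(e_t), math.log(e_r)

    obs_log = _log_ratio(lt, lr, t_tgt, t_ref, c_tgt, c_ref)
    ratio = math.exp(obs_log)

    # fixed reallocation: shuffle group labels of whole samples
    pool_tgt = np.concatenate([t_tgt, c_tgt])
    pool_ref = np.concatenate([t_ref, c_ref])
    n_t, n = len(t_tgt), len(pool_tgt)
    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_iterations, n)), axis=1)
    t_idx, c_idx = perm[:, :n_t], perm[:, n_t:]
    dct_t = pool_tgt[c_idx].mean(axis=1) - pool_tgt[t_idx].mean(axis=1)
    dct_r = pool_ref[c_idx].mean(axis=1) - pool_ref[t_idx].mean(axis=1)
    perm_log = lt * dct_t - lr * dct_r
    k = int(np.sum(np.abs(perm_log) >= abs(obs_log) - 1e-12))
    p_value = (k + 1) / (n_iterations + 1)

    # leave-one-out jackknife over samples of both groups
    jack = []
    for i in range(len(t_tgt)):
        jack.append(math.exp(_log_ratio(
            lt, lr, np.delete(t_tgt, i), np.delete(t_ref, i), c_tgt, c_ref)))
    for i in range(len(c_tgt)):
        jack.append(math.exp(_log_ratio(
            lt, lr, t_tgt, t_ref, np.delete(c_tgt, i), np.delete(c_ref, i))))
    sd = float(np.std(jack, ddof=1))
    return ExpressionRatio(ratio=float(ratio), sd=sd, p_value=float(p_value),
                           n_iterations=n_iterations, seed=seed)


def t_test_equal_var(group_a, group_b) -> TTestResult:
    """Unpaired two-sample Student's t-test with pooled (equal) variance.

    Two-sided p-value from the t distribution with nA + nB - 2 degrees of
    freedom.  With zero pooled variance the conventional limits are used
    (p = 1 for equal means, p = 0 otherwise) and the result is flagged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("t-test needs >= 2 values per group")
    na, nb = a.size, b.size
    df = na + nb - 2
    mean_a, mean_b = float(a.mean()), float(b.mean())
    ss = float(((a - mean_a) ** 2).sum() + ((b - mean_b) ** 2).sum())
    pooled_var = ss / df
    if pooled_var == 0:
        if mean_a == mean_b:
            return TTestResult(0.0, df, 1.0, (mean_a, mean_b), zero_variance=True)
        t = math.inf if mean_a > mean_b else -math.inf
        return TTestResult(t, df, 0.0, (mean_a, mean_b), zero_variance=True)
    se = math.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    t = (mean_a - mean_b) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(float(t), df, p, (mean_a, mean_b))


def percent_change(treated_mean: float, control_mean: float) -> float:
    """Signed fractional change of the treated mean relative to control."""
    if not control_mean > 0:
        raise ParameterError(f"control_mean must be > 0, got {control_mean}")
    return (treated_mean - control_mean) / control_mean
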