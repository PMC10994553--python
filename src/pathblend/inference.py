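"""Permutation significance, multiple-testing correction, bootstrap block
importances, and superscore-metadata correlation screening.

Empirical p-values follow the plain counting rule p = (#permuted >=
observed) / n_perm, with no +1 correction: a feature whose observed
statistic beats all permutations gets p = 0, which should be read as
p < 1/n_perm. Attainable p-values are exact multiples of 1/n_perm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .multiview import MBPLSModel, block_importance, fit_mbpls
from .preprocess import OutcomeVector

__all__ = [
    "PermutationResult",
    "CorrelationScreen",
    "permutation_pvalues",
    "bh_fdr",
    "bonferroni",
    "bootstrap_block_importance",
    "correlate_superscores",
]


@dataclass
class PermutationResult:
    observed: pd.Series          # per-feature statistic
    exceed_count: pd.Series      # permuted >= observed, per feature
    n_perm: int
    pvalues: pd.Series           # exceed_count / n_perm exactly
    adjusted: pd.Series          # BH-FDR
    seed: int | None

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": self.observed,
                "p": self.pvalues,
                "p_adj": self.adjusted,
            }
        )


@dataclass
class CorrelationScreen:
    table: pd.DataFrame          # LV, variable, rho, p, p_adj, passed
    rho_min: float
    alpha: float


def _permuted_y(y, perm: np.ndarray):
    if isinstance(y, OutcomeVector):
        vals = y.values.to_numpy()[perm]
        return OutcomeVector(
            values=pd.Series(vals, index=y.values.index), binary=y.binary
        )
    arr = np.asarray(y)
    return arr[perm]


def permutation_pvalues(
    fit_fn,
    blocks,
    y,
    n_perm: int = 10_000,
    seed: int | None = None,
    max_retries: int = 3,
) -> PermutationResult:
    """Empirical p-values for any per-feature statistic under label shuffles.

    `fit_fn(blocks, y)` must return a per-feature statistic (Series or
    array) and be deterministic given its inputs. The outcome is fully
    shuffled `n_perm` times; each permutation uses an independent child
    stream of the master seed, so results are reproducible and
    order-independent. A failing permutation is retried with a fresh
    shuffle up to `max_retries` times.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = pd.Series(fit_fn(blocks, y))
    n = len(observed.index)
    exceed = np.zeros(n)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_perm)
    n_samples = len(y.values) if isinstance(y, OutcomeVector) else len(y)
    for child in children:
        rng = np.random.default_rng(child)
        for attempt in range(max_retries + 1):
            perm = rng.permutation(n_samples)
            try:
                stat = np.asarray(pd.Series(fit_fn(blocks, _permuted_y(y, perm))))
                break
            except Exception:
                if attempt == max_retries:
                    raise
        exceed += stat >= observed.to_numpy()
    pvals = pd.Series(exceed / n_perm, index=observed.index)
    adjusted = bh_fdr(pvals)
    return PermutationResult(
        observed=observed,
        exceed_count=pd.Series(exceed, index=observed.index),
        n_perm=n_perm,
        pvalues=pvals,
        adjusted=adjusted,
        seed=seed,
    )


def _check_pvals(p: np.ndarray) -> None:
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")


def bh_fdr(pvals) -> pd.Series:
    """Benjamini-Hochberg step-up FDR adjustment (monotone, capped at 1)."""
    s = pd.Series(pvals, dtype=float)
    _check_pvals(s.to_numpy())
    adj = multipletests(s.to_numpy(), method="fdr_bh")[1]
    return pd.Series(adj, index=s.index)


def bonferroni(pvals) -> pd.Series:
    s = pd.Series(pvals, dtype=float)
    _check_pvals(s.to_numpy())
    return pd.Series(np.minimum(s.to_numpy() * len(s), 1.0), index=s.index)


def bootstrap_block_importance(
    blocks,
    y,
    R: int,
    n_boot: int = 100,
    seed: int | None = None,
    max_retries: int = 5,
    **fit_kwargs,
) -> pd.DataFrame:
    """Bootstrap mean and SEM of per-block, per-LV importances.

    Each replicate resamples samples with replacement (rows of every
    block and y together), refits the multi-block model, and aligns its
    latent variables to the full-data model by maximal absolute
    superscore correlation before collecting squared superweights.
    Replicates collapsing to a single outcome class are redrawn.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    from .multiview import _as_df, _as_y  # internal reuse

    dfs = [_as_df(b) for b in blocks]
    n = dfs[0].shape[0]
    full = fit_mbpls(blocks, y, R=R, **fit_kwargs)
    yv, y_binary, _ = _as_y(y, n)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            if not y_binary or len(np.unique(yv[idx])) == 2:
                break
            if attempt == max_retries:
                raise RuntimeError("could not draw a two-class bootstrap sample")
        bblocks = [d.iloc[idx].reset_index(drop=True) for d in dfs]
        by = yv[idx]
        m = fit_mbpls(bblocks, by, R=R, **fit_kwargs)
        # align replicate LVs to full-model LVs on the resampled rows
        corr = np.abs(
            np.corrcoef(full.superscores[idx].T, m.superscores.T)[:R, R:]
        )
        order = []
        used: set[int] = set()
        for r in range(R):
            cand = np.argsort(-corr[r])
            pick = next(int(c) for c in cand if int(c) not in used)
            used.add(pick)
            order.append(pick)
        imp = np.column_stack([m.superweights[j] ** 2 for j in order])  # k x R
        reps.append(imp)
    arr = np.asarray(reps)  # n_boot x k x R
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    rows = []
    for k, name in enumerate(full.block_names):
        for r in range(R):
            rows.append(
                {
                    "block": name,
                    "LV": r + 1,
                    "mean": mean[k, r],
                    "sem": sem[k, r],
                }
            )
    return pd.DataFrame(rows)


def correlate_superscores(
    model: MBPLSModel,
    metadata: pd.DataFrame,
    rho_min: float = 0.3,
    alpha: float = 0.05,
) -> CorrelationScreen:
    """Spearman-correlate each latent variable's superscore with each
    numeric metadata variable; Bonferroni over all tests; a variable
    passes when |rho| >= rho_min and adjusted p <= alpha."""
    rows = []
    for r in range(model.R):
        t_s = model.superscores[:, r]
        for var in metadata.columns:
            v = pd.to_numeric(metadata[var], errors="coerce").to_numpy(dtype=float)
            ok = ~np.isnan(v)
            if ok.sum() < 3 or np.nanstd(v) == 0:
                warnings.warn(f"metadata variable {var!r} constant or too sparse",
                              stacklevel=2)
                rows.append({"LV": r + 1, "variable": var, "rho": np.nan, "p": np.nan})
                continue
            rho, p = stats.spearmanr(t_s[ok], v[ok])
            rows.append({"LV": r + 1, "variable": var, "rho": rho, "p": p})
    df = pd.DataFrame(rows)
    m = int(df["p"].notna().sum())
    df["p_adj"] = np.minimum(df["p"] * m, 1.0)
    df["passed"] = (df["rho"].abs() >= rho_min) & (df["p_adj"] <= alpha)
    df.loc[df["p"].isna(), "passed"] = False
    return CorrelationScreen(table=df, rho_min=rho_min, alpha=alpha)
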