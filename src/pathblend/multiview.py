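"""Multi-block PLS (NIPALS) with superscores, VIP and MB-VIP.

The multi-view engine: k >= 1 predictor blocks (typically per-omics
pathway-score matrices) are modelled against a single outcome y. Per
latent variable, block weights and block scores are combined through
unit-norm superweights into a superscore; both the X blocks and Y are
deflated by the superscore (Westerhuis-style deflation), which renders
superscores across latent variables mutually orthogonal. The k = 1 case
reduces exactly to single-block NIPALS PLS, which is what the single-view
framework's default predictor uses.

Feature importance comes from the projection weights:

    VIP_j    = sqrt( J * sum_r( w_rj^2 * SSY_r ) / SSY_cum )        (k = 1)
    MB-VIP_j = sqrt( f * sum_r( w_krj^2 * SSY_r ) / SSY_cum )       (k >= 1)

with w the unit-norm-per-block weights of the deflated matrices, SSY_r the
Y sum of squares explained by latent variable r, f the total feature count
across blocks. Under these conventions mean(VIP^2) = 1 and
SS(MB-VIP)/(f*k) = 1 on every fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import OutcomeVector
from .sspa import PathwayScoreMatrix

__all__ = ["MBPLSModel", "VipResult", "fit_mbpls", "predict", "block_importance",
           "vip", "mb_vip"]


def _as_df(block) -> pd.DataFrame:
    if isinstance(block, PathwayScoreMatrix):
        return block.scores
    if isinstance(block, pd.DataFrame):
        return block
    arr = np.asarray(block, dtype=float)
    return pd.DataFrame(arr)


def _as_y(y, n: int) -> tuple[np.ndarray, bool, list]:
    """Return (numeric y, is_binary, levels)."""
    if isinstance(y, OutcomeVector):
        return y.encoded(), y.binary, sorted(pd.unique(y.values)) if y.binary else []
    arr = np.asarray(pd.Series(y).to_numpy()).ravel()
    levels = sorted(pd.unique(arr))
    if len(levels) == 2:
        return (arr == levels[1]).astype(float), True, levels
    return arr.astype(float), False, []


@dataclass
class MBPLSModel:
    """All latent-variable quantities of a fitted multi-block PLS model."""

    R: int
    block_names: list[str]
    feature_ids: list[list[str]]            # per block
    x_means: list[np.ndarray]               # training column means per block
    x_sds: list[np.ndarray]                 # training column sds per block (or ones)
    scaled: bool
    y_mean: float
    y_binary: bool
    y_levels: list
    # per LV r: lists of length R
    block_weights: list[list[np.ndarray]]   # W[r][k], unit norm per block
    block_scores: list[list[np.ndarray]]    # T[r][k], length N
    block_loadings: list[list[np.ndarray]]  # V[r][k], deflation loadings
    superweights: list[np.ndarray]          # a[r], length k, unit norm
    superscores: np.ndarray                 # N x R
    y_weights: np.ndarray                   # c[r], scalars (H = 1)
    y_scores: np.ndarray                    # N x R
    ssy: np.ndarray                         # SSY_r per LV
    beta: np.ndarray                        # concatenated-feature coefficients
    W_cat: np.ndarray                       # concatenated superweight-scaled weights
    P_cat: np.ndarray                       # concatenated deflation loadings
    n_samples: int

    @property
    def k(self) -> int:
        return len(self.block_names)

    @property
    def f(self) -> int:
        return sum(len(ids) for ids in self.feature_ids)

    @property
    def ssy_cum(self) -> float:
        return float(self.ssy.sum())

    def feature_index(self) -> pd.MultiIndex:
        pairs = [
            (bn, fid)
            for bn, ids in zip(self.block_names, self.feature_ids)
            for fid in ids
        ]
        return pd.MultiIndex.from_tuples(pairs, names=["block", "feature"])


@dataclass
class VipResult:
    """Per-feature (MB-)VIP with block membership and per-LV decomposition."""

    values: pd.Series                       # index: (block, feature)
    per_lv: pd.DataFrame                    # columns LV1..LVR, same index
    f: int
    k: int

    def top(self, n: int = 10) -> pd.Series:
        return self.values.sort_values(ascending=False).head(n)


def fit_mbpls(
    blocks,
    y,
    R: int = 2,
    tol: float = 1e-10,
    max_iter: int = 500,
    scale: bool = True,
    block_names: list[str] | None = None,
) -> MBPLSModel:
    """Fit multi-block PLS by sequential NIPALS with superscore deflation.

    Parameters
    ----------
    blocks : list of PathwayScoreMatrix / DataFrame / array
        Predictor blocks over the same samples (rows aligned).
    y : OutcomeVector, Series or array
        Outcome; binary outcomes are encoded {0,1} then mean-centered.
    R : int
        Number of latent variables.
    scale : bool
        Center (always) and unit-variance scale (if True) each column
        using the training data; the same parameters are reapplied at
        prediction time.
    """
    dfs = [_as_df(b) for b in blocks]
    n = dfs[0].shape[0]
    if any(d.shape[0] != n for d in dfs):
        raise ValueError("blocks have differing sample counts")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if R < 1:
        raise ValueError("R must be >= 1")
    if block_names is None:
        block_names = [f"block{k}" for k in range(len(dfs))]

    y_num, y_binary, y_levels = _as_y(y, n)
    y_mean = float(y_num.mean())
    Y = (y_num - y_mean).reshape(-1, 1)

    Xk, x_means, x_sds = [], [], []
    for d in dfs:
        arr = d.to_numpy(dtype=float)
        mu = arr.mean(axis=0)
        if scale:
            sd = arr.std(axis=0, ddof=1)
            sd = np.where(sd > 1e-12, sd, 1.0)
        else:
            sd = np.ones(arr.shape[1])
        Xk.append((arr - mu) / sd)
        x_means.append(mu)
        x_sds.append(sd)

    Xcat = np.hstack(Xk)
    rank = np.linalg.matrix_rank(Xcat)
    if R > rank:
        raise ValueError(f"R={R} exceeds rank {rank} of the concatenated blocks")

    K = len(Xk)
    W: list[list[np.ndarray]] = []
    T: list[list[np.ndarray]] = []
    V: list[list[np.ndarray]] = []
    A: list[np.ndarray] = []
    TS = np.zeros((n, R))
    C = np.zeros(R)
    U = np.zeros((n, R))
    ssy = np.zeros(R)
    Wcat = np.zeros((Xcat.shape[1], R))   # concatenated deflated-matrix weights
    Pcat = np.zeros((Xcat.shape[1], R))   # concatenated deflation loadings
    offsets = np.cumsum([0] + [x.shape[1] for x in Xk])

    Xdef = [x.copy() for x in Xk]
    Ydef = Y.copy()
    for r in range(R):
        ss_before = float((Ydef**2).sum())
        u = Ydef[:, 0].copy()
        if np.linalg.norm(u) < 1e-12:
            raise ValueError(f"Y fully deflated before LV {r + 1}; reduce R")
        t_s_old = None
        for it in range(max_iter):
            wk, tk = [], []
            for xk in Xdef:
                w = xk.T @ u
                nw = np.linalg.norm(w)
                if nw < 1e-14:
                    w = np.zeros_like(w)
                else:
                    w = w / nw
                wk.append(w)
                tk.append(xk @ w)
            Tmat = np.column_stack(tk)
            a = Tmat.T @ u
            na = np.linalg.norm(a)
            if na < 1e-14:
                raise ValueError(f"degenerate superweights at LV {r + 1}")
            a = a / na
            t_s = Tmat @ a
            c = float(Ydef[:, 0] @ t_s / (t_s @ t_s))
            u_new = Ydef[:, 0] * c / (c * c) if c != 0 else Ydef[:, 0].copy()
            if t_s_old is not None:
                if np.linalg.norm(t_s - t_s_old) <= tol * np.linalg.norm(t_s):
                    u = u_new
                    break
            t_s_old = t_s
            u = u_new
        else:
            raise RuntimeError(f"NIPALS did not converge at LV {r + 1}")

        # deterministic sign: largest-|entry| superweight positive
        jmax = int(np.argmax(np.abs(a)))
        if a[jmax] < 0:
            a = -a
            t_s = -t_s
            c = -c

        # deflation loadings (per block and concatenated) w.r.t. superscore
        tt = float(t_s @ t_s)
        vk = [xk.T @ t_s / tt for xk in Xdef]
        for k in range(K):
            Wcat[offsets[k]:offsets[k + 1], r] = a[k] * wk[k]
            Pcat[offsets[k]:offsets[k + 1], r] = vk[k]
            Xdef[k] = Xdef[k] - np.outer(t_s, vk[k])
        Ydef = Ydef - np.outer(t_s, [c])
        ssy[r] = ss_before - float((Ydef**2).sum())

        W.append(wk)
        T.append(tk)
        V.append(vk)
        A.append(a)
        TS[:, r] = t_s
        C[r] = c
        U[:, r] = u

    # beta on the (scaled) concatenated features: W* = W (P'W)^-1, beta = W* C'
    Wstar = Wcat @ np.linalg.inv(Pcat.T @ Wcat)
    beta = Wstar @ C.reshape(-1, 1)

    return MBPLSModel(
        R=R,
        block_names=list(block_names),
        feature_ids=[list(d.columns) for d in dfs],
        x_means=x_means,
        x_sds=x_sds,
        scaled=scale,
        y_mean=y_mean,
        y_binary=y_binary,
        y_levels=y_levels,
        block_weights=W,
        block_scores=T,
        block_loadings=V,
        superweights=A,
        superscores=TS,
        y_weights=C,
        y_scores=U,
        ssy=ssy,
        beta=beta.ravel(),
        W_cat=Wcat,
        P_cat=Pcat,
        n_samples=n,
    )


def predict(
    model: MBPLSModel, blocks, return_class: bool = False, n_lv: int | None = None
):
    """Predict the outcome for new blocks: y_hat = X_cat beta + y offset.

    Blocks are centered/scaled with the training parameters. For binary
    outcomes the continuous score (used for AUROC) is returned; with
    ``return_class=True`` a (score, class) tuple using a 0.5 threshold on
    the {0,1} encoding scale. ``n_lv`` predicts with only the first
    ``n_lv`` latent variables (NIPALS is sequential, so these coincide
    with a model fitted at the smaller R).
    """
    dfs = [_as_df(b) for b in blocks]
    if len(dfs) != model.k:
        raise ValueError(f"model has {model.k} blocks, got {len(dfs)}")
    parts = []
    for k, d in enumerate(dfs):
        cols = list(d.columns)
        if cols != model.feature_ids[k]:
            if set(cols) != set(model.feature_ids[k]):
                raise ValueError(f"block {k}: feature set mismatch")
            d = d[model.feature_ids[k]]
        parts.append((d.to_numpy(dtype=float) - model.x_means[k]) / model.x_sds[k])
    Xcat = np.hstack(parts)
    if n_lv is None or n_lv == model.R:
        beta = model.beta
    else:
        Wr = model.W_cat[:, :n_lv]
        Pr = model.P_cat[:, :n_lv]
        beta = (Wr @ np.linalg.inv(Pr.T @ Wr) @ model.y_weights[:n_lv]).ravel()
    score = Xcat @ beta + model.y_mean
    if return_class and model.y_binary:
        cls = np.where(score >= 0.5, model.y_levels[1], model.y_levels[0])
        return score, cls
    return score


def block_importance(model: MBPLSModel) -> pd.DataFrame:
    """Fraction of each latent variable carried by each block.

    Per LV r the importance of block k is the squared superweight, which
    sums to 1 across blocks; the 'aggregate' column weights LVs by their
    share of explained Y sum of squares (SSY_r / SSY_cum).
    """
    per_lv = np.column_stack([a**2 for a in model.superweights])  # k x R
    w = model.ssy / model.ssy_cum
    agg = per_lv @ w
    df = pd.DataFrame(
        per_lv,
        index=model.block_names,
        columns=[f"LV{r + 1}" for r in range(model.R)],
    )
    df["aggregate"] = agg
    return df


def _vip_core(model: MBPLSModel, total_features: int) -> tuple[np.ndarray, np.ndarray]:
    """Shared (MB-)VIP computation on concatenated unit-per-block weights."""
    wsq = np.zeros((model.f, model.R))
    off = 0
    for k in range(model.k):
        pk = len(model.feature_ids[k])
        for r in range(model.R):
            wsq[off:off + pk, r] = model.block_weights[r][k] ** 2
        off += pk
    frac = model.ssy / model.ssy_cum
    per_lv_sq = total_features * wsq * frac[None, :]
    return np.sqrt(per_lv_sq.sum(axis=1)), np.sqrt(per_lv_sq)


def vip(model: MBPLSModel) -> VipResult:
    """Single-block VIP. For k > 1 use :func:`mb_vip`."""
    if model.k != 1:
        raise ValueError("vip is defined for single-block models; use mb_vip")
    vals, per_lv = _vip_core(model, model.f)
    idx = model.feature_index()
    return VipResult(
        values=pd.Series(vals, index=idx, name="VIP"),
        per_lv=pd.DataFrame(
            per_lv, index=idx, columns=[f"LV{r + 1}" for r in range(model.R)]
        ),
        f=model.f,
        k=1,
    )


def mb_vip(model: MBPLSModel) -> VipResult:
    """Multi-block VIP; equals :func:`vip` exactly when k = 1.

    Normalised so the total sum of squares equals f*k: querying per block
    gives mean squared importance 1 within each block.
    """
    vals, per_lv = _vip_core(model, model.f)
    idx = model.feature_index()
    return VipResult(
        values=pd.Series(vals, index=idx, name="MB-VIP"),
        per_lv=pd.DataFrame(
            per_lv, index=idx, columns=[f"LV{r + 1}" for r in range(model.R)]
        ),
        f=model.f,
        k=model.k,
    )
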