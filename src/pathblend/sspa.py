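"""Single-sample pathway analysis (ssPA).

Turns a standardized samples-by-molecules matrix into a samples-by-pathway
"activity score" matrix. Two methods:

``svd``
    PLAGE-style: for each pathway, the data is restricted to the pathway's
    covered member columns (Z_i, N x L_i), column-centered, and the top
    principal-component score (projection on the first right-singular
    direction) is the pathway activity.
``kpca``
    Kernel PCA with an RBF kernel on Z_i; the first principal-component
    score of the centered kernel is the activity. Out-of-sample samples
    are projected with training-set kernel-centering statistics.

Both have strict fit/transform semantics so cross-validation never leaks
test data into the scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathways import PathwayCollection
from .preprocess import OmicsBlock

__all__ = [
    "PathwayScoreMatrix",
    "SspaTransformer",
    "fit_sspa",
    "transform_sspa",
    "fit_transform_sspa",
    "molecule_loadings",
    "bootstrap_loadings",
    "read_scores",
    "write_scores",
    "save_state",
    "load_state",
]


@dataclass
class PathwayScoreMatrix:
    """Samples-by-pathway activity matrix with provenance."""

    scores: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


@dataclass
class _SvdState:
    members: list[str]          # covered members, collection order
    col_means: np.ndarray       # training column means of Z_i
    direction: np.ndarray       # unit-norm right-singular direction, sign-fixed
    singular_value: float
    degenerate: bool            # constant submatrix -> all-zero scores


@dataclass
class _KpcaState:
    members: list[str]
    train: np.ndarray           # training submatrix (N x L_i)
    gamma: float
    kernel_col_means: np.ndarray
    kernel_mean: float
    alpha: np.ndarray           # unit-norm top eigenvector of centered kernel
    eigenvalue: float
    degenerate: bool


@dataclass
class SspaTransformer:
    """Fitted per-pathway ssPA state; apply with :func:`transform_sspa`."""

    method: str
    states: dict[str, object]
    pathway_order: list[str]
    feature_ids: list[str]


def write_scores(matrix: PathwayScoreMatrix, path, sep: str = "\t") -> None:
    """Write a score matrix as delimited text (samples x pathways)."""
    matrix.scores.to_csv(path, sep=sep)


def read_scores(path, **provenance) -> PathwayScoreMatrix:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return PathwayScoreMatrix(scores=df, provenance=provenance)


def save_state(obj, path) -> None:
    """Serialize a fitted transformer or model to a single archive, for
    reuse across train/test sessions."""
    import pickle

    with open(path, "wb") as fh:
        pickle.dump(obj, fh)


def load_state(path):
    import pickle

    with open(path, "rb") as fh:
        return pickle.load(fh)


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Deterministic sign: loading sum positive; tie broken by making the
    largest-magnitude entry positive."""
    s = v.sum()
    if abs(s) > 1e-12:
        return v if s > 0 else -v
    j = int(np.argmax(np.abs(v)))
    return v if v[j] >= 0 else -v


def _rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    np.clip(d2, 0.0, None, out=d2)
    return np.exp(-gamma * d2)


def fit_sspa(
    block: OmicsBlock,
    pathways: PathwayCollection,
    method: str = "svd",
    min_coverage: int = 2,
    gamma: float | None = None,
) -> SspaTransformer:
    """Fit per-pathway scoring state on standardized training data.

    `block` may be a single omics block or the column-concatenation of
    several (multi-omics scoring); `pathways` should already be coverage
    filtered against this block's features, but pathways falling below
    `min_coverage` here are excluded with a warning rather than failing.
    """
    if method not in ("svd", "kpca"):
        raise ValueError(f"unknown ssPA method {method!r}")
    feats = set(block.feature_ids)
    X = block.values
    col_index = {f: i for i, f in enumerate(block.feature_ids)}
    states: dict[str, object] = {}
    order: list[str] = []
    for p in pathways:
        members = [m for m in sorted(p.members) if m in feats]
        if len(members) < min_coverage:
            warnings.warn(
                f"pathway {p.id!r}: coverage {len(members)} < {min_coverage}, excluded",
                stacklevel=2,
            )
            continue
        Z = X[:, [col_index[m] for m in members]]
        if method == "svd":
            mu = Z.mean(axis=0)
            Zc = Z - mu
            u, s, vt = np.linalg.svd(Zc, full_matrices=False)
            degenerate = s[0] < 1e-12
            if degenerate:
                warnings.warn(f"pathway {p.id!r}: constant submatrix", stacklevel=2)
                direction = np.zeros(len(members))
                direction[0] = 1.0
            else:
                direction = _fix_sign(vt[0])
            states[p.id] = _SvdState(
                members=members,
                col_means=mu,
                direction=direction,
                singular_value=float(s[0]),
                degenerate=degenerate,
            )
        else:
            g = gamma if gamma is not None else 1.0 / len(members)
            K = _rbf_kernel(Z, Z, g)
            n = K.shape[0]
            col_means = K.mean(axis=0)
            k_mean = float(K.mean())
            Kc = K - col_means[None, :] - col_means[:, None] + k_mean
            evals, evecs = np.linalg.eigh(Kc)
            lam = float(evals[-1])
            degenerate = lam < 1e-12
            if degenerate:
                warnings.warn(f"pathway {p.id!r}: constant submatrix", stacklevel=2)
                alpha = np.zeros(n)
                lam = 0.0
            else:
                alpha = _fix_sign(evecs[:, -1])
            states[p.id] = _KpcaState(
                members=members,
                train=Z.copy(),
                gamma=g,
                kernel_col_means=col_means,
                kernel_mean=k_mean,
                alpha=alpha,
                eigenvalue=lam,
                degenerate=degenerate,
            )
        order.append(p.id)
    return SspaTransformer(
        method=method, states=states, pathway_order=order, feature_ids=block.feature_ids
    )


def transform_sspa(t: SspaTransformer, block: OmicsBlock) -> PathwayScoreMatrix:
    """Score new standardized data with a fitted transformer.

    New data must be standardized with the *training* standardizer and
    contain every member feature of every fitted pathway.
    """
    feats = set(block.feature_ids)
    col_index = {f: i for i, f in enumerate(block.feature_ids)}
    X = block.values
    n = X.shape[0]
    out = np.empty((n, len(t.pathway_order)))
    for j, pid in enumerate(t.pathway_order):
        st = t.states[pid]
        missing = [m for m in st.members if m not in feats]
        if missing:
            raise ValueError(f"pathway {pid!r}: missing features {missing[:5]}")
        Z = X[:, [col_index[m] for m in st.members]]
        if st.degenerate:
            out[:, j] = 0.0
        elif t.method == "svd":
            out[:, j] = (Z - st.col_means) @ st.direction
        else:
            K = _rbf_kernel(Z, st.train, st.gamma)
            Kc = (
                K
                - K.mean(axis=1, keepdims=True)
                - st.kernel_col_means[None, :]
                + st.kernel_mean
            )
            out[:, j] = Kc @ st.alpha / np.sqrt(st.eigenvalue)
    scores = pd.DataFrame(out, index=block.data.index, columns=t.pathway_order)
    return PathwayScoreMatrix(
        scores=scores, provenance={"method": t.method, "n_pathways": len(t.pathway_order)}
    )


def fit_transform_sspa(
    block: OmicsBlock,
    pathways: PathwayCollection,
    method: str = "svd",
    **kwargs,
) -> tuple[SspaTransformer, PathwayScoreMatrix]:
    t = fit_sspa(block, pathways, method=method, **kwargs)
    return t, transform_sspa(t, block)


def molecule_loadings(t: SspaTransformer, pathway_id: str) -> pd.Series:
    """Per-molecule entries of the stored unit direction (svd only).

    The kernel method has no per-molecule loadings: the component lives in
    kernel feature space.
    """
    if t.method != "svd":
        raise ValueError("molecule loadings are only defined for the svd method")
    st = t.states[pathway_id]
    return pd.Series(st.direction, index=st.members, name=pathway_id)


def bootstrap_loadings(
    block: OmicsBlock,
    pathways: PathwayCollection,
    pathway_id: str,
    n_boot: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bootstrap per-molecule loading mean/sd for one pathway (svd method).

    Samples are resampled with replacement `n_boot` times; each replicate's
    direction is sign-aligned to the full-data direction (flipped when the
    dot product is negative). Degenerate replicates are skipped.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    sub = PathwayCollection(pathways=[pathways[pathway_id]])
    full = fit_sspa(block, sub, method="svd")
    ref = full.states[pathway_id].direction
    members = full.states[pathway_id].members
    rng = np.random.default_rng(seed)
    reps = []
    n = block.n_samples
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bdata = block.data.iloc[idx]
        bdata = bdata.set_axis(range(n), axis=0)
        bblock = OmicsBlock(
            data=bdata,
            omics_label=block.omics_label,
            is_log_scale=block.is_log_scale,
            is_standardized=block.is_standardized,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = fit_sspa(bblock, sub, method="svd")
        st = t.states.get(pathway_id)
        if st is None or st.degenerate:
            warnings.warn("degenerate bootstrap replicate skipped", stacklevel=2)
            continue
        d = st.direction
        if d @ ref < 0:
            d = -d
        reps.append(d)
    arr = np.asarray(reps)
    return pd.DataFrame(
        {"mean": arr.mean(axis=0), "sd": arr.std(axis=0, ddof=1)}, index=members
    )
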