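"""Semi-synthetic spike-in benchmarking.

The benchmark inserts a known signal into otherwise signal-free data:
outcome labels are randomly shuffled (destroying any real association
while keeping the molecular covariance intact) and a constant log2 effect
``alpha`` is added to every covered member of one target pathway in the
new case group only. Detecting the target among all pathways, and
classifying case vs control, then have a known ground truth.

Because real cohort matrices cannot be redistributed, a synthetic base
generator stands in for them: correlated Gaussian blocks on the log2
scale whose covariance has within-pathway structure at a configurable
correlation, with overlapping pathway annotations. The generator defines
the study conditions; experiments vary only the effect size and seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

from . import multiview
from .inference import bonferroni
from .pathways import PathwayCollection, PathwayDef, filter_coverage
from .preprocess import (
    OmicsBlock,
    OutcomeVector,
    apply_standardizer,
    fit_standardizer,
)
from .singleview import PredictorSpec, fit_singleview, predict_singleview
from .sspa import fit_sspa, transform_sspa

__all__ = [
    "SyntheticBaseConfig",
    "SemiSyntheticRealisation",
    "DetectionOutcome",
    "generate_base",
    "make_realisation",
    "mwu_test",
    "fisher_combine_conditional",
    "univariate_experiment",
    "cv_auroc",
    "nested_lv_selection",
    "evaluate_detection",
    "downsample_experiment",
]


@dataclass
class SyntheticBaseConfig:
    """Study conditions for the synthetic base data.

    Defaults give two omics blocks over 200 samples with 100 pathways of
    4-12 molecules each, within-pathway correlation 0.5, annotation
    overlap between pathways, and no cross-block correlation.
    """

    n_samples: int = 200
    n_blocks: int = 2
    n_pathways: int = 100
    pathway_size_range: tuple[int, int] = (4, 12)
    within_correlation: float = 0.5
    cross_block_correlation: float = 0.0
    overlap_fraction: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.within_correlation < 1:
            raise ValueError("within_correlation must be in [0, 1)")
        if not 0 <= self.cross_block_correlation <= 1:
            raise ValueError("cross_block_correlation must be in [0, 1]")


@dataclass
class SemiSyntheticRealisation:
    blocks: list[OmicsBlock]
    y: OutcomeVector
    target_id: str
    alpha: float
    seed: int | None
    case_level: object


@dataclass
class DetectionOutcome:
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    target_p: float
    pvalues: pd.Series


def generate_base(
    config: SyntheticBaseConfig,
) -> tuple[list[OmicsBlock], OutcomeVector, PathwayCollection]:
    """Generate correlated Gaussian omics blocks with pathway structure.

    Each pathway owns a latent factor; its member molecules load on that
    factor with sqrt(rho) so that within-pathway correlation equals
    `within_correlation`. Members are split across blocks; block-level
    factors share a common component at `cross_block_correlation`.
    Pathways additionally annotate a fraction of molecules owned by other
    pathways, giving overlapping sets without altering the covariance.
    Data are emitted on the (centered) log2 scale, unstandardized; the
    outcome is balanced binary with no real association to the data.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    k = config.n_blocks
    rho = config.within_correlation
    c = config.cross_block_correlation

    sizes = rng.integers(
        config.pathway_size_range[0], config.pathway_size_range[1] + 1,
        size=config.n_pathways,
    )
    # home assignment: molecule -> (pathway, block)
    block_features: list[list[str]] = [[] for _ in range(k)]
    block_cols: list[list[np.ndarray]] = [[] for _ in range(k)]
    members: dict[str, set[str]] = {}
    counter = 0
    for i in range(config.n_pathways):
        pid = f"PW{i:04d}"
        g_shared = rng.standard_normal(n)
        # one factor per (pathway, block): members of a pathway within a
        # block correlate at rho; across blocks at rho * c
        g_block = {
            b: np.sqrt(c) * g_shared + np.sqrt(1 - c) * rng.standard_normal(n)
            for b in range(k)
        }
        mem: set[str] = set()
        for _ in range(int(sizes[i])):
            b = int(rng.integers(0, k))
            fid = f"B{b}_M{counter:05d}"
            counter += 1
            x = np.sqrt(rho) * g_block[b] + np.sqrt(1 - rho) * rng.standard_normal(n)
            block_features[b].append(fid)
            block_cols[b].append(x)
            mem.add(fid)
        members[pid] = mem

    # annotation overlap: extra members borrowed from other pathways
    all_feats = [f for feats in block_features for f in feats]
    ids = sorted(members)
    for pid in ids:
        n_extra = int(round(config.overlap_fraction * len(members[pid])))
        if n_extra:
            extra = rng.choice(
                [f for f in all_feats if f not in members[pid]],
                size=n_extra, replace=False,
            )
            members[pid] |= set(extra)

    sample_ids = [f"S{j:04d}" for j in range(n)]
    blocks = []
    for b in range(k):
        data = pd.DataFrame(
            np.column_stack(block_cols[b]),
            index=sample_ids,
            columns=block_features[b],
        )
        blocks.append(
            OmicsBlock(data=data, omics_label=f"omics{b}", is_log_scale=True)
        )
    y_vals = np.zeros(n, dtype=int)
    y_vals[rng.permutation(n)[: n // 2]] = 1
    y = OutcomeVector(values=pd.Series(y_vals, index=sample_ids), binary=True)
    pathways = PathwayCollection(
        pathways=[
            PathwayDef(id=pid, name=f"synthetic pathway {pid}", members=frozenset(members[pid]))
            for pid in ids
        ],
        source_tag="synthetic",
    )
    return blocks, y, pathways


def make_realisation(
    blocks: list[OmicsBlock],
    y: OutcomeVector,
    pathways: PathwayCollection,
    target_id: str,
    alpha: float,
    seed: int | None = None,
    min_target_coverage: int = 3,
) -> SemiSyntheticRealisation:
    """Shuffle labels and spike the target pathway by +alpha in cases.

    Exactly the target pathway's covered member columns differ from the
    base data, only on rows of the new case group, by exactly +alpha
    (a constant on the log2 scale, i.e. a multiplicative fold change on
    the raw scale).
    """
    target = pathways[target_id]
    observed = set()
    for b in blocks:
        observed |= set(b.feature_ids)
    covered = target.members & observed
    if len(covered) < min_target_coverage:
        raise ValueError(
            f"target {target_id!r} covered by {len(covered)} molecules, "
            f"need >= {min_target_coverage}"
        )
    if not all(b.is_log_scale for b in blocks):
        raise ValueError("spike-in requires log2-scale blocks")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(y.sample_ids))
    shuffled = OutcomeVector(
        values=pd.Series(y.values.to_numpy()[perm], index=y.values.index),
        binary=y.binary,
    )
    levels = sorted(pd.unique(shuffled.values))
    case_level = levels[1]
    case_mask = (shuffled.values == case_level).to_numpy()
    spiked = []
    for b in blocks:
        cols = [f for f in b.feature_ids if f in covered]
        if cols:
            data = b.data.copy()
            data.loc[case_mask, cols] += alpha
            spiked.append(replace(b, data=data))
        else:
            spiked.append(b)
    return SemiSyntheticRealisation(
        blocks=spiked,
        y=shuffled,
        target_id=target_id,
        alpha=alpha,
        seed=seed,
        case_level=case_level,
    )


def mwu_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact enumeration for small tie-free
    groups, normal approximation with tie correction otherwise."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs at least one value")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def fisher_combine_conditional(
    pvals,
    sig_threshold: float = 0.05,
    frac: float = 0.5,
    combine_all: bool = True,
) -> float:
    """Conditionally combine molecule-level p-values into a pathway p.

    If at least `frac` of the p-values are <= `sig_threshold` (inclusive
    boundary), Fisher's method is applied: the upper tail of -2*sum(ln p)
    under chi-square with 2m degrees of freedom, by default over all m
    member p-values (set ``combine_all=False`` to combine only the
    significant ones). Otherwise the combined p-value is 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("p = 0 clamped to smallest positive float", stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    sig = p <= sig_threshold
    if sig.mean() < frac:
        return 1.0
    use = p if combine_all else p[sig]
    stat = -2.0 * np.log(use).sum()
    return float(stats.chi2.sf(stat, df=2 * len(use)))


def _eligible_targets(
    blocks: list[OmicsBlock], pathways: PathwayCollection, min_cov: int = 3
) -> list[str]:
    observed = set()
    for b in blocks:
        observed |= set(b.feature_ids)
    return [p.id for p in pathways if len(p.members & observed) >= min_cov]


def univariate_experiment(
    blocks: list[OmicsBlock],
    y: OutcomeVector,
    pathways: PathwayCollection,
    effect_grid,
    level: str = "pathway",
    n_real: int = 100,
    seed: int | None = None,
    sspa_method: str = "kpca",
    gate_on: str = "adjusted",
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Power of univariate target detection vs effect size.

    Per realisation a random eligible target pathway is spiked. At the
    pathway level, ssPA scores for the target are compared between groups
    with a Mann-Whitney U test, Bonferroni-corrected over all scoreable
    pathways. At the molecular level, each covered target member gets an
    MWU test, Bonferroni over the members, and the member p-values are
    conditionally Fisher-combined (>= 50% significant gate, evaluated on
    adjusted p by default, ``gate_on='raw'`` to gate on raw p). Returns
    the fraction of realisations significant at `alpha_level` per effect
    size.
    """
    if level not in ("pathway", "molecular"):
        raise ValueError("level must be 'pathway' or 'molecular'")
    targets = _eligible_targets(blocks, pathways)
    if not targets:
        raise ValueError("no pathway has the required coverage")
    observed = set()
    for b in blocks:
        observed |= set(b.feature_ids)
    n_pathways_tested = len(
        filter_coverage(pathways, observed, min_coverage=2)[0]
    )
    ss = np.random.SeedSequence(seed)
    rows = []
    for alpha_effect in effect_grid:
        children = ss.spawn(n_real)
        n_sig = 0
        for child in children:
            rng = np.random.default_rng(child)
            target = targets[int(rng.integers(len(targets)))]
            real = make_realisation(
                blocks, y, pathways, target, alpha_effect,
                seed=int(rng.integers(2**31)),
            )
            case = (real.y.values == real.case_level).to_numpy()
            if level == "pathway":
                p_final = _pathway_level_p(
                    real, target, case, pathways, sspa_method, n_pathways_tested
                )
            else:
                p_final = _molecular_level_p(
                    real, pathways[target].members, case, gate_on
                )
            n_sig += p_final <= alpha_level
        rows.append(
            {
                "effect_size": float(alpha_effect),
                "level": level,
                "n_realisations": n_real,
                "proportion_significant": n_sig / n_real,
            }
        )
    return pd.DataFrame(rows)


def _pathway_level_p(real, target, case, pathways, sspa_method, m) -> float:
    cat = pd.concat([b.data for b in real.blocks], axis=1)
    block = OmicsBlock(data=cat, omics_label="concat", is_log_scale=True)
    std = fit_standardizer(block)
    block = apply_standardizer(std, block)
    sub = PathwayCollection(pathways=[pathways[target]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t = fit_sspa(block, sub, method=sspa_method)
        scores = transform_sspa(t, block).values[:, 0]
    _, p = mwu_test(scores[case], scores[~case])
    return min(p * m, 1.0)


def _molecular_level_p(real, target_members, case, gate_on) -> float:
    """MWU per covered target member, Bonferroni over members, then the
    conditional Fisher combination gated on (by default) adjusted p."""
    member_p = []
    for b in real.blocks:
        for f in b.feature_ids:
            if f in target_members:
                x = b.data[f].to_numpy()
                _, p = mwu_test(x[case], x[~case])
                member_p.append(p)
    member_p = np.asarray(member_p)
    adj = np.minimum(member_p * len(member_p), 1.0)
    gate_p = adj if gate_on == "adjusted" else member_p
    if (gate_p <= 0.05).mean() < 0.5:
        return 1.0
    # gate already passed; combine all raw member p-values
    return fisher_combine_conditional(member_p, sig_threshold=1.0, frac=0.0)


def cv_auroc(
    blocks: list[OmicsBlock],
    y: OutcomeVector,
    pathways: PathwayCollection,
    framework: str = "multiview",
    R: int = 1,
    predictor: PredictorSpec | None = None,
    sspa_method: str = "svd",
    n_repeats: int = 5,
    n_folds: int = 5,
    seed: int | None = None,
    min_coverage: int = 2,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Leakage-safe repeated stratified CV AUROC.

    Per fold, standardizers and ssPA transformers are fitted on the
    training samples only and applied to the held-out fold; the model is
    fitted on training scores and the AUROC computed from the continuous
    prediction on the held-out fold. Returns (mean AUC, normal 95% CI,
    per-fold AUCs).
    """
    yv = y.encoded()
    counts = np.bincount(yv.astype(int))
    if (counts < n_folds).any():
        raise ValueError("each class needs at least n_folds members")
    rskf = RepeatedStratifiedKFold(
        n_splits=n_folds, n_repeats=n_repeats, random_state=seed
    )
    sample_ids = np.asarray(blocks[0].sample_ids)
    aucs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr, te in rskf.split(np.zeros(len(yv)), yv):
            auc = _one_fold_auc(
                blocks, y, pathways, sample_ids, tr, te,
                framework, R, predictor, sspa_method, min_coverage,
            )
            aucs.append(auc)
    aucs = np.asarray(aucs)
    mean = float(aucs.mean())
    half = 1.96 * aucs.std(ddof=1) / np.sqrt(len(aucs))
    return mean, (mean - half, mean + half), aucs


def _one_fold_auc(
    blocks, y, pathways, sample_ids, tr, te,
    framework, R, predictor, sspa_method, min_coverage,
) -> float:
    tr_ids, te_ids = sample_ids[tr], sample_ids[te]
    tr_blocks = [b.subset_samples(tr_ids) for b in blocks]
    te_blocks = [b.subset_samples(te_ids) for b in blocks]
    y_tr, y_te = y.subset(tr_ids), y.subset(te_ids)
    if framework == "singleview":
        model = fit_singleview(
            tr_blocks, y_tr, pathways,
            sspa_method=sspa_method,
            predictor=predictor or PredictorSpec("pls", {"R": R}),
            min_coverage=min_coverage,
        )
        scores = predict_singleview(model, te_blocks)
    elif framework == "multiview":
        tr_scores, te_scores = [], []
        for btr, bte in zip(tr_blocks, te_blocks):
            std = fit_standardizer(btr)
            btr_s = apply_standardizer(std, btr)
            bte_s = apply_standardizer(std, bte)
            filt, _ = filter_coverage(
                pathways, set(btr.feature_ids), min_coverage
            )
            t = fit_sspa(btr_s, filt, method=sspa_method,
                         min_coverage=min_coverage)
            tr_scores.append(transform_sspa(t, btr_s))
            te_scores.append(transform_sspa(t, bte_s))
        model = multiview.fit_mbpls(tr_scores, y_tr, R=R)
        scores = multiview.predict(model, te_scores)
    else:
        raise ValueError(f"unknown framework {framework!r}")
    return float(roc_auc_score(y_te.encoded(), scores))


def nested_lv_selection(
    blocks: list[OmicsBlock],
    y: OutcomeVector,
    pathways: PathwayCollection,
    R_grid=(1, 2, 3, 4, 5),
    inner_folds: int = 5,
    inner_repeats: int = 5,
    sspa_method: str = "svd",
    seed: int | None = None,
    min_coverage: int = 2,
) -> tuple[int, pd.DataFrame]:
    """Select the number of latent variables by repeated inner CV.

    Fits one model per fold at max(R_grid) and evaluates each R as a
    prefix of its latent variables (NIPALS is sequential); the inner
    5-fold split is repeated `inner_repeats` times to stabilise the mean
    AUC per R. Selection rule: the smallest R whose mean inner AUC is
    within one standard error of the maximum.
    """
    R_grid = sorted(R_grid)
    if not R_grid:
        raise ValueError("R grid must be non-empty")
    R_max = R_grid[-1]
    yv = y.encoded()
    skf = RepeatedStratifiedKFold(
        n_splits=inner_folds, n_repeats=inner_repeats, random_state=seed
    )
    sample_ids = np.asarray(blocks[0].sample_ids)
    fold_aucs = {R: [] for R in R_grid}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr, te in skf.split(np.zeros(len(yv)), yv):
            tr_ids, te_ids = sample_ids[tr], sample_ids[te]
            tr_blocks = [b.subset_samples(tr_ids) for b in blocks]
            te_blocks = [b.subset_samples(te_ids) for b in blocks]
            y_tr, y_te = y.subset(tr_ids), y.subset(te_ids)
            tr_scores, te_scores = [], []
            for btr, bte in zip(tr_blocks, te_blocks):
                std = fit_standardizer(btr)
                btr_s = apply_standardizer(std, btr)
                bte_s = apply_standardizer(std, bte)
                filt, _ = filter_coverage(
                    pathways, set(btr.feature_ids), min_coverage
                )
                t = fit_sspa(btr_s, filt, method=sspa_method,
                             min_coverage=min_coverage)
                tr_scores.append(transform_sspa(t, btr_s))
                te_scores.append(transform_sspa(t, bte_s))
            model = multiview.fit_mbpls(tr_scores, y_tr, R=R_max)
            for R in R_grid:
                pred = multiview.predict(model, te_scores, n_lv=R)
                fold_aucs[R].append(roc_auc_score(y_te.encoded(), pred))
    rows = []
    for R in R_grid:
        arr = np.asarray(fold_aucs[R])
        rows.append(
            {
                "R": R,
                "mean_auc": float(arr.mean()),
                "se": float(arr.std(ddof=1) / np.sqrt(len(arr))),
            }
        )
    curve = pd.DataFrame(rows)
    best = curve.loc[curve["mean_auc"].idxmax()]
    threshold = best["mean_auc"] - best["se"]
    selected = int(curve[curve["mean_auc"] >= threshold]["R"].min())
    return selected, curve


def evaluate_detection(adjusted_pvals: pd.Series, target_id: str) -> DetectionOutcome:
    """Score one realisation's pathway ranking against the known target.

    Confusion counts use the p_adj <= 0.05 rule; the detection AUC is the
    fraction of non-target pathways with p strictly greater than the
    target's, counting ties as one half (mid-rank rule, since permutation
    p-values tie heavily on the 1/n_perm grid).
    """
    p = pd.Series(adjusted_pvals, dtype=float)
    if target_id not in p.index:
        raise ValueError(f"target {target_id!r} not among tested pathways")
    pt = float(p.loc[target_id])
    others = p.drop(index=target_id).to_numpy()
    tp = int(pt <= 0.05)
    fn = 1 - tp
    fp = int((others <= 0.05).sum())
    tn = len(others) - fp
    auc = float(((others > pt).sum() + 0.5 * (others == pt).sum()) / len(others))
    return DetectionOutcome(
        tp=tp, fp=fp, tn=tn, fn=fn, auc=auc, target_p=pt, pvalues=p
    )


def downsample_experiment(
    blocks: list[OmicsBlock],
    y: OutcomeVector,
    pathways: PathwayCollection,
    sizes,
    seed: int | None = None,
    **cv_kwargs,
) -> pd.DataFrame:
    """AUROC vs sample size, subsampling classes to an exact 1:1 ratio."""
    yv = y.encoded()
    sample_ids = np.asarray(blocks[0].sample_ids)
    n_folds = cv_kwargs.get("n_folds", 5)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size < 2 * n_folds:
            raise ValueError(f"size {size} < 2 * n_folds")
        per_class = size // 2
        if per_class > min(np.bincount(yv.astype(int))):
            raise ValueError(f"size {size} exceeds available per-class count")
        idx0 = rng.choice(np.flatnonzero(yv == 0), per_class, replace=False)
        idx1 = rng.choice(np.flatnonzero(yv == 1), per_class, replace=False)
        keep = sample_ids[np.sort(np.concatenate([idx0, idx1]))]
        sub_blocks = [b.subset_samples(keep) for b in blocks]
        sub_y = y.subset(keep)
        # CV folds share the master seed so the full-size row reproduces
        # cv_auroc on the complete data exactly
        mean, ci, aucs = cv_auroc(sub_blocks, sub_y, pathways, seed=seed,
                                  **cv_kwargs)
        rows.append(
            {
                "size": int(2 * per_class),
                "mean_auc": mean,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "auc_variance": float(np.var(aucs, ddof=1)),
            }
        )
    return pd.DataFrame(rows)
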