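"""End-to-end liking analysis: train on scored cultivars, predict the rest.

The pipeline chains the package's pieces the way the aroma study runs them:
maturity screening, pulp/skin → whole-berry blending, Hotelling's T²
outlier screening (single pass), UV scaling, OPLS component selection by
seven-fold cross-validation, permutation validation, prediction of
consumer-liking scores for unscored cultivars, VIP-based key-compound
selection, quality binning, aroma-combination grouping and hierarchical
clustering of aromatic-series profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from . import chemometrics as chem
from .compound_library import AromaTaxonomy, default_taxonomy, resolve_memberships
from .errors import ModelError, ValidationError
from .oav_series import OavTable, SeriesProfile, compute_oav, series_values, active_compounds
from .profiles import SampleSet

#: Models with cross-validated Q²Y at or below this are flagged ineffective.
EFFECTIVE_Q2Y: float = 0.5

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def quality_bin(score: float) -> str:
    """Map a liking score to its aroma-quality bin.

    poor < 3.5 ≤ average < 4.0 ≤ good ≤ 4.5 < excellent.  The bins
    partition the real line; the 4.5 boundary belongs to "good".
    """
    if not np.isfinite(score):
        raise ValidationError(f"non-finite liking score: {score!r}")
    if score < 3.5:
        return "poor"
    if score < 4.0:
        return "average"
    if score <= 4.5:
        return "good"
    return "excellent"


@dataclass
class PipelineConfig:
    """Knobs of the end-to-end analysis."""

    tissue: str = "whole"
    feature_block: str = "concentration"   # "concentration" | "series"
    folds: int = 7
    n_permutations: int = 200              # 0 skips the permutation test
    max_ortho: int = 9
    min_improvement: float = 0.01
    vip_cutoff: float = 1.0
    skin_mass_fraction: float = 0.2
    screen_outliers: bool = True
    remove_unripe: bool = False
    seed: int = 0
    taxonomy: AromaTaxonomy | None = None


@dataclass
class KeyCompound:
    compound_id: str
    vip: float
    direction: str                 # "positive" | "negative"
    is_active: bool                # pooled OAV > 1 anywhere


@dataclass
class LikingReport:
    cultivar_id: str
    predicted_score: float
    replicate_scores: list[float]
    quality_bin: str
    aroma_combination: str | None = None

    def to_dict(self) -> dict:
        return {
            "cultivar_id": self.cultivar_id,
            "predicted_score": self.predicted_score,
            "replicate_scores": self.replicate_scores,
            "quality_bin": self.quality_bin,
            "aroma_combination": self.aroma_combination,
        }


@dataclass
class ClusterResult:
    level: str
    tissue: str | None
    labels: pd.Series              # per-sample cluster id (1..k)
    cluster_means: pd.DataFrame    # cluster x series heatmap matrix
    linkage: np.ndarray


@dataclass
class FittedPipeline:
    model: chem.OplsModel
    cv: chem.CrossValResult
    vip_scores: chem.VipScores
    config: PipelineConfig
    screen: chem.HotellingScreen | None
    removed_outliers: list[str]
    permutation: chem.PermutationResult | None
    training_cultivars: list[str]
    warnings: list[str] = field(default_factory=list)

    @property
    def q2y(self) -> float:
        return self.cv.chosen_q2y

    @property
    def effective(self) -> bool:
        """Whether the model clears the Q²Y > 0.5 adequacy criterion."""
        return bool(self.q2y > EFFECTIVE_Q2Y)


def _with_whole(sset: SampleSet, config: PipelineConfig) -> SampleSet:
    if config.tissue == "whole" and "whole" not in sset.tissues:
        return sset.combine_tissues(config.skin_mass_fraction)
    return sset


def _taxonomy(config: PipelineConfig) -> AromaTaxonomy:
    return config.taxonomy if config.taxonomy is not None else default_taxonomy()


def _series_features(sset: SampleSet, config: PipelineConfig) -> pd.DataFrame:
    """Aromatic-series values (primary + secondary) as the feature block."""
    taxonomy = _taxonomy(config)
    memberships = resolve_memberships(sset.library, taxonomy)
    table = compute_oav(sset)
    prim = series_values(table, memberships, "primary")
    sec = series_values(table, memberships, "secondary")
    feats = pd.concat(
        [prim.values.add_prefix("primary:"), sec.values.add_prefix("secondary:")], axis=1
    )
    return feats


def _feature_replicates(sset: SampleSet, config: PipelineConfig) -> pd.DataFrame:
    """Per-replicate feature rows for the configured tissue, indexed by
    (cultivar_id, replicate)."""
    sset = _with_whole(sset, config)
    if config.feature_block == "concentration":
        feats = sset.data
    elif config.feature_block == "series":
        feats = _series_features(sset, config)
    else:
        raise ValidationError(f"unknown feature block {config.feature_block!r}")
    return feats.xs(config.tissue, level="tissue")


def _feature_means(sset: SampleSet, config: PipelineConfig) -> pd.DataFrame:
    return _feature_replicates(sset, config).groupby(level="cultivar_id").mean()


def train(sset: SampleSet, scores: pd.Series, config: PipelineConfig | None = None) -> FittedPipeline:
    """Fit the liking model on the scored ("popular") cultivar block.

    ``scores`` maps cultivar_id → liking on the 1–5 scale.  The stages are:
    optional ripeness filter, whole-berry blending, Hotelling's T² screen
    (flag, remove, refit once), cross-validated component selection, final
    OPLS fit, optional permutation validation and VIP computation.
    """
    config = config or PipelineConfig()
    warnings: list[str] = []
    scores = scores.astype(float)

    if config.remove_unripe:
        report = sset.screen_maturity()
        unripe = report.index[~report["ripe"]].tolist()
        if unripe:
            warnings.append(f"removed unripe cultivars: {unripe}")
            scores = scores.drop(index=[c for c in unripe if c in scores.index])

    x_all = _feature_means(sset, config)
    cultivars = [c for c in x_all.index if c in scores.index]
    if len(cultivars) < config.folds:
        raise ModelError(
            f"{len(cultivars)} scored cultivars is fewer than folds={config.folds}"
        )
    x = x_all.loc[cultivars]
    y = scores.loc[cultivars]

    screen = None
    removed: list[str] = []
    if config.screen_outliers:
        screen = chem.pca_hotelling_screen(x, alpha=0.01)
        removed = [str(c) for c in screen.outliers]
        if removed:
            warnings.append(f"Hotelling T² (99%) removed strong outliers: {removed}")
            keep = [c for c in cultivars if c not in removed]
            if len(keep) < config.folds:
                raise ModelError("outlier screening left fewer cultivars than folds")
            x, y = x.loc[keep], y.loc[keep]
            cultivars = keep

    cv = chem.cross_validate(
        x,
        y,
        folds=config.folds,
        seed=config.seed,
        min_improvement=config.min_improvement,
        max_ortho=config.max_ortho,
    )
    model = chem.fit_opls(x, y, n_ortho=cv.chosen_n_ortho)
    model.stats["Q2Y"] = float(cv.chosen_q2y)
    model.stats["RMSECV"] = float(cv.chosen_rmsecv)

    permutation = None
    if config.n_permutations > 0:
        permutation = chem.permutation_test(
            x,
            y,
            n_ortho=cv.chosen_n_ortho,
            folds=config.folds,
            n_perm=config.n_permutations,
            seed=config.seed,
        )

    scores_vip = chem.vip(model)
    fitted = FittedPipeline(
        model=model,
        cv=cv,
        vip_scores=scores_vip,
        config=config,
        screen=screen,
        removed_outliers=removed,
        permutation=permutation,
        training_cultivars=cultivars,
        warnings=warnings,
    )
    if not fitted.effective:
        fitted.warnings.append(
            f"model ineffective: Q2Y={fitted.q2y:.3f} <= {EFFECTIVE_Q2Y}; "
            "downstream key-compound selection is blocked unless overridden"
        )
    return fitted


def predict_liking(pipeline: FittedPipeline, unscored: SampleSet) -> list[LikingReport]:
    """Predict liking for unscored ("unfamiliar") cultivars.

    Predictions are made per replicate and averaged per cultivar; the
    quality bin is assigned from the cultivar mean.
    """
    feats = _feature_replicates(unscored, pipeline.config)
    reports = []
    for cultivar in sorted(set(feats.index.get_level_values("cultivar_id"))):
        rows = feats.xs(cultivar, level="cultivar_id")
        preds = pipeline.model.predict(rows)
        mean = float(np.mean(preds))
        reports.append(
            LikingReport(
                cultivar_id=str(cultivar),
                predicted_score=mean,
                replicate_scores=[float(p) for p in preds],
                quality_bin=quality_bin(mean),
            )
        )
    return reports


def select_key_compounds(
    pipeline: FittedPipeline,
    oav_table: OavTable,
    cutoff: float | None = None,
    allow_ineffective: bool = False,
) -> list[KeyCompound]:
    """Compounds with VIP above the cutoff, signed by their regression
    coefficient, flagged aroma-active if their pooled OAV exceeds 1.

    Refuses to run on an ineffective model (Q²Y ≤ 0.5) unless explicitly
    overridden.
    """
    if not pipeline.effective and not allow_ineffective:
        raise ModelError(
            f"model ineffective (Q2Y={pipeline.q2y:.3f}); pass allow_ineffective=True to override"
        )
    if pipeline.config.feature_block != "concentration":
        raise ModelError("key-compound selection requires the concentration feature block")
    cutoff = pipeline.config.vip_cutoff if cutoff is None else cutoff
    pooled = active_compounds(oav_table).pooled
    selected = pipeline.vip_scores.above(cutoff)
    signs = pipeline.vip_scores.coefficient_sign
    out = [
        KeyCompound(
            compound_id=str(cid),
            vip=float(v),
            direction="positive" if signs[cid] >= 0 else "negative",
            is_active=cid in pooled,
        )
        for cid, v in selected.items()
    ]
    out.sort(key=lambda kc: -kc.vip)
    return out


def assign_aroma_combinations(
    reports: list[LikingReport],
    key_compounds: list[KeyCompound],
    sset: SampleSet,
    n_groups: int = 5,
    seed: int = 0,
    tissue: str = "whole",
    skin_mass_fraction: float = 0.2,
) -> pd.Series:
    """Group cultivars into aroma combinations by their key-compound content.

    Per cultivar, P and N are the total whole-berry concentrations of the
    positively and negatively liking-related key compounds; cultivars are
    partitioned by seeded k-means on the UV-scaled (P, N) plane and the
    groups are labelled I, II, ... in increasing order of total content
    P + N.  Reports are annotated in place; the labels are also returned.
    """
    if n_groups < 1:
        raise ValidationError("n_groups must be >= 1")
    cultivars = [r.cultivar_id for r in reports]
    if len(cultivars) < n_groups:
        raise ValidationError(f"{len(cultivars)} cultivars cannot form {n_groups} groups")
    if tissue == "whole" and "whole" not in sset.tissues:
        sset = sset.combine_tissues(skin_mass_fraction)
    means = sset.cultivar_means(tissue)
    missing = [c for c in cultivars if c not in means.index]
    if missing:
        raise ValidationError(f"no samples for cultivars: {missing}")
    pos = [k.compound_id for k in key_compounds if k.direction == "positive"]
    neg = [k.compound_id for k in key_compounds if k.direction == "negative"]
    p = means.loc[cultivars, pos].sum(axis=1) if pos else pd.Series(0.0, index=cultivars)
    n = means.loc[cultivars, neg].sum(axis=1) if neg else pd.Series(0.0, index=cultivars)
    pn = pd.DataFrame({"positive_total": p, "negative_total": n})
    scaled, _ = chem.uv_scale(pn, "fit")
    if scaled.size == 0:    # all cultivars identical
        scaled = np.zeros((len(cultivars), 1))
    km = KMeans(n_clusters=n_groups, random_state=seed, n_init=10)
    raw_labels = km.fit_predict(scaled)
    totals = (p + n).to_numpy()
    order = sorted(range(n_groups), key=lambda g: totals[raw_labels == g].mean())
    label_of = {g: _ROMAN[rank] for rank, g in enumerate(order)}
    labels = pd.Series([label_of[g] for g in raw_labels], index=cultivars, name="aroma_combination")
    for report in reports:
        report.aroma_combination = str(labels[report.cultivar_id])
    return labels


def hca_clusters(profile: SeriesProfile, k: int, tissue: str | None = None) -> ClusterResult:
    """Hierarchical (Ward, Euclidean) clustering of UV-scaled series values.

    The dendrogram is cut to ``k`` clusters and a cluster-mean heatmap
    matrix (clusters × series, original value scale) is emitted.
    """
    values = profile.values
    if tissue is not None:
        values = values.xs(tissue, level="tissue")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(values):
        raise ValidationError(f"k={k} exceeds the {len(values)} available samples")
    scaled, params = chem.uv_scale(values, "fit")
    if scaled.shape[1] == 0:
        scaled = np.zeros((len(values), 1))
    linkage = hierarchy.linkage(scaled, method="ward", metric="euclidean")
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    label_series = pd.Series(labels, index=values.index, name="cluster")
    cluster_means = values.groupby(label_series).mean()
    cluster_means.index.name = "cluster"
    return ClusterResult(
        level=profile.level,
        tissue=tissue,
        labels=label_series,
        cluster_means=cluster_means,
        linkage=linkage,
    )
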