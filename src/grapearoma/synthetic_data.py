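"""Seeded synthetic volatile-profile cohorts.

The generator emulates the statistical structure of a table-grape aroma
study so that every downstream stage (OAV scoring, aromatic series, OPLS
liking regression) is testable without measured data:

* a compound panel spread over the eight grape chemical classes with
  log-uniform odor thresholds spanning 0.1–10000 μg/kg and descriptors
  drawn from the default aromatic-series taxonomy;
* log-normal concentrations per (cultivar, class) with tissue bias —
  ester mass concentrated in pulp, terpene mass in skin, C₆ compounds as a
  high background in both — and multiplicative replicate noise (CV ≈ 10%);
* consumer liking on a 1–5 scale generated as a clipped linear function of
  the UV-scaled whole-berry concentrations of a designated set of "key"
  compounds with mixed-sign coefficients, plus Gaussian noise;
* optional structured X variation that is exactly orthogonal to the liking
  signal across cultivars (the variation an O-PLS model should shunt into
  its orthogonal components).

Key compounds load on two latent cultivar factors (one for the positively,
one for the negatively liked group) plus idiosyncratic variation, mimicking
the co-regulation of biosynthetically related volatiles; this is what makes
coefficient signs recoverable from realistic cohort sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .compound_library import (
    Compound,
    CompoundLibrary,
    PRIMARY_SERIES,
    default_taxonomy,
)
from .errors import ReferenceError_, ValidationError
from .profiles import SampleKey, SampleSet

# Class composition of the panel, close to the relative class sizes seen in
# table grapes (terpenes and esters dominate the count, a C6 backbone, a few
# norisoprenoids and ketones).
CLASS_PROPORTIONS: dict[str, float] = {
    "ester": 0.20,
    "terpene": 0.30,
    "aldehyde": 0.13,
    "alcohol": 0.11,
    "C6": 0.07,
    "acid": 0.05,
    "C13_norisoprenoid": 0.03,
    "ketone": 0.02,
    "other": 0.09,
}

_REQUIRED_CLASSES = [c for c in CLASS_PROPORTIONS if c != "other"]

# log10 μg/kg base-abundance ranges per class; C6 compounds form the high
# background, esters sit in the mid range.
_BASE_LOG10_RANGE: dict[str, tuple[float, float]] = {
    "C6": (2.0, 3.5),
    "ester": (1.0, 3.3),
    "terpene": (0.5, 3.0),
}
_BASE_LOG10_DEFAULT = (0.0, 2.7)

# Additive natural-log tissue bias per class: (pulp, skin).
_TISSUE_BIAS: dict[str, tuple[float, float]] = {
    "ester": (1.2, -0.9),
    "terpene": (-1.2, 1.2),
    "C6": (0.4, 0.4),
}
_TISSUE_BIAS_DEFAULT = (-0.2, 0.3)

# Descriptor pools per chemical class (tokens of the default taxonomy).
_CLASS_DESCRIPTORS: dict[str, list[str]] = {
    "ester": ["apple", "banana", "strawberry", "pineapple", "grape", "citrus", "orange", "lemon"],
    "terpene": ["rose", "geranium", "violet", "lavender", "orange_flower", "citrus", "pine", "floral"],
    "C6": ["green", "grass", "leafy"],
    "aldehyde": ["citrus", "fatty", "waxy", "green"],
    "alcohol": ["green", "floral", "rose"],
    "acid": ["fatty", "cheesy", "oily"],
    "C13_norisoprenoid": ["violet", "rose", "honey"],
    "ketone": ["banana", "fatty", "caramel"],
    "other": ["solvent", "spicy", "roasted", "earthy", "balsamic", "marshmallow", "honey"],
}

# Canonical descriptor used to patch a primary series nobody drew.
_CANONICAL_DESCRIPTOR: dict[str, str] = {
    "herbaceous": "green",
    "floral": "floral",
    "fruity": "apple",
    "sweet": "honey",
    "spicy": "spicy",
    "roasty": "roasted",
    "fatty": "fatty",
    "earthy": "earthy",
    "balsamic": "balsamic",
    "solvent": "solvent",
}


@dataclass
class CohortConfig:
    """Study-condition parameters of a synthetic cohort.

    Defaults mirror the canonical study layout: a scored training block of
    20 cultivars, an unscored block of 19, triplicate profiling of pulp and
    skin over a 100-compound panel, 17 positively and 9 negatively
    liking-related key compounds, liking noise of 0.2 points on the 1–5
    scale and 3 y-orthogonal latent factors in X.
    """

    n_train_cultivars: int = 20
    n_test_cultivars: int = 19
    n_replicates: int = 3
    n_compounds: int = 100
    n_key_positive: int = 17
    n_key_negative: int = 9
    noise_sd: float = 0.2
    n_orthogonal_factors: int = 3
    replicate_cv: float = 0.10
    dropout_rate: float = 0.08
    skin_mass_fraction: float = 0.2
    liking_center: float = 3.5
    liking_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train_cultivars < 1:
            raise ValidationError("need at least one training cultivar")
        if self.n_replicates < 1 or self.n_compounds < 1:
            raise ValidationError("replicate and compound counts must be positive")
        if self.n_key_positive + self.n_key_negative > self.n_compounds:
            raise ValidationError("more key compounds than compounds in the panel")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_orthogonal_factors < 0:
            raise ValidationError("n_orthogonal_factors must be >= 0")

    @property
    def n_cultivars(self) -> int:
        return self.n_train_cultivars + self.n_test_cultivars

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What the generator actually injected.

    ``true_scores`` are the clipped noise-free liking values;
    ``observed_scores`` add the configured Gaussian noise before clipping.
    ``liking_coefficients`` are the effective signed weights applied to the
    UV-scaled whole-berry concentrations (0 for non-key compounds).
    """

    liking_coefficients: pd.Series
    true_scores: pd.Series
    observed_scores: pd.Series
    orthogonal_loadings: pd.DataFrame
    key_positive: list[str] = field(default_factory=list)
    key_negative: list[str] = field(default_factory=list)
    train_cultivars: list[str] = field(default_factory=list)
    test_cultivars: list[str] = field(default_factory=list)

    @property
    def key_compounds(self) -> list[str]:
        return self.key_positive + self.key_negative

    def save(self, path: str | Path) -> None:
        doc = {
            "liking_coefficients": self.liking_coefficients.to_dict(),
            "true_scores": self.true_scores.to_dict(),
            "observed_scores": self.observed_scores.to_dict(),
            "orthogonal_loadings": self.orthogonal_loadings.to_dict(),
            "key_positive": self.key_positive,
            "key_negative": self.key_negative,
            "train_cultivars": self.train_cultivars,
            "test_cultivars": self.test_cultivars,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def _allocate_classes(n_compounds: int) -> dict[str, int]:
    """Largest-remainder allocation of compounds to classes, every one of
    the eight grape classes guaranteed at least one compound."""
    if n_compounds < len(_REQUIRED_CLASSES):
        raise ValidationError(
            f"n_compounds={n_compounds} cannot populate all "
            f"{len(_REQUIRED_CLASSES)} chemical classes"
        )
    classes = list(CLASS_PROPORTIONS)
    if n_compounds < len(classes):
        classes = _REQUIRED_CLASSES
    shares = np.array([CLASS_PROPORTIONS[c] for c in classes])
    shares = shares / shares.sum() * n_compounds
    counts = {c: max(int(np.floor(s)), 1) for c, s in zip(classes, shares)}
    remainder = n_compounds - sum(counts.values())
    order = np.argsort(-(shares - np.floor(shares)))
    i = 0
    while remainder != 0:
        c = classes[order[i % len(classes)]]
        if remainder > 0:
            counts[c] += 1
            remainder -= 1
        elif counts[c] > 1:
            counts[c] -= 1
            remainder += 1
        i += 1
    return counts


def generate_panel(config: CohortConfig) -> CompoundLibrary:
    """Generate a synthetic compound panel.

    Compounds are allocated across the eight chemical classes in realistic
    proportions, odor thresholds are log-uniform over [0.1, 10000] μg/kg,
    and each compound draws 1–3 descriptors from a class-typical pool of
    the default taxonomy (esters fruity, terpenes floral, C₆ green, ...);
    any primary series left unpopulated is patched with its canonical
    descriptor so all ten series can be exercised downstream.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    counts = _allocate_classes(config.n_compounds)
    taxonomy = default_taxonomy()
    compounds: list[Compound] = []
    idx = 0
    for cls, count in counts.items():
        pool = _CLASS_DESCRIPTORS[cls]
        for _ in range(count):
            idx += 1
            cid = f"cmp{idx:03d}"
            threshold = float(10 ** rng.uniform(-1, 4))
            n_desc = int(rng.integers(1, 4))
            descriptors = [pool[int(rng.integers(0, len(pool)))]]
            all_pool = sorted(taxonomy.primary_of)
            while len(descriptors) < n_desc:
                tok = all_pool[int(rng.integers(0, len(all_pool)))]
                if tok not in descriptors:
                    descriptors.append(tok)
            compounds.append(
                Compound(
                    compound_id=cid,
                    name=f"synthetic {cls} {idx}",
                    chemical_class=cls,
                    odor_threshold=threshold,
                    descriptors=tuple(descriptors),
                )
            )
    covered = set()
    for c in compounds:
        for d in c.descriptors:
            hit = taxonomy.lookup(d)
            if hit:
                covered.add(hit[0])
    for j, series in enumerate(PRIMARY_SERIES):
        if series not in covered:
            c = compounds[j % len(compounds)]
            compounds[j % len(compounds)] = Compound(
                compound_id=c.compound_id,
                name=c.name,
                chemical_class=c.chemical_class,
                odor_threshold=c.odor_threshold,
                descriptors=c.descriptors + (_CANONICAL_DESCRIPTOR[series],),
            )
    return CompoundLibrary(compounds)


def generate_cohort(
    config: CohortConfig, panel: CompoundLibrary | None = None
) -> tuple[SampleSet, GroundTruth]:
    """Generate a full synthetic cohort and its ground truth.

    Returns a :class:`SampleSet` holding pulp and skin triplicates plus
    maturity records for ``n_train + n_test`` cultivars, and the
    :class:`GroundTruth` (injected coefficients, noise-free and observed
    liking scores, orthogonal-factor loadings).
    """
    if panel is None:
        panel = generate_panel(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids = panel.ids
    classes = panel.classes()
    n_c = config.n_cultivars
    cultivars = [f"P{i + 1:02d}" for i in range(config.n_train_cultivars)] + [
        f"U{i + 1:02d}" for i in range(config.n_test_cultivars)
    ]
    train = cultivars[: config.n_train_cultivars]
    test = cultivars[config.n_train_cultivars :]

    # -- key compounds and their latent factor structure -------------------
    keys = rng.choice(ids, size=config.n_key_positive + config.n_key_negative, replace=False)
    key_pos = [str(k) for k in keys[: config.n_key_positive]]
    key_neg = [str(k) for k in keys[config.n_key_positive :]]
    # The scored block plays the role of a sensory-panel training set, which
    # is assembled to span the preference space: standardize both latent
    # factors (and decorrelate them) within that block.
    f_pos = rng.standard_normal(n_c)
    f_neg = rng.standard_normal(n_c)
    n_tr = config.n_train_cultivars
    if n_tr >= 3:
        f_pos[:n_tr] = (f_pos[:n_tr] - f_pos[:n_tr].mean()) / f_pos[:n_tr].std(ddof=1)
        ft = f_neg[:n_tr] - f_neg[:n_tr].mean()
        fp = f_pos[:n_tr]
        ft = ft - (ft @ fp) / (fp @ fp) * fp
        sd_ft = ft.std(ddof=1)
        if sd_ft > 0:
            f_neg[:n_tr] = ft / sd_ft
    factor_loading = {c: float(rng.uniform(0.55, 0.7)) for c in key_pos + key_neg}

    # -- base abundance per compound (ln μg/kg) -----------------------------
    base = np.empty(len(ids))
    for j, cid in enumerate(ids):
        lo, hi = _BASE_LOG10_RANGE.get(classes[cid], _BASE_LOG10_DEFAULT)
        base[j] = np.log(10.0) * rng.uniform(lo, hi)

    class_effect = {
        (c, cls): rng.normal(0.0, 0.1) for c in cultivars for cls in set(classes)
    }
    idio_sd = np.where(np.isin(ids, key_pos + key_neg), 0.08, 0.25)
    idio = rng.normal(0.0, 1.0, size=(n_c, len(ids))) * idio_sd

    ln_mu = np.empty((n_c, 2, len(ids)))  # cultivar x (pulp, skin) x compound
    for i, cultivar in enumerate(cultivars):
        for j, cid in enumerate(ids):
            cls = classes[cid]
            bias = _TISSUE_BIAS.get(cls, _TISSUE_BIAS_DEFAULT)
            factor = 0.0
            if cid in key_pos:
                factor = factor_loading[cid] * f_pos[i]
            elif cid in key_neg:
                factor = factor_loading[cid] * f_neg[i]
            level = base[j] + class_effect[(cultivar, cls)] + idio[i, j] + factor
            ln_mu[i, 0, j] = level + bias[0]
            ln_mu[i, 1, j] = level + bias[1]

    # -- replicate-level concentrations, dropout on non-key compounds ------
    rep_sd = float(config.replicate_cv)
    dropout = (rng.random((n_c, 2, len(ids))) < config.dropout_rate) & ~np.isin(
        ids, key_pos + key_neg
    )
    rows, index = [], []
    conc = np.empty((n_c, 2, config.n_replicates, len(ids)))
    for i, cultivar in enumerate(cultivars):
        for s, tissue in enumerate(("pulp", "skin")):
            for r in range(config.n_replicates):
                noise = rng.normal(0.0, rep_sd, size=len(ids))
                values = np.exp(ln_mu[i, s] + noise)
                values[dropout[i, s]] = 0.0
                conc[i, s, r] = values

    # -- liking scores from UV-scaled whole-berry cultivar means -----------
    f = config.skin_mass_fraction
    whole = f * conc[:, 1].mean(axis=1) + (1 - f) * conc[:, 0].mean(axis=1)
    mu = whole.mean(axis=0)
    sd = whole.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (whole - mu) / sd
    beta = pd.Series(0.0, index=ids)
    for cid in key_pos:
        beta[cid] = rng.uniform(0.7, 1.0)
    for cid in key_neg:
        beta[cid] = -rng.uniform(0.7, 1.0)
    # Balance the two key groups so liked and disliked volatiles contribute
    # comparable liking variance: preference is a trade-off, not a head count.
    raw_pos = z[:, [ids.index(c) for c in key_pos]] @ beta[key_pos].to_numpy()
    raw_neg = z[:, [ids.index(c) for c in key_neg]] @ beta[key_neg].to_numpy()
    if key_pos and key_neg and raw_neg.std(ddof=1) > 0:
        balance = raw_pos.std(ddof=1) / raw_neg.std(ddof=1)
        beta[key_neg] *= balance
    raw = z @ beta.to_numpy()
    # Center/scale on the scored block: its panel scores span the sensory
    # range by design, the unscored block inherits the same mapping.
    anchor = raw[:n_tr] if n_tr >= 3 else raw
    raw_sd = anchor.std(ddof=1)
    scale = config.liking_sd / raw_sd if raw_sd > 0 else 0.0
    y_lin = config.liking_center + scale * (raw - anchor.mean())
    beta_eff = beta * scale
    true_scores = np.clip(y_lin, 1.0, 5.0)
    observed = np.clip(y_lin + rng.normal(0.0, config.noise_sd, size=n_c), 1.0, 5.0)

    # -- y-orthogonal structured variation, added to X only -----------------
    loadings = np.zeros((config.n_orthogonal_factors, len(ids)))
    if config.n_orthogonal_factors > 0:
        yc = y_lin - y_lin.mean()
        g_prev: list[np.ndarray] = []
        for m in range(config.n_orthogonal_factors):
            g = rng.standard_normal(n_c)
            if yc @ yc > 0:
                g = g - (g @ yc) / (yc @ yc) * yc
            for gp in g_prev:
                g = g - (g @ gp) / (gp @ gp) * gp
            g_prev.append(g)
            u = rng.normal(0.0, 0.12, size=len(ids))
            loadings[m] = u
            conc *= np.exp(np.einsum("i,j->ij", g, u))[:, None, None, :]

    for i, cultivar in enumerate(cultivars):
        for s, tissue in enumerate(("pulp", "skin")):
            for r in range(config.n_replicates):
                index.append((cultivar, tissue, r + 1))
                rows.append(conc[i, s, r])

    data = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["cultivar_id", "tissue", "replicate"]),
        columns=ids,
    )
    maturity = pd.DataFrame(
        {
            "tss_brix": rng.uniform(16.5, 22.0, size=n_c),
            "ta_g_per_l": rng.uniform(2.0, 5.0, size=n_c),
            "ph": rng.uniform(3.0, 4.2, size=n_c),
            "berry_weight_g": rng.uniform(4.0, 12.0, size=n_c),
        },
        index=pd.Index(cultivars, name="cultivar_id"),
    )
    sset = SampleSet(data, panel, maturity)
    truth = GroundTruth(
        liking_coefficients=beta_eff,
        true_scores=pd.Series(true_scores, index=cultivars, name="true_score"),
        observed_scores=pd.Series(observed, index=cultivars, name="liking_score"),
        orthogonal_loadings=pd.DataFrame(loadings, columns=ids),
        key_positive=key_pos,
        key_negative=key_neg,
        train_cultivars=train,
        test_cultivars=test,
    )
    return sset, truth


def inject_outlier(sset: SampleSet, key: SampleKey, magnitude: float) -> SampleSet:
    """Return a copy of the sample set with one sample's concentrations
    multiplied by ``magnitude`` (a test fixture for outlier screening)."""
    if magnitude <= 0:
        raise ValidationError("magnitude must be > 0")
    tup = key.as_tuple()
    if tup not in sset.data.index:
        raise ReferenceError_(f"no such sample: {key}")
    data = sset.data.copy()
    data.loc[tup] = data.loc[tup] * magnitude
    return SampleSet(data, sset.library, sset.maturity)
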