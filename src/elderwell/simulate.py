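"""Synthetic elderly-wellbeing survey generator with known ground truth.

The generator emulates the structure the analysis pipeline assumes: ~300
respondents aged 65+, three ordinal wellbeing instruments (CASP-19 1-4,
Satisfaction with Life 1-7, WHO-5 1-6 reverse-keyed), demographic fields
with realistic marginals (most respondents retired, two children and primary
education modal, ~63% in good health), activity participation with exercise
the most common class and the library the most visited place, a 205:87
yes:no split on the learning-attitude question with 8 non-responses, and
linear covariate effects on wellbeing of the magnitudes the regression stage
is expected to recover.

Data-generating model, per respondent i and wellbeing domain h:

    W_hi = alpha_h + sum_c beta_hc x_ci + eps_hi,    eps ~ N(0, noise_sd_h)

W is squashed onto [0, 1] (identity-with-clipping by default, so planted
effects pass through undistorted; a logistic option exists), treated as the
respondent's target normalized response, and each item of the scale is drawn
by adding item-level noise, clipping to [0, 1], and inverse-mapping onto the
ordinal grid [m_j, M_j] honouring the item's orientation.  Because the index
of a constant response vector d = (w, ..., w) equals w, the latent effects
are, up to discretization noise, exactly the regression coefficients the
downstream OLS estimates.

All randomness flows from the single seed via one numpy Generator; identical
config + seed reproduce the table byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codebook as cb
from .codebook import CLASS_FLAGS, PLACE_FLAGS, Codebook, default_codebook

DOMAINS = ("quality", "satisfaction", "psychological")

#: latent effect per (covariate, domain): the magnitudes the regressions are
#: expected to print, in index units per predictor unit.
DEFAULT_EFFECTS: dict[str, tuple[float, float, float]] = {
    "learn_elderly": (0.0611, 0.0414, 0.0289),
    "class_total": (0.0491, 0.0739, 0.0802),
    "places_total": (0.00355, -0.00305, 0.000605),
    "disability": (-0.00879, 0.0989, 0.0137),
    "mobility": (-0.0197, -0.0601, -0.0501),
    "health_good": (0.0957, 0.108, 0.0972),
    "family_good": (0.0482, 0.128, 0.111),
    "friends_good": (0.0299, 0.0281, 0.0103),
    "retired_yes": (0.0160, 0.0844, 0.0658),
    "female": (-0.0259, -0.00938, 0.000197),
    "married": (0.0260, 0.0202, 0.0322),
    "secondary_more": (0.0173, -0.0620, -0.0485),
    "no_children": (0.00714, 0.00244, -0.000965),
}
DEFAULT_INTERCEPTS = (0.343, 0.293, 0.348)

#: demographic category probabilities; chosen so the implied counts at n=300
#: match the survey's reported profile (106 with 2 children, 103 primary
#: education, 228 retired, 189 in good or very good health, 43 with more
#: than secondary education, 205/87 yes/no learning attitudes).
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "marital": {"single": 0.10, "married": 0.62, "widowed": 0.22, "divorced": 0.06},
    "education": {
        "no formal": 0.15,
        "primary": 103 / 300,
        "secondary": 1 - 0.15 - 103 / 300 - 43 / 300,
        "post-secondary": 28 / 300,
        "tertiary": 15 / 300,
    },
    "work": {
        "working": 0.10,
        "part-time": 0.07,
        "ad-hoc": 0.03,
        "freelance": 0.02,
        "retired": 228 / 300,
        "unemployed": 1 - 0.22 - 228 / 300,
    },
    "gender": {"male": 0.45, "female": 0.55},
    "health": {"poor": 0.10, "fair": 1 - 0.10 - 189 / 300, "good": 126 / 300, "very good": 63 / 300},
    "disability": {"no": 0.94, "yes": 0.06},
    "mobility": {"no": 0.82, "yes": 0.18},
    "family_rel": {"poor": 0.05, "fair": 0.15, "good": 0.55, "excellent": 0.25},
    "friends_rel": {"poor": 0.05, "fair": 0.20, "good": 0.55, "excellent": 0.20},
    "learn_elderly": {"no": 87 / 292, "yes": 205 / 292},
}

#: P(number of children = k); mode at 2 (106 of 300 respondents).
DEFAULT_CHILD_DIST = {0: 0.10, 1: 0.20, 2: 106 / 300, 3: 0.197, 4: 1 - 0.10 - 0.20 - 106 / 300 - 0.197 - 0.05, 5: 0.05}

#: class-activity participation: count distribution 147/118/27 over answered
#: cases (two-or-more split 20/7), and relative popularity of each class with
#: exercise most frequent.
DEFAULT_CLASS_COUNTS = {0: 147 / 292, 1: 118 / 292, 2: 20 / 292, 3: 7 / 292}
DEFAULT_CLASS_WEIGHTS = {
    "class_exercise": 0.45,
    "class_singing": 0.25,
    "class_dancing": 0.10,
    "class_music": 0.08,
    "class_other": 0.12,
}
#: place visits: 225/52/15 over answered cases; library the most popular.
DEFAULT_PLACE_COUNTS = {0: 225 / 292, 1: 52 / 292, 2: 10 / 292, 3: 5 / 292}
DEFAULT_PLACE_WEIGHTS = {
    "place_library": 0.40,
    "place_gym": 0.12,
    "place_sports_club": 0.12,
    "place_museum": 0.12,
    "place_educational_institute": 0.12,
    "place_other": 0.12,
}


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic survey draw.

    ``effects`` maps covariate name to its latent effect per domain
    (quality, satisfaction, psychological), in index units; ``noise_sd`` is
    the per-domain residual scale and ``item_noise_sd`` the per-item scale,
    both on the unit interval.  ``squash`` is ``identity`` (clip to [0, 1];
    default, so effects pass through undistorted) or ``logistic``.
    """

    n: int = 300
    seed: int = 0
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    intercepts: tuple[float, float, float] = DEFAULT_INTERCEPTS
    noise_sd: tuple[float, float, float] = (0.13, 0.17, 0.19)
    shared_resid_frac: float = 0.5
    item_noise_sd: float = 0.12
    missing_learn: int = 8
    squash: str = "identity"
    marginals: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()})
    child_dist: dict = field(default_factory=lambda: dict(DEFAULT_CHILD_DIST))
    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    class_weights: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    place_counts: dict = field(default_factory=lambda: dict(DEFAULT_PLACE_COUNTS))
    place_weights: dict = field(default_factory=lambda: dict(DEFAULT_PLACE_WEIGHTS))

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if any(s <= 0 for s in self.noise_sd) or self.item_noise_sd <= 0:
            raise ConfigError("noise scales must be > 0")
        if not 0 <= self.shared_resid_frac <= 1:
            raise ConfigError("shared_resid_frac must lie in [0, 1]")
        if not 0 <= self.missing_learn <= self.n:
            raise ConfigError("missing_learn must lie in [0, n]")
        if self.squash not in ("identity", "logistic"):
            raise ConfigError(f"unknown squash {self.squash!r}")
        unknown = set(self.effects) - set(DEFAULT_EFFECTS)
        if unknown:
            raise ConfigError(f"effect(s) for unknown covariate(s): {sorted(unknown)}")
        for fld, probs in self.marginals.items():
            tot = sum(probs.values())
            if abs(tot - 1.0) > 1e-8:
                raise ConfigError(f"marginals for {fld!r} sum to {tot}, not 1")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    W: pd.DataFrame           # latent wellbeing per domain, after squash
    design: pd.DataFrame      # realized numeric covariates (regression coding)
    effects: dict             # effect vectors used
    intercepts: tuple


def _draw_cat(rng: np.random.Generator, probs: dict[str, float], n: int) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[l] for l in levels], dtype=float)
    return rng.choice(levels, size=n, p=p / p.sum())


def _draw_activities(
    rng: np.random.Generator, n: int, counts: dict, weights: dict
) -> pd.DataFrame:
    """Per-respondent activity flags: draw how many, then which ones,
    weighted by popularity, without replacement."""
    ks = np.array(list(counts), dtype=int)
    pk = np.array([counts[k] for k in ks], dtype=float)
    n_acts = rng.choice(ks, size=n, p=pk / pk.sum())
    names = list(weights)
    w = np.array([weights[a] for a in names], dtype=float)
    w = w / w.sum()
    flags = np.zeros((n, len(names)))
    for i, k in enumerate(n_acts):
        if k > 0:
            chosen = rng.choice(len(names), size=min(k, len(names)), replace=False, p=w)
            flags[i, chosen] = 1.0
    return pd.DataFrame(flags, columns=names)


def _squash(W: np.ndarray, kind: str) -> np.ndarray:
    if kind == "identity":
        return np.clip(W, 0.0, 1.0)
    return 1.0 / (1.0 + np.exp(-(W - 0.5) * 4.0))   # gentle logistic centred at 0.5


def generate_survey(
    config: GeneratorConfig | None = None, codebook: Codebook | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one synthetic survey table plus its ground truth.

    Returns a table matching the default codebook schema (items numeric,
    learning attitude blank for exactly ``missing_learn`` respondents) and a
    :class:`GroundTruth` with the latent wellbeing and the realized design.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    book = codebook or default_codebook()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    tbl = pd.DataFrame({"respondent_id": [f"R{i + 1:04d}" for i in range(n)]})
    for fld in ("marital", "education", "work", "gender", "health",
                "disability", "mobility", "family_rel", "friends_rel", "learn_elderly"):
        tbl[fld] = _draw_cat(rng, cfg.marginals[fld], n)
    kids_levels = np.array(list(cfg.child_dist), dtype=int)
    kids_p = np.array(list(cfg.child_dist.values()), dtype=float)
    tbl["no_children"] = rng.choice(kids_levels, size=n, p=kids_p / kids_p.sum()).astype(float)

    classes = _draw_activities(rng, n, cfg.class_counts, cfg.class_weights)
    places = _draw_activities(rng, n, cfg.place_counts, cfg.place_weights)
    for c in CLASS_FLAGS:
        tbl[c] = classes[c].to_numpy()
    for c in PLACE_FLAGS:
        tbl[c] = places[c].to_numpy()

    # regression-coded design (before any missingness is applied)
    design = pd.DataFrame(
        {
            "learn_elderly": (tbl["learn_elderly"] == "yes").astype(float),
            "class_total": classes.sum(axis=1),
            "places_total": places.sum(axis=1),
            "disability": (tbl["disability"] == "yes").astype(float),
            "mobility": (tbl["mobility"] == "yes").astype(float),
            "health_good": tbl["health"].isin(("good", "very good")).astype(float),
            "family_good": tbl["family_rel"].isin(("good", "excellent")).astype(float),
            "friends_good": tbl["friends_rel"].isin(("good", "excellent")).astype(float),
            "retired_yes": (tbl["work"] == "retired").astype(float),
            "female": (tbl["gender"] == "female").astype(float),
            "married": (tbl["marital"] == "married").astype(float),
            "secondary_more": tbl["education"].isin(("post-secondary", "tertiary")).astype(float),
            "no_children": tbl["no_children"].astype(float),
        }
    )

    # residuals share a common person-level wellbeing factor so the three
    # indices correlate beyond what the covariates induce
    f = cfg.shared_resid_frac
    common = rng.normal(0.0, 1.0, size=n)
    W = np.zeros((n, 3))
    for h in range(3):
        mu = np.full(n, cfg.intercepts[h])
        for cov, eff in cfg.effects.items():
            mu += eff[h] * design[cov].to_numpy()
        own = rng.normal(0.0, 1.0, size=n)
        resid = cfg.noise_sd[h] * (np.sqrt(f) * common + np.sqrt(1.0 - f) * own)
        W[:, h] = mu + resid
    W = _squash(W, cfg.squash)

    # item responses: target mean d = W_h, plus item noise, onto the grid
    for scale_id, h in zip(("quality", "satisfaction", "psychological"), range(3)):
        scale = book.scales[scale_id]
        noise = rng.normal(0.0, cfg.item_noise_sd, size=(n, scale.k))
        d = np.clip(W[:, [h]] + noise, 0.0, 1.0)
        for j, item in enumerate(scale.items):
            m, M = scale.m[j], scale.M[j]
            steps = np.rint(d[:, j] * (M - m))
            if scale.orientation[j] == cb.HIGHER_IS_BETTER:
                tbl[item] = m + steps
            else:
                tbl[item] = M - steps

    if cfg.missing_learn:
        blank = rng.choice(n, size=cfg.missing_learn, replace=False)
        tbl.loc[blank, "learn_elderly"] = np.nan
    tbl["learn_elderly"] = pd.Categorical(tbl["learn_elderly"], categories=["no", "yes"])
    for fld in ("marital", "education", "work", "gender", "health",
                "family_rel", "friends_rel"):
        tbl[fld] = pd.Categorical(tbl[fld], categories=book.fields[fld].levels)
    for fld in ("disability", "mobility"):
        tbl[fld] = (tbl[fld] == "yes").astype(float)

    truth = GroundTruth(
        W=pd.DataFrame(W, columns=list(DOMAINS)),
        design=design,
        effects=dict(cfg.effects),
        intercepts=tuple(cfg.intercepts),
    )
    return tbl, truth


# -- fixtures ----------------------------------------------------------------

def _allbest4() -> pd.DataFrame:
    """Four respondents answering every item at its best level."""
    book = default_codebook()
    tbl = pd.DataFrame({"respondent_id": [f"B{i}" for i in range(1, 5)]})
    for scale in book.scales.values():
        for j, item in enumerate(scale.items):
            best = scale.M[j] if scale.orientation[j] == cb.HIGHER_IS_BETTER else scale.m[j]
            tbl[item] = float(best)
    tbl["marital"] = pd.Categorical(["married"] * 4, categories=cb.MARITAL_LEVELS)
    tbl["no_children"] = 2.0
    tbl["education"] = pd.Categorical(["primary"] * 4, categories=cb.EDUCATION_LEVELS)
    tbl["work"] = pd.Categorical(["retired"] * 4, categories=cb.WORK_LEVELS)
    tbl["gender"] = pd.Categorical(["female", "male", "female", "male"], categories=("male", "female"))
    tbl["health"] = pd.Categorical(["good"] * 4, categories=cb.HEALTH_LEVELS)
    tbl["disability"] = 0.0
    tbl["mobility"] = 0.0
    tbl["family_rel"] = pd.Categorical(["good"] * 4, categories=cb.REL_LEVELS)
    tbl["friends_rel"] = pd.Categorical(["good"] * 4, categories=cb.REL_LEVELS)
    tbl["learn_elderly"] = pd.Categorical(["yes", "yes", "no", "no"], categories=cb.YESNO)
    for f in CLASS_FLAGS + PLACE_FLAGS:
        tbl[f] = 0.0
    tbl["class_exercise"] = 1.0
    return tbl


FIXTURES = {
    "tiny8": lambda: generate_survey(GeneratorConfig(n=8, seed=82, missing_learn=0))[0],
    "paper_like_300": lambda: generate_survey(GeneratorConfig(n=300, seed=300, missing_learn=8))[0],
    "allbest4": _allbest4,
}


def make_fixture(name: str) -> pd.DataFrame:
    """Deterministic named tables used across the test suite."""
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    return factory()
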