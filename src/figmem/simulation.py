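"""Synthetic persons, responses and study-like datasets.

The generative model is exactly the one the estimators assume: log-abilities
``theta_v ~ N(0, person_sd^2)`` and counts
``Y_vi ~ Poisson(exp(theta_v + log_easiness_i))`` (or mean-parameterised CMP
when ``dispersion_nu != 1``), optionally right-censored at the maximum item
score -- real tests cannot score above the number of presented units, and
censoring is one candidate mechanism for the underdispersion such data show.

``synthesize_study`` emulates the reference pilot-study design: 208 persons,
9 items in 3 visual-load families with counts-scale family easiness
(10.80, 9.08, 7.12), small within-family log-easiness jitter, person SD
0.229 on the log scale, three presentation-order condition groups of sizes
63/76/69, scores censored at 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cmp import cmp_pmf_table
from .data import ResponseMatrix

__all__ = [
    "SimConfig",
    "BlockDesign",
    "simulate_responses",
    "synthesize_study",
    "make_block_design",
    "STUDY_FAMILY_EASINESS",
    "STUDY_PERSON_SD",
    "STUDY_GROUP_SIZES",
]

#: counts-scale expected score per visual-load family for an average person
STUDY_FAMILY_EASINESS = (10.80, 9.08, 7.12)
#: SD of the log-ability random intercept
STUDY_PERSON_SD = 0.229
#: presentation-order condition group sizes (sum = 208)
STUDY_GROUP_SIZES = (63, 76, 69)
#: within-family log-easiness jitter emulating incidental difficulty variation
STUDY_JITTER_SD = 0.04


@dataclass
class SimConfig:
    """Configuration of one simulated dataset."""

    n_persons: int
    item_log_easiness: np.ndarray  # (I,) log-scale easiness sigma~_i
    person_sd: float = STUDY_PERSON_SD
    radical_levels: np.ndarray | None = None
    incidental_ids: np.ndarray | None = None
    dispersion_nu: float = 1.0  # 1 = Poisson; > 1 underdispersed CMP
    censor_at_max: bool = False
    max_score: int = 20
    seed: int = 0

    def __post_init__(self):
        self.item_log_easiness = np.asarray(self.item_log_easiness, dtype=float)
        if not np.all(np.isfinite(self.item_log_easiness)):
            raise ValueError("item_log_easiness must be finite")
        if self.person_sd < 0:
            raise ValueError("person_sd must be >= 0")
        if self.max_score < 1:
            raise ValueError("max_score must be >= 1")
        if self.dispersion_nu <= 0:
            raise ValueError("dispersion_nu must be > 0")
        I = len(self.item_log_easiness)
        if self.radical_levels is None:
            self.radical_levels = np.ones(I, dtype=int)
        if self.incidental_ids is None:
            counts: dict = {}
            ids = []
            for lev in self.radical_levels:
                counts[lev] = counts.get(lev, 0) + 1
                ids.append(counts[lev])
            self.incidental_ids = np.asarray(ids)


def _sample_cmp(rng: np.random.Generator, mu: np.ndarray, nu: float) -> np.ndarray:
    """Inverse-cdf sampling from the mean-parameterised CMP, elementwise."""
    flat = mu.reshape(-1)
    out = np.empty(flat.shape, dtype=np.int64)
    u = rng.random(flat.shape)
    for k, m in enumerate(flat):
        pmf = cmp_pmf_table(float(m), nu)
        out[k] = int(np.searchsorted(np.cumsum(pmf), u[k]))
    return out.reshape(mu.shape)


def simulate_responses(cfg: SimConfig):
    """Draw one dataset; returns ``(ResponseMatrix, truth dict)``.

    The truth dict carries the drawn person effects and the generating
    parameters for recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    theta = cfg.person_sd * rng.standard_normal(cfg.n_persons)
    mu = np.exp(theta[:, None] + cfg.item_log_easiness[None, :])
    if cfg.dispersion_nu == 1.0:
        y = rng.poisson(mu)
    else:
        y = _sample_cmp(rng, mu, cfg.dispersion_nu)
    if cfg.censor_at_max:
        y = np.minimum(y, cfg.max_score)
        max_score = cfg.max_score
    else:
        # uncensored model-exact draws may exceed the nominal bound; widen the
        # container's declared range instead of truncating them
        max_score = max(cfg.max_score, int(y.max(initial=0)))
    data = ResponseMatrix(
        scores=y.astype(np.int64),
        radical_levels=cfg.radical_levels,
        incidental_ids=cfg.incidental_ids,
        max_score=max_score,
    )
    truth = {
        "theta_log": theta,
        "person_sd": cfg.person_sd,
        "item_log_easiness": cfg.item_log_easiness.copy(),
        "dispersion_nu": cfg.dispersion_nu,
    }
    return data, truth


def study_config(
    seed: int,
    jitter_sd: float = STUDY_JITTER_SD,
    censor_at_max: bool = True,
    dispersion_nu: float = 1.0,
) -> SimConfig:
    """Study-like configuration: 208 persons, 3 families x 3 incidentals."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 104729]))
    eta = np.log(np.asarray(STUDY_FAMILY_EASINESS))
    levels = np.repeat([1, 2, 3], 3)
    log_eps = eta[levels - 1] + jitter_sd * rng.standard_normal(9)
    return SimConfig(
        n_persons=int(np.sum(STUDY_GROUP_SIZES)),
        item_log_easiness=log_eps,
        person_sd=STUDY_PERSON_SD,
        radical_levels=levels,
        incidental_ids=np.tile([1, 2, 3], 3),
        dispersion_nu=dispersion_nu,
        censor_at_max=censor_at_max,
        max_score=20,
        seed=int(seed),
    )


def synthesize_study(seed: int, jitter_sd: float = STUDY_JITTER_SD) -> ResponseMatrix:
    """One full synthetic pilot-study dataset (208 x 9, grouped, censored)."""
    cfg = study_config(seed, jitter_sd=jitter_sd, censor_at_max=True)
    data, _ = simulate_responses(cfg)
    data.groups = np.repeat([1, 2, 3], STUDY_GROUP_SIZES)
    return data


# --- presentation-order design -------------------------------------------------


@dataclass(frozen=True)
class BlockDesign:
    """Latin-square-oriented presentation order of the nine study items.

    ``blocks[c][b]`` lists the ``(radical_level_letter, incidental_id)`` pairs
    of block ``b`` (0-based) in presentation order for condition ``c``.
    """

    n_conditions: int
    blocks: tuple


def make_block_design(n_conditions: int = 3) -> BlockDesign:
    """The three-condition design: block 1 in increasing difficulty for every
    condition (warm-up); within blocks 2 and 3 the three load levels are
    rotated so that each level appears once at every position across
    conditions."""
    if n_conditions != 3:
        raise ValueError("only the 3-condition design is supported")
    levels = ("L", "M", "H")

    def rotate(seq, k):
        return tuple(seq[(j + k) % 3] for j in range(3))

    conditions = []
    for c in range(3):
        block1 = tuple((lev, 1) for lev in levels)  # increasing difficulty
        block2 = tuple((lev, 2) for lev in rotate(levels, c))
        block3 = tuple((lev, 3) for lev in rotate(levels, 2 * c))
        conditions.append((block1, block2, block3))
    return BlockDesign(n_conditions=3, blocks=tuple(conditions))
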