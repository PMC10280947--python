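"""Simulated odds ratios (sOR) for clinical patient profiles.

A trained classifier is interrogated with Monte-Carlo patient profiles: the
features that define a clinical condition are held fixed (age may be fixed
as a Gaussian, e.g. mean 45, SD 5), every other feature is drawn at random,
and the "risk" of a profile is the fraction of S simulated patients the
model classifies as needing more than one tele-visit.  Each risk is
replicated R times; per replicate the target and reference odds are
compared, giving R sOR samples whose mean is the point estimate and whose
2.5/97.5 percentiles form a 95% credibility interval.

Free features are drawn from the cohort generator's calibrated margins by
default (tumour site conditional on gender, so profiles stay clinically
plausible); a uniform-over-levels mode is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SITES, GENDERS, AGE_MIN, AGE_MAX, CohortSpec
from scipy.stats import truncnorm

FEATURES = ("age", "ecog", "gender", "site", "bone_mets", "btcp", "neuropathic", "med_gt60")
_BINARY = ("bone_mets", "btcp", "neuropathic", "med_gt60")


@dataclass
class ProfileSpec:
    """A clinical profile: fixed feature assignments, the rest free.

    ``fixed`` maps feature names to values; ``age_gauss`` optionally fixes
    age as (mean, sd) of a Gaussian truncated to the clinical age range.
    """

    fixed: dict = field(default_factory=dict)
    age_gauss: tuple | None = None

    @property
    def free(self) -> frozenset:
        fixed = set(self.fixed)
        if self.age_gauss is not None:
            fixed.add("age")
        return frozenset(FEATURES) - fixed


@dataclass
class SORConfig:
    S: int = 200  # simulated patients per profile per replicate
    R: int = 300  # replicates
    seed: int = 0
    eps: float | None = None  # continuity correction; default 0.5/S

    def __post_init__(self):
        if self.S < 1 or self.R < 1:
            raise ValueError("S and R must be at least 1")
        if self.eps is None:
            self.eps = 0.5 / self.S


@dataclass
class SORResult:
    samples: np.ndarray  # replicate-level sORs, length R
    risks_target: np.ndarray
    risks_reference: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def median(self) -> float:
        return float(np.median(self.samples))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.percentile(self.samples, 2.5)),
            float(np.percentile(self.samples, 97.5)),
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(len(self.samples)),
                "risk_target": self.risks_target,
                "risk_reference": self.risks_reference,
                "sor": self.samples,
            }
        )


def odds(p: float, eps: float = 0.0025) -> float:
    """p/(1-p) with a Haldane-style continuity correction at the boundary."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p == 0.0:
        p = eps
    elif p == 1.0:
        p = 1.0 - eps
    return p / (1.0 - p)


def sample_profiles(
    profile: ProfileSpec,
    spec: CohortSpec,
    n: int,
    rng: np.random.Generator,
    mode: str = "margins",
) -> pd.DataFrame:
    """Draw ``n`` feature rows for a profile.

    Free features come from the cohort spec's margins (``mode='margins'``)
    or uniformly over their levels (``mode='uniform'``); site is always
    sampled conditional on gender so the gender-consistency contract holds.
    """
    if mode not in ("margins", "uniform"):
        raise ValueError("mode must be 'margins' or 'uniform'")
    fx = profile.fixed
    out = {}

    # gender first (site depends on it); a fixed site can force gender
    if "gender" in fx:
        gender = np.full(n, fx["gender"], dtype=object)
    elif fx.get("site") == "prostate":
        gender = np.full(n, "male", dtype=object)
    elif fx.get("site") in ("gynecological", "breast"):
        gender = np.full(n, "female", dtype=object)
    else:
        p_f = spec.gender_split if mode == "margins" else 0.5
        gender = np.where(rng.random(n) < p_f, "female", "male")

    if "site" in fx:
        site = np.full(n, fx["site"], dtype=object)
    else:
        site = np.empty(n, dtype=object)
        for g in GENDERS:
            mask = gender == g
            if not mask.any():
                continue
            table = spec.site_table[g]
            sites = [s for s in table if table[s] > 0]
            if mode == "margins":
                probs = np.array([table[s] for s in sites])
                probs = probs / probs.sum()
            else:
                probs = np.full(len(sites), 1.0 / len(sites))
            site[mask] = rng.choice(sites, size=int(mask.sum()), p=probs)

    if profile.age_gauss is not None:
        mu, sd = profile.age_gauss
        a, b = (AGE_MIN - mu) / sd, (AGE_MAX - mu) / sd
        age = truncnorm.rvs(a, b, mu, sd, size=n, random_state=rng)
    elif "age" in fx:
        age = np.full(n, float(fx["age"]))
    elif mode == "margins":
        a, b = (AGE_MIN - spec.age_mean) / spec.age_sd, (AGE_MAX - spec.age_mean) / spec.age_sd
        age = truncnorm.rvs(a, b, spec.age_mean, spec.age_sd, size=n, random_state=rng)
    else:
        age = rng.integers(AGE_MIN, AGE_MAX + 1, size=n).astype(float)
    out["age"] = np.clip(np.rint(age), AGE_MIN, AGE_MAX).astype(int)

    for var in _BINARY:
        if var in fx:
            out[var] = np.full(n, int(fx[var]))
        else:
            p = spec.prevalences[var] if mode == "margins" else 0.5
            out[var] = (rng.random(n) < p).astype(int)

    if "ecog" in fx:
        out["ecog"] = np.full(n, int(fx["ecog"]))
    else:
        p = list(spec.ecog_dist) if mode == "margins" else [0.2] * 5
        out["ecog"] = rng.choice(5, size=n, p=p)

    out["gender"] = gender
    out["site"] = site
    return pd.DataFrame(out)[list(FEATURES)]


def _classify(model, X: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Simulated classification of each patient: the predicted label is drawn
    from the model's class probability, so a patient the model scores at 0.7
    is classified 'more' in 70% of simulations.  Models without probability
    outputs fall back to their hard labels."""
    if hasattr(model, "predict_proba_more"):
        p = np.asarray(model.predict_proba_more(X), float)
        return (rng.random(len(p)) < p).astype(int)
    return (np.asarray(model.predict(X)) == 1).astype(int)


def simulate_profile(model, profile: ProfileSpec, spec: CohortSpec, S: int, rng, mode="margins") -> float:
    """Risk of a profile: fraction of S simulated patients classified 'more'."""
    X = sample_profiles(profile, spec, S, rng, mode=mode)
    return float(np.mean(_classify(model, X, rng)))


def compute_sor(
    model,
    target: ProfileSpec,
    reference: ProfileSpec,
    spec: CohortSpec,
    config: SORConfig | None = None,
    mode: str = "margins",
) -> SORResult:
    """Replicated simulated odds ratio of target vs reference profiles.

    For each of R replicates the risk of each profile is estimated from S
    fresh simulated patients and the replicate sOR is
    odds(risk_target)/odds(risk_reference).  Classification is batched over
    all S x R patients per profile, which is equivalent to per-replicate
    simulation and much faster for forest models.
    """
    config = config or SORConfig()
    if target.free != reference.free:
        raise ValueError("target and reference profiles must share the same free features")
    rng = np.random.default_rng(config.seed)
    S, R = config.S, config.R

    Xt = sample_profiles(target, spec, S * R, rng, mode=mode)
    Xr = sample_profiles(reference, spec, S * R, rng, mode=mode)
    pt = _classify(model, Xt, rng).reshape(R, S).mean(axis=1)
    pr = _classify(model, Xr, rng).reshape(R, S).mean(axis=1)
    sors = np.array(
        [odds(t, config.eps) / odds(r, config.eps) for t, r in zip(pt, pr)]
    )
    return SORResult(samples=sors, risks_target=pt, risks_reference=pr)


def condition_presets() -> list[tuple[str, ProfileSpec, ProfileSpec]]:
    """The four standard clinical comparisons.

    - ``age``: older patients (Gaussian age mean 75, SD 5) vs younger
      (mean 45, SD 5); the reported sOR (0.3) is odds(older)/odds(younger)
    - ``btcp``: breakthrough cancer pain present vs absent
    - ``neuropathic``: neuropathic pain present vs absent
    - ``btcp_neuro``: both pain conditions vs neither
    """
    return [
        ("age", ProfileSpec(age_gauss=(75, 5)), ProfileSpec(age_gauss=(45, 5))),
        ("btcp", ProfileSpec(fixed={"btcp": 1}), ProfileSpec(fixed={"btcp": 0})),
        ("neuropathic", ProfileSpec(fixed={"neuropathic": 1}), ProfileSpec(fixed={"neuropathic": 0})),
        (
            "btcp_neuro",
            ProfileSpec(fixed={"btcp": 1, "neuropathic": 1}),
            ProfileSpec(fixed={"btcp": 0, "neuropathic": 0}),
        ),
    ]


def risk_by_age(model, ages, spec: CohortSpec, S: int = 200, rng=None, mode="margins") -> pd.DataFrame:
    """Risk curve over an age grid: one simulated risk per age point with age
    fixed at the point and everything else free."""
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    for a in ages:
        risk = simulate_profile(model, ProfileSpec(fixed={"age": int(a)}), spec, S, rng, mode=mode)
        rows.append({"age": int(a), "risk": risk})
    return pd.DataFrame(rows)
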