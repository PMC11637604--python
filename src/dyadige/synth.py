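"""Synthetic mating-trial data with heritable direct and indirect effects.

This generator reproduces the statistical structure the analysis assumes —
not the behaviour of real crickets.  Breeding values flow down a pedigree
(founders i.i.d. multivariate normal, offspring = mid-parent + Mendelian
deviation), dyadic trials combine the focal individual's direct effects with
the partner's indirect effects plus permanent-environment and residual
noise, and morphology is generated as repeated (body mass) or once-measured
(mandible, testis) traits.

All behavioural traits are generated directly on the z-score scale: the
analysis operates on z-transformed trait scores, so the generative scale is
the analysis scale and no raw-latency back-transformation exists here.

Trait schema
------------
* ``lat_sing``  — male latency to sing (male-expressed, dyadic)
* ``lat_mount`` — female latency to mount (female-expressed, dyadic)
* ``guard_dist``— post-copulatory guarding distance (male-expressed, dyadic)
* ``male_mass``, ``female_mass`` — body mass, repeated per trial
* ``mandible``, ``testis`` — male morphology, measured once

Genetic channels are (trait, role) pairs with role ``direct`` (own genotype)
or ``indirect`` (partner genotype); morphology has no indirect channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import (
    MALE,
    Pedigree,
    build_half_sib_design,
    mendelian_variance,
    relationship_matrix,
)

DIRECT = "direct"
INDIRECT = "indirect"

#: dyadic traits by expresser sex
DYADIC_TRAITS = {"lat_sing": "male", "lat_mount": "female", "guard_dist": "male"}
#: repeated morphology (measured at every trial of the expresser)
REPEATED_TRAITS = {"male_mass": "male", "female_mass": "female"}
#: once-measured morphology (males only in this design)
ONCE_TRAITS = {"mandible": "male", "testis": "male"}
ALL_TRAITS = {**DYADIC_TRAITS, **REPEATED_TRAITS, **ONCE_TRAITS}

TRIAL_COLUMNS = [
    "male_id", "female_id", "order", "shelf",
    "lat_sing", "lat_mount", "guard_dist", "male_mass", "female_mass",
]

__all__ = [
    "DIRECT",
    "INDIRECT",
    "Channel",
    "ChannelSet",
    "GeneticCovariance",
    "EnvironmentConfig",
    "AssayDesign",
    "DesignInfeasibleError",
    "sample_breeding_values",
    "simulate_trials",
    "paper_scale_preset",
    "scaled_preset",
    "preset_to_dict",
    "preset_from_dict",
    "apply_preset_overrides",
    "simulate_study",
    "DYADIC_TRAITS",
    "REPEATED_TRAITS",
    "ONCE_TRAITS",
    "TRIAL_COLUMNS",
]


@dataclass(frozen=True, order=True)
class Channel:
    """One genetic channel: a trait and the role of the genotype behind it."""

    trait: str
    role: str  # DIRECT or INDIRECT

    def __post_init__(self):
        if self.role not in (DIRECT, INDIRECT):
            raise ValueError(f"role must be {DIRECT!r} or {INDIRECT!r}")
        if self.trait not in ALL_TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.role == INDIRECT and self.trait not in DYADIC_TRAITS:
            raise ValueError(f"{self.trait!r} is not dyadic: no indirect channel")

    @property
    def label(self) -> str:
        return f"{self.trait}:{self.role}"

    @property
    def expresser_sex(self) -> str:
        """Sex of the individual whose genotype feeds this channel."""
        sex = ALL_TRAITS[self.trait]
        if self.role == DIRECT:
            return sex
        return "female" if sex == "male" else "male"


class ChannelSet(Sequence):
    """Ordered, unique collection of genetic channels."""

    def __init__(self, channels: Iterable[Channel]):
        chans = list(channels)
        if len(set(chans)) != len(chans):
            raise ValueError("duplicate channels")
        self._channels = chans
        self._pos = {c: k for k, c in enumerate(chans)}

    def __len__(self):
        return len(self._channels)

    def __getitem__(self, k):
        return self._channels[k]

    def __iter__(self):
        return iter(self._channels)

    def __contains__(self, c):
        return c in self._pos

    def __eq__(self, other):
        return isinstance(other, ChannelSet) and self._channels == other._channels

    def position(self, c: Channel) -> int:
        return self._pos[c]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self._channels]


class GeneticCovariance:
    """Additive genetic (co)variance matrix over a set of channels.

    Validated at construction: symmetric, PSD (smallest eigenvalue
    >= -1e-10 relative to scale), non-negative diagonal.
    """

    def __init__(self, channels: ChannelSet, G0: np.ndarray):
        G0 = np.asarray(G0, dtype=float)
        q = len(channels)
        if G0.shape != (q, q):
            raise ValueError(f"G0 must be {q}x{q}")
        if not np.allclose(G0, G0.T, atol=1e-12):
            raise ValueError("G0 must be symmetric")
        if np.any(np.diag(G0) < 0):
            raise ValueError("G0 diagonal must be non-negative")
        if q:
            scale = max(1.0, float(np.abs(G0).max()))
            if np.linalg.eigvalsh(G0).min() < -1e-10 * scale:
                raise ValueError("G0 is not positive semidefinite")
        self.channels = channels if isinstance(channels, ChannelSet) else ChannelSet(channels)
        self.G0 = 0.5 * (G0 + G0.T)

    def value(self, ci: Channel, cj: Channel) -> float:
        return float(self.G0[self.channels.position(ci), self.channels.position(cj)])

    def submatrix(self, channels: Sequence[Channel]) -> "GeneticCovariance":
        idx = [self.channels.position(c) for c in channels]
        return GeneticCovariance(ChannelSet(channels), self.G0[np.ix_(idx, idx)])

    @classmethod
    def from_entries(
        cls,
        channels: Sequence[Channel],
        variances: Mapping[Channel, float],
        covariances: Mapping[tuple[Channel, Channel], float] | None = None,
    ) -> "GeneticCovariance":
        cs = ChannelSet(channels)
        G = np.zeros((len(cs), len(cs)))
        for c, v in variances.items():
            G[cs.position(c), cs.position(c)] = v
        for (ci, cj), v in (covariances or {}).items():
            i, j = cs.position(ci), cs.position(cj)
            G[i, j] = G[j, i] = v
        return cls(cs, G)


@dataclass
class EnvironmentConfig:
    """Non-genetic parts of the generative model.

    ``pe_variance`` maps channels to permanent-environment variances (the
    repeatable non-genetic individual effect attached to the same individual
    as the channel's genotype); ``residual_variance`` maps traits to V_R;
    the ``beta_*`` fields are fixed-effect coefficients applied to dyadic
    behavioural traits (intercept, testing-order slope, upper-shelf
    contrast) and ``intercept`` also to morphology.
    """

    pe_variance: dict[Channel, float] = field(default_factory=dict)
    residual_variance: dict[str, float] = field(default_factory=dict)
    intercept: dict[str, float] = field(default_factory=dict)
    beta_order: dict[str, float] = field(default_factory=dict)
    beta_shelf: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for c, v in self.pe_variance.items():
            if v < 0:
                raise ValueError(f"negative PE variance for {c.label}")
            if c.trait in ONCE_TRAITS:
                raise ValueError(f"{c.trait!r} is measured once: no PE channel")
        for t, v in self.residual_variance.items():
            if v < 0:
                raise ValueError(f"negative residual variance for {t}")


@dataclass
class AssayDesign:
    """Mating-trial bookkeeping: who meets whom, how often.

    Each phenotyped male runs 1-3 trials (one per day, order 1, 2, 3) with a
    randomly drawn female partner; females are drawn without replacement
    until the pool is exhausted, after which reuse is allowed (matching a
    design where slightly more assays exist than distinct females).  Shelf
    (lower/upper) is assigned at random per trial.
    """

    target_assays: int | None = None
    n_males: int | None = None
    max_trials_per_male: int = 3
    allow_female_reuse: bool = True

    def __post_init__(self):
        if not (1 <= self.max_trials_per_male <= 3):
            raise ValueError("max_trials_per_male must be in 1..3")


class DesignInfeasibleError(ValueError):
    """The assay design demands more distinct females than the pedigree supplies."""


def _genetic_factor(G0: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix via eigendecomposition (handles singular G0)."""
    if G0.size == 0:
        return G0
    w, U = np.linalg.eigh(G0)
    return U * np.sqrt(np.clip(w, 0.0, None))


def sample_breeding_values(
    ped: Pedigree, g: GeneticCovariance, seed: int
) -> pd.DataFrame:
    """Draw additive breeding values for every individual and channel.

    Founders are i.i.d. MVN(0, G0).  An offspring's vector is the mid-parent
    average plus a Mendelian deviation ~ MVN(0, d_i * G0) where
    ``d_i = 0.5 - 0.25 (F_sire + F_dam)`` (unknown parents raise d_i toward 1
    and contribute 0 to the mean).  Deterministic given ``seed``.

    Returns a DataFrame indexed by individual id with one column per channel
    label.
    """
    rng = np.random.default_rng(seed)
    q = len(g.channels)
    L = _genetic_factor(g.G0)
    d = mendelian_variance(ped)
    n = len(ped)
    bv = np.zeros((n, q))
    z = rng.standard_normal((n, q))
    for i in range(n):
        mean = np.zeros(q)
        s, t = ped.sire_idx[i], ped.dam_idx[i]
        if s >= 0:
            mean += 0.5 * bv[s]
        if t >= 0:
            mean += 0.5 * bv[t]
        bv[i] = mean + np.sqrt(d[i]) * (L @ z[i])
    return pd.DataFrame(bv, index=pd.Index(ped.ids, name="id"), columns=g.channels.labels)


def _pe_table(
    ped: Pedigree, env: EnvironmentConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Permanent-environment values, drawn once per individual per channel."""
    cols = {}
    for c in sorted(env.pe_variance, key=lambda c: c.label):
        v = env.pe_variance[c]
        cols[c.label] = np.sqrt(v) * rng.standard_normal(len(ped))
    return pd.DataFrame(cols, index=pd.Index(ped.ids, name="id"))


def simulate_trials(
    ped: Pedigree,
    bv: pd.DataFrame,
    env: EnvironmentConfig,
    design: AssayDesign,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the dyadic mating trials and morphology measurements.

    For a male-expressed dyadic trait in the trial of male ``m`` with female
    ``f``::

        y = b0 + b_order*order + b_shelf*[shelf=upper]
            + a_direct(m) + a_indirect(f) + pe_direct(m) + pe_indirect(f) + e

    with roles swapped for female-expressed traits; body mass per trial is
    ``mu + a_direct + pe + e`` for the individual on that trial; mandible and
    testis are measured once per male with no permanent-environment term.

    Returns ``(trials, morphology)`` tables; see :data:`TRIAL_COLUMNS` and
    the morphology schema ``id,trait,value,occasion``.
    """
    rng = np.random.default_rng(seed)
    males = [i for i, f in zip(ped.ids, ped.is_founder) if not f and ped.sex[ped.index[i]] == MALE]
    females = [i for i, f in zip(ped.ids, ped.is_founder) if not f and ped.sex[ped.index[i]] != MALE]
    if not males or not females:
        raise DesignInfeasibleError("pedigree supplies no phenotypable males or females")

    if design.n_males is not None and design.n_males < len(males):
        keep = rng.choice(len(males), size=design.n_males, replace=False)
        males = [males[k] for k in np.sort(keep)]

    n_males = len(males)
    kmax = design.max_trials_per_male
    if design.target_assays is None:
        k_per_male = rng.integers(1, kmax + 1, size=n_males)
    else:
        target = design.target_assays
        if target > kmax * n_males:
            # the realized pedigree supplies fewer males than the target
            # presumes: run every male at the trial cap instead
            warnings.warn(
                f"target of {target} assays exceeds {kmax} trials x {n_males} "
                f"males; running {kmax * n_males} assays"
            )
            target = kmax * n_males
        if target < n_males:
            raise DesignInfeasibleError("fewer assays than phenotyped males")
        base = target // n_males
        extra = target - base * n_males
        k_per_male = np.full(n_males, base)
        k_per_male[rng.permutation(n_males)[:extra]] += 1

    total = int(k_per_male.sum())
    # partner pool: females without replacement until exhausted, then reuse
    pool: list[str] = []
    while len(pool) < total:
        if pool and not design.allow_female_reuse:
            raise DesignInfeasibleError(
                f"{total} assays need reuse of the {len(females)} females but reuse is disabled"
            )
        pool.extend(rng.permutation(females).tolist())
    pool = pool[:total]

    rows = []
    cursor = 0
    for m, k in zip(males, k_per_male):
        seen = set()
        for order in range(1, int(k) + 1):
            f = pool[cursor]
            if f in seen:  # keep a male's 1-3 partners distinct
                for j in range(cursor + 1, total):
                    if pool[j] not in seen:
                        pool[cursor], pool[j] = pool[j], pool[cursor]
                        f = pool[cursor]
                        break
            seen.add(f)
            cursor += 1
            rows.append((m, f, order))

    shelf = np.where(rng.random(total) < 0.5, "lower", "upper")
    trials = pd.DataFrame(rows, columns=["male_id", "female_id", "order"])
    trials["shelf"] = shelf

    pe = _pe_table(ped, env, rng)

    def chan_value(table: pd.DataFrame, ids: pd.Series, label: str) -> np.ndarray:
        if label in table.columns:
            return table[label].to_numpy()[[ped.index[i] for i in ids]]
        return np.zeros(len(ids))

    upper = (trials["shelf"] == "upper").astype(float).to_numpy()
    order = trials["order"].astype(float).to_numpy()

    for trait, sex in DYADIC_TRAITS.items():
        focal = trials["male_id"] if sex == "male" else trials["female_id"]
        partner = trials["female_id"] if sex == "male" else trials["male_id"]
        y = (
            env.intercept.get(trait, 0.0)
            + env.beta_order.get(trait, 0.0) * order
            + env.beta_shelf.get(trait, 0.0) * upper
            + chan_value(bv, focal, f"{trait}:{DIRECT}")
            + chan_value(bv, partner, f"{trait}:{INDIRECT}")
            + chan_value(pe, focal, f"{trait}:{DIRECT}")
            + chan_value(pe, partner, f"{trait}:{INDIRECT}")
        )
        vr = env.residual_variance.get(trait, 0.0)
        if vr > 0:
            y = y + np.sqrt(vr) * rng.standard_normal(total)
        trials[trait] = y

    for trait, sex in REPEATED_TRAITS.items():
        focal = trials["male_id"] if sex == "male" else trials["female_id"]
        y = (
            env.intercept.get(trait, 0.0)
            + chan_value(bv, focal, f"{trait}:{DIRECT}")
            + chan_value(pe, focal, f"{trait}:{DIRECT}")
        )
        vr = env.residual_variance.get(trait, 0.0)
        if vr > 0:
            y = y + np.sqrt(vr) * rng.standard_normal(total)
        trials[trait] = y

    morph_rows = []
    for trait, sex in ONCE_TRAITS.items():
        subjects = males if sex == "male" else sorted(set(pool))
        a = chan_value(bv, pd.Series(subjects), f"{trait}:{DIRECT}")
        vr = env.residual_variance.get(trait, 0.0)
        e = np.sqrt(vr) * rng.standard_normal(len(subjects)) if vr > 0 else 0.0
        y = env.intercept.get(trait, 0.0) + a + e
        for i, val in zip(subjects, np.atleast_1d(y + np.zeros(len(subjects)))):
            morph_rows.append((i, trait, val, 1))
    morph = pd.DataFrame(morph_rows, columns=["id", "trait", "value", "occasion"])
    return trials[TRIAL_COLUMNS], morph


# ----------------------------------------------------------------------
# Study-scale presets
# ----------------------------------------------------------------------

@dataclass
class StudyPreset:
    """Full parameterization of a simulated half-sib mating-trial study."""

    n_sires: int
    dams_per_sire: int
    offspring_per_family: int
    family_failure_rate: float
    sex_ratio: float  # P(male)
    design: AssayDesign
    genetic: GeneticCovariance
    environment: EnvironmentConfig


def _default_channels() -> list[Channel]:
    chans = []
    for t in DYADIC_TRAITS:
        chans.append(Channel(t, DIRECT))
        chans.append(Channel(t, INDIRECT))
    for t in list(REPEATED_TRAITS) + list(ONCE_TRAITS):
        chans.append(Channel(t, DIRECT))
    return chans


def _default_genetic() -> GeneticCovariance:
    """Moderate heritable variance in every behavioural channel, strongly
    heritable morphology, planted cross-channel correlations echoing the
    qualitative architecture the analysis is meant to detect, and zero
    genetic variance in guarding (the scenario where no heritable signal
    exists and correlations become untestable)."""
    chans = _default_channels()
    v = {
        Channel("lat_sing", DIRECT): 0.15,
        Channel("lat_sing", INDIRECT): 0.10,
        Channel("lat_mount", DIRECT): 0.15,
        Channel("lat_mount", INDIRECT): 0.10,
        Channel("guard_dist", DIRECT): 0.0,
        Channel("guard_dist", INDIRECT): 0.0,
        Channel("male_mass", DIRECT): 0.40,
        Channel("female_mass", DIRECT): 0.40,
        Channel("mandible", DIRECT): 0.50,
        Channel("testis", DIRECT): 0.50,
    }
    cov = {
        # direct-indirect covariance within each heritable behaviour
        (Channel("lat_sing", DIRECT), Channel("lat_sing", INDIRECT)): 0.05,
        (Channel("lat_mount", DIRECT), Channel("lat_mount", INDIRECT)): 0.05,
        # female genotypes that elicit fast male singing (low latency) carry
        # large-testis alleles: negative on the raw latency scale, positive
        # attractiveness-testis correlation after reverse-scoring
        (Channel("lat_sing", INDIRECT), Channel("testis", DIRECT)):
            -0.6 * np.sqrt(0.10 * 0.50),
        # male morphology is genetically integrated
        (Channel("male_mass", DIRECT), Channel("mandible", DIRECT)):
            0.6 * np.sqrt(0.40 * 0.50),
    }
    return GeneticCovariance.from_entries(chans, v, cov)


def _default_environment() -> EnvironmentConfig:
    pe = {}
    for t, sex in DYADIC_TRAITS.items():
        pe[Channel(t, DIRECT)] = 0.10
        pe[Channel(t, INDIRECT)] = 0.10
    for t in REPEATED_TRAITS:
        pe[Channel(t, DIRECT)] = 0.20
    resid = {t: 0.60 for t in DYADIC_TRAITS}
    resid.update({t: 0.40 for t in REPEATED_TRAITS})
    resid.update({t: 0.50 for t in ONCE_TRAITS})
    return EnvironmentConfig(
        pe_variance=pe,
        residual_variance=resid,
        intercept={t: 0.0 for t in ALL_TRAITS},
        beta_order={t: -0.10 for t in DYADIC_TRAITS},
        beta_shelf={t: 0.15 for t in DYADIC_TRAITS},
    )


def paper_scale_preset() -> StudyPreset:
    """The study-scale simulation preset.

    35 sires x 2 dams with a family failure rate of 4/70 (expected 66
    surviving full-sib families), 16 offspring per family, sex ratio
    P(male) = 310/1057 so that roughly 310 males and 747 females are
    available for testing; 826 assays spread over the males at 1-3 trials
    each, one per day.
    """
    return StudyPreset(
        n_sires=35,
        dams_per_sire=2,
        offspring_per_family=16,
        family_failure_rate=4.0 / 70.0,
        sex_ratio=310.0 / 1057.0,
        design=AssayDesign(target_assays=826, n_males=310),
        genetic=_default_genetic(),
        environment=_default_environment(),
    )


def scaled_preset(n_sires: int) -> StudyPreset:
    """The study preset with the design shrunk proportionally to ``n_sires``
    (same variance structure; assay and male counts scale with the sire
    count).  Used for cheaper simulation experiments."""
    p = paper_scale_preset()
    frac = n_sires / p.n_sires
    design = AssayDesign(
        target_assays=int(round(p.design.target_assays * frac)),
        n_males=int(round(p.design.n_males * frac)),
    )
    return replace(p, n_sires=n_sires, design=design)


def preset_to_dict(p: StudyPreset) -> dict:
    """Flat, YAML-friendly view of a study preset.

    Names every pedigree parameter, design knob, genetic variance and
    covariance (by channel label), PE variance, residual variance and
    fixed-effect coefficient, so a config file can override any of them.
    """
    cs = p.genetic.channels
    cov = {}
    for i, ci in enumerate(cs):
        for j in range(i + 1, len(cs)):
            v = float(p.genetic.G0[i, j])
            if v != 0.0:
                cov[f"{ci.label}|{cs[j].label}"] = v
    return {
        "pedigree": {
            "n_sires": p.n_sires,
            "dams_per_sire": p.dams_per_sire,
            "offspring_per_family": p.offspring_per_family,
            "family_failure_rate": p.family_failure_rate,
            "sex_ratio": p.sex_ratio,
        },
        "design": {
            "target_assays": p.design.target_assays,
            "n_males": p.design.n_males,
            "max_trials_per_male": p.design.max_trials_per_male,
            "allow_female_reuse": p.design.allow_female_reuse,
        },
        "genetic": {
            "variances": {c.label: float(p.genetic.value(c, c)) for c in cs},
            "covariances": cov,
        },
        "environment": {
            "pe_variance": {c.label: float(v) for c, v in p.environment.pe_variance.items()},
            "residual_variance": dict(p.environment.residual_variance),
            "intercept": dict(p.environment.intercept),
            "beta_order": dict(p.environment.beta_order),
            "beta_shelf": dict(p.environment.beta_shelf),
        },
    }


def _parse_channel_label(label: str) -> Channel:
    trait, _, role = label.partition(":")
    return Channel(trait, role or DIRECT)


def preset_from_dict(d: Mapping) -> StudyPreset:
    """Inverse of :func:`preset_to_dict`."""
    ped = d["pedigree"]
    des = d.get("design", {})
    gen = d.get("genetic", {})
    env = d.get("environment", {})
    variances = {
        _parse_channel_label(k): float(v)
        for k, v in gen.get("variances", {}).items()
    }
    covariances = {}
    for pair, v in gen.get("covariances", {}).items():
        a, _, b = pair.partition("|")
        covariances[(_parse_channel_label(a), _parse_channel_label(b))] = float(v)
    genetic = GeneticCovariance.from_entries(
        list(variances), variances, covariances)
    environment = EnvironmentConfig(
        pe_variance={
            _parse_channel_label(k): float(v)
            for k, v in env.get("pe_variance", {}).items()
        },
        residual_variance={k: float(v) for k, v in env.get("residual_variance", {}).items()},
        intercept={k: float(v) for k, v in env.get("intercept", {}).items()},
        beta_order={k: float(v) for k, v in env.get("beta_order", {}).items()},
        beta_shelf={k: float(v) for k, v in env.get("beta_shelf", {}).items()},
    )
    return StudyPreset(
        n_sires=int(ped["n_sires"]),
        dams_per_sire=int(ped["dams_per_sire"]),
        offspring_per_family=int(ped["offspring_per_family"]),
        family_failure_rate=float(ped.get("family_failure_rate", 0.0)),
        sex_ratio=float(ped.get("sex_ratio", 0.5)),
        design=AssayDesign(
            target_assays=des.get("target_assays"),
            n_males=des.get("n_males"),
            max_trials_per_male=int(des.get("max_trials_per_male", 3)),
            allow_female_reuse=bool(des.get("allow_female_reuse", True)),
        ),
        genetic=genetic,
        environment=environment,
    )


def _deep_update(base: dict, override: Mapping) -> dict:
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def apply_preset_overrides(preset: StudyPreset, overrides: Mapping) -> StudyPreset:
    """Return the preset with a (possibly partial) parameter dict merged in."""
    return preset_from_dict(_deep_update(preset_to_dict(preset), overrides))


def simulate_study(
    preset: StudyPreset, seed: int
) -> tuple[Pedigree, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run a preset end to end: pedigree, breeding values, trials, morphology.

    Returns ``(pedigree, breeding_values, trials, morphology)``; the three
    stochastic stages consume distinct streams derived from ``seed``.
    """
    ped = build_half_sib_design(
        preset.n_sires,
        preset.dams_per_sire,
        preset.offspring_per_family,
        preset.family_failure_rate,
        preset.sex_ratio,
        seed=seed,
    )
    bv = sample_breeding_values(ped, preset.genetic, seed=seed + 1)
    trials, morph = simulate_trials(
        ped, bv, preset.environment, preset.design, seed=seed + 2
    )
    return ped, bv, trials, morph
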