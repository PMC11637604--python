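"""Configuration-driven orchestration of the full analysis.

simulate (or load) -> z-transform and reverse-score -> univariate animal
models with component LRTs and total heritable variance -> significance-
gated bivariate fits -> genetic-correlation report, with full seed
provenance and bit-for-bit reproducible outputs.

Every numeric table is written with a fixed float format and no timestamps,
so re-running a configuration reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, animal_model, genearch, synth
from .animal_model import (
    Constraint,
    FittedModel,
    ModelSpec,
    VarianceComponents,
    build_mixed_model,
    fit,
    fit_constrained,
)
from .genearch import LRTResult, lrt, reverse_score
from .pedigree import Pedigree, read_pedigree
from .synth import (
    Channel,
    DIRECT,
    DYADIC_TRAITS,
    GeneticCovariance,
    INDIRECT,
    ONCE_TRAITS,
    REPEATED_TRAITS,
    StudyPreset,
    paper_scale_preset,
    scaled_preset,
    simulate_study,
)

logger = logging.getLogger("dyadige.pipeline")

FLOAT_FMT = "%.12g"
DEFAULT_TRAITS = [
    "lat_sing", "lat_mount", "guard_dist",
    "male_mass", "female_mass", "mandible", "testis",
]
#: latency traits reverse-scored before bivariate fits and reporting
LATENCY_TRAITS = ("lat_sing", "lat_mount")
DEFAULT_PAIRS = [
    ["lat_sing:indirect", "testis:direct"],
    ["lat_sing:direct", "lat_mount:indirect"],
    ["male_mass:direct", "mandible:direct"],
]

__all__ = [
    "PipelineConfig",
    "UnivariateResult",
    "run_pipeline",
    "select_pairs",
    "ztransform",
    "parse_channel",
]


def parse_channel(label: str) -> Channel:
    trait, _, role = label.partition(":")
    return Channel(trait, role or DIRECT)


def ztransform(values: np.ndarray) -> np.ndarray:
    """Mean-0, SD-1 transform over the analysis sample (NaNs preserved)."""
    v = np.asarray(values, dtype=float)
    m = np.nanmean(v)
    s = np.nanstd(v)
    if s == 0:
        return v - m
    return (v - m) / s


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    Either ``preset`` names a simulation scenario (``"paper"`` for the
    study-scale design, or ``n_sires`` shrinks it proportionally), or the
    three input paths point at existing pedigree/trial/morphology CSVs.
    """

    seed: int = 1
    out_dir: str = "run"
    preset: str | None = "paper"
    n_sires: int | None = None
    pedigree_path: str | None = None
    trials_path: str | None = None
    morphology_path: str | None = None
    traits: list = field(default_factory=lambda: list(DEFAULT_TRAITS))
    pairs: list = field(default_factory=lambda: [list(p) for p in DEFAULT_PAIRS])
    pair_policy: str = "paper_rule"  # or "all"
    alpha: float = 0.05
    restarts: int = 1  # pipeline fits are warm-started; see docs/methods.md
    generator: dict | None = None  # partial overrides of the preset parameters

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_dict(self, exclude_location: bool = False) -> dict:
        d = dataclasses.asdict(self)
        if exclude_location:
            d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        # the output location does not affect the run's content
        blob = json.dumps(self.to_dict(exclude_location=True), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class UnivariateResult:
    """One trait's univariate fit plus its component tests."""

    trait: str
    fitted: FittedModel
    lrts: dict[str, LRTResult]
    vtbv: float | None
    table: pd.DataFrame


def _setup_logging(out: Path):
    fmt = logging.Formatter("%(name)s %(levelname)s %(message)s")
    root = logging.getLogger("dyadige")
    for h in list(root.handlers):
        root.removeHandler(h)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(fmt)
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    root.addHandler(fh)
    root.addHandler(sh)
    root.setLevel(logging.INFO)


def _preset_for(cfg: PipelineConfig) -> StudyPreset:
    if cfg.n_sires is not None:
        preset = scaled_preset(cfg.n_sires)
    elif cfg.preset in (None, "paper"):
        preset = paper_scale_preset()
    else:
        raise ValueError(f"unknown preset {cfg.preset!r}")
    if cfg.generator:
        preset = synth.apply_preset_overrides(preset, cfg.generator)
    return preset


def prepare_inputs(cfg: PipelineConfig, out: Path):
    """Simulate (writing the input tables) or load the three input files."""
    if cfg.preset is not None or cfg.n_sires is not None:
        preset = _preset_for(cfg)
        ped, _, trials, morph = simulate_study(preset, seed=cfg.seed)
        ped.to_csv(out / "pedigree.csv")
        trials.to_csv(out / "trials.csv", index=False, float_format=FLOAT_FMT)
        morph.to_csv(out / "morphology.csv", index=False, float_format=FLOAT_FMT)
        logger.info("simulated %d assays, %d pedigree members", len(trials), len(ped))
        return ped, trials, morph
    ped = read_pedigree(cfg.pedigree_path)
    trials = pd.read_csv(cfg.trials_path)
    morph = pd.read_csv(cfg.morphology_path)
    return ped, trials, morph


def _preprocess(trials: pd.DataFrame, morph: pd.DataFrame, reverse: bool):
    """Z-transform every trait; optionally reverse-score latencies."""
    t = trials.copy()
    for col in t.columns:
        if col in DYADIC_TRAITS or col in REPEATED_TRAITS:
            z = ztransform(t[col].to_numpy())
            if reverse and col in LATENCY_TRAITS:
                z = reverse_score(z)
            t[col] = z
    m = morph.copy()
    for trait, sub in m.groupby("trait"):
        m.loc[sub.index, "value"] = ztransform(sub["value"].to_numpy())
    return t, m


def _sex_symbol(c: Channel, kind: str) -> str:
    """Field symbol for a channel's variance (V_Am, V_Af, V_PEm, V_PEf)."""
    suffix = "m" if c.expresser_sex == "male" else "f"
    return ("V_A" if kind == "G" else "V_PE") + suffix


def run_univariate(
    trials, morph, ped: Pedigree, trait: str, seed: int, restarts: int = 1
) -> UnivariateResult:
    """Fit one univariate animal model and test its genetic components.

    Dyadic traits get direct+indirect genetic and PE channels with order and
    shelf fixed effects; repeated morphology gets a direct genetic and PE
    channel; once-measured morphology gets only the direct genetic channel
    (PE constrained to zero).  Each genetic variance is tested with the
    boundary mixture convention and the direct-indirect covariance with the
    chi-square(1) convention.
    """
    spec = ModelSpec.univariate(trait)
    mm = build_mixed_model(trials, morph, ped, spec)
    full = fit(mm, seed=seed, restarts=restarts)
    for line in full.trace:
        logger.info("optimizer %s: %s", trait, line)
    reduced: dict[str, tuple] = {}
    tm = spec.traits[0]
    for k, c in enumerate(mm.gchannels):
        red = fit_constrained(
            mm, [Constraint("genetic_variance", (c,))],
            seed=seed + 10 + k, init=full.components, restarts=1,
        )
        reduced[f"G:{c.label}|{c.label}"] = (red, "variance")
    if tm.kind == "dyadic" and tm.indirect_genetic:
        cd, ci = Channel(trait, DIRECT), Channel(trait, INDIRECT)
        red = fit_constrained(
            mm, [Constraint("genetic_covariance", (cd, ci))],
            seed=seed + 20, init=full.components, restarts=1,
        )
        reduced[f"G:{cd.label}|{ci.label}"] = (red, "covariance_or_correlation")
    full = animal_model.refit_if_beaten(
        full, [r for r, _ in reduced.values()], mm, seed=seed + 30
    )
    lrts = {
        name: lrt(full.loglik, red.loglik, kind)
        for name, (red, kind) in reduced.items()
    }
    vtbv = None
    if tm.kind == "dyadic" and tm.indirect_genetic:
        cd, ci = Channel(trait, DIRECT), Channel(trait, INDIRECT)
        g = full.components.genetic
        vtbv = genearch.total_heritable_variance(
            g.value(cd, cd), g.value(ci, ci), g.value(cd, ci)
        )

    rows = []
    sig = full.components.to_sigma(mm)
    for k, name in enumerate(full.component_names):
        res = lrts.get(name)
        kind, _, rest = name.partition(":")
        if kind == "G":
            a, b = rest.split("|")
            symbol = _sex_symbol(parse_channel(a), "G") if a == b else "COV_Am,Af"
        elif kind == "PE":
            symbol = _sex_symbol(parse_channel(rest), "PE")
        else:
            symbol = "V_R"
        rows.append((
            name, symbol, float(sig[k]),
            full.se.get(name, float("nan")),
            bool(full.boundary.get(name, False)),
            res.statistic if res else float("nan"),
            res.convention if res else "",
            res.p_value if res else float("nan"),
        ))
    if vtbv is not None:
        rows.append(("V_TBV", "V_TBV", vtbv, float("nan"), False,
                     float("nan"), "", float("nan")))
    table = pd.DataFrame(
        rows,
        columns=["component", "symbol", "estimate", "se", "boundary",
                 "lrt", "convention", "p"],
    )
    return UnivariateResult(trait, full, lrts, vtbv, table)


def select_pairs(
    unifits: dict[str, UnivariateResult],
    declared: list[tuple[Channel, Channel]],
    policy: str = "paper_rule",
    alpha: float = 0.05,
) -> list[tuple[Channel, Channel]]:
    """Gate the declared bivariate channel pairs on univariate significance.

    ``paper_rule`` keeps a pair only when each member channel's genetic
    variance is significant at ``alpha`` by its univariate LRT; ``all``
    keeps every declared pair.
    """
    if policy == "all":
        return list(declared)
    if policy != "paper_rule":
        raise ValueError(f"unknown pair policy {policy!r}")
    out = []
    for ca, cb in declared:
        ok = True
        for c in (ca, cb):
            uf = unifits.get(c.trait)
            res = uf.lrts.get(f"G:{c.label}|{c.label}") if uf else None
            if res is None or res.p_value >= alpha:
                ok = False
        if ok:
            out.append((ca, cb))
    return out


def run_bivariate(
    trials, morph, ped: Pedigree,
    ca: Channel, cb: Channel,
    unifits: dict[str, UnivariateResult] | None,
    seed: int,
    restarts: int = 1,
) -> dict:
    """Bivariate fit for one channel pair; returns a report row.

    Intercept-only fixed effects; the full fit estimates all genetic
    covariances between the two traits' channels, and the focal pair's
    covariance is then pinned to zero for a chi-square(1) LRT.  Pairs whose
    parent variances are boundary-pinned are reported NA-with-flag.
    """
    spec = ModelSpec.bivariate(ca.trait, cb.trait)
    mm = build_mixed_model(trials, morph, ped, spec)
    init = None
    if unifits and ca.trait in unifits and cb.trait in unifits:
        init = _bivariate_init(mm, unifits[ca.trait].fitted, unifits[cb.trait].fitted)
    full = fit(mm, init=init, seed=seed, restarts=restarts)
    label = _pair_label(ca, cb)
    for line in full.trace:
        logger.info("optimizer %s: %s", label, line)
    vnames = (f"G:{ca.label}|{ca.label}", f"G:{cb.label}|{cb.label}")
    if any(full.boundary.get(v, False) for v in vnames):
        logger.info("pair %s: parent genetic variance on boundary; correlation NA", label)
        return dict(pair_label=label, r=float("nan"), se=float("nan"),
                    lrt=float("nan"), df_convention="", p=float("nan"),
                    significant=False, flagged=True, converged=full.converged)
    red = fit_constrained(
        mm, [Constraint("genetic_covariance", (ca, cb))],
        seed=seed + 1, init=full.components, restarts=1,
    )
    full = animal_model.refit_if_beaten(full, [red], mm, seed=seed + 2)
    res = lrt(full.loglik, red.loglik, "covariance_or_correlation")
    r, se = full.correlation(ca, cb)
    return dict(pair_label=label, r=r, se=se, lrt=res.statistic,
                df_convention=res.convention, p=res.p_value,
                significant=bool(res.p_value < 0.05), flagged=not full.converged,
                converged=full.converged)


def _pair_label(ca: Channel, cb: Channel) -> str:
    def one(c: Channel) -> str:
        star = "*" if c.trait in LATENCY_TRAITS else ""
        return f"{c.trait}{star}:{c.role}"
    return f"{one(ca)}-{one(cb)}"


def _bivariate_init(mm, fit_a: FittedModel, fit_b: FittedModel) -> VarianceComponents:
    """Warm start a bivariate fit from the two univariate solutions."""
    q = len(mm.gchannels)
    G = np.zeros((q, q))
    for a in range(q):
        for b in range(a, q):
            ca, cb = mm.gchannels[a], mm.gchannels[b]
            for f in (fit_a, fit_b):
                gch = f.components.genetic.channels
                if ca in gch and cb in gch:
                    G[a, b] = G[b, a] = f.components.genetic.value(ca, cb)
                    break
    G = 0.5 * (G + G.T)
    w, U = np.linalg.eigh(G)
    G = (U * np.clip(w, 1e-8, None)) @ U.T
    pe = {}
    for c in mm.pe_channels:
        for f in (fit_a, fit_b):
            if c in f.components.pe:
                pe[c] = max(f.components.pe[c], 1e-6)
                break
        else:
            pe[c] = 0.05
    resid = {}
    for t in mm.resid_traits:
        for f in (fit_a, fit_b):
            if t in f.components.residual:
                resid[t] = f.components.residual[t]
                break
        else:
            resid[t] = 0.5
    return VarianceComponents(GeneticCovariance(mm.gchannels, G), pe, resid)


def run_pipeline(cfg: PipelineConfig, stage: str = "report") -> Path:
    """Run the pipeline up to ``stage`` (simulate, fit-uni, fit-bi, report).

    Writes inputs, per-trait univariate component tables, the bivariate
    correlation report, a machine-readable manifest and a log into
    ``cfg.out_dir``; a rerun with the same configuration reproduces every
    numeric output byte for byte.
    """
    stages = ("simulate", "fit-uni", "fit-bi", "report")
    if stage not in stages:
        raise ValueError(f"stage must be one of {stages}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    logger.info("pipeline start: preset=%s seed=%d", cfg.preset, cfg.seed)

    ped, trials, morph = prepare_inputs(cfg, out)
    manifest = {
        "config": cfg.to_dict(exclude_location=True),
        "config_sha256": cfg.config_hash(),
        "version": __version__,
        "n_pedigree": len(ped),
        "n_assays": int(len(trials)),
    }
    if stage == "simulate":
        _write_manifest(out, manifest)
        return out

    z_trials, z_morph = _preprocess(trials, morph, reverse=False)
    rz_trials, rz_morph = _preprocess(trials, morph, reverse=True)

    unifits: dict[str, UnivariateResult] = {}
    for k, trait in enumerate(cfg.traits):
        logger.info("univariate fit: %s", trait)
        res = run_univariate(
            z_trials, z_morph, ped, trait,
            seed=cfg.seed + 100 * (k + 1), restarts=cfg.restarts,
        )
        if not res.fitted.converged:
            logger.warning("univariate fit for %s flagged non-converged", trait)
        res.table.to_csv(out / f"univariate_{trait}.csv", index=False,
                         float_format=FLOAT_FMT)
        unifits[trait] = res
    if stage == "fit-uni":
        _write_manifest(out, manifest)
        return out

    declared = [tuple(parse_channel(x) for x in pair) for pair in cfg.pairs]
    pairs = select_pairs(unifits, declared, cfg.pair_policy, cfg.alpha)
    logger.info("bivariate pairs after %s gate: %d of %d declared",
                cfg.pair_policy, len(pairs), len(declared))

    rows = []
    for k, (ca, cb) in enumerate(pairs):
        logger.info("bivariate fit: %s", _pair_label(ca, cb))
        try:
            rows.append(run_bivariate(
                rz_trials, rz_morph, ped, ca, cb, unifits,
                seed=cfg.seed + 1000 * (k + 1), restarts=cfg.restarts,
            ))
        except Exception as exc:  # partial-failure isolation
            logger.warning("pair %s failed: %s", _pair_label(ca, cb), exc)
            rows.append(dict(pair_label=_pair_label(ca, cb), r=float("nan"),
                             se=float("nan"), lrt=float("nan"), df_convention="",
                             p=float("nan"), significant=False, flagged=True,
                             converged=False))
    for ca, cb in declared:
        if (ca, cb) not in pairs:
            rows.append(dict(pair_label=_pair_label(ca, cb), r=float("nan"),
                             se=float("nan"), lrt=float("nan"), df_convention="",
                             p=float("nan"), significant=False, flagged=True,
                             converged=True))
    report = pd.DataFrame(
        rows, columns=["pair_label", "r", "se", "lrt", "df_convention", "p",
                       "significant", "flagged", "converged"],
    )
    report.to_csv(out / "correlations.csv", index=False, float_format=FLOAT_FMT)

    summary = pd.concat(
        [res.table.assign(trait=t) for t, res in unifits.items()],
        ignore_index=True,
    )
    summary.to_csv(out / "univariate_summary.csv", index=False,
                   float_format=FLOAT_FMT)
    _write_manifest(out, manifest)
    logger.info("pipeline done")
    return out


def _write_manifest(out: Path, manifest: dict):
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n"
    )
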