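"""REML animal models with direct and indirect genetic effect channels.

The estimation core of the package.  A model is specified trait-by-trait
(one or two response traits): each trait names which individual on a record
supplies the *direct* effect (own genotype / permanent environment) and,
for dyadic traits, which supplies the *indirect* effect (the partner's
genotype / permanent environment).  The implied covariance structure is

    V = sum_{c<=d} G_cd (Z_c A Z_d' + Z_d A Z_c') + sum_c V_PE,c Z_c Z_c'
        + diag residual blocks,

with ``A`` the numerator relationship matrix, ``G`` the additive genetic
covariance over the active channels, PE variances diagonal per channel, and
per-trait residual variances.  The restricted likelihood is maximized on an
unconstrained scale (log-Cholesky for the genetic block, log variances for
PE and residual) by average-information Newton ascent followed by an
L-BFGS-B polish with analytic gradients; standard errors come from the
inverse average-information matrix at the optimum.

Model invariants enforced at specification time: morphology traits carry no
indirect channel (their expression does not depend on the partner);
once-measured traits carry no permanent-environment channel (PE is not
separable from residual without repeats); bivariate specifications carry no
fixed effects beyond trait-specific intercepts.

The restricted log-likelihood convention used throughout is

    logL = -0.5 [ (n-p) log 2*pi - log|X'X| + log|V| + log|X'V^-1 X| + y'Py ]

which equals the exact Gaussian log-density of the error contrasts ``B'y``
for any orthonormal basis ``B`` of the null space of ``X'``; differences of
log-likelihoods (LRTs) do not depend on the constant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .pedigree import Pedigree, relationship_matrix
from .synth import (
    ALL_TRAITS,
    DIRECT,
    DYADIC_TRAITS,
    INDIRECT,
    ONCE_TRAITS,
    REPEATED_TRAITS,
    Channel,
    ChannelSet,
    GeneticCovariance,
)

logger = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)

#: a variance estimate below this is considered pinned to its zero boundary
BOUNDARY_VARIANCE = 1e-6
#: a correlation within this of +/-1 is considered boundary-pinned
BOUNDARY_CORRELATION = 1e-4

__all__ = [
    "TraitModel",
    "ModelSpec",
    "Constraint",
    "ModelMatrices",
    "VarianceComponents",
    "FittedModel",
    "AdmissibilityError",
    "ModelBuildError",
    "build_mixed_model",
    "reml_loglik",
    "fit",
    "fit_constrained",
]


class AdmissibilityError(ValueError):
    """Variance components imply a non-PSD covariance structure."""


class ModelBuildError(ValueError):
    """The data, pedigree and specification cannot be assembled into a model."""


@dataclass(frozen=True)
class TraitModel:
    """How one response trait enters the model.

    ``kind`` is ``"dyadic"`` (trial-level behaviour with a focal expresser
    and an opposite-sex partner), ``"repeated"`` (morphology measured at
    every trial of the expresser) or ``"once"`` (morphology measured a
    single time).  ``expresser`` names the sex whose column of the trial
    table supplies the direct-effect individual.
    """

    name: str
    kind: str
    expresser: str
    direct_genetic: bool = True
    indirect_genetic: bool = False
    direct_pe: bool = False
    indirect_pe: bool = False

    def __post_init__(self):
        if self.kind not in ("dyadic", "repeated", "once"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.expresser not in ("male", "female"):
            raise ValueError("expresser must be 'male' or 'female'")
        if self.kind != "dyadic" and (self.indirect_genetic or self.indirect_pe):
            raise ValueError(
                f"{self.name!r}: morphology depends only on the expresser; "
                "indirect channels are not allowed"
            )
        if self.kind == "once" and (self.direct_pe or self.indirect_pe):
            raise ValueError(
                f"{self.name!r}: measured once; permanent-environment "
                "variance is not separable and must stay constrained to zero"
            )

    @classmethod
    def standard(cls, name: str) -> "TraitModel":
        """The full channel layout for a trait of the standard schema."""
        if name in DYADIC_TRAITS:
            return cls(name, "dyadic", DYADIC_TRAITS[name],
                       indirect_genetic=True, direct_pe=True, indirect_pe=True)
        if name in REPEATED_TRAITS:
            return cls(name, "repeated", REPEATED_TRAITS[name], direct_pe=True)
        if name in ONCE_TRAITS:
            return cls(name, "once", ONCE_TRAITS[name])
        raise ValueError(f"unknown trait {name!r}")

    def channels(self) -> list[Channel]:
        out = []
        if self.direct_genetic:
            out.append(Channel(self.name, DIRECT))
        if self.indirect_genetic:
            out.append(Channel(self.name, INDIRECT))
        return out

    def pe_channels(self) -> list[Channel]:
        out = []
        if self.direct_pe:
            out.append(Channel(self.name, DIRECT))
        if self.indirect_pe:
            out.append(Channel(self.name, INDIRECT))
        return out


@dataclass(frozen=True)
class Constraint:
    """A component pinned for a constrained (reduced) fit.

    ``kind``: ``"genetic_variance"`` (drops the channel and every covariance
    involving it), ``"genetic_covariance"`` (pins one off-diagonal of G to
    zero) or ``"pe_variance"`` (drops a permanent-environment channel).
    """

    kind: str
    channels: tuple[Channel, ...]

    def __post_init__(self):
        if self.kind not in ("genetic_variance", "genetic_covariance", "pe_variance"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        need = 2 if self.kind == "genetic_covariance" else 1
        if len(self.channels) != need:
            raise ValueError(f"{self.kind} takes {need} channel(s)")


@dataclass(frozen=True)
class ModelSpec:
    """One- or two-trait model specification."""

    traits: tuple[TraitModel, ...]
    fixed_effects: tuple[str, ...] = ()
    pinned_covariances: frozenset = frozenset()

    def __post_init__(self):
        if len(self.traits) not in (1, 2):
            raise ValueError("1 or 2 response traits supported")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate response trait")
        bad = set(self.fixed_effects) - {"order", "shelf"}
        if bad:
            raise ValueError(f"unknown fixed effects {sorted(bad)}")
        if len(self.traits) == 2 and self.fixed_effects:
            raise ValueError(
                "bivariate models carry trait-specific intercepts only "
                "(no further fixed effects)"
            )

    @classmethod
    def univariate(cls, name: str, fixed_effects=("order", "shelf")) -> "ModelSpec":
        t = TraitModel.standard(name)
        if t.kind != "dyadic":
            fixed_effects = ()
        return cls(traits=(t,), fixed_effects=tuple(fixed_effects))

    @classmethod
    def bivariate(cls, name_a: str, name_b: str) -> "ModelSpec":
        return cls(traits=(TraitModel.standard(name_a), TraitModel.standard(name_b)))

    def to_dict(self) -> dict:
        """YAML/JSON-friendly representation (round-trips via from_dict)."""
        return {
            "traits": [
                {
                    "name": t.name, "kind": t.kind, "expresser": t.expresser,
                    "direct_genetic": t.direct_genetic,
                    "indirect_genetic": t.indirect_genetic,
                    "direct_pe": t.direct_pe, "indirect_pe": t.indirect_pe,
                }
                for t in self.traits
            ],
            "fixed_effects": list(self.fixed_effects),
            "pinned_covariances": sorted(
                "|".join(sorted(c.label for c in pair))
                for pair in self.pinned_covariances
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        def chan(label: str) -> Channel:
            trait, _, role = label.partition(":")
            return Channel(trait, role or DIRECT)

        pins = frozenset(
            frozenset(chan(lbl) for lbl in pair.split("|"))
            for pair in d.get("pinned_covariances", [])
        )
        return cls(
            traits=tuple(TraitModel(**t) for t in d["traits"]),
            fixed_effects=tuple(d.get("fixed_effects", ())),
            pinned_covariances=pins,
        )


# ----------------------------------------------------------------------
# Model matrices
# ----------------------------------------------------------------------

@dataclass
class ModelMatrices:
    """Assembled structures for one REML problem.

    ``K[(i, j)]`` (channel positions, i <= j) holds the symmetrized
    relationship kernel ``Z_i A Z_j' (+ transpose)`` so that the phenotypic
    covariance is a *linear* combination of fixed matrices; this is what
    makes repeated likelihood evaluations cheap.
    """

    spec: ModelSpec
    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    trait_slices: dict[str, slice]
    gchannels: ChannelSet
    K: dict[tuple[int, int], np.ndarray]
    pe_channels: list[Channel]
    Kpe: list[np.ndarray]
    resid_traits: list[str]
    resid_masks: dict[str, np.ndarray]
    pinned: frozenset
    logdetXtX: float

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    # -- component bookkeeping ---------------------------------------
    def genetic_pairs(self) -> list[tuple[int, int]]:
        q = len(self.gchannels)
        return [(i, j) for i in range(q) for j in range(i, q)]

    def component_names(self) -> list[str]:
        names = []
        for i, j in self.genetic_pairs():
            ci, cj = self.gchannels[i], self.gchannels[j]
            names.append(f"G:{ci.label}|{cj.label}")
        for c in self.pe_channels:
            names.append(f"PE:{c.label}")
        for t in self.resid_traits:
            names.append(f"R:{t}")
        return names

    def is_pinned(self, i: int, j: int) -> bool:
        pair = frozenset((self.gchannels[i], self.gchannels[j]))
        return len(pair) == 2 and pair in self.pinned

    # -- derived model views -----------------------------------------
    def with_response(self, y: np.ndarray) -> "ModelMatrices":
        """Same structure, different response (shares the kernel matrices)."""
        y = np.asarray(y, dtype=float)
        if y.shape != self.y.shape:
            raise ValueError("response length mismatch")
        return replace(self, y=y)

    def with_constraints(self, constraints: Iterable[Constraint]) -> "ModelMatrices":
        """Reduced model: dropped channels / pinned covariances."""
        drop_g, drop_pe = set(), set()
        pins = set(self.pinned)
        for con in constraints:
            if con.kind == "genetic_variance":
                drop_g.add(con.channels[0])
            elif con.kind == "pe_variance":
                drop_pe.add(con.channels[0])
            else:
                pins.add(frozenset(con.channels))
        for c in drop_g | {c for pair in pins for c in pair}:
            if c not in self.gchannels:
                raise ValueError(f"no genetic channel {c.label} in model")
        for c in drop_pe:
            if c not in self.pe_channels:
                raise ValueError(f"no PE channel {c.label} in model")

        keep = [c for c in self.gchannels if c not in drop_g]
        old_pos = {c: k for k, c in enumerate(self.gchannels)}
        new_K = {}
        for a, ci in enumerate(keep):
            for b in range(a, len(keep)):
                cj = keep[b]
                i, j = sorted((old_pos[ci], old_pos[cj]))
                new_K[(a, b)] = self.K[(i, j)]
        pe_keep = [c for c in self.pe_channels if c not in drop_pe]
        kpe = [k for c, k in zip(self.pe_channels, self.Kpe) if c not in drop_pe]
        pins = frozenset(p for p in pins if all(c in keep for c in p))
        return replace(
            self,
            gchannels=ChannelSet(keep),
            K=new_K,
            pe_channels=pe_keep,
            Kpe=kpe,
            pinned=pins,
        )


def _trait_records(trials: pd.DataFrame, morph: pd.DataFrame, t: TraitModel):
    """(response values, direct ids, indirect ids or None) for one trait."""
    if t.kind in ("dyadic", "repeated"):
        if t.name not in trials.columns:
            raise ModelBuildError(f"trait {t.name!r} not in trial table")
        sub = trials.loc[trials[t.name].notna()]
        focal_col = "male_id" if t.expresser == "male" else "female_id"
        partner_col = "female_id" if t.expresser == "male" else "male_id"
        y = sub[t.name].to_numpy(dtype=float)
        direct = sub[focal_col].to_numpy()
        indirect = sub[partner_col].to_numpy() if t.kind == "dyadic" else None
        return y, direct, indirect, sub
    sub = morph.loc[(morph["trait"] == t.name) & morph["value"].notna()]
    if sub.empty:
        raise ModelBuildError(f"trait {t.name!r} not in morphology table")
    return sub["value"].to_numpy(dtype=float), sub["id"].to_numpy(), None, sub


def build_mixed_model(
    trials: pd.DataFrame,
    morph: pd.DataFrame,
    ped: Pedigree,
    spec: ModelSpec,
) -> ModelMatrices:
    """Assemble response, fixed-effect and covariance-kernel matrices.

    The testing-order covariate is centered within each trait's record set;
    shelf is coded lower=0 / upper=1.  Rank-deficient fixed-effect columns
    are dropped with a logged warning.
    """
    A = relationship_matrix(ped).A

    ys, Xblocks, slices = [], [], {}
    chan_rows: list[tuple[Channel, np.ndarray, np.ndarray]] = []   # genetic
    pe_rows: list[tuple[Channel, np.ndarray, np.ndarray]] = []
    start = 0
    per_trait_X: list[np.ndarray] = []
    fixed_names: list[str] = []

    def ped_idx(ids: np.ndarray) -> np.ndarray:
        try:
            return np.array([ped.index[i] for i in ids], dtype=np.int64)
        except KeyError as exc:
            raise ModelBuildError(f"individual {exc.args[0]!r} not in pedigree") from exc

    for t in spec.traits:
        y, direct, indirect, sub = _trait_records(trials, morph, t)
        if len(y) == 0:
            raise ModelBuildError(f"all responses missing for {t.name!r}")
        rows = np.arange(start, start + len(y))
        slices[t.name] = slice(start, start + len(y))
        start += len(y)
        ys.append(y)

        cols = [np.ones(len(y))]
        names = [f"intercept:{t.name}"]
        if t.kind == "dyadic":
            if "order" in spec.fixed_effects:
                order = sub["order"].to_numpy(dtype=float)
                cols.append(order - order.mean())
                names.append("order")
            if "shelf" in spec.fixed_effects:
                cols.append((sub["shelf"].to_numpy() == "upper").astype(float))
                names.append("shelf:upper")
        per_trait_X.append(np.column_stack(cols))
        fixed_names.extend(names)

        d_idx = ped_idx(direct)
        if t.direct_genetic:
            chan_rows.append((Channel(t.name, DIRECT), rows, d_idx))
        if t.direct_pe:
            pe_rows.append((Channel(t.name, DIRECT), rows, d_idx))
        if indirect is not None:
            i_idx = ped_idx(indirect)
            if t.indirect_genetic:
                chan_rows.append((Channel(t.name, INDIRECT), rows, i_idx))
            if t.indirect_pe:
                pe_rows.append((Channel(t.name, INDIRECT), rows, i_idx))

    n = start
    y = np.concatenate(ys)
    X = np.zeros((n, sum(b.shape[1] for b in per_trait_X)))
    c0 = 0
    for t, block in zip(spec.traits, per_trait_X):
        X[slices[t.name], c0:c0 + block.shape[1]] = block
        c0 += block.shape[1]

    # resolve rank deficiency by dropping redundant columns
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        dropped = [nm for nm, k in zip(fixed_names, keep) if not k]
        logger.warning("dropping rank-deficient fixed-effect columns: %s", dropped)
        X = X[:, keep]
        fixed_names = [nm for nm, k in zip(fixed_names, keep) if k]
    if X.shape[1] == 0:
        raise ModelBuildError("fixed-effect matrix has rank 0")

    gchannels = ChannelSet([c for c, _, _ in chan_rows])
    ginfo = {c: (rows, idx) for c, rows, idx in chan_rows}
    K: dict[tuple[int, int], np.ndarray] = {}
    for i, ci in enumerate(gchannels):
        ri, ii = ginfo[ci]
        for j in range(i, len(gchannels)):
            cj = gchannels[j]
            rj, ij = ginfo[cj]
            M = np.zeros((n, n))
            B = A[np.ix_(ii, ij)]
            M[np.ix_(ri, rj)] += B
            if i != j:
                M[np.ix_(rj, ri)] += B.T
            K[(i, j)] = M

    pe_channels = [c for c, _, _ in pe_rows]
    Kpe = []
    for c, rows, idx in pe_rows:
        M = np.zeros((n, n))
        M[np.ix_(rows, rows)] = (idx[:, None] == idx[None, :]).astype(float)
        Kpe.append(M)

    resid_traits = [t.name for t in spec.traits]
    resid_masks = {
        t.name: (np.arange(n) >= slices[t.name].start) & (np.arange(n) < slices[t.name].stop)
        for t in spec.traits
    }
    sign, logdetXtX = np.linalg.slogdet(X.T @ X)
    return ModelMatrices(
        spec=spec,
        y=y,
        X=X,
        fixed_names=fixed_names,
        trait_slices=slices,
        gchannels=gchannels,
        K=K,
        pe_channels=pe_channels,
        Kpe=Kpe,
        resid_traits=resid_traits,
        resid_masks=resid_masks,
        pinned=frozenset(spec.pinned_covariances),
        logdetXtX=float(logdetXtX),
    )


# ----------------------------------------------------------------------
# Variance components and the restricted likelihood
# ----------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """All (co)variance parameters of one model, on the analysis scale."""

    genetic: GeneticCovariance
    pe: dict[Channel, float]
    residual: dict[str, float]

    def validate(self):
        for c, v in self.pe.items():
            if v < -1e-12:
                raise AdmissibilityError(f"negative PE variance for {c.label}")
        for t, v in self.residual.items():
            if v <= 0:
                raise AdmissibilityError(f"residual variance for {t} must be > 0")
        # GeneticCovariance validated PSD at construction
        return self

    def to_sigma(self, mm: ModelMatrices) -> np.ndarray:
        vals = []
        for i, j in mm.genetic_pairs():
            vals.append(self.genetic.value(mm.gchannels[i], mm.gchannels[j]))
        for c in mm.pe_channels:
            vals.append(self.pe[c])
        for t in mm.resid_traits:
            vals.append(self.residual[t])
        return np.array(vals)

    @classmethod
    def from_sigma(cls, mm: ModelMatrices, sigma: np.ndarray) -> "VarianceComponents":
        q = len(mm.gchannels)
        G = np.zeros((q, q))
        k = 0
        for i, j in mm.genetic_pairs():
            G[i, j] = G[j, i] = sigma[k]
            k += 1
        # numerically tiny negative eigenvalues from the optimizer boundary
        # are projected away so the invariant holds by construction
        if q:
            w, U = np.linalg.eigh(G)
            G = (U * np.clip(w, 0.0, None)) @ U.T
        pe = {c: max(float(sigma[k + m]), 0.0) for m, c in enumerate(mm.pe_channels)}
        k += len(mm.pe_channels)
        resid = {t: float(sigma[k + m]) for m, t in enumerate(mm.resid_traits)}
        return cls(GeneticCovariance(mm.gchannels, G), pe, resid)


def _build_V(mm: ModelMatrices, sigma: np.ndarray) -> np.ndarray:
    n = mm.n
    V = np.zeros((n, n))
    k = 0
    for pair in mm.genetic_pairs():
        s = sigma[k]
        if s != 0.0:
            V += s * mm.K[pair]
        k += 1
    for M in mm.Kpe:
        s = sigma[k]
        if s != 0.0:
            V += s * M
        k += 1
    d = np.zeros(n)
    for t in mm.resid_traits:
        d[mm.resid_masks[t]] = sigma[k]
        k += 1
    V[np.diag_indices(n)] += d
    return V


def _reml_core(mm: ModelMatrices, sigma: np.ndarray):
    """Cholesky pieces of the restricted likelihood; None if V not PD."""
    V = _build_V(mm, sigma)
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    ViY = linalg.cho_solve((c, low), mm.y, check_finite=False)
    ViX = linalg.cho_solve((c, low), mm.X, check_finite=False)
    W = mm.X.T @ ViX
    try:
        wc = linalg.cho_factor(W, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    beta = linalg.cho_solve(wc, mm.X.T @ ViY, check_finite=False)
    Py = ViY - ViX @ beta
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    logdetW = 2.0 * np.sum(np.log(np.diag(wc[0])))
    quad = float(mm.y @ Py)
    n, p = mm.n, mm.p
    logl = -0.5 * ((n - p) * LOG2PI - mm.logdetXtX + logdetV + logdetW + quad)
    return dict(logl=logl, chol=(c, low), ViX=ViX, W=W, wc=wc, beta=beta, Py=Py)


def _loglik_sigma(mm: ModelMatrices, sigma: np.ndarray) -> float | None:
    core = _reml_core(mm, sigma)
    return None if core is None else core["logl"]


def _loglik_grad_sigma(mm: ModelMatrices, sigma: np.ndarray, want_ai: bool = False):
    """Restricted log-likelihood, gradient and (optionally) the average-
    information matrix, all in component space.

    dlogL/ds_k = -0.5 [ tr(P K_k) - Py' K_k Py ] with
    P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1; the average information is
    AI_kl = 0.5 (K_k Py)' P (K_l Py).  Everything shares one factorization.
    """
    core = _reml_core(mm, sigma)
    if core is None:
        return (None, None, None) if want_ai else (None, None)
    c, low = core["chol"]
    Vi = linalg.cho_solve((c, low), np.eye(mm.n), check_finite=False)
    ViX = core["ViX"]
    P = Vi - ViX @ linalg.cho_solve(core["wc"], ViX.T, check_finite=False)
    Py = core["Py"]
    grads = []
    tvecs = []
    for pair in mm.genetic_pairs():
        Kk = mm.K[pair]
        t = Kk @ Py
        tvecs.append(t)
        grads.append(-0.5 * (np.vdot(P, Kk) - Py @ t))
    for Kk in mm.Kpe:
        t = Kk @ Py
        tvecs.append(t)
        grads.append(-0.5 * (np.vdot(P, Kk) - Py @ t))
    dP = np.diag(P)
    for tr in mm.resid_traits:
        m = mm.resid_masks[tr]
        t = np.zeros(mm.n)
        t[m] = Py[m]
        tvecs.append(t)
        grads.append(-0.5 * (dP[m].sum() - np.sum(Py[m] ** 2)))
    g = np.array(grads)
    if not want_ai:
        return core["logl"], g
    T = np.column_stack(tvecs)
    ai = 0.5 * (T.T @ (P @ T))
    return core["logl"], g, ai


def reml_loglik(mm: ModelMatrices, vc: VarianceComponents) -> float:
    """Restricted log-likelihood at the given variance components.

    Raises :class:`AdmissibilityError` when the components are inadmissible
    or imply a non-positive-definite phenotypic covariance.
    """
    vc.validate()
    ll = _loglik_sigma(mm, vc.to_sigma(mm))
    if ll is None:
        raise AdmissibilityError("phenotypic covariance V is not positive definite")
    return ll


# ----------------------------------------------------------------------
# Unconstrained reparameterization
# ----------------------------------------------------------------------

class _Parameterization:
    """Map an unconstrained vector theta to the component vector sigma.

    Genetic block: log-Cholesky (diagonal of L on log scale).  A single
    pinned off-diagonal is realized exactly by permuting the two pinned
    channels to the front, where ``L[1, 0] = 0`` implies ``G[0, 1] = 0``.
    PE and residual variances live on the log scale.
    """

    LOG_LO, LOG_HI = -16.0, 5.0
    OFF_LO, OFF_HI = -30.0, 30.0

    def __init__(self, mm: ModelMatrices):
        self.mm = mm
        q = len(mm.gchannels)
        self.q = q
        pin_pairs = [
            (i, j) for (i, j) in mm.genetic_pairs() if i != j and mm.is_pinned(i, j)
        ]
        if len(pin_pairs) > 1:
            raise NotImplementedError(
                "at most one pinned genetic covariance per fit is supported"
            )
        perm = list(range(q))
        self.zero_entry = None
        if pin_pairs:
            i, j = pin_pairs[0]
            rest = [k for k in range(q) if k not in (i, j)]
            perm = [i, j] + rest
            self.zero_entry = (1, 0)
        self.perm = perm
        self.tril = [
            (r, c) for r in range(q) for c in range(r + 1)
            if (r, c) != self.zero_entry
        ]
        self.n_theta = len(self.tril) + len(mm.pe_channels) + len(mm.resid_traits)

    def bounds(self):
        b = []
        for r, c in self.tril:
            b.append((self.LOG_LO, self.LOG_HI) if r == c else (self.OFF_LO, self.OFF_HI))
        b.extend([(self.LOG_LO, self.LOG_HI)] * (len(self.mm.pe_channels) + len(self.mm.resid_traits)))
        return b

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        q = self.q
        L = np.zeros((q, q))
        for t, (r, c) in zip(theta, self.tril):
            L[r, c] = math.exp(min(t, self.LOG_HI)) if r == c else t
        Gp = L @ L.T
        G = np.zeros((q, q))
        for a in range(q):
            for b in range(q):
                G[self.perm[a], self.perm[b]] = Gp[a, b]
        vals = []
        for i, j in self.mm.genetic_pairs():
            vals.append(G[i, j])
        off = len(self.tril)
        for t in theta[off:]:
            vals.append(math.exp(min(t, self.LOG_HI)))
        return np.array(vals)

    def jacobian(self, theta: np.ndarray, h: float = 1e-6) -> np.ndarray:
        """d sigma / d theta by central differences (theta dimension is small)."""
        J = np.zeros((len(self.mm.component_names()), self.n_theta))
        for t in range(self.n_theta):
            up, dn = theta.copy(), theta.copy()
            up[t] += h
            dn[t] -= h
            J[:, t] = (self.sigma(up) - self.sigma(dn)) / (2 * h)
        return J

    def theta_from(self, vc: VarianceComponents) -> np.ndarray:
        q = self.q
        G = np.zeros((q, q))
        for a in range(q):
            for b in range(q):
                ca, cb = self.mm.gchannels[self.perm[a]], self.mm.gchannels[self.perm[b]]
                G[a, b] = vc.genetic.value(ca, cb)
        if self.zero_entry is not None:
            G[0, 1] = G[1, 0] = 0.0
        jitter = 1e-8 * max(1.0, np.trace(G) / max(q, 1)) if q else 0.0
        theta = []
        if q:
            L = np.linalg.cholesky(G + jitter * np.eye(q))
            for r, c in self.tril:
                theta.append(math.log(max(L[r, c], 1e-7)) if r == c else L[r, c])
        for c in self.mm.pe_channels:
            theta.append(math.log(max(vc.pe[c], 1e-7)))
        for t in self.mm.resid_traits:
            theta.append(math.log(max(vc.residual[t], 1e-7)))
        return np.array(theta)


def _auto_init(mm: ModelMatrices) -> VarianceComponents:
    """Equal split of each trait's phenotypic variance across its channels."""
    q = len(mm.gchannels)
    G = np.zeros((q, q))
    pe = {}
    resid = {}
    for t in mm.resid_traits:
        yv = float(np.var(mm.y[mm.trait_slices[t]]))
        yv = yv if yv > 0 else 1.0
        t_g = [i for i, c in enumerate(mm.gchannels) if c.trait == t]
        t_pe = [c for c in mm.pe_channels if c.trait == t]
        parts = len(t_g) + len(t_pe) + 1
        share = yv / parts
        for i in t_g:
            G[i, i] = share
        for c in t_pe:
            pe[c] = share
        resid[t] = share
    return VarianceComponents(GeneticCovariance(mm.gchannels, G), pe, resid)


# ----------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------

@dataclass
class FittedModel:
    """REML estimates for one model."""

    spec: ModelSpec
    components: VarianceComponents
    loglik: float
    beta: np.ndarray
    fixed_names: list[str]
    converged: bool
    boundary: dict[str, bool]
    se: dict[str, float]
    cov_sigma: np.ndarray | None
    component_names: list[str]
    n_records: int
    trace: list[str] = field(default_factory=list)
    mm: ModelMatrices | None = field(default=None, repr=False)

    def correlation(self, ci: Channel, cj: Channel) -> tuple[float, float]:
        """Genetic correlation between two channels and its delta-method SE.

        Returns ``(nan, nan)`` when either parent variance is boundary-pinned
        (the correlation is then undefined and cannot be tested).
        """
        g = self.components.genetic
        vi, vj = g.value(ci, ci), g.value(cj, cj)
        if vi < BOUNDARY_VARIANCE or vj < BOUNDARY_VARIANCE:
            return float("nan"), float("nan")
        cij = g.value(ci, cj)
        r = cij / math.sqrt(vi * vj)
        se = float("nan")
        if self.cov_sigma is not None:
            names = self.component_names
            try:
                ki = names.index(f"G:{ci.label}|{ci.label}")
                kj = names.index(f"G:{cj.label}|{cj.label}")
                kc = names.index(f"G:{ci.label}|{cj.label}")
            except ValueError:
                kc = names.index(f"G:{cj.label}|{ci.label}")
                ki = names.index(f"G:{ci.label}|{ci.label}")
                kj = names.index(f"G:{cj.label}|{cj.label}")
            # dr/d(vi, vj, cij)
            grad = np.zeros(len(names))
            grad[ki] = -0.5 * cij / (vi ** 1.5 * math.sqrt(vj))
            grad[kj] = -0.5 * cij / (vj ** 1.5 * math.sqrt(vi))
            grad[kc] = 1.0 / math.sqrt(vi * vj)
            var = float(grad @ self.cov_sigma @ grad)
            se = math.sqrt(var) if var > 0 else float("nan")
        return r, se

    def to_frame(self) -> pd.DataFrame:
        """Component table: component, estimate, SE, boundary flag."""
        rows = []
        sig = self.components.to_sigma(self.mm) if self.mm is not None else None
        for k, name in enumerate(self.component_names):
            est = float(sig[k]) if sig is not None else float("nan")
            rows.append(
                (name, est, self.se.get(name, float("nan")),
                 self.boundary.get(name, False))
            )
        return pd.DataFrame(rows, columns=["component", "estimate", "se", "boundary"])


def _flags_and_se(mm: ModelMatrices, sigma: np.ndarray):
    names = mm.component_names()
    boundary = {}
    k = 0
    q = len(mm.gchannels)
    gvar = {}
    for i, j in mm.genetic_pairs():
        if i == j:
            gvar[i] = sigma[k]
        k += 1
    k = 0
    for i, j in mm.genetic_pairs():
        if i == j:
            boundary[names[k]] = sigma[k] < BOUNDARY_VARIANCE
        else:
            vi, vj = gvar[i], gvar[j]
            if vi < BOUNDARY_VARIANCE or vj < BOUNDARY_VARIANCE:
                boundary[names[k]] = True
            else:
                r = sigma[k] / math.sqrt(vi * vj)
                boundary[names[k]] = abs(r) > 1.0 - BOUNDARY_CORRELATION
        k += 1
    for _ in mm.pe_channels:
        boundary[names[k]] = sigma[k] < BOUNDARY_VARIANCE
        k += 1
    for _ in mm.resid_traits:
        boundary[names[k]] = sigma[k] < BOUNDARY_VARIANCE
        k += 1

    se = {}
    cov = None
    _, _, ai = _loglik_grad_sigma(mm, sigma, want_ai=True)
    if ai is not None:
        try:
            cov = np.linalg.pinv(0.5 * (ai + ai.T))
            d = np.diag(cov)
            for nm, v in zip(names, d):
                se[nm] = math.sqrt(v) if v > 0 else float("nan")
        except np.linalg.LinAlgError:
            cov = None
    return boundary, se, cov


def _ai_newton(mm: ModelMatrices, par: _Parameterization, theta0: np.ndarray,
               maxiter: int = 60):
    """Average-information Newton ascent on the unconstrained scale.

    The AI matrix mapped through the reparameterization Jacobian serves as
    a Gauss-Newton Hessian; steps are backtracked until the restricted
    likelihood increases.  Returns (theta, logL, converged) or None when the
    start is inadmissible.
    """
    lb = np.array([b[0] for b in par.bounds()])
    ub = np.array([b[1] for b in par.bounds()])
    theta = np.clip(theta0, lb, ub)
    out = _loglik_grad_sigma(mm, par.sigma(theta), want_ai=True)
    if out[0] is None:
        return None
    ll, g_sigma, ai = out
    converged = False
    for _ in range(maxiter):
        J = par.jacobian(theta)
        g = J.T @ g_sigma
        H = J.T @ ai @ J
        ridge = 1e-8 * max(1.0, np.trace(H) / max(len(theta), 1))
        try:
            step = np.linalg.solve(H + ridge * np.eye(len(theta)), g)
        except np.linalg.LinAlgError:
            step = g
        norm = np.linalg.norm(step)
        if norm > 5.0:  # trust region: log-scale steps beyond this overshoot
            step *= 5.0 / norm
        t, accepted = 1.0, None
        for _ in range(25):
            cand = np.clip(theta + t * step, lb, ub)
            ll2 = _loglik_sigma(mm, par.sigma(cand))
            if ll2 is not None and np.isfinite(ll2) and ll2 > ll - 1e-13:
                accepted = (cand, ll2)
                break
            t *= 0.5
        if accepted is None:
            break
        cand, ll2 = accepted
        dll, dth = ll2 - ll, np.max(np.abs(cand - theta))
        theta = cand
        out = _loglik_grad_sigma(mm, par.sigma(theta), want_ai=True)
        if out[0] is None:
            break
        ll, g_sigma, ai = out
        if dll < 1e-8 * (1.0 + abs(ll)) and dth < 1e-6:
            converged = True
            break
    return theta, ll, converged


def fit(
    mm: ModelMatrices,
    init: VarianceComponents | None = None,
    seed: int = 0,
    restarts: int = 3,
    lbfgs_maxiter: int = 300,
) -> FittedModel:
    """Maximize the restricted likelihood over the admissible region.

    Average-information Newton steps on the unconstrained scale
    (log-Cholesky genetic block, log PE/residual variances) do the heavy
    lifting; a short L-BFGS-B polish with analytic gradients then enforces
    the convergence criteria (relative log-likelihood change < 1e-8,
    parameter change < 1e-6).  ``restarts`` optimizations from seed-jittered
    initial values are run and the best log-likelihood kept; non-convergence
    after the restart budget yields a flagged result, not an exception.
    ``init=None`` uses the automatic equal-split start.
    """
    par = _Parameterization(mm)
    vc0 = init if init is not None else _auto_init(mm)
    theta0 = par.theta_from(vc0)
    rng = np.random.default_rng(seed)
    trace: list[str] = []

    def neg_grad(theta):
        ll, g = _loglik_grad_sigma(mm, par.sigma(theta))
        if ll is None or not np.isfinite(ll):
            return 1e10, np.zeros_like(theta)
        J = par.jacobian(theta)
        return -ll, -(J.T @ g)

    best = None
    best_success = False
    for r in range(max(restarts, 1)):
        th = theta0 if r == 0 else theta0 + rng.normal(0.0, 0.3, size=theta0.shape)
        newton = _ai_newton(mm, par, th)
        if newton is not None:
            th = newton[0]
        res = optimize.minimize(
            neg_grad, th, jac=True, method="L-BFGS-B", bounds=par.bounds(),
            options={"maxiter": lbfgs_maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        success = bool(res.success) or (newton is not None and newton[2])
        trace.append(
            f"restart {r}: logL={-res.fun:.6f} nit={res.nit} success={success}"
        )
        if best is None or res.fun < best.fun - 1e-9:
            best, best_success = res, success
        elif res.fun < best.fun + 1e-9:
            best_success = best_success or success

    sigma = par.sigma(best.x)
    # zero-out boundary dust so the returned components satisfy their invariants
    sigma = np.where(np.abs(sigma) < 1e-12, 0.0, sigma)
    vc = VarianceComponents.from_sigma(mm, sigma)
    core = _reml_core(mm, sigma)
    logl = core["logl"] if core is not None else -best.fun
    boundary, se, cov = _flags_and_se(mm, sigma)
    return FittedModel(
        spec=mm.spec,
        components=vc,
        loglik=float(logl),
        beta=core["beta"] if core is not None else np.full(mm.p, np.nan),
        fixed_names=mm.fixed_names,
        converged=best_success,
        boundary=boundary,
        se=se,
        cov_sigma=cov,
        component_names=mm.component_names(),
        n_records=mm.n,
        trace=trace,
        mm=mm,
    )


def expand_components(mm: ModelMatrices, vc: VarianceComponents) -> VarianceComponents:
    """Embed a reduced model's components into ``mm``'s full pattern.

    Channels absent from the reduced fit get zero variance; pinned
    covariances stay zero.  Used to warm-restart a full fit from a
    constrained solution (the constrained optimum is always admissible for
    the full model).
    """
    q = len(mm.gchannels)
    G = np.zeros((q, q))
    src = vc.genetic.channels
    for a in range(q):
        for b in range(q):
            ca, cb = mm.gchannels[a], mm.gchannels[b]
            if ca in src and cb in src:
                G[a, b] = vc.genetic.value(ca, cb)
    pe = {c: vc.pe.get(c, 0.0) for c in mm.pe_channels}
    resid = {t: vc.residual[t] for t in mm.resid_traits}
    return VarianceComponents(GeneticCovariance(mm.gchannels, G), pe, resid)


def refit_if_beaten(
    full: FittedModel,
    reduced: Sequence[FittedModel],
    mm: ModelMatrices,
    seed: int = 0,
) -> FittedModel:
    """Guard against a constrained fit numerically beating the full fit.

    If any reduced log-likelihood exceeds the full one (possible only
    through optimizer noise near a boundary), the full model is refit from
    that reduced solution and the better result kept, restoring the nesting
    inequality before LRTs are formed.
    """
    best = max(reduced, key=lambda f: f.loglik, default=None)
    if best is None or best.loglik <= full.loglik + 1e-9:
        return full
    refit = fit(mm, init=expand_components(mm, best.components),
                seed=seed, restarts=1)
    return refit if refit.loglik > full.loglik else full


def fit_constrained(
    mm: ModelMatrices,
    constraints: Iterable[Constraint],
    seed: int = 0,
    init: VarianceComponents | None = None,
    **kwargs,
) -> FittedModel:
    """REML fit with components pinned (reduced model for an LRT).

    A constrained genetic variance removes the channel from the
    parameterization; a constrained covariance pins the off-diagonal at
    zero.  The returned log-likelihood can exceed the full fit's only by
    numerical slack.
    """
    constraints = list(constraints)
    mm2 = mm.with_constraints(constraints)
    init2 = None
    if init is not None:
        q = len(mm2.gchannels)
        G = np.zeros((q, q))
        for a in range(q):
            for b in range(q):
                ca, cb = mm2.gchannels[a], mm2.gchannels[b]
                if frozenset((ca, cb)) in mm2.pinned and a != b:
                    continue
                G[a, b] = init.genetic.value(ca, cb)
        try:
            gc = GeneticCovariance(mm2.gchannels, G)
        except ValueError:
            gc = GeneticCovariance(mm2.gchannels, np.diag(np.diag(G)))
        init2 = VarianceComponents(
            gc,
            {c: init.pe[c] for c in mm2.pe_channels},
            {t: init.residual[t] for t in mm2.resid_traits},
        )
    return fit(mm2, init=init2, seed=seed, **kwargs)
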