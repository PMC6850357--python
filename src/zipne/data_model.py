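"""Domain types, validation, and CSV/YAML I/O for mark-resight data.

Encounter data consist of per-individual identified-resighting count
histories ``y_{s,t}`` (with release occasions ``b_s``), per-occasion totals
of unidentified-mark sightings ``e_t`` and unmarked sightings ``u_t``, and
study-design facts: cohort sizes ``R_t`` and whether the number of marks
on the study area ``n_t`` is known for each occasion.

Model structure (which estimator, which heterogeneity form, and how each
parameter family is constrained over occasions) lives in :class:`ModelSpec`.
Occasions are 1-based throughout the public API (``t = 1..T``); internal
arrays are 0-indexed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

__all__ = [
    "EncounterData",
    "ParameterSet",
    "ModelSpec",
    "ParameterMapping",
    "read_encounter_data",
    "write_encounter_data",
    "read_model_spec",
    "validate_model_spec",
    "PARAM_FAMILIES",
]


# ---------------------------------------------------------------------------
# Encounter data
# ---------------------------------------------------------------------------

@dataclass
class EncounterData:
    """Mark-resight encounter data for ``T`` sighting occasions.

    Attributes
    ----------
    T : int
        Number of sighting occasions.
    y : (M_T, T) int array
        Identified resighting counts per marked individual and occasion.
    b : (M_T,) int array
        First occasion (1-based) at which each individual was marked and
        available for resighting.  ``y[s, t] == 0`` for ``t < b[s]``.
    e : (T,) int array
        Per-occasion totals of marked-but-unidentified sightings.
    u : (T,) int array
        Per-occasion totals of unmarked-individual sightings.
    R : (T,) int array
        Number of individuals newly marked before each occasion.
    n_known : (T,) bool array
        Whether the number of marks on the study area is known at ``t``.
    n : (T,) int array
        Known mark counts; only meaningful where ``n_known`` is True.
    """

    T: int
    y: np.ndarray
    b: np.ndarray
    e: np.ndarray
    u: np.ndarray
    R: np.ndarray
    n_known: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.y.ndim != 2:
            raise ValueError("y must be a 2-D (individuals x occasions) array")
        self.b = np.asarray(self.b, dtype=np.int64)
        self.e = np.asarray(self.e, dtype=np.int64)
        self.u = np.asarray(self.u, dtype=np.int64)
        self.R = np.asarray(self.R, dtype=np.int64)
        self.n_known = np.asarray(self.n_known, dtype=bool)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        T = self.T
        if T < 1:
            raise ValueError("T must be >= 1")
        M_T = self.y.shape[0]
        if self.y.shape[1] != T:
            raise ValueError(f"y has {self.y.shape[1]} columns but T={T}")
        for name in ("e", "u", "R", "n_known", "n"):
            v = getattr(self, name)
            if v.shape != (T,):
                raise ValueError(f"{name} must have length T={T}, got {v.shape}")
        if self.b.shape != (M_T,):
            raise ValueError("b must have one entry per row of y")
        if np.any((self.b < 1) | (self.b > T)):
            raise ValueError("release occasions b must lie in 1..T")
        if np.any(self.y < 0) or np.any(self.e < 0) or np.any(self.u < 0):
            raise ValueError("counts must be non-negative")
        # no sightings before release
        occ = np.arange(1, T + 1)
        before = occ[None, :] < self.b[:, None]
        bad = np.flatnonzero(np.any(self.y * before > 0, axis=1))
        if bad.size:
            raise ValueError(f"sighting before release for individual row {bad[0]}")
        tab = np.bincount(self.b, minlength=T + 1)[1:]
        if not np.array_equal(tab, self.R):
            raise ValueError("cohort sizes R inconsistent with release occasions b")
        M_t = np.cumsum(self.R)
        if np.any(self.n_known & (self.n > M_t)):
            raise ValueError("known n_t exceeds number of marks ever released M_t")

    # -- derived ------------------------------------------------------------
    @property
    def M_T(self) -> int:
        """Total number of marked individuals ever released."""
        return int(self.y.shape[0])

    @property
    def M_t(self) -> np.ndarray:
        """Cumulative number of marks released before each occasion."""
        return np.cumsum(self.R)

    def seen(self) -> np.ndarray:
        """Boolean (M_T, T): individual identified at least once at ``t``."""
        return self.y > 0


def write_encounter_data(data: EncounterData, path: str | Path) -> None:
    """Write ``individuals.csv`` and ``occasions.csv`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cols = {"id": np.arange(1, data.M_T + 1), "b": data.b}
    for t in range(data.T):
        cols[f"y{t + 1}"] = data.y[:, t]
    pd.DataFrame(cols).to_csv(path / "individuals.csv", index=False)
    occ = pd.DataFrame(
        {
            "t": np.arange(1, data.T + 1),
            "e": data.e,
            "u": data.u,
            "n_known": data.n_known.astype(int),
            "n": [int(n) if k else "" for n, k in zip(data.n, data.n_known)],
        }
    )
    occ.to_csv(path / "occasions.csv", index=False)


def read_encounter_data(path: str | Path) -> EncounterData:
    """Read encounter data from a directory with the two CSV files.

    Expects ``individuals.csv`` (columns ``id, b, y1..yT``) and
    ``occasions.csv`` (columns ``t, e, u, n_known, n``; ``n`` blank where
    unknown).  All invariants are enforced; malformed input raises
    ``ValueError`` naming the offending row.
    """
    path = Path(path)
    ind = pd.read_csv(path / "individuals.csv")
    occ = pd.read_csv(path / "occasions.csv")
    ycols = [c for c in ind.columns if c.startswith("y")]
    T_ind = len(ycols)
    if sorted(ycols) != sorted(f"y{t}" for t in range(1, T_ind + 1)):
        raise ValueError(f"individuals.csv count columns malformed: {ycols}")
    if len(occ) != T_ind:
        raise ValueError(
            f"inconsistent T: individuals.csv has {T_ind} occasions, "
            f"occasions.csv has {len(occ)} rows"
        )
    occ = occ.sort_values("t")
    if not np.array_equal(occ["t"].to_numpy(), np.arange(1, T_ind + 1)):
        raise ValueError("occasions.csv must cover t = 1..T exactly once")
    y = ind[[f"y{t}" for t in range(1, T_ind + 1)]].to_numpy(dtype=np.int64)
    b = ind["b"].to_numpy(dtype=np.int64)
    n_known = occ["n_known"].to_numpy().astype(bool)
    n_raw = occ["n"].to_numpy()
    n = np.zeros(T_ind, dtype=np.int64)
    for i, (known, v) in enumerate(zip(n_known, n_raw)):
        if known:
            if pd.isna(v):
                raise ValueError(f"occasions.csv row t={i + 1}: n_known but n blank")
            n[i] = int(v)
    R = np.bincount(b, minlength=T_ind + 1)[1:]
    return EncounterData(
        T=T_ind,
        y=y,
        b=b,
        e=occ["e"].to_numpy(dtype=np.int64),
        u=occ["u"].to_numpy(dtype=np.int64),
        R=R,
        n_known=n_known,
        n=n,
    )


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

#: family name -> (length given T, link)
PARAM_FAMILIES: dict[str, tuple[str, str]] = {
    "alpha": ("T", "identity"),
    "sigma": ("T", "log"),
    "r": ("T", "logit"),
    "w": ("T", "logit"),
    "g": ("T", "logit"),
    "phi": ("T-1", "logit"),
    "gammaPP": ("T-1", "logit"),
    "gammaP": ("T-1", "logit"),
    "U": ("T", "log"),
}

_PROB_EPS = 1e-12


def _family_len(family: str, T: int) -> int:
    return T if PARAM_FAMILIES[family][0] == "T" else max(T - 1, 0)


def _link(link: str, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if link == "identity":
        return x
    if link == "log":
        return np.log(np.maximum(x, 1e-300))
    return logit(np.clip(x, _PROB_EPS, 1.0 - _PROB_EPS))


def _link_inv(link: str, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if link == "identity":
        return x
    if link == "log":
        return np.exp(x)
    return expit(x)


@dataclass
class ParameterSet:
    """All model parameters on the natural scale.

    ``alpha`` and ``sigma`` are the log-scale mean and SD of the individual
    sighting rate; ``r`` the mark-identification probability; ``w`` the
    probability a new mark was alive and not a permanent emigrant at its
    release occasion and ``g`` the conditional probability it was on the
    study area; ``phi`` apparent survival per interval; ``gammaPP`` the
    observable-to-unobservable and ``gammaP`` the unobservable-to-
    unobservable temporary-emigration transition probabilities; ``U`` the
    unmarked observable population sizes.
    """

    alpha: np.ndarray
    sigma: np.ndarray
    r: np.ndarray
    w: np.ndarray
    g: np.ndarray
    phi: np.ndarray
    gammaPP: np.ndarray
    gammaP: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        for name in PARAM_FAMILIES:
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        self.validate()

    @property
    def T(self) -> int:
        return len(self.alpha)

    def validate(self) -> None:
        T = self.T
        for name, (length, _) in PARAM_FAMILIES.items():
            v = getattr(self, name)
            want = T if length == "T" else T - 1
            if len(v) != want:
                raise ValueError(f"{name} must have length {want} for T={T}, got {len(v)}")
        for name in ("r", "w", "g", "phi", "gammaPP", "gammaP"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        if np.any(self.U <= 0):
            raise ValueError("U must be positive")

    @classmethod
    def constant(cls, T: int, **values: float) -> "ParameterSet":
        """Build a time-constant parameter set from scalars (convenience)."""
        defaults = dict(alpha=0.0, sigma=0.0, r=1.0, w=1.0, g=1.0,
                        phi=1.0, gammaPP=0.0, gammaP=0.0, U=100.0)
        defaults.update(values)
        kw = {}
        for name in PARAM_FAMILIES:
            ln = _family_len(name, T)
            kw[name] = np.full(ln, float(defaults[name]))
        return cls(**kw)

    def to_dict(self) -> dict[str, list[float]]:
        return {name: np.asarray(getattr(self, name)).tolist() for name in PARAM_FAMILIES}


# ---------------------------------------------------------------------------
# Model specification and design resolution
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Estimator variant plus the constraint design for each parameter family.

    ``designs`` maps family names to one of:

    - ``"constant"`` — one shared link-scale coefficient across occasions;
    - ``"time"`` — one free coefficient per occasion (fully time-dependent);
    - ``{"fixed": value-or-list}`` — no free coefficients, fixed natural values;
    - ``{"design": "constant"|"time", "fixed": {occasion: value}}`` — some
      occasions pinned at natural values, the rest following the base design;
    - ``{"matrix": 2-D list}`` — an explicit link-scale design matrix
      (rows = occasions, columns = free coefficients);
    - ``{"tie": other_family}`` — equality constraint, e.g. random temporary
      emigration ``gammaPP = gammaP``.

    Unlisted families default to ``"constant"``.
    """

    estimator: str = "ziPNE"
    heterogeneity: str = "within"
    L: int = 101
    designs: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.estimator not in ("ziPNE", "ztPNE"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.heterogeneity not in ("none", "within", "across"):
            raise ValueError(f"unknown heterogeneity mode {self.heterogeneity!r}")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        unknown = set(self.designs) - set(PARAM_FAMILIES)
        if unknown:
            raise ValueError(f"designs refer to unknown parameter families: {sorted(unknown)}")
        if self.heterogeneity == "none" and "sigma" not in self.designs:
            self.designs = {**self.designs, "sigma": {"fixed": 0.0}}

    def with_estimator(self, estimator: str) -> "ModelSpec":
        return replace(self, estimator=estimator)


@dataclass
class _FamilyDesign:
    """Resolved design for one parameter family."""

    family: str
    link: str
    X: np.ndarray              # (n_occ, k) link-scale design for free rows
    fixed_mask: np.ndarray     # (n_occ,) True where pinned at a natural value
    fixed_values: np.ndarray   # natural values where pinned
    tie_to: str | None = None

    @property
    def k(self) -> int:
        return 0 if self.tie_to else self.X.shape[1]


def _resolve_family(family: str, design: Any, T: int) -> _FamilyDesign:
    n = _family_len(family, T)
    link = PARAM_FAMILIES[family][1]
    fixed_mask = np.zeros(n, dtype=bool)
    fixed_values = np.zeros(n, dtype=float)

    def base_matrix(kind: str, free: np.ndarray) -> np.ndarray:
        nfree = int(free.sum())
        if nfree == 0:
            return np.zeros((n, 0))
        if kind == "constant":
            X = np.zeros((n, 1))
            X[free, 0] = 1.0
            return X
        # fully time-dependent: identity over free rows
        X = np.zeros((n, nfree))
        X[np.flatnonzero(free), np.arange(nfree)] = 1.0
        return X

    if design is None:
        design = "constant"
    if isinstance(design, str):
        if design not in ("constant", "time"):
            raise ValueError(f"unknown design {design!r} for {family}")
        return _FamilyDesign(family, link, base_matrix(design, np.ones(n, bool)),
                             fixed_mask, fixed_values)
    if isinstance(design, Mapping):
        if "tie" in design:
            target = design["tie"]
            if target not in PARAM_FAMILIES or _family_len(target, T) != n:
                raise ValueError(f"cannot tie {family} to {target}")
            return _FamilyDesign(family, link, np.zeros((n, 0)), fixed_mask,
                                 fixed_values, tie_to=target)
        if "matrix" in design:
            X = np.asarray(design["matrix"], dtype=float)
            if X.shape[0] != n:
                raise ValueError(f"design matrix for {family} must have {n} rows")
            return _FamilyDesign(family, link, X, fixed_mask, fixed_values)
        if "fixed" in design and "design" not in design:
            vals = np.broadcast_to(np.asarray(design["fixed"], dtype=float), (n,)).copy()
            fixed_mask[:] = True
            return _FamilyDesign(family, link, np.zeros((n, 0)), fixed_mask, vals)
        if "design" in design:
            pins: Mapping[int, float] = design.get("fixed", {})
            for occ, val in pins.items():
                idx = int(occ) - 1
                if not 0 <= idx < n:
                    raise ValueError(f"fixed occasion {occ} out of range for {family}")
                fixed_mask[idx] = True
                fixed_values[idx] = float(val)
            X = base_matrix(design["design"], ~fixed_mask)
            return _FamilyDesign(family, link, X, fixed_mask, fixed_values)
    raise ValueError(f"cannot interpret design {design!r} for {family}")


class ParameterMapping:
    """Maps a flat free link-scale coefficient vector to a :class:`ParameterSet`.

    Resolved from a :class:`ModelSpec` and a number of occasions ``T``.
    Fixed natural values respect parameter ranges; design matrices must have
    full column rank.
    """

    def __init__(self, spec: ModelSpec, T: int):
        self.spec = spec
        self.T = T
        self.families: dict[str, _FamilyDesign] = {}
        order = list(PARAM_FAMILIES)
        for family in order:
            fd = _resolve_family(family, spec.designs.get(family), T)
            if fd.k and np.linalg.matrix_rank(fd.X[~fd.fixed_mask]) < fd.k:
                raise ValueError(f"design matrix for {family} is rank-deficient")
            self.families[family] = fd
        # tie targets must not themselves be ties
        for fd in self.families.values():
            if fd.tie_to and self.families[fd.tie_to].tie_to:
                raise ValueError("chained parameter ties are not supported")
        self._slices: dict[str, slice] = {}
        pos = 0
        for family in order:
            k = self.families[family].k
            self._slices[family] = slice(pos, pos + k)
            pos += k
        self.n_free = pos

    @property
    def free_names(self) -> list[str]:
        names = []
        for family, sl in self._slices.items():
            for j in range(sl.stop - sl.start):
                names.append(f"{family}[{j}]")
        return names

    def to_params(self, beta: np.ndarray) -> ParameterSet:
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} free coefficients, got {beta.shape}")
        natural: dict[str, np.ndarray] = {}
        for family, fd in self.families.items():
            if fd.tie_to:
                continue
            vals = np.empty(_family_len(family, self.T))
            vals[fd.fixed_mask] = fd.fixed_values[fd.fixed_mask]
            free = ~fd.fixed_mask
            if fd.k:
                eta = fd.X[free] @ beta[self._slices[family]]
                vals[free] = _link_inv(fd.link, eta)
            elif free.any():
                raise ValueError(f"family {family} has free occasions but no design columns")
            natural[family] = vals
        for family, fd in self.families.items():
            if fd.tie_to:
                natural[family] = natural[fd.tie_to].copy()
        return ParameterSet(**natural)

    def to_beta(self, params: ParameterSet) -> np.ndarray:
        """Best link-scale coefficients reproducing ``params`` (least squares)."""
        beta = np.zeros(self.n_free)
        for family, fd in self.families.items():
            if fd.k == 0:
                continue
            free = ~fd.fixed_mask
            eta = _link(fd.link, np.asarray(getattr(params, family))[free])
            sol, *_ = np.linalg.lstsq(fd.X[free], eta, rcond=None)
            beta[self._slices[family]] = sol
        return beta


def read_model_spec(path: str | Path) -> ModelSpec:
    """Read a model specification from a YAML file (schema in README)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return ModelSpec(
        estimator=doc.get("estimator", "ziPNE"),
        heterogeneity=doc.get("heterogeneity", "within"),
        L=int(doc.get("L", 101)),
        designs=doc.get("designs", {}) or {},
    )


def validate_model_spec(spec: ModelSpec, data: EncounterData) -> list[str]:
    """Check a model specification against data; return estimability warnings.

    In a fully time-dependent model for ``w`` and ``g`` only the product
    ``w_T * g_T`` is estimable; with ``T == 1`` only ``w_1 * g_1`` is.
    Rank-deficient design matrices raise ``ValueError``.
    """
    mapping = ParameterMapping(spec, data.T)  # raises on rank deficiency
    warnings: list[str] = []
    T = data.T

    def last_free(family: str) -> bool:
        fd = mapping.families[family]
        if fd.tie_to or fd.k == 0:
            return False
        if fd.fixed_mask[-1]:
            return False
        # fully time-dependent means the last occasion has its own column
        col = fd.X[-1]
        return np.count_nonzero(col) == 1 and np.count_nonzero(fd.X[:, col.argmax()]) == 1

    if T == 1:
        wfd, gfd = mapping.families["w"], mapping.families["g"]
        if wfd.k and gfd.k and not wfd.fixed_mask[0] and not gfd.fixed_mask[0]:
            warnings.append(
                "with T=1, w_1 and g_1 are not separately estimable: "
                "only the product w_1*g_1 is identified"
            )
    elif last_free("w") and last_free("g"):
        warnings.append(
            f"fully time-dependent w and g: w_{T} and g_{T} are not separately "
            f"estimable, only the product w_{T}*g_{T} is identified"
        )
    return warnings
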