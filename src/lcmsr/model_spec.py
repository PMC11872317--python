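"""Symbolic LCM-SR model specifications and their RAM-matrix compilation.

A latent curve model with structured residuals (LCM-SR) decomposes each
observed score into a between-person growth part (per-burst random
intercepts, optionally per-burst slopes) and a latent wave-specific
residual. The residuals carry the within-person dynamics: first-order
autoregressions within a construct, cross-lagged regressions between
constructs, and within-wave cross-construct covariances.

Builders emit :class:`ModelSpec` objects (sets of typed paths with free
parameters identified by string labels); :func:`compile_spec` realizes a
spec as RAM matrices (A: directed paths, S: variances/covariances, M:
means, F: observed-variable filter) for the FIML machinery.

Label conventions (parsed by start-value and reporting code)::

    resvar_{c}_{t}    latent residual (wave-1 marginal / innovation) variance
    ar_{c}_{t}        autoregression residual t -> t+1 within construct c
    cl_{a}_{b}_{t}    cross-lag residual a_t -> b_{t+1}
    wcov_{a}_{b}_{t}  within-wave residual covariance at wave t
    imean_{c}_{b}     random-intercept mean, construct c, burst b
    ivar_{c}_{b}      random-intercept variance
    icov_{c1}{b1}_{c2}{b2}  intercept-intercept covariance (zeta)
    smean_{c}_{b}     slope mean; svar / scov / sicov analogous
    omean_{c}_{t}     observed-variable mean (level-1 models only)
    covvar/covmean/ccov_{...}  exogenous time-varying covariate moments
    tvc_{x}_{c}_{t}   covariate x_t -> residual c_t regression
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PathSpec",
    "ModelSpec",
    "RAMMatrices",
    "build_univariate",
    "build_bivariate",
    "add_time_varying_covariate",
    "split_groups",
    "compile_spec",
    "decompile",
    "canonical_bivariate",
]

PATH_KINDS = ("loading", "regression", "variance", "covariance", "mean")


@dataclass(frozen=True)
class PathSpec:
    """One typed path: fixed to a value, or free with a (shareable) label."""

    src: str
    dst: str
    kind: str
    value: float | None = None  # fixed value; None when free
    label: str | None = None  # free-parameter label; None when fixed

    def __post_init__(self):
        if self.kind not in PATH_KINDS:
            raise ValueError(f"unknown path kind {self.kind!r}")
        if (self.value is None) == (self.label is None):
            raise ValueError("a path is either fixed(value) or free(label)")
        if self.value is not None and not np.isfinite(self.value):
            raise ValueError("fixed paths must carry a finite value")

    @property
    def free(self) -> bool:
        return self.label is not None


@dataclass
class ModelSpec:
    """Symbolic model: variables plus a list of typed paths."""

    observed_vars: list[str]
    latent_vars: list[str]
    paths: list[PathSpec]
    meta: dict = field(default_factory=dict)

    def free_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.paths:
            if p.free and p.label not in seen:
                seen[p.label] = None
        return list(seen)

    @property
    def n_free(self) -> int:
        return len(self.free_labels())

    def structural_df(self) -> int:
        """Degrees of freedom against the saturated mean+covariance model."""
        p = len(self.observed_vars)
        return p * (p + 1) // 2 + p - self.n_free

    def copy(self) -> "ModelSpec":
        return ModelSpec(
            list(self.observed_vars), list(self.latent_vars), list(self.paths), dict(self.meta)
        )


# ---------------------------------------------------------------------------
# builders


def _check_bursts(bursts: Sequence[Sequence[int]], n_waves: int) -> list[list[int]]:
    flat = [w for b in bursts for w in b]
    if sorted(flat) != list(range(1, n_waves + 1)):
        raise ValueError("bursts must partition waves 1..n_waves")
    for b in bursts:
        if list(b) != list(range(b[0], b[0] + len(b))):
            raise ValueError("each burst must be a contiguous block of waves")
    return [list(b) for b in bursts]


def build_univariate(
    construct: str,
    model_level: int,
    n_waves: int = 14,
    bursts: Sequence[Sequence[int]] | None = None,
) -> ModelSpec:
    """Univariate model ladder, levels 1-4.

    Level 1: latent autoregressive residuals only, free per-wave observed
    means. Level 2 adds per-burst random intercepts (which then carry the
    means; observed means fixed to 0). Level 3 adds per-burst slopes with
    free mean but zero variance ("fixed slopes", loadings 0,1,2,... within
    burst). Level 4 frees the slope variances and the covariances among all
    growth factors.
    """
    if model_level not in (1, 2, 3, 4):
        raise ValueError(f"model_level must be 1..4, got {model_level}")
    if n_waves < 2:
        raise ValueError("n_waves must be >= 2")
    if bursts is None:
        if n_waves == 14:
            bursts = [list(range(1, 8)), list(range(8, 15))]
        else:
            bursts = [list(range(1, n_waves + 1))]
    bursts = _check_bursts(bursts, n_waves)
    c = construct
    obs = [f"{c}{t}" for t in range(1, n_waves + 1)]
    res = [f"R_{c}{t}" for t in range(1, n_waves + 1)]
    paths: list[PathSpec] = []

    for t in range(1, n_waves + 1):
        o, r = f"{c}{t}", f"R_{c}{t}"
        paths.append(PathSpec(r, o, "loading", value=1.0))
        paths.append(PathSpec(o, o, "variance", value=0.0))
        paths.append(PathSpec(r, r, "variance", label=f"resvar_{c}_{t}"))
        if model_level == 1:
            paths.append(PathSpec(o, o, "mean", label=f"omean_{c}_{t}"))
        else:
            paths.append(PathSpec(o, o, "mean", value=0.0))
    for t in range(1, n_waves):
        paths.append(PathSpec(f"R_{c}{t}", f"R_{c}{t+1}", "regression", label=f"ar_{c}_{t}"))

    latent = list(res)
    if model_level >= 2:
        ris = []
        for b, waves in enumerate(bursts, start=1):
            ri = f"RI_{c}{b}"
            ris.append(ri)
            latent.append(ri)
            for t in waves:
                paths.append(PathSpec(ri, f"{c}{t}", "loading", value=1.0))
            paths.append(PathSpec(ri, ri, "mean", label=f"imean_{c}_{b}"))
            paths.append(PathSpec(ri, ri, "variance", label=f"ivar_{c}_{b}"))
        for (b1, r1), (b2, r2) in itertools.combinations(enumerate(ris, start=1), 2):
            paths.append(PathSpec(r1, r2, "covariance", label=f"icov_{c}{b1}_{c}{b2}"))
    if model_level >= 3:
        sls = []
        for b, waves in enumerate(bursts, start=1):
            sl = f"S_{c}{b}"
            sls.append(sl)
            latent.append(sl)
            for j, t in enumerate(waves):
                if j > 0:  # loading 0 at burst start contributes nothing
                    paths.append(PathSpec(sl, f"{c}{t}", "loading", value=float(j)))
            paths.append(PathSpec(sl, sl, "mean", label=f"smean_{c}_{b}"))
            if model_level == 3:
                paths.append(PathSpec(sl, sl, "variance", value=0.0))
            else:
                paths.append(PathSpec(sl, sl, "variance", label=f"svar_{c}_{b}"))
        if model_level == 4:
            for (b1, s1), (b2, s2) in itertools.combinations(enumerate(sls, start=1), 2):
                paths.append(PathSpec(s1, s2, "covariance", label=f"scov_{c}{b1}_{c}{b2}"))
            for sb, sl in enumerate(sls, start=1):
                for ib in range(1, len(bursts) + 1):
                    paths.append(
                        PathSpec(sl, f"RI_{c}{ib}", "covariance", label=f"sicov_{c}_{sb}_{ib}")
                    )

    meta = {
        "constructs": [c],
        "n_waves": n_waves,
        "bursts": bursts,
        "levels": {c: model_level},
        "slope_coding": {c: {b: list(range(len(w))) for b, w in enumerate(bursts, start=1)}}
        if model_level >= 3
        else {},
    }
    return ModelSpec(obs, latent, paths, meta)


def build_bivariate(spec_a: ModelSpec, spec_b: ModelSpec) -> ModelSpec:
    """Combine two univariate specs, adding cross-lags and within-wave
    residual covariances.

    Adds, per wave pair (t, t+1): a cross-lag from each construct's
    residual to the other's next residual (labels ``cl_{a}_{b}_{t}`` for
    a_t -> b_{t+1}); per wave t: the within-wave cross-construct residual
    covariance ``wcov_{a}_{b}_{t}``; and all cross-construct random-
    intercept covariances (completing the zeta set).
    """
    if spec_a.meta.get("n_waves") != spec_b.meta.get("n_waves"):
        raise ValueError("constructs must share the wave count")
    if spec_a.meta.get("bursts") != spec_b.meta.get("bursts"):
        raise ValueError("constructs must share the burst structure")
    (a,) = spec_a.meta["constructs"]
    (b,) = spec_b.meta["constructs"]
    n_waves = spec_a.meta["n_waves"]
    bursts = spec_a.meta["bursts"]

    paths = list(spec_a.paths) + list(spec_b.paths)
    for t in range(1, n_waves):
        paths.append(PathSpec(f"R_{a}{t}", f"R_{b}{t+1}", "regression", label=f"cl_{a}_{b}_{t}"))
        paths.append(PathSpec(f"R_{b}{t}", f"R_{a}{t+1}", "regression", label=f"cl_{b}_{a}_{t}"))
    for t in range(1, n_waves + 1):
        paths.append(PathSpec(f"R_{a}{t}", f"R_{b}{t}", "covariance", label=f"wcov_{a}_{b}_{t}"))
    ris_a = [v for v in spec_a.latent_vars if v.startswith("RI_")]
    ris_b = [v for v in spec_b.latent_vars if v.startswith("RI_")]
    for r1 in ris_a:
        for r2 in ris_b:
            b1, b2 = r1.split(a)[-1], r2.split(b)[-1]
            paths.append(PathSpec(r1, r2, "covariance", label=f"icov_{a}{b1}_{b}{b2}"))

    meta = {
        "constructs": [a, b],
        "n_waves": n_waves,
        "bursts": bursts,
        "levels": {**spec_a.meta.get("levels", {}), **spec_b.meta.get("levels", {})},
        "slope_coding": {
            **spec_a.meta.get("slope_coding", {}),
            **spec_b.meta.get("slope_coding", {}),
        },
    }
    return ModelSpec(
        spec_a.observed_vars + spec_b.observed_vars,
        spec_a.latent_vars + spec_b.latent_vars,
        paths,
        meta,
    )


def canonical_bivariate(n_waves: int = 14, bursts=None) -> ModelSpec:
    """The selected model structure: FI with random intercepts (level 2)
    combined with LS with random intercepts and fixed slopes (level 3)."""
    fi = build_univariate("FI", 2, n_waves, bursts)
    ls = build_univariate("LS", 3, n_waves, bursts)
    return build_bivariate(fi, ls)


def add_time_varying_covariate(
    spec: ModelSpec, covariate: str, target: str | Sequence[str] = "both"
) -> ModelSpec:
    """Add an exogenous time-varying covariate regressed on latent residuals.

    ``target`` selects which construct's residuals receive the wave-specific
    regression paths: a construct name, a sequence of names, or ``"both"``.
    The covariate gets free per-wave means and variances; when other
    exogenous covariates are present, within-wave covariances among them
    are freed as well.
    """
    constructs = spec.meta["constructs"]
    if target == "both":
        targets = list(constructs)
    elif isinstance(target, str):
        targets = [target]
    else:
        targets = list(target)
    unknown = [t for t in targets if t not in constructs]
    if unknown:
        raise ValueError(f"unknown target construct(s) {unknown}")
    n_waves = spec.meta["n_waves"]

    out = spec.copy()
    prior_covs = list(out.meta.get("covariates", []))
    for t in range(1, n_waves + 1):
        x = f"{covariate}{t}"
        if x in out.observed_vars:
            raise ValueError(f"covariate column {x} already in model")
        out.observed_vars.append(x)
        out.paths.append(PathSpec(x, x, "variance", label=f"covvar_{covariate}_{t}"))
        out.paths.append(PathSpec(x, x, "mean", label=f"covmean_{covariate}_{t}"))
        for other in prior_covs:
            out.paths.append(
                PathSpec(f"{other}{t}", x, "covariance", label=f"ccov_{other}_{covariate}_{t}")
            )
        for c in targets:
            out.paths.append(
                PathSpec(x, f"R_{c}{t}", "regression", label=f"tvc_{covariate}_{c}_{t}")
            )
    out.meta["covariates"] = prior_covs + [covariate]
    return out


def split_groups(
    spec: ModelSpec,
    groups: Sequence[str],
    equal: Iterable[str] = (),
) -> dict[str, ModelSpec]:
    """Per-group copies of a spec for multiple-group analysis.

    Free labels are suffixed ``@group`` so every parameter is group-specific,
    except labels whose family (leading ``_``-token, e.g. ``wcov``) appears
    in ``equal`` — those keep their label, encoding cross-group equality.
    """
    groups = list(groups)
    if len(groups) == 0 or any(g == "" or g is None for g in groups):
        raise ValueError("groups must be non-empty labels")
    if len(set(groups)) != len(groups):
        raise ValueError("duplicate group labels")
    if len(groups) == 1:
        return {groups[0]: spec.copy()}
    equal = set(equal)
    out = {}
    for g in groups:
        paths = []
        for p in spec.paths:
            if p.free and p.label.split("_", 1)[0] not in equal:
                paths.append(replace(p, label=f"{p.label}@{g}"))
            else:
                paths.append(p)
        gspec = spec.copy()
        gspec.paths = paths
        gspec.meta = {**spec.meta, "group": g}
        out[g] = gspec
    return out


# ---------------------------------------------------------------------------
# RAM compilation


@dataclass
class RAMMatrices:
    """RAM realization of a spec.

    ``A0`` holds directed paths (A[i, j] = path j -> i), ``S0`` symmetric
    variances/covariances, ``M0`` means; free cells are zero in the base
    matrices and are indexed by ``free`` (label -> list of (matrix, i, j)).
    Implied moments are ``mu = F (I-A)^-1 M`` and
    ``Sigma = F (I-A)^-1 S (I-A)^-T F^T``.
    """

    names: list[str]
    obs_idx: np.ndarray
    A0: np.ndarray
    S0: np.ndarray
    M0: np.ndarray
    free: dict[str, list[tuple[str, int, int]]]
    labels: list[str]
    variance_labels: set[str]
    cell_kind: dict[tuple[str, int, int], str]
    spec: ModelSpec | None = None

    @property
    def n_free(self) -> int:
        return len(self.labels)

    @property
    def n_obs_vars(self) -> int:
        return len(self.obs_idx)

    def realize(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fill free cells with parameter values; returns (A, S, M)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise ValueError(f"theta must have length {self.n_free}")
        A = self.A0.copy()
        S = self.S0.copy()
        M = self.M0.copy()
        for val, label in zip(theta, self.labels):
            for mat, i, j in self.free[label]:
                if mat == "A":
                    A[i, j] = val
                elif mat == "S":
                    S[i, j] = val
                    S[j, i] = val
                else:
                    M[i] = val
        return A, S, M

    def implied_moments(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Model-implied mean vector and covariance of the observed variables."""
        A, S, M = self.realize(theta)
        k = A.shape[0]
        B = np.linalg.solve(np.eye(k) - A, np.eye(k))
        total = B @ S @ B.T
        mu = (B @ M)[self.obs_idx]
        sigma = total[np.ix_(self.obs_idx, self.obs_idx)]
        return mu, sigma


def compile_spec(spec: ModelSpec) -> RAMMatrices:
    """Compile a validated :class:`ModelSpec` to RAM matrices.

    Raises on conflicting duplicate paths and on cyclic regression
    structure (the directed-path matrix must be nilpotent).
    """
    names = list(spec.observed_vars) + list(spec.latent_vars)
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable names")
    index = {n: i for i, n in enumerate(names)}
    k = len(names)
    A0 = np.zeros((k, k))
    S0 = np.zeros((k, k))
    M0 = np.zeros(k)
    free: dict[str, list[tuple[str, int, int]]] = {}
    labels: list[str] = []
    cell_owner: dict[tuple[str, int, int], PathSpec] = {}
    cell_kind: dict[tuple[str, int, int], str] = {}

    def claim(mat: str, i: int, j: int, p: PathSpec):
        key = (mat, i, j)
        prior = cell_owner.get(key)
        if prior is not None and (prior.label, prior.value) != (p.label, p.value):
            raise ValueError(f"conflicting paths on cell {key}: {prior} vs {p}")
        if prior is not None:
            return  # identical duplicate is harmless
        cell_owner[key] = p
        cell_kind[key] = p.kind
        if p.free:
            if p.label not in free:
                free[p.label] = []
                labels.append(p.label)
            free[p.label].append(key)
        else:
            if mat == "A":
                A0[i, j] = p.value
            elif mat == "S":
                S0[i, j] = p.value
                S0[j, i] = p.value
            else:
                M0[i] = p.value

    for p in spec.paths:
        try:
            si, di = index[p.src], index[p.dst]
        except KeyError as e:
            raise KeyError(f"path references unknown variable {e}") from None
        if p.kind in ("loading", "regression"):
            claim("A", di, si, p)
        elif p.kind == "variance":
            if si != di:
                raise ValueError(f"variance path must be a self-loop: {p}")
            claim("S", si, si, p)
        elif p.kind == "covariance":
            i, j = min(si, di), max(si, di)
            claim("S", i, j, p)
        else:  # mean
            if si != di:
                raise ValueError(f"mean path must be a self-loop: {p}")
            claim("M", si, si, p)

    # acyclicity: A with all structural cells marked must be nilpotent
    adj = (A0 != 0).astype(float)
    for cells in free.values():
        for mat, i, j in cells:
            if mat == "A":
                adj[i, j] = 1.0
    reach = adj.copy()
    power = adj.copy()
    for _ in range(k):
        power = (power @ adj > 0).astype(float)
        if not power.any():
            break
        reach = ((reach + power) > 0).astype(float)
    else:
        pass
    if np.any(np.diag(reach) > 0) or power.any():
        raise ValueError("cyclic regression structure: A is not nilpotent")

    variance_labels = {
        lab
        for lab, cells in free.items()
        if all(mat == "S" and i == j for mat, i, j in cells)
    }
    obs_idx = np.array([index[v] for v in spec.observed_vars], dtype=int)
    return RAMMatrices(
        names=names,
        obs_idx=obs_idx,
        A0=A0,
        S0=S0,
        M0=M0,
        free=free,
        labels=labels,
        variance_labels=variance_labels,
        cell_kind=cell_kind,
        spec=spec,
    )


def decompile(ram: RAMMatrices) -> set[tuple]:
    """Recover the path set from compiled matrices (round-trip check).

    Returns tuples ``(src, dst, kind, value, label)`` reconstructed from
    matrix cells, comparable with the normalized path set of the source
    spec.
    """
    out = set()
    names = ram.names

    def path_of(key, value, label):
        mat, i, j = key
        kind = ram.cell_kind[key]
        if mat == "A":
            return (names[j], names[i], kind, value, label)
        return (names[min(i, j)], names[max(i, j)], kind, value, label)

    for key, kind in ram.cell_kind.items():
        mat, i, j = key
        owned_free = None
        for lab, cells in ram.free.items():
            if key in cells:
                owned_free = lab
                break
        if owned_free is not None:
            out.add(path_of(key, None, owned_free))
        else:
            val = {"A": ram.A0[i, j], "S": ram.S0[i, j], "M": ram.M0[i]}[mat]
            out.add(path_of(key, float(val), None))
    return out


def normalized_paths(spec: ModelSpec) -> set[tuple]:
    """Spec paths normalized the way :func:`decompile` reports them."""
    index = {n: i for i, n in enumerate(spec.observed_vars + spec.latent_vars)}
    out = set()
    for p in spec.paths:
        if p.kind == "covariance":
            si, di = index[p.src], index[p.dst]
            names = spec.observed_vars + spec.latent_vars
            src, dst = names[min(si, di)], names[max(si, di)]
        else:
            src, dst = p.src, p.dst
        out.add((src, dst, p.kind, None if p.free else float(p.value), p.label))
    return out
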