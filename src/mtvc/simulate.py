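"""Correlated multi-trait phenotype simulation on a genomic kinship.

The generative model is the multi-trait animal model

    y = a + e,   vec(a) ~ N(0, G0 (x) A),   vec(e) ~ N(0, R0 (x) I),

with G0 and R0 the trait-by-trait additive-genetic and residual
covariance matrices and A the genomic relationship matrix.  Sampling
uses the Kronecker identity: with Z an n x t matrix of iid standard
normals, ``a = L_A @ Z @ chol(G0).T`` has ``cov(vec a) = G0 (x) A``
(column-major vec), so the n*t x n*t covariance is never materialized.

The default two-trait architecture has heritabilities 0.1 and 0.5, a
genetic correlation of 0.3 and a residual correlation of 0.1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import RelationshipMatrix, cholesky_psd

__all__ = [
    "TraitArchitecture",
    "ImpliedParameters",
    "SimulatedDataset",
    "ScenarioConfig",
    "default_architecture",
    "implied_parameters",
    "simulate_traits",
    "make_scenario",
]


def _check_spd(C: np.ndarray, name: str) -> None:
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(C)[0] <= 0:
        raise ValueError(f"{name} must be positive definite")


@dataclass(frozen=True)
class TraitArchitecture:
    """Genetic (G0) and residual (R0) trait covariance matrices.

    Both must be symmetric positive definite and imply per-trait
    heritabilities strictly inside (0, 1).
    """

    G0: np.ndarray
    R0: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "G0", np.asarray(self.G0, dtype=float))
        object.__setattr__(self, "R0", np.asarray(self.R0, dtype=float))
        _check_spd(self.G0, "G0")
        _check_spd(self.R0, "R0")
        if self.G0.shape != self.R0.shape:
            raise ValueError("G0 and R0 must have the same shape")
        h2 = np.diag(self.G0) / (np.diag(self.G0) + np.diag(self.R0))
        if not ((h2 > 0) & (h2 < 1)).all():
            raise ValueError("implied heritabilities must lie in (0, 1)")

    @property
    def n_traits(self) -> int:
        return self.G0.shape[0]


def default_architecture() -> TraitArchitecture:
    """Two-trait design: h2 = (0.1, 0.5), genetic correlation ~0.30,
    residual correlation ~0.10."""
    return TraitArchitecture(
        G0=np.array([[1.0, 0.67], [0.67, 5.0]]),
        R0=np.array([[9.0, 0.67], [0.67, 5.0]]),
    )


@dataclass(frozen=True)
class ImpliedParameters:
    h2: np.ndarray
    genetic_correlation: np.ndarray
    residual_correlation: np.ndarray


def implied_parameters(arch: TraitArchitecture) -> ImpliedParameters:
    """Heritabilities and correlation matrices implied by (G0, R0)."""
    dg = np.diag(arch.G0)
    dr = np.diag(arch.R0)
    h2 = dg / (dg + dr)

    def corr(C: np.ndarray) -> np.ndarray:
        s = np.sqrt(np.diag(C))
        return C / np.outer(s, s)

    return ImpliedParameters(
        h2=h2,
        genetic_correlation=corr(arch.G0),
        residual_correlation=corr(arch.R0),
    )


@dataclass
class SimulatedDataset:
    """Phenotypes with their true genetic and residual components.

    ``y = a_true + e_true`` holds exactly; ``train_idx`` and ``test_idx``
    partition the animal index set.
    """

    y: np.ndarray
    a_true: np.ndarray
    e_true: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    @property
    def n_animals(self) -> int:
        return self.y.shape[0]

    @property
    def n_traits(self) -> int:
        return self.y.shape[1]


def simulate_traits(
    A: RelationshipMatrix | np.ndarray,
    arch: TraitArchitecture,
    seed: int = 0,
    n_test: int = 0,
) -> SimulatedDataset:
    """Draw one replicate of correlated phenotypes on kinship ``A``.

    ``a = L_A Z B'`` with ``B = chol(G0)`` gives ``cov(vec a) = G0 (x) A``;
    residuals use the identity kinship.  A uniformly random (seeded)
    train/test split withholds ``n_test`` animals.
    """
    if isinstance(A, RelationshipMatrix):
        L_A = A.chol
        n = A.n
    else:
        L_A, _ = cholesky_psd(np.asarray(A, dtype=float))
        n = L_A.shape[0]
    t = arch.n_traits
    if n_test < 0 or n_test >= n:
        raise ValueError("need 0 <= n_test < n_animals")
    rng = np.random.default_rng(seed)
    B_g = np.linalg.cholesky(arch.G0)
    B_r = np.linalg.cholesky(arch.R0)
    a = L_A @ rng.standard_normal((n, t)) @ B_g.T
    e = rng.standard_normal((n, t)) @ B_r.T
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return SimulatedDataset(
        y=a + e,
        a_true=a,
        e_true=e,
        train_idx=train_idx,
        test_idx=test_idx,
        seed=seed,
    )


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    n_animals: int
    n_train: int
    n_test: int
    architecture: TraitArchitecture
    n_replicates: int = 10

    def __post_init__(self) -> None:
        if self.n_train + self.n_test != self.n_animals:
            raise ValueError("n_train + n_test must equal n_animals")


_SCENARIOS = {
    "scenario1": dict(n_animals=2314, n_train=2000, n_test=314),
    "scenario2": dict(n_animals=578, n_train=500, n_test=78),
}


def make_scenario(name: str, scale: float = 1.0) -> ScenarioConfig:
    """The two study designs: scenario1 (2314 animals, 2000/314 split)
    and scenario2 (578 animals, 500/78 split), both with the default
    two-trait architecture and 10 replicates.

    ``scale`` shrinks the animal counts proportionally (preserving the
    train:test ratio up to rounding) for desk-scale runs.
    """
    if name not in _SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {sorted(_SCENARIOS)}"
        )
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    base = _SCENARIOS[name]
    n_animals = max(4, round(base["n_animals"] * scale))
    n_test = max(1, round(base["n_test"] * scale)) if scale < 1.0 else base["n_test"]
    if scale == 1.0:
        n_train = base["n_train"]
    else:
        n_train = n_animals - n_test
    return ScenarioConfig(
        name=name,
        n_animals=n_animals,
        n_train=n_train,
        n_test=n_test,
        architecture=default_architecture(),
        n_replicates=10,
    )
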