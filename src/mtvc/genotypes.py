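"""SNP genotype handling: quality control, the VanRaden genomic relationship
matrix, synthetic genotype panels, and PSD factorization utilities.

Genotypes are coded as counts of the second allele (0, 1 or 2); the
constant :data:`MISSING` (-1) marks missing calls.  The genomic
relationship matrix (GRM) is

    A = M M' / sum_j 2 p_j (1 - p_j),

where ``m_ij = g_ij - 2 p_j`` centers each SNP column at the observed
second-allele frequency ``p_j``.  Missing genotypes are imputed to the
SNP mean ``2 p_j`` (equivalently ``m_ij = 0``) so centering stays exact.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "QCThresholds",
    "RelationshipMatrix",
    "allele_frequencies",
    "hwe_pvalues",
    "qc_filter",
    "compute_grm",
    "cholesky_psd",
    "eigen_psd",
    "synthetic_genotypes",
]


@dataclass
class GenotypeMatrix:
    """An n_animals x n_snps matrix of 0/1/2 genotype codes.

    ``codes`` may contain :data:`MISSING` for missing calls; every other
    entry must be 0, 1 or 2.
    """

    codes: np.ndarray
    animal_ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("genotype codes must be a 2-D array")
        n, m = self.codes.shape
        if n < 2:
            raise ValueError("need at least 2 animals")
        if m < 1:
            raise ValueError("need at least 1 SNP")
        valid = np.isin(self.codes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.codes[~valid])
            raise ValueError(f"invalid genotype codes present: {bad.tolist()}")
        if not self.animal_ids:
            self.animal_ids = [f"animal_{i + 1}" for i in range(n)]
        if not self.snp_ids:
            self.snp_ids = [f"snp_{j + 1}" for j in range(m)]
        if len(self.animal_ids) != n:
            raise ValueError("animal_ids length does not match codes")
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length does not match codes")

    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]


@dataclass(frozen=True)
class QCThresholds:
    """SNP exclusion thresholds: keep a SNP when MAF >= maf_min, call rate
    >= call_rate_min and the Hardy-Weinberg chi-square P-value >= hwe_p_min."""

    maf_min: float = 0.05
    call_rate_min: float = 0.95
    hwe_p_min: float = 0.001

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class RelationshipMatrix:
    """A symmetric PSD genomic kinship matrix with its Cholesky factor.

    ``jitter`` is the non-negative value added to the diagonal before
    factorization succeeded; ``chol`` satisfies
    ``chol @ chol.T == A + jitter * I`` (up to round-off).
    """

    A: np.ndarray
    jitter: float = 0.0
    chol: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise ValueError("A must be symmetric (tolerance 1e-10)")
        if self.chol is None:
            self.chol, self.jitter = cholesky_psd(self.A)

    @property
    def n(self) -> int:
        return self.A.shape[0]


def allele_frequencies(codes: np.ndarray) -> np.ndarray:
    """Observed second-allele frequency per SNP, ignoring missing calls.

    SNPs with zero non-missing calls get frequency NaN.
    """
    codes = np.asarray(codes)
    obs = codes != MISSING
    n_obs = obs.sum(axis=0)
    counts = np.where(obs, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, counts / (2.0 * n_obs), np.nan)
    return p


def hwe_pvalues(codes: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg equilibrium P-values per SNP.

    Chi-square goodness-of-fit with 1 df on observed versus expected
    genotype counts, expectations taken at the observed allele frequency.
    Monomorphic SNPs (or SNPs without calls) return P = 1: there is no
    evidence against equilibrium, and such SNPs are caught by the MAF or
    call-rate rules anyway.
    """
    codes = np.asarray(codes)
    obs = codes != MISSING
    n_obs = obs.sum(axis=0).astype(float)
    n2 = ((codes == 2) & obs).sum(axis=0).astype(float)
    n1 = ((codes == 1) & obs).sum(axis=0).astype(float)
    n0 = n_obs - n1 - n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2.0 * n2 + n1) / (2.0 * n_obs)
    q = 1.0 - p
    e0 = n_obs * q * q
    e1 = n_obs * 2.0 * p * q
    e2 = n_obs * p * p
    chi2 = np.zeros(codes.shape[1])
    ok = (n_obs > 0) & (p > 0) & (p < 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = (
            (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
        )
    chi2[ok] = stat[ok]
    pvals = np.ones(codes.shape[1])
    pvals[ok] = stats.chi2.sf(chi2[ok], df=1)
    return pvals


def qc_filter(
    g: GenotypeMatrix, thr: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop SNPs failing MAF, call-rate or Hardy-Weinberg criteria.

    Returns the filtered panel and the indices of the retained SNPs (in
    their original order).  Raises ``ValueError`` when no SNP survives.
    """
    codes = g.codes
    obs = codes != MISSING
    call_rate = obs.mean(axis=0)
    p = allele_frequencies(codes)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)
    hwe_p = hwe_pvalues(codes)
    keep = (
        (maf >= thr.maf_min)
        & (call_rate >= thr.call_rate_min)
        & (hwe_p >= thr.hwe_p_min)
    )
    kept = np.flatnonzero(keep)
    if kept.size == 0:
        raise ValueError("empty panel: all SNPs removed by quality control")
    filtered = GenotypeMatrix(
        codes=codes[:, kept],
        animal_ids=list(g.animal_ids),
        snp_ids=[g.snp_ids[j] for j in kept],
    )
    return filtered, kept


def compute_grm(g: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from a QC-passed panel.

    Monomorphic SNPs make the denominator term 2p(1-p) vanish and are
    rejected with an error naming the first offending SNP.
    """
    codes = g.codes
    p = allele_frequencies(codes)
    if np.isnan(p).any():
        j = int(np.flatnonzero(np.isnan(p))[0])
        raise ValueError(f"SNP {g.snp_ids[j]} has no non-missing calls")
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        j = int(np.flatnonzero(mono)[0])
        raise ValueError(
            f"monomorphic SNP {g.snp_ids[j]} (p={p[j]:g}); run qc_filter first"
        )
    M = np.where(codes == MISSING, 0.0, codes - 2.0 * p)
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    A = (M @ M.T) / denom
    A = 0.5 * (A + A.T)  # enforce exact symmetry against round-off
    return RelationshipMatrix(A=A)


_JITTER_STEPS = (0.0, 1e-10, 1e-8, 1e-6)


def cholesky_psd(
    A: np.ndarray, jitter_steps: tuple[float, ...] = _JITTER_STEPS
) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of a (possibly semi-definite) symmetric matrix.

    Tries ``A + jitter * I`` with jitter escalating through
    ``jitter_steps * mean(diag(A))`` until factorization succeeds; returns
    the factor and the jitter actually used.  Raises if the matrix is still
    indefinite at the largest jitter, reporting its most negative eigenvalue.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.allclose(A, A.T, atol=1e-8 * max(1.0, np.abs(A).max())):
        raise ValueError("A must be symmetric")
    scale = float(np.mean(np.diag(A)))
    if scale <= 0:
        scale = 1.0
    for step in jitter_steps:
        jitter = step * scale
        try:
            L = np.linalg.cholesky(A + jitter * np.eye(A.shape[0]))
            return L, jitter
        except np.linalg.LinAlgError:
            continue
    lam_min = float(np.linalg.eigvalsh(A)[0])
    raise np.linalg.LinAlgError(
        f"matrix not PSD even after jitter {jitter_steps[-1] * scale:g}; "
        f"most negative eigenvalue {lam_min:g}"
    )


def eigen_psd(A: np.ndarray, floor_rel: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a symmetric PSD matrix with an eigenvalue floor.

    Returns ``(d, U)`` with ``A ~= U @ diag(d) @ U.T`` and every eigenvalue
    clipped from below at ``floor_rel * mean(d)``, mirroring the diagonal
    jitter used for Cholesky factorization of near-singular kinships.
    """
    d, U = np.linalg.eigh(np.asarray(A, dtype=float))
    if d.size == 0:
        return d, U
    floor = floor_rel * max(float(np.mean(np.abs(d))), np.finfo(float).tiny)
    return np.maximum(d, floor), U


def synthetic_genotypes(
    n_animals: int,
    n_snps: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    n_families: int = 0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Generate a synthetic SNP panel, optionally with full-sib families.

    Per-SNP second-allele frequencies are drawn Uniform(maf_low, maf_high).
    Unrelated animals are drawn Binomial(2, p_j) per SNP (Hardy-Weinberg
    proportions).  With ``n_families > 0`` the animals are split into
    full-sib families of (near-)equal size and genotypes are gene-dropped
    from simulated parents, so the resulting GRM carries off-diagonal
    structure (~0.5 within families) emulating a closed nucleus line.

    The drawn frequencies are stashed on the returned object as
    ``true_frequencies`` for simulation-verification purposes.
    """
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if n_families < 0:
        raise ValueError("n_families must be >= 0")
    if n_families > 0 and n_animals < 2 * n_families:
        raise ValueError(
            f"n_animals={n_animals} too small for {n_families} families "
            "(need at least 2 animals per family)"
        )
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=n_snps)
    if n_families == 0:
        codes = rng.binomial(2, p[None, :], size=(n_animals, n_snps))
    else:
        sizes = np.full(n_families, n_animals // n_families)
        sizes[: n_animals % n_families] += 1
        sire = rng.binomial(2, p[None, :], size=(n_families, n_snps))
        dam = rng.binomial(2, p[None, :], size=(n_families, n_snps))
        rows = []
        for f in range(n_families):
            k = int(sizes[f])
            # each parent transmits one allele: Bernoulli(genotype / 2)
            from_sire = rng.binomial(1, sire[f][None, :] / 2.0, size=(k, n_snps))
            from_dam = rng.binomial(1, dam[f][None, :] / 2.0, size=(k, n_snps))
            rows.append(from_sire + from_dam)
        codes = np.concatenate(rows, axis=0)
    g = GenotypeMatrix(codes=codes.astype(np.int8))
    g.true_frequencies = p  # type: ignore[attr-defined]
    return g
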