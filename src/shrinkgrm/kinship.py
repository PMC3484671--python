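"""Realized (genomic) relationship matrix estimation with optional shrinkage.

The additive relationship matrix A is defined on identity-by-state grounds and
scaled so that the mean diagonal element equals 1 + f, where f is the
inbreeding coefficient of the current population.  With the centered genotype
matrix W (W_ik = X_ik - 2 p_k, p_k the allele frequency of marker k) the
high-density estimator is

    A_hat = W W' / (2 sum_k p_k q_k),          q = 1 - p.

When markers are few relative to lines, the n x n covariance of lines across
loci, S = m^-1 W W' - <W.k><W.k>', is a noisy estimate of its genomic
counterpart, and a Ledoit-Wolf-type shrinkage toward the trace-preserving
target T = <S_ii> I reduces its mean-squared error:

    A* = [ delta <S_ii> I + (1 - delta) S + <W.k><W.k>' ] / (2 <p_j q_j>).

Because the target preserves the trace, A* never shrinks the inbreeding
coefficient: tr(A*) is the same for every delta.  The analytically optimal
intensity (Schaefer-Strimmer form) is computed from the row-centered matrix Z:

    delta = m^-2 sum_k ||Z.k Z.k' - S||^2 / ||S - <S_ii> I||^2,

clamped to [0,1], with the numerator evaluated through the elementwise-squared
matrix Gamma = m^-1 [Z^2][Z^2]'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix

__all__ = [
    "CenteredGenotypes",
    "ShrinkageDiagnostics",
    "KinshipMatrix",
    "InbreedingSummary",
    "center_genotypes",
    "sample_covariance",
    "shrinkage_intensity",
    "shrinkage_intensity_raw",
    "kinship_plain",
    "kinship_shrunk",
    "kinship_from_genotypes",
    "heuristic_intensity",
    "eigenvalue_cv",
    "inbreeding_summary",
    "ibs_matrix",
]


@dataclass
class CenteredGenotypes:
    """Centered marker matrix W with allele frequencies and row means.

    ``denom`` is 2 * sum_k p_k q_k, the scaling constant of the plain
    relationship-matrix estimator.
    """

    W: np.ndarray
    p: np.ndarray
    row_means: np.ndarray
    denom: float
    line_ids: list[str]

    @property
    def n_lines(self) -> int:
        return self.W.shape[0]

    @property
    def n_markers(self) -> int:
        return self.W.shape[1]


@dataclass
class ShrinkageDiagnostics:
    """Ingredients of the analytic shrinkage intensity.

    ``delta`` is ``delta_raw`` clamped to [0,1]; ``numerator`` is the
    variance-of-S term (already scaled by m^-1), ``denominator`` the squared
    Frobenius distance between S and its shrinkage target <S_ii> I.
    """

    S: np.ndarray
    delta_raw: float
    delta: float
    target_scale: float
    numerator: float
    denominator: float


@dataclass
class KinshipMatrix:
    """Estimated realized relationship matrix with provenance.

    ``f`` is the population inbreeding coefficient implied by the estimate,
    mean(diag(A)) - 1.  ``delta`` records the shrinkage intensity actually
    used (0 for the plain estimator).
    """

    A: np.ndarray
    line_ids: list[str]
    method: str = "plain"
    delta: float = 0.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        # guard against accumulated asymmetry from BLAS reductions
        self.A = 0.5 * (self.A + self.A.T)

    @property
    def f(self) -> float:
        return float(np.mean(np.diag(self.A)) - 1.0)

    @property
    def n_lines(self) -> int:
        return self.A.shape[0]

    def index_of(self, ids) -> np.ndarray:
        lookup = {lid: i for i, lid in enumerate(self.line_ids)}
        try:
            return np.array([lookup[str(i)] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown line ID {e.args[0]!r}") from None

    def spectral(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition of A (ascending eigenvalues)."""
        if "eigh" not in self._cache:
            self._cache["eigh"] = np.linalg.eigh(self.A)
        return self._cache["eigh"]

    def plot_histograms(self, ax=None, bins=50):
        """Histogram the diagonal and off-diagonal relationship coefficients."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(8, 3))
        off = self.A[~np.eye(self.n_lines, dtype=bool)]
        ax[0].hist(off, bins=bins)
        ax[0].set_xlabel("off-diagonal A_ij")
        ax[1].hist(np.diag(self.A), bins=bins)
        ax[1].set_xlabel("diagonal A_ii")
        return ax


@dataclass
class InbreedingSummary:
    """Per-locus (f_k), per-individual (phi_i) and overall (f) inbreeding.

    The weights beta_k = p_k q_k / sum_j p_j q_j sum to one over polymorphic
    loci, and the two averages agree exactly: f = sum_k beta_k f_k
    = n^-1 sum_i phi_i.
    """

    f_k: np.ndarray
    beta_k: np.ndarray
    phi_i: np.ndarray
    f: float
    line_ids: list[str]
    marker_ids: list[str]


def _require_complete(G: GenotypeMatrix, op: str) -> None:
    if not G.is_complete():
        raise ValueError(
            f"{op} requires complete genotypes; impute missing values first "
            "(impute_population_mean)"
        )


def center_genotypes(G: GenotypeMatrix) -> CenteredGenotypes:
    """Center each marker by twice its allele frequency.

    p_k = (2n)^-1 sum_i X_ik from the observed dosages; W = X - 2p per
    column; ``denom`` = 2 sum_k p_k q_k.
    """
    _require_complete(G, "center_genotypes")
    X = G.values
    p = X.mean(axis=0) / 2.0
    W = X - 2.0 * p
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    return CenteredGenotypes(W, p, W.mean(axis=1), denom, list(G.line_ids))


def sample_covariance(C: CenteredGenotypes) -> np.ndarray:
    """Covariance of lines across loci: S = m^-1 W W' - <W.k><W.k>'."""
    m = C.n_markers
    if m < 1:
        raise ValueError("need at least one marker")
    S = C.W @ C.W.T / m - np.outer(C.row_means, C.row_means)
    return 0.5 * (S + S.T)


def shrinkage_intensity_raw(Z: np.ndarray) -> ShrinkageDiagnostics:
    """Analytic MSE-optimal shrinkage intensity for S = m^-1 Z Z'.

    ``Z`` holds m column observations of a zero-mean n-variate variable.
    The target is <S_ii> I.  The numerator sum_k ||Z.k Z.k' - S||^2 is
    evaluated via Gamma = m^-1 [Z^2][Z^2]' as m * sum_ij (Gamma_ij - S_ij^2).
    A zero denominator (S already proportional to I) yields delta = 0.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("non-finite values in input matrix")
    n, m = Z.shape
    if m < 2:
        raise ValueError("shrinkage intensity needs at least 2 columns")
    S = Z @ Z.T / m
    S = 0.5 * (S + S.T)
    Z2 = Z * Z
    Gamma = Z2 @ Z2.T / m
    numerator = float(np.sum(Gamma - S * S) / m)
    target_scale = float(np.mean(np.diag(S)))
    D = S - target_scale * np.eye(n)
    denominator = float(np.sum(D * D))
    if denominator == 0.0:
        delta_raw = 0.0
    else:
        delta_raw = numerator / denominator
    delta = float(min(1.0, max(0.0, delta_raw)))
    return ShrinkageDiagnostics(S, float(delta_raw), delta, target_scale,
                                numerator, denominator)


def shrinkage_intensity(C: CenteredGenotypes) -> ShrinkageDiagnostics:
    """Shrinkage intensity for genotype data (W adjusted to zero row means)."""
    Z = C.W - C.row_means[:, None]
    return shrinkage_intensity_raw(Z)


def kinship_plain(C: CenteredGenotypes, ids: list[str] | None = None) -> KinshipMatrix:
    """Plain (high-density) estimator A = W W' / (2 sum_k p_k q_k)."""
    if C.denom <= 0:
        raise ValueError("all markers monomorphic: relationship matrix undefined")
    A = C.W @ C.W.T / C.denom
    return KinshipMatrix(A, list(ids) if ids is not None else list(C.line_ids),
                         method="plain", delta=0.0)


def kinship_shrunk(
    C: CenteredGenotypes,
    ids: list[str] | None = None,
    delta: float | str = "auto",
) -> KinshipMatrix:
    """Shrinkage estimator of the realized relationship matrix.

    A* = [delta <S_ii> I + (1-delta) S + <W.k><W.k>'] / (2 <p_j q_j>).

    With ``delta="auto"`` the analytic MSE-optimal intensity is used.  At
    delta = 0 this reproduces the plain estimator exactly, and tr(A*) is the
    same for every delta (the target preserves the trace), so the inbreeding
    coefficient is never shrunk.
    """
    if C.denom <= 0:
        raise ValueError("all markers monomorphic: relationship matrix undefined")
    if isinstance(delta, str):
        if delta != "auto":
            raise ValueError(f"delta must be a number in [0,1] or 'auto', got {delta!r}")
        delta_val = shrinkage_intensity(C).delta
    else:
        delta_val = float(delta)
        if not 0.0 <= delta_val <= 1.0:
            raise ValueError(f"delta must lie in [0,1], got {delta_val}")
    S = sample_covariance(C)
    n = C.n_lines
    target_scale = float(np.mean(np.diag(S)))
    numer = (delta_val * target_scale * np.eye(n)
             + (1.0 - delta_val) * S
             + np.outer(C.row_means, C.row_means))
    mean_pq = C.denom / (2.0 * C.n_markers)  # <p_j q_j>
    A = numer / (2.0 * mean_pq)
    return KinshipMatrix(A, list(ids) if ids is not None else list(C.line_ids),
                         method="shrunk", delta=delta_val)


def kinship_from_genotypes(
    G: GenotypeMatrix, method: str = "plain", delta: float | str = "auto"
) -> KinshipMatrix:
    """Convenience path from a complete GenotypeMatrix to a KinshipMatrix."""
    C = center_genotypes(G)
    if method == "plain":
        return kinship_plain(C)
    if method == "shrunk":
        return kinship_shrunk(C, delta=delta)
    raise ValueError(f"unknown method {method!r}; use 'plain' or 'shrunk'")


def heuristic_intensity(n: int, m: int, cv: float) -> float:
    """Order-of-magnitude shrinkage heuristic delta ~ n / (m CV^2).

    ``cv`` is the coefficient of variation of the eigenvalues of S.  The
    value is deliberately not clamped; n/m << CV^2 signals that shrinkage
    is negligible.
    """
    if n <= 0 or m <= 0:
        raise ValueError("n and m must be positive")
    if cv <= 0:
        raise ValueError("cv must be positive")
    return float(n) / (float(m) * cv * cv)


def eigenvalue_cv(S: np.ndarray) -> float:
    """Coefficient of variation (1 = 100%) of the eigenvalues of S.

    Uses the population (n-divisor) standard deviation over all n
    eigenvalues.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if np.max(np.abs(S - S.T)) > 1e-8 * max(1.0, np.max(np.abs(S))):
        raise ValueError("S must be symmetric")
    lam = np.linalg.eigvalsh(S)
    mean = lam.mean()
    if mean <= 0:
        raise ValueError("mean eigenvalue must be positive")
    return float(lam.std() / mean)


def inbreeding_summary(G: GenotypeMatrix) -> InbreedingSummary:
    """Per-locus, per-individual and overall IBS inbreeding coefficients.

    The per-locus coefficient is the standardized homozygosity excess

        f_k = sum_i (X_ik - 2 p_k)^2 / (2 n p_k q_k) - 1,

    which for integer dosages equals the intra-individual gametic
    correlation (write X = x1 + x2 with binary gametes; the cross term is
    the correlation and the squared-gamete terms sum to 2 n p_k q_k).  The
    per-individual analog is phi_i = sum_k (X_ik - 2p_k)^2 / (2 sum_j p_j q_j)
    - 1, i.e. the diagonal of the plain relationship matrix minus one.  With
    weights beta_k = p_k q_k / sum_j p_j q_j the two averages coincide
    exactly, for integer or imputed real dosages alike:

        f = sum_k beta_k f_k = n^-1 sum_i phi_i = <A_ii> - 1.

    Monomorphic loci get f_k = 0 and beta_k = 0.  When every allele
    frequency is 1/2, phi_i reduces to 2*psi - 1 with psi the individual's
    homozygous fraction.
    """
    _require_complete(G, "inbreeding_summary")
    X = G.values
    n = X.shape[0]
    p = X.mean(axis=0) / 2.0
    pq = p * (1.0 - p)
    poly = pq > 0
    if not poly.any():
        raise ValueError("all loci monomorphic: inbreeding undefined")
    sum_pq = float(pq.sum())
    D2 = (X - 2.0 * p) ** 2
    f_k = np.zeros(X.shape[1])
    f_k[poly] = D2[:, poly].sum(axis=0) / (2.0 * n * pq[poly]) - 1.0
    beta_k = pq / sum_pq
    phi_i = D2.sum(axis=1) / (2.0 * sum_pq) - 1.0
    f = float(beta_k @ f_k)
    return InbreedingSummary(f_k, beta_k, phi_i, f, list(G.line_ids),
                             list(G.marker_ids))


def ibs_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Marker identity-in-state coefficients, 1/2 (m^-1 X_sym X_sym' + J).

    ``X_sym`` is the symmetric {-1,0,1} coding (dosage - 1) and J the
    all-ones matrix.  For fully homozygous lines, entry (i,j) is the fraction
    of loci at which the two lines carry the same genotype.
    """
    _require_complete(G, "ibs_matrix")
    Xs = G.values - 1.0
    m = G.n_markers
    B = 0.5 * (Xs @ Xs.T / m + 1.0)
    return 0.5 * (B + B.T)
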