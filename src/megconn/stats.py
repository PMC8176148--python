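"""Covariate-adjusted group contrasts with permutation inference and FDR.

Each analysis unit (a seed's band power, or one connectome edge's AEC)
is tested with a one-way ANCOVA — group effect adjusted for age and
head motion — whose F statistic is referenced to a permutation null.
Because the covariates break simple label exchangeability, permutations
follow the Freedman–Lane scheme: the outcome is residualised on the
covariates, the residuals are permuted (the same permutation sequence
for every unit, for spatial coherence of the map) and the covariate fit
is added back before recomputing F.  P-values use the add-one
convention and are corrected across units with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .bands import BAND_NAMES


@dataclass
class CovariateTable:
    """Per-subject design information: group indicator plus nuisances."""

    group: np.ndarray  # 1 = patient (mtbi), 0 = control
    age: np.ndarray
    head_motion: np.ndarray

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.head_motion = np.asarray(self.head_motion, dtype=float)
        n = self.group.size
        if self.age.size != n or self.head_motion.size != n:
            raise ValueError("covariate arrays must have equal length")
        if not np.all(np.isfinite(np.concatenate([self.group, self.age, self.head_motion]))):
            raise ValueError("covariates contain missing values")
        if len(np.unique(self.group)) != 2:
            raise ValueError("both groups must be present")

    @property
    def n(self) -> int:
        return self.group.size

    @classmethod
    def from_metadata(cls, metadata) -> "CovariateTable":
        """Build from a list of SubjectMetadata (patients coded 1)."""
        return cls(
            group=np.array([1.0 if m.group == "mtbi" else 0.0 for m in metadata]),
            age=np.array([m.age for m in metadata]),
            head_motion=np.array([m.head_motion for m in metadata]),
        )


def _design_matrices(covars: CovariateTable) -> tuple[np.ndarray, np.ndarray]:
    ones = np.ones(covars.n)
    X_full = np.column_stack([ones, covars.group, covars.age, covars.head_motion])
    X_red = np.column_stack([ones, covars.age, covars.head_motion])
    return X_full, X_red


def _residual_maker(X: np.ndarray) -> np.ndarray:
    """I - X (X'X)^-1 X', via pinv for numerical safety."""
    return np.eye(X.shape[0]) - X @ np.linalg.pinv(X)


def ancova_f(y: np.ndarray, covars: CovariateTable) -> float:
    """ANCOVA F for the group effect adjusted for age and head motion.

    F = ((RSS_reduced - RSS_full) / 1) / (RSS_full / (n - 4)) with the
    full model {intercept, group, age, motion} and the reduced model
    dropping group.
    """
    y = np.asarray(y, dtype=float)
    n = covars.n
    if y.size != n:
        raise ValueError("outcome length does not match covariate table")
    if n <= 4:
        raise ValueError("need more than 4 subjects for the ANCOVA")
    X_full, X_red = _design_matrices(covars)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    rss_full = np.sum((_residual_maker(X_full) @ y) ** 2)
    rss_red = np.sum((_residual_maker(X_red) @ y) ** 2)
    scale = np.sum((y - y.mean()) ** 2)
    tol = 1e-12 * scale + (1e-13 * n * np.max(np.abs(y))) ** 2 + 1e-300
    if rss_full <= tol:  # perfect (or degenerate) full-model fit
        return 0.0 if rss_red <= tol else np.inf
    return float((rss_red - rss_full) / (rss_full / (n - 4)))


def adjusted_group_difference(y: np.ndarray, covars: CovariateTable) -> float:
    """Group coefficient of the full model (patient minus control, adjusted)."""
    X_full, _ = _design_matrices(covars)
    beta, *_ = np.linalg.lstsq(X_full, np.asarray(y, dtype=float), rcond=None)
    return float(beta[1])


def permutation_pvalues(
    feature_matrix: np.ndarray,
    covars: CovariateTable,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Freedman–Lane permutation p-values for every unit (column).

    All units share the same seeded permutation sequence.  Returns a
    DataFrame with observed F, permutation p (add-one convention, never
    zero) and the adjusted effect direction.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(rng)
    Y = np.atleast_2d(np.asarray(feature_matrix, dtype=float))
    if Y.shape[0] != covars.n:
        Y = Y.T
    n, n_units = Y.shape
    X_full, X_red = _design_matrices(covars)
    R_full = _residual_maker(X_full)
    R_red = _residual_maker(X_red)
    dof = n - X_full.shape[1]

    Yc = Y - Y.mean(axis=0)
    # per-unit degeneracy scale: relative to outcome variance, with an
    # absolute floor at the rounding error of the raw magnitudes
    amax = np.max(np.abs(Y), axis=0)
    tol = 1e-12 * np.sum(Yc**2, axis=0) + (1e-13 * n * amax) ** 2 + 1e-300

    def f_stats(E: np.ndarray) -> np.ndarray:
        # E are reduced-model residuals of the (permuted) outcome; the
        # full/reduced RSS of the Freedman-Lane surrogate depend only on E.
        rss_red = np.sum((R_red @ E) ** 2, axis=0)
        rss_full = np.sum((R_full @ E) ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (rss_red - rss_full) / (rss_full / dof)
        return np.where(rss_full <= tol, np.where(rss_red <= tol, 0.0, np.inf), f)

    E_obs = R_red @ Y
    f_obs = f_stats(E_obs)
    exceed = np.zeros(n_units)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        exceed += f_stats(E_obs[perm]) >= f_obs
    p = (1.0 + exceed) / (1.0 + n_perm)

    direction = np.array([adjusted_group_difference(Y[:, u], covars) for u in range(n_units)])
    return pd.DataFrame({"F": f_obs, "p_perm": p, "direction": np.sign(direction)})


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (adjusted p-values, significance mask)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def wilcoxon_ranksum(y: np.ndarray, group: np.ndarray) -> tuple[float, float, float]:
    """Mann–Whitney U with tie-corrected normal approximation: (U, z, p)."""
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    a, b = y[group == 1], y[group != 1]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    ranks = sps.rankdata(y)
    U = float(np.sum(ranks[group == 1]) - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(y, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return U, 0.0, 1.0
    z = (U - mu) / np.sqrt(sigma2)
    p = 2 * sps.norm.sf(abs(z))
    return U, float(z), float(p)


def _stat_map(
    Y: np.ndarray,
    covars: CovariateTable,
    unit_ids: list,
    n_perm: int,
    q: float,
    rng,
) -> pd.DataFrame:
    df = permutation_pvalues(Y, covars, n_perm=n_perm, rng=rng)
    p_adj, reject = bh_fdr(df["p_perm"].to_numpy(), q)
    df.insert(0, "unit", unit_ids)
    df["p_fdr"] = p_adj
    df["significant"] = reject
    return df


def contrast_power(
    band_table: pd.DataFrame,
    covars: CovariateTable,
    subject_order: list[str],
    n_perm: int = 10_000,
    q: float = 0.05,
    rng: np.random.Generator | int | None = None,
    bands: tuple[str, ...] = BAND_NAMES,
) -> dict[str, pd.DataFrame]:
    """Per-band seed-wise ANCOVA maps with FDR within band.

    ``band_table`` is the long-format subject x seed x band power table;
    ``subject_order`` fixes the row order matching ``covars``.
    """
    rng = np.random.default_rng(rng)
    out = {}
    for band in bands:
        sub = band_table[band_table["band"] == band]
        wide = sub.pivot(index="subject_id", columns="seed", values="power")
        wide = wide.loc[subject_order]
        out[band] = _stat_map(
            wide.to_numpy(), covars, list(wide.columns), n_perm, q, rng
        )
    return out


def upper_triangle_edges(n_seeds: int) -> list[tuple[int, int]]:
    """Deterministic (i < j) edge ordering of the connectome."""
    return [(i, j) for i in range(n_seeds) for j in range(i + 1, n_seeds)]


def contrast_connectivity(
    conn: np.ndarray,
    covars: CovariateTable,
    n_perm: int = 10_000,
    q: float = 0.05,
    rng: np.random.Generator | int | None = None,
    band_names: tuple[str, ...] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-band edge-wise ANCOVA maps on vectorised upper triangles.

    ``conn`` is (n_subjects, n_bands, n_seeds, n_seeds); 90 seeds give
    4005 unique edges per band.  FDR is applied within band across all
    edges.
    """
    rng = np.random.default_rng(rng)
    n_subjects, n_bands, n_seeds, _ = conn.shape
    edges = upper_triangle_edges(n_seeds)
    iu = np.triu_indices(n_seeds, k=1)
    band_names = band_names or BAND_NAMES[:n_bands]
    out = {}
    for b, name in enumerate(band_names):
        Y = conn[:, b][:, iu[0], iu[1]]  # (subjects, 4005)
        out[name] = _stat_map(Y, covars, edges, n_perm, q, rng)
    return out
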