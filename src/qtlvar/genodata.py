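"""Genotype coding, kinship construction and table I/O.

Genotypes at a biallelic locus are coded +1 (A1A1), 0 (A1A2) and -1 (A2A2).
Before model fitting the code vector is standardized to sample mean 0 and
sample variance 1 so that the variance contributed by the locus equals the
squared allele-substitution effect.  Marker-inferred kinship matrices are
normalized so that their trace equals the sample size, which makes the
polygenic variance component interpretable on the same scale as the residual
variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeVector",
    "KinshipMatrix",
    "GenotypeFrequencies",
    "Tables",
    "standardize_genotypes",
    "genotype_moments",
    "classical_qtl_variance",
    "kinship_from_markers",
    "fullsib_numerator_matrix",
    "read_tables",
]

#: valid raw genotype codes for a biallelic locus
RAW_CODES = (1, 0, -1)


def standardize_genotypes(raw_codes, name: str | None = None) -> np.ndarray:
    """Standardize a genotype code vector to mean 0 and sample variance 1.

    Uses the (n-1)-denominator sample standard deviation so the sum of
    squared deviations of the result equals n-1, which makes the sampling
    variance of a single-marker regression coefficient equal sigma^2/(n-1)
    and ties the corrected heritability exactly to the adjusted R-squared.

    Missing values (NaN) are mean-imputed before standardization and logged.
    Idempotent: standardizing an already standardized vector returns it
    unchanged (up to floating point).

    Parameters
    ----------
    raw_codes : array-like
        Per-individual genotype codes; typically in {+1, 0, -1} but any
        numeric vector (e.g. expected codes at pseudo markers) is accepted.
    name : str, optional
        Marker label used in error messages.

    Raises
    ------
    ValueError
        If fewer than 3 individuals or the marker is monomorphic.
    """
    z = np.asarray(raw_codes, dtype=float).ravel()
    label = name if name is not None else "marker"
    if z.size < 3:
        raise ValueError(f"{label}: need at least 3 individuals, got {z.size}")
    if np.isnan(z).any():
        n_missing = int(np.isnan(z).sum())
        logger.warning("%s: mean-imputing %d missing genotype code(s)", label, n_missing)
        z = np.where(np.isnan(z), np.nanmean(z), z)
    sd = z.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError(f"{label}: monomorphic (all codes identical), cannot standardize")
    return (z - z.mean()) / sd


@dataclass
class GenotypeVector:
    """Raw and standardized genotype codes for one marker.

    Attributes
    ----------
    raw_codes : ndarray
        Codes per individual, +1/0/-1 for the three ordered genotypes.
    standardized : ndarray
        Mean-0, sample-variance-1 transform of ``raw_codes``.
    name : str
        Marker label.
    """

    raw_codes: np.ndarray
    standardized: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = "marker"

    def __post_init__(self):
        self.raw_codes = np.asarray(self.raw_codes, dtype=float).ravel()
        if self.standardized is None:
            self.standardized = standardize_genotypes(self.raw_codes, name=self.name)
        else:
            self.standardized = np.asarray(self.standardized, dtype=float).ravel()
            if self.standardized.shape != self.raw_codes.shape:
                raise ValueError(f"{self.name}: raw and standardized lengths differ")
        if np.unique(self.raw_codes[~np.isnan(self.raw_codes)]).size < 2:
            raise ValueError(f"{self.name}: monomorphic marker")
        m, v = self.standardized.mean(), self.standardized.var(ddof=1)
        if abs(m) > 1e-10 or abs(v - 1.0) > 1e-10:
            raise ValueError(
                f"{self.name}: standardized codes have mean {m:.2e}, variance {v:.6f}; "
                "expected mean 0 and sample variance 1"
            )

    @property
    def n(self) -> int:
        return self.raw_codes.size

    @classmethod
    def from_codes(cls, raw_codes, name: str = "marker") -> "GenotypeVector":
        raw = np.asarray(raw_codes, dtype=float).ravel()
        return cls(raw_codes=raw, standardized=standardize_genotypes(raw, name=name), name=name)


@dataclass
class KinshipMatrix:
    """An n-by-n additive relationship (numerator) or marker kinship matrix.

    Must be symmetric and positive semidefinite.  When ``normalized`` the
    trace equals n, the convention used throughout for marker-inferred
    kinship.
    """

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        K = np.asarray(self.values, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError(f"kinship matrix must be square, got shape {K.shape}")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric (tolerance 1e-10)")
        K = 0.5 * (K + K.T)
        w = np.linalg.eigvalsh(K)
        if w[0] < -1e-8 * max(w[-1], 1.0):
            raise ValueError(
                f"kinship matrix is not positive semidefinite (min eigenvalue {w[0]:.3e})"
            )
        if self.normalized and abs(np.trace(K) - K.shape[0]) > 1e-8:
            raise ValueError(
                f"normalized kinship must have trace n={K.shape[0]}, got {np.trace(K):.8f}"
            )
        self.values = K

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def normalize(self) -> "KinshipMatrix":
        """Rescale so that the trace equals the sample size."""
        tr = np.trace(self.values)
        if tr <= 0:
            raise ValueError("cannot normalize a kinship matrix with non-positive trace")
        return KinshipMatrix(self.values * (self.n / tr), normalized=True)


@dataclass
class GenotypeFrequencies:
    """Hardy-Weinberg genotype frequencies at a biallelic locus."""

    p: float
    q: float = field(init=False)
    P: float = field(init=False)
    H: float = field(init=False)
    Q: float = field(init=False)

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"allele frequency must be in [0, 1], got {self.p}")
        self.q = 1.0 - self.p
        self.P = self.p * self.p
        self.H = 2.0 * self.p * self.q
        self.Q = 1.0 - (self.P + self.H)  # enforce exact P + H + Q = 1


def genotype_moments(freq: GenotypeFrequencies) -> tuple[float, float]:
    """Mean and variance of the +1/0/-1 genotype code under Hardy-Weinberg.

    Returns (p - q, 2pq): the code equals (number of A1 alleles) - 1, so its
    mean is p - q and its variance the binomial 2pq.
    """
    return freq.p - freq.q, 2.0 * freq.p * freq.q


def classical_qtl_variance(freq: GenotypeFrequencies, alpha: float) -> float:
    """Classical additive QTL variance 2*p*q*alpha^2 for substitution effect alpha."""
    return 2.0 * freq.p * freq.q * alpha * alpha


def kinship_from_markers(marker_matrix) -> KinshipMatrix:
    """Marker-inferred kinship: standardized cross-product rescaled to trace n.

    Each marker column is standardized (mean 0, sample variance 1); monomorphic
    columns are dropped with a warning.  K = W W^T rescaled so tr(K) = n.

    Parameters
    ----------
    marker_matrix : array-like of shape (n_individuals, n_markers)
        Raw genotype codes.
    """
    M = np.asarray(marker_matrix, dtype=float)
    if M.ndim != 2:
        raise ValueError("marker matrix must be 2-dimensional (individuals x markers)")
    n, m = M.shape
    if n < 2 or m < 1:
        raise ValueError(f"need at least 2 individuals and 1 marker, got {n} x {m}")
    sd = M.std(axis=0, ddof=1)
    poly = sd > 0
    if not poly.any():
        raise ValueError("all markers are monomorphic; kinship is undefined")
    if not poly.all():
        logger.warning("dropping %d monomorphic marker(s) from kinship", int((~poly).sum()))
    W = (M[:, poly] - M[:, poly].mean(axis=0)) / sd[poly]
    K = W @ W.T
    K *= n / np.trace(K)
    return KinshipMatrix(K, normalized=True)


def fullsib_numerator_matrix(n_families: int, m_sibs: int) -> KinshipMatrix:
    """Block-diagonal additive relationship matrix for full-sib families.

    Each family block of size ``m_sibs`` has 1 on the diagonal and the
    full-sib additive relationship 1/2 off the diagonal; families are
    unrelated.  The trace equals n_families * m_sibs by construction.
    """
    if n_families < 1 or m_sibs < 1:
        raise ValueError("n_families and m_sibs must both be >= 1")
    block = np.full((m_sibs, m_sibs), 0.5)
    np.fill_diagonal(block, 1.0)
    n = n_families * m_sibs
    A = np.zeros((n, n))
    for f in range(n_families):
        s = f * m_sibs
        A[s : s + m_sibs, s : s + m_sibs] = block
    return KinshipMatrix(A, normalized=True)


@dataclass
class Tables:
    """Aligned in-memory inputs for model fitting and genome scans."""

    y: np.ndarray
    covariates: pd.DataFrame | None
    markers: pd.DataFrame  # individuals x markers, raw codes
    kinship: KinshipMatrix | None
    map: pd.DataFrame | None
    ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.y.size


def _read_delim(path) -> pd.DataFrame:
    # delimiter sniffing fails on single-column files; peek at the header
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def _read_kinship(path, n: int) -> KinshipMatrix:
    df = _read_delim(path)
    # tolerate leading bookkeeping columns (e.g. 'parm', 'row') used by some
    # mixed-model software kinship layouts
    drop = [c for c in df.columns if str(c).strip().lower() in {"parm", "row", "id"}]
    df = df.drop(columns=drop)
    K = df.to_numpy(dtype=float)
    if K.shape != (n, n):
        raise ValueError(
            f"kinship file {path}: expected a {n} x {n} matrix, got {K.shape[0]} x {K.shape[1]}"
        )
    return KinshipMatrix(K)


def _read_map(path) -> pd.DataFrame:
    df = _read_delim(path)
    cols = {str(c).strip().lower(): c for c in df.columns}
    try:
        marker = cols.get("marker", cols.get("bin", cols.get("id")))
        chrom = cols["chromosome"] if "chromosome" in cols else cols["chr"]
        pos = next(cols[k] for k in ("position", "cm", "position_cm", "pos") if k in cols)
    except (KeyError, StopIteration) as exc:
        raise ValueError(
            f"map file {path}: need columns (marker, chromosome, position-in-cM), got {list(df.columns)}"
        ) from exc
    out = pd.DataFrame(
        {
            "marker": df[marker].astype(str),
            "chromosome": df[chrom],
            "position": df[pos].astype(float),
        }
    )
    out = out.sort_values(["chromosome", "position"], kind="stable").reset_index(drop=True)
    for ch, grp in out.groupby("chromosome"):
        if grp["position"].diff().dropna().le(0).any():
            raise ValueError(f"map file {path}: positions not strictly increasing on chromosome {ch}")
    return out


def _geno_frame(df: pd.DataFrame, n: int, id_col: str | None, path) -> pd.DataFrame:
    cols = {str(c).strip().lower(): c for c in df.columns}
    marker_col = cols.get("marker", cols.get("bin"))
    if marker_col is not None:
        # long layout: one row per individual x marker, sorted by marker
        code_col = next((cols[k] for k in ("z0", "code", "z") if k in cols), None)
        if code_col is None:
            raise ValueError(f"genotype file {path}: long layout needs a 'z0' (or 'code'/'z') column")
        wide = {}
        for mk, grp in df.groupby(marker_col, sort=False):
            if len(grp) != n:
                raise ValueError(
                    f"genotype file {path}: marker {mk} has {len(grp)} records, expected {n}"
                )
            wide[str(mk)] = grp[code_col].to_numpy(dtype=float)
        return pd.DataFrame(wide)
    drop = [id_col] if id_col is not None and id_col in df.columns else []
    geno = df.drop(columns=drop)
    if len(geno) != n:
        raise ValueError(f"genotype file {path}: {len(geno)} rows, expected {n} individuals")
    try:
        return geno.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"genotype file {path}: unreadable genotype codes ({exc})") from exc


def read_tables(
    pheno_path,
    geno_path,
    kinship_path=None,
    map_path=None,
    *,
    trait: str = "y",
    covariates: tuple[str, ...] = (),
    id_col: str | None = None,
) -> Tables:
    """Read aligned phenotype/genotype (and optional kinship/map) tables.

    Delimited text (comma or tab, header row).  The phenotype file holds one
    row per individual with the trait column (default ``y``) and any covariate
    columns.  The genotype file is either wide (one column of raw codes per
    marker, optionally an id column) or long with (marker|bin, z0) columns
    sorted by marker, one block of n rows per marker.  The kinship file is a
    square matrix keyed by row order; leading 'parm'/'row' bookkeeping columns
    are ignored.  The map file has (marker, chromosome, position-in-cM)
    columns and is returned sorted by chromosome then position.
    """
    pheno = _read_delim(pheno_path)
    if trait not in pheno.columns:
        raise ValueError(f"phenotype file {pheno_path}: no trait column '{trait}'")
    missing = [c for c in covariates if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype file {pheno_path}: missing covariate column(s) {missing}")
    y = pheno[trait].to_numpy(dtype=float)
    n = y.size
    cov = pheno[list(covariates)].astype(float) if covariates else None
    ids = pheno[id_col].to_numpy() if id_col is not None and id_col in pheno.columns else None

    markers = _geno_frame(_read_delim(geno_path), n, id_col, geno_path)
    kin = _read_kinship(kinship_path, n) if kinship_path is not None else None
    map_df = _read_map(map_path) if map_path is not None else None
    if map_df is not None:
        unknown = set(map_df["marker"]) - set(map(str, markers.columns))
        if unknown:
            raise ValueError(f"map file {map_path}: markers absent from genotype table: {sorted(unknown)[:5]}")
    return Tables(y=y, covariates=cov, markers=markers, kinship=kin, map=map_df, ids=ids)
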