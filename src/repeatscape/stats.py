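"""Comparative statistics: abundance matrices, correlation tests, PCA,
genome-size calibration.

Cluster abundances are read proportions per sample; multiplying by haploid
genome size (picograms, converted at 978 Mb/pg) turns them into Mb of
sequence per haploid genome, the scale on which abundances are compared
across species and reconstructed on the phylogeny. Correlations are Pearson
product-moment tests with exact two-sided Student-t p-values; the PCA is run
on variance-standardized items so every cluster carries equal weight; and
flow-cytometry signal intensities are converted to genome sizes by an
ordinary least-squares calibration against published C-values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .simulate import MB_PER_PG

SEX_COLUMN_PATTERN = r"^(?P<species>.+)_(?P<sex>[A-Za-z]+)$"


@dataclass
class CorrelationResult:
    r: float
    n: int
    df: int
    t: float
    p: float
    r_is_unit: bool = False  # |r| = 1: p reported as the limiting 0


@dataclass
class PCAResult:
    loadings: np.ndarray  # items x components
    scores: np.ndarray  # cases x components
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    items: list[str]


@dataclass
class CalibrationFit:
    slope: float
    intercept: float
    adjusted_r2: float
    predicted_pg: np.ndarray


def t_to_p(t: float, df: int) -> float:
    """Two-sided Student-t tail probability via the regularized incomplete beta.

    P = I_{df/(df+t^2)}(df/2, 1/2).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = float(t)
    return float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))


def pearson_test(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with exact t and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has undefined correlation")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = min(1.0, max(-1.0, r))
    df = n - 2
    if abs(r) >= 1.0 - 1e-14:
        return CorrelationResult(r=r, n=n, df=df, t=np.inf * np.sign(r),
                                 p=0.0, r_is_unit=True)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return CorrelationResult(r=r, n=n, df=df, t=float(t), p=t_to_p(t, df))


def average_sex_columns(matrix: pd.DataFrame,
                        pattern: str = SEX_COLUMN_PATTERN) -> pd.DataFrame:
    """Average male/female sample columns into one column per species.

    Columns are expected to follow ``<species>_<sex>``; the regex is
    configurable. Averaging identical columns is idempotent.
    """
    rx = re.compile(pattern)
    groups: dict[str, list[str]] = {}
    for col in matrix.columns:
        m = rx.match(str(col))
        species = m.group("species") if m else str(col)
        groups.setdefault(species, []).append(col)
    out = {sp: matrix[cols].mean(axis=1) for sp, cols in groups.items()}
    return pd.DataFrame(out, index=matrix.index)


def abundance_to_mb(matrix: pd.DataFrame,
                    genome_sizes_pg: dict[str, float]) -> pd.DataFrame:
    """Convert read proportions to Mb per haploid genome.

    cell_Mb = proportion x genome size (pg) x 978 Mb/pg.
    """
    missing = [c for c in matrix.columns if c not in genome_sizes_pg]
    if missing:
        raise ValueError(f"missing genome size(s) for sample(s): {missing}")
    sizes = pd.Series({c: genome_sizes_pg[c] for c in matrix.columns})
    return matrix.mul(sizes * MB_PER_PG, axis=1)


def pca_standardized(matrix: pd.DataFrame) -> PCAResult:
    """PCA on variance-standardized items (eigen-decomposition of the item
    correlation matrix).

    ``matrix`` is cases x items. With standardized items the eigenvalues sum
    to the number of items, so an eigenvalue above unity marks a component
    explaining more variance than any single item. Loading signs are fixed by
    making each vector's largest-magnitude element positive.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 cases and 2 items")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [str(c) for c, s in zip(matrix.columns, sd) if s == 0]
        raise ValueError(f"constant item(s): {bad}")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    return PCAResult(
        loadings=eigvec,
        scores=z @ eigvec,
        eigenvalues=eigval,
        variance_fractions=eigval / eigval.sum(),
        items=[str(c) for c in matrix.columns],
    )


def calibrate_genome_size(signal, published_pg) -> CalibrationFit:
    """Least-squares calibration of genome size (pg) on flow-cytometry signal."""
    signal = np.asarray(signal, dtype=float)
    published_pg = np.asarray(published_pg, dtype=float)
    n = len(signal)
    if n < 3 or len(published_pg) != n:
        raise ValueError("need >= 3 calibration points of equal length")
    fit = sps.linregress(signal, published_pg)
    r2 = fit.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return CalibrationFit(slope=float(fit.slope), intercept=float(fit.intercept),
                          adjusted_r2=float(adj),
                          predicted_pg=fit.slope * signal + fit.intercept)


def predict_genome_size(fit: CalibrationFit, signal) -> np.ndarray:
    return fit.slope * np.asarray(signal, dtype=float) + fit.intercept


def abundance_matrix(clusters, total_reads_by_sample: dict[str, int],
                     top_k: int = 15) -> pd.DataFrame:
    """Clusters x samples matrix of read proportions from joint clusters.

    Each cell is the fraction of a sample's analyzed reads that fell into the
    cluster; rows are the ``top_k`` most abundant clusters.
    """
    rows = {}
    for c in sorted(clusters, key=lambda c: c.cluster_id)[:top_k]:
        per_sample: dict[str, int] = {}
        for rid in c.members:
            sample = rid.split("|")[0]
            per_sample[sample] = per_sample.get(sample, 0) + 1
        rows[c.cluster_id] = {
            s: per_sample.get(s, 0) / total_reads_by_sample[s]
            for s in total_reads_by_sample
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
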